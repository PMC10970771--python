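# Methods

`mircog` re-implements, as a tested and reusable pipeline, a two-phase
plasma-miRNA biomarker analysis for cognitive decline in Parkinson's disease
(PD): a **discovery phase** that screens a supersaturated small-RNA-seq count
matrix for group-discriminative miRNAs with a Dantzig-type linear-programming
selector, and a **validation phase** that quantifies a candidate miRNA by
droplet digital PCR (ddPCR) as a target/reference ratio and evaluates it with
rank statistics and logistic ROC models. Because patient-level data of this
kind are typically not public, the package ships a synthetic-data generator
that emulates both study designs, so every stage is exercised end to end.

## Discovery phase

### Count preprocessing

Input is a raw miRNA × sample read-count matrix over four clinical groups
(HC, PDND, PD-MCI, PDD; MoCA bands ≥26 / ≥26 / 22–25 / ≤21) sequenced in two
batches. The processing chain is:

1. **Missing-value imputation.** Missing entries (stored as absent, not
   zero) are set to 0 before any normalisation.
2. **TMM normalisation** (trimmed mean of M-values, Robinson–Oshlack). Per
   sample, M-values (log2 expression ratios vs a reference sample) and
   A-values (average log abundance) are formed over miRNAs nonzero in both
   samples; the M-distribution is trimmed by 30% per tail and the
   A-distribution by 5% per tail (the method's canonical defaults — the trim
   fractions are a free parameter here); the scaling factor is the weighted
   mean of surviving M-values with weights equal to the inverse delta-method
   binomial variance of M; factors are rescaled to geometric mean 1. The
   reference sample is the one whose upper-quartile of library-scaled counts
   is closest to the mean upper-quartile. The implementation agrees with
   edgeR's `calcNormFactors(method="TMM")` to ~1e-6 (cross-checked in the
   test suite via Rscript).
3. **log2 CPM transform.** `value = log2(count / (libsize · f) · 1e6 + 1)`.
   The +1 pseudocount avoids −∞ at zero counts and is configurable.
4. **Low-expression trimming.** Within each batch, miRNAs are ranked by mean
   normalised value; the union of the per-batch bottom 10% is removed.
   "Lowest expressed" is defined as the within-batch mean of the normalised
   log2 values — the simplest batch-local summary.
5. **Batch adjustment.** Per miRNA, each batch's values are mean-centred and
   shifted to the pooled per-miRNA mean. This location-only correction
   replaces surrogate-variable analysis, which is out of scope; it is exact
   for the location-only batch model the generator produces, and that is
   precisely what the tests can certify. Real batch effects with
   scale or rank-deficient structure are *not* removed by it.

The group fold-change statistic is `log2(mean(case)/mean(control))` computed
on linear-scale normalised reads (CPM), i.e. the log of the ratio of group
means, not the mean of log ratios. Whether the original analysis used raw,
CPM or TMM-scaled means is not documented; the choice here is recorded and
configurable.

### The selector

With X the standardized (mean 0, sd 1, ddof = 1) expression matrix over the
two contrasted groups and Yc the centered 0/1 response, the selector solves,
for each δ on a grid,

    min ‖β‖₁   s.t.   ‖Xᵀ(Yc − Xβ)‖∞ ≤ δ

— the Dantzig selector LP on the centered binary response. The LP is solved
with HiGHS through `scipy.optimize.linprog`, using the positive/negative
part split plus an auxiliary fitted-value variable z = Xβ that keeps the
constraint matrix sparse (O(np) nonzeros instead of a dense p×p Gram
block); this is what makes the p ≫ n case fast (~70 ms at n = 60, p = 500).
The solution is identically zero for δ ≥ δmax = max|XᵀYc|, so the grid is
15 uniformly spaced points on (0, δmax] — δ = 0 is excluded because it can
be infeasible for p < n, and δmax is included so every grid point is
guaranteed feasible.

A *linear* rather than logistic score constraint is used deliberately: the
scheme standardizes X, centers Y, and bounds the grid by max|XᵀY| — exactly
the quantity at which the linear Dantzig solution degenerates to zero. The
logistic model enters only as the classifier built on the selected features.
A linearized logistic-score variant would change the constraint to
Xᵀ(Y − p(β)); this is left as a possible extension, not a config default.

δ is tuned by stratified 5-fold cross-validation (stratification is not
documented in the original scheme but is necessary at ~23 cases per class to
avoid single-class test folds). Within each fold the training columns are
re-standardized; the LP runs on training rows; features with |β| > 1e-8 feed
a logistic classifier scored by test-fold AUC. The classifier uses a tiny
ridge (1e-6, configurable) because perfect separation is routine on
48-sample training folds; the ridge only stabilises the fit and leaves the
score ordering (hence AUC) essentially untouched. Folds with no selected
feature score AUC 0.5 by convention. The best δ maximises mean AUC, ties
resolving to the larger (sparser) δ.

The final full-data solution path over [best δ, δmax] ranks candidates by
**shrink-to-zero order**: the last coefficient to leave the active set as δ
grows is the most important. Ties (same shrink-to-zero grid point) break by
|β| at that point, then by |XᵀYc|, then by feature order — a deterministic
rule chosen so the ranking is reproducible; the original scheme does not
specify one.

## Validation phase

### ddPCR quantification

Each well partitions ~15,000 droplets of ~0.85 nL (QX200 convention;
configurable). With k of N droplets positive, the undiluted concentration is
`c = −ln(1 − k/N)/V_d · D` (copies/µL) for dilution factor D. QC requires
N > 10,000 accepted droplets and k > 3 positives; the thresholds are printed
with copies/µL units in the source protocol but describe droplet counts
(10,000 is the conventional accepted-droplet floor) — a config switch
applies them to concentrations instead. Failing wells are flagged and their
samples excluded with an explicit reason, never silently dropped.

The biomarker is the ratio of back-diluted concentrations
miR-203a-3p (1:10) / miR-16-5p (1:320); computing it on as-measured
concentrations would change it only by the constant 320/10, so the choice
matters solely for cross-study comparability. The exogenous spike-in UniSp6
monitors extraction efficiency: a Kruskal–Wallis test of miR-16-5p/UniSp6
across groups should *not* reject; p < 0.05 raises a warning.

Per clinical group, ratios outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
(linear-interpolation quantiles) are flagged as outliers and excluded from
downstream statistics while remaining in the record.

### Statistics and models

Group comparison uses the tie-corrected Kruskal–Wallis test (chi-square
approximation) followed by Dunn's pairwise z tests with Bonferroni-style
multiply-by-m adjustment capped at 1 (Holm available); adjusted p ≥ 0.9999
displays as "> 0.9999", matching the reporting convention of the commercial
software this emulates. Spearman correlations (mid-ranks; two-sided p via
the t approximation on n−2 df) relate the ratio to the MoCA total and its
seven domains within the PD patients, with no multiplicity adjustment —
matching the presentation being reproduced.

Dementia is dichotomised as MoCA ≤ 21. Logistic models over the candidate
predictors {age, gender, onset age, education, UPDRS III, ratio} are fit by
damped Newton/IRLS maximum likelihood (convergence |Δcoef| < 1e-8, ≤ 100
iterations, optional ridge that stabilises the Hessian without entering the
reported likelihood; perfect separation is detected and raised). Model
reduction is an *exhaustive* smallest-AIC search over all ≤ 63 non-empty
subsets — exhaustive beats stepwise and is cheap at six candidates; ties
prefer fewer predictors, then lexicographic order.

Evaluation: a 70/30 split stratified by the dementia label (the 5-fold CV on
the 70% side is used only as a stability check; final coefficients are refit
on the full training side), ROC on the test side with AUC computed as the
Mann–Whitney statistic (ties ½), the operating point maximising
sensitivity + specificity over the observed cut-points (ties toward higher
specificity — a deterministic rule the source does not specify), and 95%
class-stratified percentile bootstrap confidence intervals with B = 2000.

### Power computation

The a-priori sample size reproduces a G*Power-style fixed-effects one-way
ANOVA calculation: power = P(F′ > F_crit) with F′ noncentral F(k−1, N−k,
λ = f²·N) — the total-N noncentrality convention. For Cohen's f = 0.5,
α = 0.05, power 0.8, k = 4 groups the minimum total N is 48
(power(48) = 0.803, power(47) = 0.793).

## Synthetic data

The generator's defaults are the published study conditions; everything else
is a fixed, documented choice.

**Discovery** (`DiscoveryDesign`): 40/37/23/23 subjects (HC/PDND/PD-MCI/PDD),
2600 miRNAs, two batches of 53/70 (the two sequencing runs held 75 and 99
samples *including* an out-of-scope disease cohort; 53/70 is the
proportional split of the 123 in-scope samples). Baseline log2 relative
abundances are N(0, 3) — giving the strongly skewed abundance profile of
plasma miRNA-seq; counts are negative binomial with overdispersion 0.2
(typical for miRNA-seq biological replicates) on per-sample library sizes
uniform in [0.5M, 2M] (MiSeq scale); per-batch per-miRNA multiplicative
log2 biases are N(0, 0.25), drawn once per batch — location-only, matching
the location-only adjustment downstream; planted effects multiply the case
group's mean by 2^effect; 2% of entries are dropped to missing so the
imputation rule is exercised downstream rather than pre-applied.

**Validation** (`ValidationDesign`): 30 subjects per group. True ratios are
drawn from group-wise lognormals **moment-matched** to the published
means/SDs (HC 1.21e-3 ± 6.42e-4, PDND 1.03e-3 ± 5.89e-4, PD-MCI
8.66e-4 ± 5.65e-4, PDD 1.68e-3 ± 1.01e-3). Lognormal because ratios are
positive and right-skewed, and the PDD SD is ~60% of its mean — a normal
truncated at zero would distort the matched moments. The distributional
family of the real ratios is unknown; this is a modelling choice, not an
inference about the cohort. The undiluted miR-16-5p concentration is uniform
on [2e4, 1e5] copies/µL times a lognormal(0, 0.15) extraction efficiency
shared with the UniSp6 spike (5e4 copies/µL), so the miR-16-5p/UniSp6 check
is null by construction; the miR-203a-3p concentration is ratio × reference.
Wells realise `Binomial(N, 1 − exp(−c_diluted·V_d))` droplet counts.
Covariates follow the published group summaries: mean ± SD variables are
normal; median ± IQR variables (MoCA, Hoehn–Yahr, UPDRS III) are normal with
sd = IQR/1.349, rounded to the scale's step and clipped to its legal range;
MoCA totals are additionally clipped to the diagnostic band of the group,
and the seven domain scores are obtained by multinomially distributing the
total deficit across domains proportionally to each domain's maximum.

What the generator does **not** emulate: sequencing-level artefacts (UMIs,
adapters, mapping ambiguity), non-location batch effects, covariate-ratio
dependence beyond group structure, droplet rain/misclassification, and
between-well replicate variance. Passing tests therefore certify the
*analysis machinery* under the stated statistical model, not performance on
real cohorts; in particular the six published candidate miRNAs and the
published Table-level numbers cannot be reproduced without the patient data.

## Numerical choices

- Active-set tolerance on standardized coefficients: 1e-8; LP feasibility
  re-verified to 1e-6 after each solve.
- IRLS: step-halving on the penalised deviance; linear predictors clipped at
  ±35 inside the weights so the Hessian never becomes exactly singular;
  separation detected as saturation of every fitted probability.
- Quantiles (IQR rule, TMM reference choice): linear interpolation
  (`numpy.percentile` default); the convention of the original software is
  unknown, so it is recorded in config.
- Degenerate inputs: zero-variance features are dropped with a warning before
  standardization; all-identical samples give H = 0, p = 1; empty candidate
  sets are a valid selector outcome (warning, empty report).
- Seeds: a single pipeline seed fans out to per-stage seeds via
  `numpy.random.SeedSequence`, so stages can be rerun in isolation and
  every output is reproducible byte for byte.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the discovery recovery
experiment at p = 500 features as a surrogate for the ~2600 of the real
study (the selector's cost is dominated by the LP, which scales with n·p;
p = 2600 changes nothing qualitatively, and a full-size run is a one-line
design change); recovery uses 20 seeds, the validation directional check
100 seeds, the Kruskal–Wallis type-I simulation 2000 replications, and the
bootstrap-coverage simulation 300–500 outer replications at B = 2000.

## Known limitations

- The batch adjustment is location-only by design; it is not SVA.
- The selector's ranking can list fewer than six candidates when
  cross-validation favours a large δ; that is a faithful outcome of the
  scheme, not a failure mode.
- Spearman p-values use the t approximation throughout (standard at n ≥ 30);
  an exact permutation option would be preferable below n ≈ 10.
- The AIC search treats predictors marginally; interactions and nonlinear
  terms are out of scope.
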