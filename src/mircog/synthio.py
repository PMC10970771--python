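"""Synthetic discovery and validation datasets.

Emulates the statistical structure the two-phase analysis assumes, so every
downstream stage is exercisable without patient data:

* discovery — a supersaturated negative-binomial count matrix (~2600 plasma
  miRNAs over four clinical groups sequenced in two batches) with per-sample
  library sizes, per-batch multiplicative log2 bias, a configurable set of
  planted group-discriminative log2 effects, and missing entries stored as
  absent (NaN), not zero;
* validation — a four-group ddPCR cohort whose per-subject true
  miR-203a-3p/miR-16-5p ratios are drawn from group-wise lognormals moment-
  matched to the published means/SDs, realised as droplet counts
  ``Binomial(N, 1 - exp(-c_diluted * V_d))`` per well, together with
  clinical covariates (age, sex, education, onset, duration, Hoehn-Yahr,
  UPDRS III, LEDD, MoCA total + 7 domains) matched to the published
  group summaries, with MoCA totals clipped to the diagnostic bands.

Everything is reproducible element-for-element from the design seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ddpcr_quant import (
    DEFAULT_DROPLET_VOLUME_UL,
    REFERENCE_ASSAY,
    SPIKEIN_ASSAY,
    TARGET_ASSAY,
    DdpcrWell,
)
from .ngs_preprocess import CountMatrix

GROUPS = ("HC", "PDND", "PD-MCI", "PDD")
PD_GROUPS = ("PDND", "PD-MCI", "PDD")

#: MoCA diagnostic bands used for grouping (total score)
MOCA_BANDS = {"HC": (26, 30), "PDND": (26, 30), "PD-MCI": (22, 25), "PDD": (0, 21)}

#: maximum score per MoCA domain (sums to 30)
MOCA_DOMAIN_MAX = {
    "visuospatial": 5,
    "naming": 3,
    "attention": 6,
    "language": 3,
    "abstraction": 2,
    "memory": 5,
    "orientation": 6,
}

#: convert a printed IQR to a normal sd (IQR of N(0,1) is ~1.349)
IQR_TO_SD = 1.0 / 1.349


@dataclass(frozen=True)
class PlantedEffect:
    """A group-discriminative log2 mean shift on one miRNA.

    The case group's mean is multiplied by ``2**log2_effect``; all other
    groups stay at baseline, so the case-vs-control fold change equals
    ``log2_effect`` in expectation.
    """

    mirna_index: int
    case_group: str
    control_group: str
    log2_effect: float


@dataclass
class DiscoveryDesign:
    """Study conditions of the discovery-phase simulator."""

    n_per_group: dict = field(
        default_factory=lambda: {"HC": 40, "PDND": 37, "PD-MCI": 23, "PDD": 23}
    )
    p_mirnas: int = 2600
    batch_sizes: tuple[int, int] = (53, 70)
    planted: list[PlantedEffect] = field(default_factory=list)
    libsize_range: tuple[float, float] = (5e5, 2e6)
    dispersion: float = 0.2  # NB overdispersion: var = mu + dispersion * mu^2
    abundance_log2_sd: float = 3.0  # spread of baseline log2 relative abundance
    batch_log2_shift: float = 0.25  # sd of the per-batch per-miRNA log2 bias
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("every group needs n >= 2")
        if sum(self.batch_sizes) != sum(self.n_per_group.values()):
            raise ValueError("batch_sizes must partition the samples")
        for eff in self.planted:
            if not 0 <= eff.mirna_index < self.p_mirnas:
                raise ValueError(f"planted index {eff.mirna_index} >= p_mirnas")
            if not np.isfinite(eff.log2_effect):
                raise ValueError("planted effect sizes must be finite")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class ValidationDesign:
    """Study conditions of the ddPCR validation-phase simulator.

    ``ratio_mean_sd`` defaults to the published group means/SDs of the
    miR-203a-3p/miR-16-5p ratio; covariate parameters default to the
    published group summaries (mean +/- SD, or median +/- IQR for MoCA,
    Hoehn-Yahr and UPDRS III).
    """

    n_per_group: dict = field(default_factory=lambda: {g: 30 for g in GROUPS})
    ratio_mean_sd: dict = field(
        default_factory=lambda: {
            "HC": (1.21e-3, 6.42e-4),
            "PDND": (1.03e-3, 5.89e-4),
            "PD-MCI": (8.66e-4, 5.65e-4),
            "PDD": (1.68e-3, 1.01e-3),
        }
    )
    male_fraction: dict = field(
        default_factory=lambda: {"HC": 0.5667, "PDND": 0.5667, "PD-MCI": 0.5333, "PDD": 0.4667}
    )
    age_mean_sd: dict = field(
        default_factory=lambda: {
            "HC": (66.67, 5.14),
            "PDND": (69.67, 7.03),
            "PD-MCI": (70.13, 6.75),
            "PDD": (75.20, 6.92),
        }
    )
    education_mean_sd: dict = field(
        default_factory=lambda: {
            "HC": (14.13, 4.13),
            "PDND": (14.13, 2.79),
            "PD-MCI": (11.47, 4.75),
            "PDD": (10.73, 4.64),
        }
    )
    onset_mean_sd: dict = field(
        default_factory=lambda: {
            "PDND": (63.53, 7.96),
            "PD-MCI": (64.13, 7.96),
            "PDD": (67.37, 8.71),
        }
    )
    duration_mean_sd: dict = field(
        default_factory=lambda: {
            "PDND": (7.10, 3.91),
            "PD-MCI": (6.90, 3.07),
            "PDD": (7.23, 4.75),
        }
    )
    ledd_mean_sd: dict = field(
        default_factory=lambda: {
            "PDND": (682.54, 438.75),
            "PD-MCI": (747.78, 398.03),
            "PDD": (765.82, 419.36),
        }
    )
    moca_median_iqr: dict = field(
        default_factory=lambda: {
            "HC": (28.0, 2.0),
            "PDND": (28.0, 1.25),
            "PD-MCI": (23.0, 1.0),
            "PDD": (17.5, 7.0),
        }
    )
    hy_median_iqr: dict = field(
        default_factory=lambda: {"PDND": (2.0, 1.0), "PD-MCI": (2.0, 1.0), "PDD": (3.0, 2.0)}
    )
    updrs_median_iqr: dict = field(
        default_factory=lambda: {
            "PDND": (13.0, 12.0),
            "PD-MCI": (18.5, 9.0),
            "PDD": (27.0, 22.0),
        }
    )
    reference_conc_range: tuple[float, float] = (2e4, 1e5)  # copies/uL, undiluted miR-16-5p
    spikein_conc: float = 5e4  # copies/uL UniSp6 spike level before extraction loss
    extraction_log_sd: float = 0.15  # lognormal sd of per-sample extraction efficiency
    droplets_per_well: int = 15_000
    dilution_target: float = 10.0
    dilution_reference: float = 320.0
    dilution_spikein: float = 320.0
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (m, s) in self.ratio_mean_sd.items():
            if m <= 0 or s < 0:
                raise ValueError(f"ratio mean must be > 0 and sd >= 0 for {g}")
        for d in (self.dilution_target, self.dilution_reference, self.dilution_spikein):
            if d < 1:
                raise ValueError("dilution factors must be >= 1")
        if self.droplets_per_well < 1:
            raise ValueError("droplets_per_well must be >= 1")


def _design_from_json(cls, path: str | Path):
    data = json.loads(Path(path).read_text())
    if cls is DiscoveryDesign and "planted" in data:
        data["planted"] = [PlantedEffect(**p) for p in data["planted"]]
    for key in ("batch_sizes", "libsize_range", "reference_conc_range"):
        if key in data:
            data[key] = tuple(data[key])
    if "ratio_mean_sd" in data:
        data["ratio_mean_sd"] = {g: tuple(v) for g, v in data["ratio_mean_sd"].items()}
    return cls(**data)


def load_discovery_design(path: str | Path) -> DiscoveryDesign:
    return _design_from_json(DiscoveryDesign, path)


def load_validation_design(path: str | Path) -> ValidationDesign:
    return _design_from_json(ValidationDesign, path)


# -- discovery ---------------------------------------------------------------


def generate_discovery(design: DiscoveryDesign) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts + sample sheet for the discovery phase."""
    rng = np.random.default_rng(design.seed)
    groups = [g for g in design.n_per_group for _ in range(design.n_per_group[g])]
    n = len(groups)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    mirna_ids = [f"miR-sim-{i + 1:04d}" for i in range(design.p_mirnas)]

    perm = rng.permutation(n)
    batch = np.empty(n, dtype=object)
    batch[perm[: design.batch_sizes[0]]] = "batch1"
    batch[perm[design.batch_sizes[0] :]] = "batch2"

    log2_abund = rng.normal(0.0, design.abundance_log2_sd, size=design.p_mirnas)
    props = 2.0**log2_abund
    props /= props.sum()
    lib = rng.uniform(*design.libsize_range, size=n)
    batch_shift = {
        b: rng.normal(0.0, design.batch_log2_shift, size=design.p_mirnas)
        for b in ("batch1", "batch2")
    }

    log2_effect = np.zeros((design.p_mirnas, n))
    group_arr = np.array(groups)
    for eff in design.planted:
        log2_effect[eff.mirna_index, group_arr == eff.case_group] += eff.log2_effect

    mu = props[:, None] * lib[None, :] * 2.0**log2_effect
    for j in range(n):
        mu[:, j] *= 2.0 ** batch_shift[batch[j]]

    if design.dispersion > 0:
        size = 1.0 / design.dispersion
        counts = rng.negative_binomial(size, size / (size + mu)).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)

    if design.missing_rate > 0:
        mask = rng.random(counts.shape) < design.missing_rate
        counts[mask] = np.nan

    counts_df = pd.DataFrame(counts, index=mirna_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "batch": batch}
    ).set_index("sample_id")
    return CountMatrix(counts_df, samples["batch"]), samples.reset_index()


# -- validation --------------------------------------------------------------


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and sd (moments)."""
    if sd == 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def simulate_well(
    concentration: float,
    dilution: float,
    n_droplets: int,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "sim",
    assay: str = TARGET_ASSAY,
) -> DdpcrWell:
    """One ddPCR well: positives ~ Binomial(N, 1 - exp(-(c/D) V_d))."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if dilution < 1:
        raise ValueError("dilution must be >= 1")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_pos = -np.expm1(-(concentration / dilution) * droplet_volume)
    k = int(rng.binomial(n_droplets, p_pos))
    return DdpcrWell(
        sample_id=sample_id,
        assay=assay,
        total_droplets=n_droplets,
        positive_droplets=k,
        dilution=dilution,
        droplet_volume=droplet_volume,
    )


def _moca_domains(total: int, rng: np.random.Generator) -> dict[str, int]:
    """Distribute the deficit (30 - total) across the seven domains."""
    domains = list(MOCA_DOMAIN_MAX)
    scores = {d: MOCA_DOMAIN_MAX[d] for d in domains}
    deficit = 30 - int(total)
    maxima = np.array([MOCA_DOMAIN_MAX[d] for d in domains], dtype=float)
    while deficit > 0:
        room = np.array([scores[d] for d in domains], dtype=float)
        probs = np.where(room > 0, maxima, 0.0)
        probs /= probs.sum()
        take = rng.multinomial(deficit, probs)
        applied = 0
        for d, t in zip(domains, take):
            dec = min(int(t), scores[d])
            scores[d] -= dec
            applied += dec
        deficit -= applied
    return scores


def _rounded_clipped(
    rng: np.random.Generator,
    median: float,
    iqr: float,
    n: int,
    lo: float,
    hi: float,
    step: float = 1.0,
) -> np.ndarray:
    """Normal(median, IQR/1.349), rounded to ``step`` and clipped to [lo, hi]."""
    draw = rng.normal(median, iqr * IQR_TO_SD, size=n)
    return np.clip(np.round(draw / step) * step, lo, hi)


def generate_validation(
    design: ValidationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ddPCR well table + clinical cohort table (without measured ratios).

    Per subject: a true ratio is drawn from its group's moment-matched
    lognormal, the undiluted miR-16-5p concentration from
    ``reference_conc_range`` (times a lognormal extraction efficiency shared
    with the UniSp6 spike-in), and the miR-203a-3p concentration as
    ratio x reference. One well per assay realises droplet counts. The
    cohort table carries the covariates and the ground-truth ``true_ratio``
    (a synthetic-only column; real cohorts have no such thing).
    """
    rng = np.random.default_rng(design.seed)
    well_rows: list[dict] = []
    cohort_rows: list[dict] = []
    counter = 0
    for g in GROUPS:
        n_g = design.n_per_group.get(g, 0)
        if n_g == 0:
            continue
        mu_ln, sd_ln = lognormal_params(*design.ratio_mean_sd[g])
        lo_band, hi_band = MOCA_BANDS[g]
        for _ in range(n_g):
            counter += 1
            sid = f"V{counter:03d}"
            true_ratio = float(np.exp(rng.normal(mu_ln, sd_ln))) if sd_ln > 0 else float(
                np.exp(mu_ln)
            )
            efficiency = float(np.exp(rng.normal(0.0, design.extraction_log_sd)))
            conc_ref = float(rng.uniform(*design.reference_conc_range)) * efficiency
            conc_target = true_ratio * conc_ref
            conc_spike = design.spikein_conc * efficiency

            for assay, conc, dil in (
                (TARGET_ASSAY, conc_target, design.dilution_target),
                (REFERENCE_ASSAY, conc_ref, design.dilution_reference),
                (SPIKEIN_ASSAY, conc_spike, design.dilution_spikein),
            ):
                well = simulate_well(
                    conc, dil, design.droplets_per_well, design.droplet_volume,
                    rng=rng, sample_id=sid, assay=assay,
                )
                well_rows.append(
                    {
                        "sample_id": sid,
                        "assay": assay,
                        "dilution": dil,
                        "total_droplets": well.total_droplets,
                        "positive_droplets": well.positive_droplets,
                    }
                )

            age = float(rng.normal(*design.age_mean_sd[g]))
            sex = "M" if rng.random() < design.male_fraction[g] else "F"
            education = float(np.clip(rng.normal(*design.education_mean_sd[g]), 0, None))
            moca_total = int(
                _rounded_clipped(rng, *design.moca_median_iqr[g], 1, lo_band, hi_band)[0]
            )
            domains = _moca_domains(moca_total, rng)
            row = {
                "sample_id": sid,
                "group": g,
                "age": round(age, 1),
                "sex": sex,
                "education": round(education, 1),
                "moca_total": moca_total,
                "true_ratio": true_ratio,
            }
            if g in PD_GROUPS:
                onset = float(rng.normal(*design.onset_mean_sd[g]))
                duration = float(np.clip(rng.normal(*design.duration_mean_sd[g]), 0.1, None))
                row.update(
                    {
                        "onset_age": round(onset, 1),
                        "duration": round(duration, 1),
                        "hy": float(
                            _rounded_clipped(rng, *design.hy_median_iqr[g], 1, 1, 5, step=0.5)[0]
                        ),
                        "updrs3": int(
                            _rounded_clipped(rng, *design.updrs_median_iqr[g], 1, 0, 108)[0]
                        ),
                        "ledd": round(
                            float(np.clip(rng.normal(*design.ledd_mean_sd[g]), 0, None)), 1
                        ),
                    }
                )
            else:
                row.update(
                    {"onset_age": np.nan, "duration": np.nan, "hy": np.nan,
                     "updrs3": np.nan, "ledd": np.nan}
                )
            for d, score in domains.items():
                row[f"moca_{d}"] = score
            cohort_rows.append(row)

    wells = pd.DataFrame(well_rows)
    cohort = pd.DataFrame(cohort_rows)
    return wells, cohort


# -- file dialect ------------------------------------------------------------


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """counts.tsv: integer reads, empty cell = missing."""
    out = matrix.counts.copy()
    out.to_csv(path, sep="\t", float_format="%.0f", na_rep="")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_wells(wells: pd.DataFrame, path: str | Path) -> None:
    wells.to_csv(path, index=False)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def design_to_json(design, path: str | Path) -> None:
    data = asdict(design)
    Path(path).write_text(json.dumps(data, indent=2, default=list))
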