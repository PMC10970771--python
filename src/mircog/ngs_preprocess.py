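"""Discovery-phase count preprocessing.

Turns a raw miRNA x sample read-count matrix into the TMM-normalised,
low-expression-trimmed, batch-adjusted log2 expression matrix that feeds the
selector, and computes the group fold-change statistic
``log2(mean(case) / mean(control))`` on linear-scale normalised reads.

TMM (trimmed mean of M-values) follows the Robinson-Oshlack formulation:
per-sample scaling factors from a weighted trimmed mean of per-miRNA log2
expression ratios (M) against a reference sample, double-trimmed by M and by
average log abundance (A), weighted by the inverse asymptotic variance of M,
and rescaled to geometric mean 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: canonical TMM trim fractions: 30% of M-values, 5% of A-values per tail
LOGRATIO_TRIM = 0.30
SUM_TRIM = 0.05

#: pseudocount added to CPM before the log2 transform (avoids -inf at zero)
CPM_PSEUDOCOUNT = 1.0


@dataclass
class CountMatrix:
    """Raw reads (miRNA x sample); NaN marks a missing entry, not a zero."""

    counts: pd.DataFrame
    batch: pd.Series  # per-sample batch label, indexed by sample id

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate miRNA or sample identifiers")
        if not set(self.counts.columns) <= set(self.batch.index):
            raise ValueError("every sample needs a batch label")
        self.batch = self.batch.loc[self.counts.columns]
        present = self.counts.to_numpy()
        if np.nanmin(present, initial=0) < 0 or not np.all(
            np.isfinite(present[~np.isnan(present)])
        ):
            raise ValueError("counts must be finite and non-negative where present")


@dataclass
class NormalizedMatrix:
    """TMM-normalised log2 CPM values with the factors that produced them."""

    values: pd.DataFrame  # miRNA x sample, log2 scale
    tmm_factors: pd.Series
    lib_sizes: pd.Series
    batch: pd.Series

    def linear(self) -> pd.DataFrame:
        """Back-transform to linear-scale normalised reads (CPM)."""
        return 2.0**self.values - CPM_PSEUDOCOUNT


def impute_missing(matrix: CountMatrix) -> CountMatrix:
    """Replace missing entries by 0; nothing else changes."""
    return CountMatrix(matrix.counts.fillna(0.0), matrix.batch.copy())


def _quantile_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose upper-quartile (of scaled counts) is closest to the mean."""
    f75 = np.array(
        [np.quantile(counts[:, j], 0.75) / lib_sizes[j] for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(
    matrix: CountMatrix,
    reference_sample: str | None = None,
    logratio_trim: float = LOGRATIO_TRIM,
    sum_trim: float = SUM_TRIM,
) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    miRNAs with a zero count in either the sample or the reference are
    excluded from that pair's M/A computation. Weights are the inverse
    asymptotic (delta-method binomial) variance of M.
    """
    counts = matrix.counts
    if counts.isna().any().any():
        raise ValueError("impute missing values before TMM")
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if np.any(lib <= 0):
        bad = list(counts.columns[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")

    if reference_sample is None:
        ref_j = _quantile_reference(arr, lib)
    else:
        ref_j = counts.columns.get_loc(reference_sample)
    ref = arr[:, ref_j]
    n_ref = lib[ref_j]

    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        obs = arr[:, j]
        n_obs = lib[j]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            continue
        o, r = obs[keep], ref[keep]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        # delta-method (binomial) variance of M; weights are its inverse
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if trimmed.sum() == 0:
            continue
        factors[j] = 2.0 ** (
            np.sum(m[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
        )

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_log2(matrix: CountMatrix, factors: pd.Series) -> NormalizedMatrix:
    """log2 CPM on the TMM-effective library:
    ``log2(count / (libsize * factor) * 1e6 + 1)``."""
    counts = matrix.counts
    if counts.isna().any().any():
        raise ValueError("impute missing values before normalising")
    factors = factors.loc[counts.columns]
    if np.any(factors.to_numpy() <= 0):
        raise ValueError("TMM factors must be positive")
    lib = counts.sum(axis=0)
    cpm = counts / (lib * factors) * 1e6
    values = np.log2(cpm + CPM_PSEUDOCOUNT)
    return NormalizedMatrix(values, factors, lib, matrix.batch.copy())


def trim_low_expressed(
    matrix: NormalizedMatrix, q: float = 0.10
) -> tuple[NormalizedMatrix, dict]:
    """Remove the union of each batch's lowest-expressed ``q`` fraction.

    "Lowest expressed" is the within-batch mean of the normalised log2
    values; the bottom ``floor(q * p)`` miRNAs per batch form the per-batch
    set and the union is dropped. Returns the trimmed matrix and a report
    of removed identifiers per batch.
    """
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    batches = matrix.batch.unique()
    if len(batches) < 2:
        raise ValueError("need >= 2 batches")
    p = matrix.values.shape[0]
    n_bottom = int(np.floor(q * p))
    report: dict = {"per_batch": {}, "removed": []}
    union: set[str] = set()
    for b in batches:
        cols = matrix.batch.index[matrix.batch == b]
        means = matrix.values[cols].mean(axis=1)
        order = np.argsort(means.to_numpy(), kind="stable")
        bottom = list(matrix.values.index[order[:n_bottom]])
        report["per_batch"][str(b)] = bottom
        union.update(bottom)
    report["removed"] = sorted(union)
    keep = [g for g in matrix.values.index if g not in union]
    return (
        NormalizedMatrix(
            matrix.values.loc[keep], matrix.tmm_factors, matrix.lib_sizes, matrix.batch
        ),
        report,
    )


def batch_adjust(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Location-only batch correction.

    Per miRNA, each batch's values are mean-centred and shifted to the
    pooled per-miRNA mean, which is left unchanged. Single-sample batches
    are passed through with a warning (their mean is not estimable).
    """
    values = matrix.values.copy()
    pooled = values.mean(axis=1)
    for b in matrix.batch.unique():
        cols = matrix.batch.index[matrix.batch == b]
        if len(cols) < 2:
            warnings.warn(f"batch {b!r} has a single sample; passed through unadjusted")
            continue
        sub = values[cols]
        values[cols] = sub.sub(sub.mean(axis=1), axis=0).add(pooled, axis=0)
    return NormalizedMatrix(values, matrix.tmm_factors, matrix.lib_sizes, matrix.batch)


def fold_change(
    matrix: NormalizedMatrix,
    groups: pd.Series,
    case_label: str,
    control_label: str,
) -> pd.Series:
    """Per-miRNA ``log2(mean(case) / mean(control))`` on linear-scale reads.

    Undefined (control mean 0) entries are reported as NaN.
    """
    case_cols = groups.index[groups == case_label]
    control_cols = groups.index[groups == control_label]
    if len(case_cols) == 0 or len(control_cols) == 0:
        raise ValueError("both groups must be non-empty")
    linear = matrix.linear()
    case_mean = linear[case_cols].mean(axis=1)
    control_mean = linear[control_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(case_mean / control_mean)
    fc[control_mean == 0] = np.nan
    return pd.Series(fc, index=matrix.values.index, name=f"log2FC_{case_label}_vs_{control_label}")


def preprocess_pipeline(
    matrix: CountMatrix, q: float = 0.10
) -> tuple[NormalizedMatrix, dict]:
    """impute -> TMM -> log2 CPM -> trim -> batch-adjust, deterministically."""
    imputed = impute_missing(matrix)
    factors = tmm_factors(imputed)
    normalized = normalize_log2(imputed, factors)
    trimmed, report = trim_low_expressed(normalized, q=q)
    return batch_adjust(trimmed), report


# -- file dialect ------------------------------------------------------------


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read counts.tsv (rows = miRNAs; empty cell = missing) + samples.tsv."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    samples = samples.set_index("sample_id")
    return CountMatrix(counts, samples["batch"])


def write_normalized(matrix: NormalizedMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def write_trim_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
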