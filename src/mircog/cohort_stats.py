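"""Nonparametric group comparison and correlation machinery.

Used in both study phases: the Kruskal-Wallis omnibus test (tie-corrected,
chi-square approximation), Dunn's post hoc pairwise z tests with a
multiply-by-m (Bonferroni) adjustment capped at 1, and Spearman rank
correlations of the miRNA ratio against the MoCA total and its seven
cognitive domains. All statistics are rank-based (mid-ranks for ties) and
therefore invariant under strictly monotone transforms of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MOCA_DOMAINS = (
    "visuospatial",
    "naming",
    "attention",
    "language",
    "abstraction",
    "memory",
    "orientation",
)


@dataclass
class CorrelationReport:
    variable: str
    spearman_r: float
    p_value: float
    n: int


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    ``H' = H / (1 - sum(t^3 - t) / (N^3 - N))`` with ``t`` the tie-group
    sizes; p from chi-square with (groups - 1) df.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if pooled.size < len(arrays) + 1:
        raise ValueError("too few observations")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(
    samples: Mapping[str, Sequence[float]],
    adjustment: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise z tests on mid-ranks, with multiplicity adjustment.

    For groups i, j:
        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
        T = sum(t^3 - t) / (12 (N - 1)).
    Two-sided p from the standard normal; 'bonferroni' multiplies by the
    number of pairs and caps at 1 (the paper-style "> 0.9999" report);
    'holm' is the step-down alternative.
    """
    names = list(samples)
    arrays = {g: np.asarray(samples[g], dtype=float) for g in names}
    pooled = np.concatenate([arrays[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    offset = 0
    for g in names:
        n_g = arrays[g].size
        mean_ranks[g] = float(ranks[offset : offset + n_g].mean())
        offset += n_g

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    pairs = list(combinations(names, 2))
    for g1, g2 in pairs:
        n1, n2 = arrays[g1].size, arrays[g2].size
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": p_raw})
    table = pd.DataFrame(rows)

    m = len(pairs)
    if adjustment == "bonferroni":
        table["p_adjusted"] = np.minimum(1.0, m * table["p_raw"])
    elif adjustment == "holm":
        order = np.argsort(table["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank_idx, i in enumerate(order):
            running = max(running, (m - rank_idx) * table["p_raw"].iloc[i])
            adj[i] = min(1.0, running)
        table["p_adjusted"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    table["p_display"] = [format_p(p) for p in table["p_adjusted"]]
    return table


def format_p(p: float) -> str:
    """GraphPad-style display: adjusted p >= 0.9999 prints as '> 0.9999'."""
    if p >= 0.9999:
        return "> 0.9999"
    return f"{p:.4g}"


def spearman(x: Sequence[float], y: Sequence[float], variable: str = "") -> CorrelationReport:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    r is the Pearson correlation of mid-ranks; p from
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 df, with r = +/-1 mapped to p = 0.
    Zero variance in either vector yields NaN r and p.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have the same length")
    if xa.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationReport(variable, float("nan"), float("nan"), int(xa.size))
    r, _ = stats.spearmanr(xa, ya)
    r = float(r)
    n = xa.size
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationReport(variable, r, p, n)


def domain_correlation_table(cohort: pd.DataFrame, ratio_col: str = "ratio") -> pd.DataFrame:
    """Spearman correlations of the miRNA ratio with MoCA total and domains.

    Expects a cohort already restricted to PD patients, with columns
    ``ratio``, ``moca_total`` and ``moca_<domain>`` for the seven domains.
    No multiplicity adjustment is applied (each row is reported as-is).
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    rows = []
    fields = [("total", "moca_total")] + [(d, f"moca_{d}") for d in MOCA_DOMAINS]
    for label, col in fields:
        sub = cohort[[ratio_col, col]].dropna()
        rep = spearman(sub[ratio_col], sub[col], variable=label)
        rows.append(
            {"domain": label, "spearman_r": rep.spearman_r, "p_value": rep.p_value, "n": rep.n}
        )
    return pd.DataFrame(rows)
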