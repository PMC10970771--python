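"""Prior sample-size computation for a fixed-effects one-way ANOVA.

Power is evaluated under the noncentral F distribution with noncentrality
``lambda = f**2 * N`` (total-N convention, as used by G*Power), where ``f``
is Cohen's effect size. ``min_total_n`` inverts the power function over the
integers.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    """An a-priori power question for a one-way fixed-effects ANOVA.

    Parameters
    ----------
    effect_size_f : Cohen's f (> 0); f = 0.25 is "medium", 0.5 "large".
    alpha : type-I error rate of the F test.
    target_power : desired power (only used by :func:`min_total_n`).
    n_groups : number of groups k (>= 2).
    """

    effect_size_f: float = 0.5
    alpha: float = 0.05
    target_power: float = 0.8
    n_groups: int = 4

    def __post_init__(self) -> None:
        if self.effect_size_f <= 0:
            raise ValueError("effect_size_f must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")


def anova_power(n_total: int, query: PowerQuery) -> float:
    """Power of the one-way ANOVA F test at total sample size ``n_total``.

    ``P(F' > F_crit)`` where ``F'`` is noncentral F with df1 = k - 1,
    df2 = N - k and noncentrality ``f**2 * N``, and ``F_crit`` is the
    (1 - alpha) quantile of the central F.
    """
    k = query.n_groups
    if n_total <= k:
        raise ValueError(f"n_total must exceed the number of groups ({k})")
    df1, df2 = k - 1, n_total - k
    f_crit = stats.f.ppf(1.0 - query.alpha, df1, df2)
    lam = query.effect_size_f**2 * n_total
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def min_total_n(query: PowerQuery, n_max: int = 100_000) -> int:
    """Smallest total N with ``anova_power(N) >= target_power``."""
    for n in range(query.n_groups + 1, n_max + 1):
        if anova_power(n, query) >= query.target_power:
            return n
    raise RuntimeError(f"target power not reached by N = {n_max}")
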