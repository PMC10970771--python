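"""Droplet digital PCR quantification and QC.

A ddPCR well partitions the reaction into ~nL droplets; template molecules
distribute over droplets approximately as a Poisson process, so the undiluted
concentration is recovered from the positive-droplet fraction as

    c = -ln(1 - k/N) / V_d * D      [copies/uL]

with N total droplets, k positive droplets, droplet volume V_d (uL) and
dilution factor D. On top of the Poisson math this module enforces the
well-level QC rules (accepted-droplet floor, minimum positive count),
forms the target/reference ratio miR-203a-3p / miR-16-5p and the
miR-16-5p / UniSp6 extraction-efficiency check, and applies the 1.5 x IQR
outlier rule per clinical group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: assay labels used throughout the validation phase
TARGET_ASSAY = "miR-203a-3p"
REFERENCE_ASSAY = "miR-16-5p"
SPIKEIN_ASSAY = "UniSp6"

#: QX200 convention, uL per droplet (0.85 nL); instrument calibrations differ
DEFAULT_DROPLET_VOLUME_UL = 0.85e-3

#: QC floors: accepted droplets per well and positive droplets per well.
#: Interpreted as counts; ``qc_pass(..., on_concentration=True)`` applies the
#: same numbers to copies/uL instead.
MIN_TOTAL_DROPLETS = 10_000
MIN_POSITIVE_DROPLETS = 3


class SaturatedWellError(ValueError):
    """Every droplet positive: the Poisson estimate diverges."""


@dataclass(frozen=True)
class DdpcrWell:
    """One ddPCR well: droplet counts for a single assay of a single sample."""

    sample_id: str
    assay: str
    total_droplets: int
    positive_droplets: int
    dilution: float = 1.0
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL

    def __post_init__(self) -> None:
        if self.total_droplets < 1:
            raise ValueError("total_droplets must be >= 1")
        if not 0 <= self.positive_droplets <= self.total_droplets:
            raise ValueError("positive_droplets must lie in [0, total_droplets]")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be > 0")


@dataclass
class RatioRecord:
    """Back-diluted target and reference concentrations and their ratio."""

    sample_id: str
    conc_target: float
    conc_reference: float
    ratio: float
    qc_flags: list[str] = field(default_factory=list)
    outlier: bool = False


def concentration(well: DdpcrWell) -> float:
    """Undiluted concentration (copies/uL) from the positive-droplet fraction."""
    k, n = well.positive_droplets, well.total_droplets
    if k == n:
        raise SaturatedWellError(
            f"saturated well {well.sample_id}/{well.assay}: all {n} droplets positive"
        )
    frac = k / n
    return float(-np.log1p(-frac) / well.droplet_volume * well.dilution)


def qc_pass(well: DdpcrWell, *, on_concentration: bool = False) -> tuple[bool, list[str]]:
    """Apply the well QC rules; failing wells are flagged, never dropped here.

    Default reads the thresholds as droplet counts (N > 10000 accepted
    droplets, k > 3 positives); ``on_concentration=True`` applies them to the
    measured copies/uL instead.
    """
    flags: list[str] = []
    if on_concentration:
        try:
            c = concentration(well)
        except SaturatedWellError:
            flags.append("saturated")
            return False, flags
        if c <= MIN_TOTAL_DROPLETS:
            flags.append("low_concentration")
        if c <= MIN_POSITIVE_DROPLETS:
            flags.append("low_positives")
    else:
        if well.total_droplets <= MIN_TOTAL_DROPLETS:
            flags.append("low_droplets")
        if well.positive_droplets <= MIN_POSITIVE_DROPLETS:
            flags.append("low_positives")
    return not flags, flags


def sample_ratio(
    wells: Sequence[DdpcrWell],
    target_assay: str = TARGET_ASSAY,
    reference_assay: str = REFERENCE_ASSAY,
) -> RatioRecord:
    """Target/reference ratio of back-diluted concentrations for one sample.

    Expects exactly one QC-passing well per assay. A missing or QC-failing
    assay well raises ``ValueError`` with the reason, so callers can exclude
    the sample explicitly rather than silently.
    """
    by_assay: dict[str, DdpcrWell] = {}
    sample_ids = {w.sample_id for w in wells}
    if len(sample_ids) > 1:
        raise ValueError(f"wells from multiple samples: {sorted(sample_ids)}")
    for w in wells:
        if w.assay in (target_assay, reference_assay):
            if w.assay in by_assay:
                raise ValueError(f"duplicate well for assay {w.assay}")
            by_assay[w.assay] = w

    flags: list[str] = []
    for assay in (target_assay, reference_assay):
        if assay not in by_assay:
            raise ValueError(f"sample {sample_ids or '?'}: missing {assay} well")
        ok, well_flags = qc_pass(by_assay[assay])
        if not ok:
            raise ValueError(
                f"sample {by_assay[assay].sample_id}: QC failure on {assay}: {well_flags}"
            )
        flags.extend(f"{assay}:{f}" for f in well_flags)

    c_target = concentration(by_assay[target_assay])
    c_reference = concentration(by_assay[reference_assay])
    if c_reference == 0:
        raise ValueError(f"sample {by_assay[target_assay].sample_id}: reference concentration is 0")
    return RatioRecord(
        sample_id=by_assay[target_assay].sample_id,
        conc_target=c_target,
        conc_reference=c_reference,
        ratio=c_target / c_reference,
        qc_flags=flags,
    )


def extraction_check(
    reference_conc: Mapping[str, float],
    spikein_conc: Mapping[str, float],
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> dict:
    """Kruskal-Wallis comparison of the miR-16-5p/UniSp6 ratio across groups.

    A group effect on this ratio would indicate non-uniform RNA extraction
    efficiency; p < alpha raises a warning flag in the report.
    """
    ids = sorted(set(reference_conc) & set(spikein_conc) & set(groups))
    ratios = pd.Series({s: reference_conc[s] / spikein_conc[s] for s in ids})
    labels = pd.Series({s: groups[s] for s in ids})
    samples = [ratios[labels == g].to_numpy() for g in labels.unique()]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0  # scipy rejects all-identical input
    else:
        h, p = stats.kruskal(*samples)
    return {
        "ratios": ratios,
        "H": float(h),
        "p_value": float(p),
        "warning": bool(p < alpha),
    }


def iqr_outliers(values: Sequence[float], k: float = 1.5) -> np.ndarray:
    """Boolean mask of values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear-interpolation quantiles. Intended to be applied
    within each clinical group.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 values per group for the IQR rule")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x > q3 + k * iqr) | (x < q1 - k * iqr)


def grouped_iqr_outliers(values: pd.Series, groups: pd.Series, k: float = 1.5) -> pd.Series:
    """Apply :func:`iqr_outliers` within each group; returns an aligned mask."""
    mask = pd.Series(False, index=values.index)
    for g, idx in values.groupby(groups).groups.items():
        mask.loc[idx] = iqr_outliers(values.loc[idx].to_numpy(), k=k)
    return mask
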