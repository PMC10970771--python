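"""End-to-end orchestration of the two study phases.

``run_discovery`` chains impute -> TMM -> log2 CPM -> trim -> batch-adjust ->
standardize -> delta grid -> CV tuning -> final shrink-to-zero selection,
then reports per-candidate fold changes and four-group Kruskal-Wallis/Dunn
comparisons. ``run_validation`` chains droplet Poisson quantification -> QC
-> target/reference ratio -> extraction-efficiency check -> per-group IQR
outlier flags -> Kruskal-Wallis/Dunn -> MoCA domain correlations -> the
train/test logistic model comparison.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so stages can be rerun in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bold_selector, cohort_stats, ddpcr_quant, ngs_preprocess, predictive_models

STAGE_SEEDS = ("discovery_sim", "cv_tune", "validation_sim", "split", "bootstrap")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {error}")


@dataclass
class PipelineConfig:
    """All switches of the pipeline, with their recorded defaults."""

    counts_path: str | None = None
    samples_path: str | None = None
    wells_path: str | None = None
    cohort_path: str | None = None
    out_dir: str | None = None
    contrast: tuple[str, str] = ("PD-MCI", "PDND")  # (case, control)
    grid_points: int = 15
    cv_folds: int = 5
    trim_q: float = 0.10
    apply_outlier_rule: bool = True
    n_boot: int = 2000
    train_frac: float = 0.7
    seed: int = 0
    # module-level decision switches
    cpm_pseudocount: float = ngs_preprocess.CPM_PSEUDOCOUNT
    active_tol: float = bold_selector.ACTIVE_TOL
    cv_ridge: float = bold_selector.CV_RIDGE
    qc_on_concentration: bool = False
    dunn_adjustment: str = "bonferroni"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "contrast" in data:
            data["contrast"] = tuple(data["contrast"])
        return cls(**data)


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one reproducible sub-seed (< 2**31) per pipeline stage."""
    children = np.random.SeedSequence(seed).spawn(len(STAGE_SEEDS))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGE_SEEDS, children)
    }


def run_discovery(
    config: PipelineConfig,
    matrix: ngs_preprocess.CountMatrix | None = None,
    samples: pd.DataFrame | None = None,
) -> dict:
    """Discovery phase: preprocessing, selector tuning, candidate report."""
    seeds = stage_seeds(config.seed)
    if matrix is None or samples is None:
        try:
            matrix = ngs_preprocess.read_counts(config.counts_path, config.samples_path)
            samples = pd.read_csv(config.samples_path, sep="\t")
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineStageError("read_inputs", exc) from exc
    samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples

    try:
        normalized, trim_report = ngs_preprocess.preprocess_pipeline(matrix, q=config.trim_q)
    except Exception as exc:
        raise PipelineStageError("preprocess", exc) from exc

    case, control = config.contrast
    groups = samples["group"]
    contrast_samples = groups.index[groups.isin([case, control])]
    labels = (groups.loc[contrast_samples] == case).astype(int)

    try:
        sel_input = bold_selector.standardize(normalized.values[contrast_samples], labels)
        grid = bold_selector.delta_grid(sel_input, n_points=config.grid_points)
        tuning = bold_selector.cv_tune(
            sel_input, grid, k=config.cv_folds, seed=seeds["cv_tune"],
            tol=config.active_tol, ridge=config.cv_ridge,
        )
        selection = bold_selector.final_selection(
            sel_input, tuning.best_delta, grid, tol=config.active_tol, ridge=config.cv_ridge
        )
    except Exception as exc:
        raise PipelineStageError("selector", exc) from exc

    try:
        fc = ngs_preprocess.fold_change(normalized, groups, case, control)
        group_tests = []
        for cand in selection.candidates:
            values = normalized.values.loc[cand]
            grouped = {g: values[groups.index[groups == g]].to_numpy()
                       for g in groups.unique()}
            h, p = cohort_stats.kruskal_wallis(list(grouped.values()))
            dunn = cohort_stats.dunn_posthoc(grouped, adjustment=config.dunn_adjustment)
            group_tests.append(
                {"mirna": cand, "log2fc": float(fc.loc[cand]), "kw_H": h, "kw_p": p,
                 "dunn": dunn.to_dict(orient="records")}
            )
    except Exception as exc:
        raise PipelineStageError("candidate_stats", exc) from exc

    report = {
        "contrast": {"case": case, "control": control},
        "n_mirnas_after_trim": int(normalized.values.shape[0]),
        "trim_removed": trim_report["removed"],
        "delta_grid": grid.tolist(),
        "best_delta": tuning.best_delta,
        "mean_cv_auc": {float(d): float(a) for d, a in tuning.mean_auc.items()},
        "candidates": selection.candidates,
        "candidate_stats": group_tests,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ngs_preprocess.write_normalized(normalized, out / "normalized.tsv")
        ngs_preprocess.write_trim_report(trim_report, out / "trim_report.json")
        fc.to_csv(out / "fc.tsv", sep="\t")
        (out / "discovery_report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def quantify_wells(
    wells: pd.DataFrame,
    qc_on_concentration: bool = False,
    droplet_volume: float = ddpcr_quant.DEFAULT_DROPLET_VOLUME_UL,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-sample ratios from a well table; returns (ratios, exclusions)."""
    records = []
    excluded = []
    spike_conc: dict[str, float] = {}
    ref_conc: dict[str, float] = {}
    for sid, sub in wells.groupby("sample_id"):
        sample_wells = [
            ddpcr_quant.DdpcrWell(
                sample_id=str(sid),
                assay=row["assay"],
                total_droplets=int(row["total_droplets"]),
                positive_droplets=int(row["positive_droplets"]),
                dilution=float(row["dilution"]),
                droplet_volume=droplet_volume,
            )
            for _, row in sub.iterrows()
        ]
        for w in sample_wells:
            if w.assay == ddpcr_quant.SPIKEIN_ASSAY:
                ok, _ = ddpcr_quant.qc_pass(w, on_concentration=qc_on_concentration)
                if ok:
                    spike_conc[str(sid)] = ddpcr_quant.concentration(w)
        try:
            rec = ddpcr_quant.sample_ratio(sample_wells)
        except ValueError as exc:
            excluded.append({"sample_id": str(sid), "reason": str(exc)})
            continue
        ref_conc[str(sid)] = rec.conc_reference
        records.append(
            {"sample_id": rec.sample_id, "conc_target": rec.conc_target,
             "conc_reference": rec.conc_reference, "ratio": rec.ratio,
             "qc_flags": ";".join(rec.qc_flags)}
        )
    ratios = pd.DataFrame(records)
    ratios.attrs["spikein_conc"] = spike_conc
    ratios.attrs["reference_conc"] = ref_conc
    return ratios, excluded


def run_validation(
    config: PipelineConfig,
    wells: pd.DataFrame | None = None,
    cohort: pd.DataFrame | None = None,
) -> dict:
    """Validation phase: quantification, group statistics, ROC modelling."""
    seeds = stage_seeds(config.seed)
    if wells is None or cohort is None:
        try:
            wells = pd.read_csv(config.wells_path)
            cohort = pd.read_csv(config.cohort_path)
        except Exception as exc:
            raise PipelineStageError("read_inputs", exc) from exc

    try:
        ratios, excluded = quantify_wells(wells, config.qc_on_concentration)
        if ratios.empty:
            raise ValueError("no sample passed well QC")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("quantification", exc) from exc

    data = cohort.merge(ratios, on="sample_id", how="inner")
    if "sex" in data.columns and "gender" not in data.columns:
        data["gender"] = (data["sex"] == "M").astype(int)

    try:
        extraction = None
        spike = ratios.attrs.get("spikein_conc", {})
        if spike:
            group_of = dict(zip(cohort["sample_id"].astype(str), cohort["group"]))
            extraction = ddpcr_quant.extraction_check(
                ratios.attrs["reference_conc"], spike, group_of
            )
    except Exception as exc:
        raise PipelineStageError("extraction_check", exc) from exc

    try:
        if config.apply_outlier_rule:
            data["outlier"] = ddpcr_quant.grouped_iqr_outliers(
                data["ratio"], data["group"]
            ).to_numpy()
        else:
            data["outlier"] = False
        clean = data[~data["outlier"]]
    except Exception as exc:
        raise PipelineStageError("outlier_rule", exc) from exc

    try:
        grouped = {g: clean.loc[clean["group"] == g, "ratio"].to_numpy()
                   for g in clean["group"].unique()}
        kw_h, kw_p = cohort_stats.kruskal_wallis(list(grouped.values()))
        dunn = cohort_stats.dunn_posthoc(grouped, adjustment=config.dunn_adjustment)
    except Exception as exc:
        raise PipelineStageError("group_stats", exc) from exc

    try:
        pd_subset = clean[clean["group"].isin(["PDND", "PD-MCI", "PDD"])]
        domain_table = cohort_stats.domain_correlation_table(pd_subset)
    except Exception as exc:
        raise PipelineStageError("domain_correlations", exc) from exc

    try:
        comparison = predictive_models.model_comparison_table(
            pd_subset.reset_index(drop=True),
            train_frac=config.train_frac,
            n_boot=config.n_boot,
            seed=seeds["split"],
        )
    except Exception as exc:
        raise PipelineStageError("model_comparison", exc) from exc

    group_means = clean.groupby("group")["ratio"].agg(["mean", "std", "count"])
    report = {
        "n_quantified": int(len(ratios)),
        "excluded": excluded,
        "n_outliers": int(data["outlier"].sum()),
        "group_ratio_summary": group_means.to_dict(orient="index"),
        "kruskal_wallis": {"H": kw_h, "p": kw_p},
        "dunn": dunn.to_dict(orient="records"),
        "extraction_check": (
            None if extraction is None else
            {"H": extraction["H"], "p": extraction["p_value"],
             "warning": extraction["warning"]}
        ),
        "domain_correlations": domain_table.to_dict(orient="records"),
        "model_comparison": comparison.to_dict(orient="records"),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        data.to_csv(out / "ratios.csv", index=False)
        domain_table.to_csv(out / "domain_correlations.csv", index=False)
        comparison.to_csv(out / "model_comparison.csv", index=False)
        (out / "validation_report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def config_to_json(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2, default=list))
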