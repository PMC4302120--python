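"""End-to-end pipeline driver.

Fixed stage order: preprocess (beta, detection-p mask) -> probe QC
(replicate SE) -> missingness filter -> sample QC (pseudo-twin null) ->
cell-composition adjustment -> EWAS on all pairs -> EWAS on the extreme
subset -> cohort statistics.  Every run directory carries a config snapshot
and the package version; reruns with identical config and inputs reproduce
identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import MethylationMatrix, TwinCohort, ValidationError, read_matrix_tsv
from . import preprocess, qc, cellcomp, ewas, cohort_stats

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("twinewas")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a pipeline run.

    Thresholds default to the study's QC conventions: detection p > 0.01
    masked, probes > 5% missing dropped, replicate SE > 0.05 unstable,
    extreme discordance dbw% >= 25, genome-wide significance FDR < 0.05,
    10,000 pseudo-twin replicates split at age 45.
    """

    sample_sheet: str = ""
    beta_matrix: str | None = None
    m_matrix: str | None = None
    u_matrix: str | None = None
    detection_p: str | None = None
    cell_reference: str | None = None
    manifest: str | None = None
    out_dir: str = "twinewas_run"

    detection_p_threshold: float = 0.01
    max_missing_frac: float = 0.05
    se_threshold: float = 0.05
    extreme_threshold: float = 25.0
    extreme_strict: bool = False
    fdr: float = 0.05
    null_replicates: int = 10_000
    age_split: float = 45.0
    logit_eps: float = 1e-4
    sum_to_one: bool = False
    response: str = "mvalue-diff"   # or "beta-log-ratio" (fold-change scale)
    reml: bool = True
    probe_qc_first: bool = True     # probe QC before sample QC
    seed: int = 0

    def validate(self) -> None:
        if not self.sample_sheet:
            raise ValidationError("sample_sheet path is required")
        if self.beta_matrix is None and (self.m_matrix is None or self.u_matrix is None):
            raise ValidationError("provide beta_matrix or both m_matrix and u_matrix")
        for name, lo, hi in (("detection_p_threshold", 0, 1), ("max_missing_frac", 0, 1),
                             ("se_threshold", 0, np.inf), ("extreme_threshold", 0, 100),
                             ("fdr", 0, 1), ("logit_eps", 0, 0.5)):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValidationError(f"{name}={v} outside ({lo}, {hi})")
        if self.null_replicates < 100:
            raise ValidationError("null_replicates must be >= 100")
        if self.response not in ("mvalue-diff", "beta-log-ratio"):
            raise ValidationError(f"unknown response {self.response!r}")
        for name in ("sample_sheet", "beta_matrix", "m_matrix", "u_matrix",
                     "detection_p", "cell_reference", "manifest"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict):       # e.g. a [thresholds] or [paths] section
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


def validate_inputs(sheet: pd.DataFrame, matrix: MethylationMatrix | None = None) -> list:
    """Machine-readable issue list for a sample sheet and optional matrix.

    Checks cohort invariants, sheet/matrix sample-id agreement, and the
    declared value scale.  Returns a list of ``{"issue", "detail"}`` dicts;
    empty means clean.
    """
    issues = []
    try:
        cohort = TwinCohort(sheet.copy())
    except ValidationError as exc:
        msg = str(exc)
        kind = "incomplete pair" if "exactly two members" in msg else "invalid sample sheet"
        issues.append({"issue": kind, "detail": msg})
        cohort = None
    if matrix is not None:
        sheet_ids = set(sheet["sample_id"]) if "sample_id" in sheet.columns else set()
        unknown = [s for s in matrix.sample_ids if s not in sheet_ids]
        absent = sorted(sheet_ids - set(matrix.sample_ids))
        if unknown:
            issues.append({"issue": "unknown sample",
                           "detail": f"matrix columns not in sample sheet: {unknown[:10]}"})
        if absent:
            issues.append({"issue": "sample without data",
                           "detail": f"sheet samples missing from matrix: {absent[:10]}"})
        if matrix.scale == "beta":
            vals = matrix.masked_values().to_numpy()
            bad = np.nansum((vals < 0) | (vals > 1))
            if bad:
                issues.append({"issue": "scale mismatch",
                               "detail": f"{int(bad)} beta values outside [0, 1]"})
    return issues


def _analysis_scale(matrix: MethylationMatrix, config: PipelineConfig) -> MethylationMatrix:
    if config.response == "mvalue-diff":
        return preprocess.to_mvalues(matrix, epsilon=config.logit_eps)
    # fold-change scale: natural log of beta; pair differences are log fold changes
    b = np.clip(matrix.values.to_numpy(float), config.logit_eps, 1.0)
    return MethylationMatrix(
        pd.DataFrame(np.log(b), index=matrix.probe_ids, columns=matrix.sample_ids),
        scale="mvalue", mask=matrix.mask.copy(),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write artifacts to ``config.out_dir``.

    Returns a dict of output paths plus in-memory results.  A stage failure
    raises with a stage-attributed message after writing an ``incomplete``
    marker to the run directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "INCOMPLETE").write_text("run in progress")
    stage = "load"
    try:
        results = _run_stages(config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {_CURRENT_STAGE['name']}: {exc}") from exc
    (out / "INCOMPLETE").unlink(missing_ok=True)
    return results


_CURRENT_STAGE = {"name": "load"}


def _stage(name: str, **counts) -> None:
    _CURRENT_STAGE["name"] = name
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s %s", name, extras)


def _run_stages(config: PipelineConfig, out: Path) -> dict:
    meta = {"version": __version__, "config": config.snapshot(), "stages": {}}

    _stage("load")
    cohort = TwinCohort.from_csv(config.sample_sheet)
    if config.beta_matrix:
        matrix = read_matrix_tsv(config.beta_matrix, scale="beta")
    else:
        M = pd.read_csv(config.m_matrix, sep="\t", index_col=0)
        U = pd.read_csv(config.u_matrix, sep="\t", index_col=0)
        matrix = preprocess.compute_beta(M, U)
    issues = validate_inputs(cohort.data, matrix)
    fatal = [i for i in issues if i["issue"] != "sample without data"]
    if fatal:
        raise ValidationError(f"input validation failed: {fatal}")
    matrix = matrix.subset_samples([s for s in cohort.sample_ids if s in set(matrix.sample_ids)])
    meta["stages"]["load"] = {"n_samples": matrix.shape[1], "n_probes": matrix.shape[0],
                              "n_pairs": cohort.n_pairs}

    _stage("detection_mask")
    if config.detection_p:
        detp = pd.read_csv(config.detection_p, sep="\t", index_col=0)
        matrix = preprocess.apply_detection_mask(
            matrix, detp[matrix.sample_ids.tolist()].loc[matrix.probe_ids],
            threshold=config.detection_p_threshold)
    meta["stages"]["detection_mask"] = {"masked_cells": int(matrix.mask.to_numpy().sum())}

    _stage("probe_qc")
    unstable: list = []
    probe_se = None
    reps = cohort.replicates
    rep_in_matrix = reps["sample_id"].isin(matrix.sample_ids)
    if rep_in_matrix.sum() >= 4:
        rep_ids = reps.loc[rep_in_matrix, "sample_id"].tolist()
        rep_map = dict(zip(reps["sample_id"], reps["is_replicate_of"]))
        probe_se = qc.probe_replicate_se(matrix.subset_samples(rep_ids), rep_map)
        unstable = qc.flag_unstable_probes(probe_se, se_threshold=config.se_threshold)
        keep = [p for p in matrix.probe_ids if p not in set(unstable)]
        matrix = matrix.subset_probes(keep)
    meta["stages"]["probe_qc"] = {"unstable_probes": len(unstable),
                                  "probes_kept": matrix.shape[0]}

    _stage("missingness_filter")
    matrix, dropped = preprocess.filter_probes_missingness(matrix, config.max_missing_frac)
    meta["stages"]["missingness_filter"] = {"dropped_probes": len(dropped),
                                            "probes_kept": matrix.shape[0]}

    _stage("sample_qc")
    primary_ids = cohort.primary["sample_id"].tolist()
    analysis = matrix.subset_samples(primary_ids)
    corrs = qc.pair_correlations(analysis, cohort)
    intervals = qc.pseudo_twin_null(analysis, cohort, n_replicates=config.null_replicates,
                                    age_split=config.age_split, seed=config.seed)
    pair_qc = qc.flag_bad_pairs(corrs, intervals)
    report = qc.QCReport(
        probe_se if probe_se is not None else pd.DataFrame(columns=["replicate_se"]),
        unstable, pair_qc, intervals, se_threshold=config.se_threshold)
    report.to_json(out / "qc_report.json")
    report.pair_qc_tsv(out / "pair_qc.tsv")
    flagged = report.flagged_pairs
    kept_pairs = [p for p in cohort.primary["pair_id"].unique() if p not in set(flagged)]
    cohort_kept = cohort.subset_pairs(kept_pairs)
    analysis = analysis.subset_samples(cohort_kept.primary["sample_id"].tolist())
    meta["stages"]["sample_qc"] = {"flagged_pairs": len(flagged), "pairs_kept": len(kept_pairs)}

    _stage("cell_composition")
    mvals = _analysis_scale(analysis, config)
    compositions = None
    if config.cell_reference:
        reference = cellcomp.CellReference.from_tsv(config.cell_reference)
        compositions = cellcomp.estimate_composition(analysis, reference,
                                                     sum_to_one=config.sum_to_one)
        compositions.rename_axis("sample_id").to_csv(out / "compositions.csv")
        mvals = cellcomp.residualize(mvals, compositions, drop_one=config.sum_to_one)
    meta["stages"]["cell_composition"] = {"adjusted": compositions is not None}

    _stage("ewas_full")
    result_full = ewas.run_ewas(mvals, cohort_kept, label="full", reml=config.reml)
    result_full.to_tsv(out / "ewas_full.tsv")
    meta["stages"]["ewas_full"] = {"n_pairs": result_full.n_pairs,
                                   "n_probes": len(result_full.table)}

    _stage("ewas_extreme")
    extreme = ewas.select_extreme(cohort_kept, threshold=config.extreme_threshold,
                                  strict=config.extreme_strict)
    result_extreme = None
    if extreme.n_pairs >= ewas.MIN_PAIRS:
        sub = mvals.subset_samples(extreme.primary["sample_id"].tolist())
        result_extreme = ewas.run_ewas(sub, extreme, label="extreme", reml=config.reml)
        result_extreme.to_tsv(out / "ewas_extreme.tsv")
    meta["stages"]["ewas_extreme"] = {"n_pairs": extreme.n_pairs,
                                      "analysed": result_extreme is not None}

    _stage("manhattan")
    manifest = None
    if config.manifest:
        manifest = pd.read_csv(config.manifest, sep="\t")
    ewas.manhattan_table(result_full, manifest).rename_axis("probe_id") \
        .to_csv(out / "manhattan_full.tsv", sep="\t")
    if result_extreme is not None:
        ewas.manhattan_table(result_extreme, manifest).rename_axis("probe_id") \
            .to_csv(out / "manhattan_extreme.tsv", sep="\t")

    _stage("cohort_stats")
    summary = cohort_stats.cohort_summary(cohort_kept, age_split=config.age_split)
    stats_out: dict = {"summary": summary}
    dbw = ewas.compute_dbw_pct(cohort_kept)
    pairs = cohort_kept.pairs()
    young = pairs["age"] < config.age_split
    if young.sum() >= 2 and (~young).sum() >= 2:
        t, df, p = cohort_stats.welch_t(dbw[young.to_numpy()], dbw[(~young).to_numpy()])
        stats_out["dbw_young_vs_old"] = {"t": t, "df": df, "p": p}
    try:
        enr = cohort_stats.preterm_enrichment(cohort_kept, dbw_threshold=config.extreme_threshold)
        enr["table"] = enr["table"].tolist()
        stats_out["preterm_enrichment"] = enr
    except ValidationError as exc:
        stats_out["preterm_enrichment"] = {"error": str(exc)}
    (out / "cohort_stats.json").write_text(json.dumps(stats_out, indent=1))

    _stage("finalize")
    (out / "metadata.json").write_text(json.dumps(meta, indent=1))
    return {
        "out_dir": out,
        "qc_report": report,
        "ewas_full": result_full,
        "ewas_extreme": result_extreme,
        "cohort_stats": stats_out,
        "compositions": compositions,
        "metadata": meta,
    }
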