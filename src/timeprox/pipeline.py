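"""End-to-end orchestration: phenotype -> regions -> quantify -> features ->
associations -> survival -> report, with a run manifest.

Every stage persists its output as tidy CSV in the run directory, so every
number in the report traces back to a results-CSV cell.  A completed run
directory is a no-op to re-run unless ``force`` is set; identical inputs,
config and seed reproduce identical result CSVs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .errors import StageError, TimeproxError
from .io import (CellTable, PatientRecord, clinical_frame, read_cell_table,
                 read_clinical_table, summarize_cohort)
from .phenotyping import (INDEX_LABEL, CheckpointGates, assign_memberships,
                          compute_gates, enumerate_taxonomy)
from .quantification import FeatureTable, build_feature_table, slide_metrics
from .regions import delineate_regions
from .stats import (bh_adjust, cox_fit, km_logrank, mann_whitney, roc_auc,
                    screened_multivariate)

DENSITY_METRICS = ("density_tumor", "density_stroma", "density_overall")
ASSOCIATION_METRICS = DENSITY_METRICS + ("proximity_score",)


# --------------------------------------------------------------------------
# input loading
# --------------------------------------------------------------------------

def load_inputs(input_dir: str | Path,
                config: AnalysisConfig) -> tuple[list[PatientRecord], dict[str, CellTable]]:
    input_dir = Path(input_dir)
    clin_path = input_dir / "clinical.csv"
    cell_dir = input_dir / "cells"
    if not clin_path.exists() or not cell_dir.is_dir():
        raise StageError("input", f"expected clinical.csv and cells/ under {input_dir}")
    records = read_clinical_table(clin_path)
    tables = {}
    for path in sorted(cell_dir.glob("*.csv")):
        if path.name.endswith(".truth.csv"):
            continue
        t = read_cell_table(path, config)
        for sid, sub in t.per_slide():
            tables[sid] = sub
    if not tables:
        raise StageError("input", f"no cell tables found in {cell_dir}")
    return records, tables


# --------------------------------------------------------------------------
# analysis stages
# --------------------------------------------------------------------------

def stage_phenotype(tables: dict[str, CellTable],
                    config: AnalysisConfig) -> tuple[CheckpointGates, dict]:
    """Gate positivity and assign the 88-label memberships per slide.

    With ``tertile_scope: cohort`` the checkpoint tertiles are pooled across
    all slides (batch-processed staining makes intensities comparable);
    ``slide`` recomputes them per slide.
    """
    order = sorted(tables)
    if config.tertile_scope == "cohort":
        gates = compute_gates([tables[s] for s in order], config)
        memberships = {s: assign_memberships(tables[s], gates, config) for s in order}
    else:
        memberships = {}
        for s in order:
            gates = compute_gates([tables[s]], config)
            memberships[s] = assign_memberships(tables[s], gates, config)
    return gates, memberships


def stage_regions(tables, memberships, config) -> dict:
    return {
        sid: delineate_regions(tables[sid],
                               memberships[sid].positivity["panCK"].to_numpy(),
                               config.region)
        for sid in sorted(tables)
    }


def stage_quantify(tables, memberships, partitions, config) -> dict[str, pd.DataFrame]:
    return {sid: slide_metrics(tables[sid], memberships[sid], partitions[sid], config)
            for sid in sorted(tables)}


def stage_features(metrics_by_slide, records, config) -> FeatureTable:
    return build_feature_table(metrics_by_slide, records, config)


def stage_associations(features: FeatureTable,
                       config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame, str | None]:
    """Responder-vs-non-responder Mann-Whitney battery plus the ROC table.

    One BH family per metric type (all 88 labels of e.g. overall density vs
    response form one family).  Undefined proximity scores are excluded
    pairwise, mirroring the separate presence analysis rather than imputing 0.
    """
    data = features.data
    resp = data["responder"].astype(bool)
    if resp.sum() < 2 or (~resp).sum() < 2:
        return (pd.DataFrame(), pd.DataFrame(),
                "associations skipped: fewer than 2 patients per response group")
    rows = []
    for metric in ASSOCIATION_METRICS:
        for label in enumerate_taxonomy():
            vals = data[f"{label}__{metric}"].astype(float)
            keep = vals.notna()
            x = vals[keep & resp].to_numpy()
            y = vals[keep & ~resp].to_numpy()
            if len(x) < 2 or len(y) < 2:
                continue
            res = mann_whitney(x, y, feature_id=f"{label}__{metric}",
                               exact_max_n=config.mw_exact_max_n,
                               group_names=("responder", "non-responder"))
            rows.append({"label": label, "metric": metric,
                         "n_responder": len(x), "n_nonresponder": len(y),
                         "statistic": res.statistic, "p_value": res.p_value,
                         "direction": res.direction, "method": res.method,
                         "degenerate": res.degenerate})
    assoc = pd.DataFrame(rows)
    if not assoc.empty:
        assoc["q_value"] = np.nan
        for metric in ASSOCIATION_METRICS:
            fam = assoc["metric"] == metric
            if fam.any():
                assoc.loc[fam, "q_value"] = bh_adjust(assoc.loc[fam, "p_value"].to_numpy())
        assoc = assoc.sort_values(["metric", "q_value", "label"]).reset_index(drop=True)

    # ROC: index-subset proximity score and overall density vs the clinical TPS
    roc_rows = []
    for name, col in (("proximity_score", f"{INDEX_LABEL}__proximity_score"),
                      ("density_overall", f"{INDEX_LABEL}__density_overall"),
                      ("pdl1_tps", "pdl1_tps")):
        try:
            r = roc_auc(data[col].astype(float), resp, feature_id=name)
            roc_rows.append({"feature": name, "auc": r.auc,
                             "n_responder": r.n_positive,
                             "n_nonresponder": r.n_negative})
        except TimeproxError as exc:
            roc_rows.append({"feature": name, "auc": np.nan,
                             "n_responder": 0, "n_nonresponder": 0,
                             "note": str(exc)})
    return assoc, pd.DataFrame(roc_rows), None


def _survival_covariates(data: pd.DataFrame, prox_col: str) -> pd.DataFrame:
    """Candidate covariates for the screened Cox model: the proximity-low
    group plus clinicopathologic characteristics and regimen indicators."""
    return pd.DataFrame({
        "prox_low": (data[prox_col] == "low").astype(float),
        "age": data["age"].astype(float),
        "sex_male": (data["sex"] == "male").astype(float),
        "smoking_heavy": (data["smoking"] == ">=400").astype(float),
        "histology_nonadeno": (data["histology"] == "non-adenocarcinoma").astype(float),
        "stage_iv": (data["stage"] == "IV").astype(float),
        "pdl1_tps": data["pdl1_tps"].astype(float),
        "treatment_line": data["treatment_line"].astype(float),
        "combo_ctla4": (data["combination"] == "anti-CTLA-4").astype(float),
        "combo_chemo": (data["combination"] == "chemo").astype(float),
    }, index=data.index)


def stage_survival(features: FeatureTable, config: AnalysisConfig) -> dict:
    """KM/log-rank on the presence and median-split proximity groups, and
    univariate -> p<0.1-screened multivariate Cox, for OS and PFS."""
    data = features.data
    prox_col = f"{INDEX_LABEL}__prox_group_survival"
    presence_col = f"{INDEX_LABEL}__presence_group"
    out: dict = {"logrank": [], "cox": {}}
    for outcome in ("os", "pfs"):
        times = data[f"{outcome}_months"].to_numpy(float)
        events = data[f"{outcome}_event"].to_numpy(int)
        for split_name, col in (("presence", presence_col), ("proximity_median", prox_col)):
            groups = data[col]
            keep = groups.notna().to_numpy()
            if keep.sum() < 2 or groups[keep].nunique() < 2 or events[keep].sum() == 0:
                out["logrank"].append({"outcome": outcome, "split": split_name,
                                       "statistic": np.nan, "p_value": np.nan,
                                       "flagged": True})
                continue
            km = km_logrank(times[keep], events[keep], groups[keep].to_numpy())
            out["logrank"].append({"outcome": outcome, "split": split_name,
                                   "statistic": km.statistic, "p_value": km.p_value,
                                   "flagged": km.flagged})
            out[f"km_{outcome}_{split_name}"] = km
        cov = _survival_covariates(data, prox_col)
        keep = data[prox_col].notna().to_numpy()
        try:
            out["cox"][outcome] = screened_multivariate(
                times[keep], events[keep], cov[keep].reset_index(drop=True),
                alpha=0.1, ties=config.cox_ties)
        except TimeproxError as exc:
            warnings.warn(f"Cox stage skipped for {outcome}: {exc}")
            out["cox"][outcome] = None
    out["logrank"] = pd.DataFrame(out["logrank"])
    return out


# --------------------------------------------------------------------------
# run orchestration
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _input_checksums(input_dir: Path) -> dict[str, str]:
    files = sorted(p for p in input_dir.rglob("*.csv"))
    return {str(p.relative_to(input_dir)): _sha256(p) for p in files}


def run_all(config: AnalysisConfig, input_dir: str | Path, out_dir: str | Path,
            force: bool = False) -> dict:
    """Execute all stages; returns the run manifest.

    Partial failure leaves completed stage outputs in place and writes an
    error manifest naming the failed stage.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    checksums = _input_checksums(input_dir) if input_dir.exists() else {}
    fingerprint = {"config_hash": config.content_hash(), "inputs": checksums,
                   "seed": config.seed}
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if (old.get("config_hash") == fingerprint["config_hash"]
                and old.get("inputs") == checksums and old.get("status") == "ok"):
            old["skipped"] = True
            return old

    manifest = dict(fingerprint)
    manifest["started"] = datetime.datetime.now().isoformat(timespec="seconds")
    outputs: list[str] = []
    stage = "input"
    try:
        records, tables = load_inputs(input_dir, config)

        stage = "phenotype"
        gates, memberships = stage_phenotype(tables, config)
        (out_dir / "gates.yaml").write_text(yaml.safe_dump(gates.to_dict()))
        outputs.append("gates.yaml")

        stage = "regions"
        partitions = stage_regions(tables, memberships, config)
        pd.DataFrame([{"slide_id": sid, "tumor_mm2": p.tumor_area_mm2,
                       "stroma_mm2": p.stroma_area_mm2, "tissue_mm2": p.tissue_area_mm2}
                      for sid, p in partitions.items()]
                     ).to_csv(out_dir / "region_areas.csv", index=False)
        outputs.append("region_areas.csv")

        stage = "quantify"
        metrics = stage_quantify(tables, memberships, partitions, config)
        pd.concat([m.assign(slide_id=sid) for sid, m in metrics.items()]
                  ).to_csv(out_dir / "slide_metrics.csv")
        outputs.append("slide_metrics.csv")

        stage = "features"
        features = stage_features(metrics, records, config)
        features.data.to_csv(out_dir / "features.csv", index=False)
        summarize_cohort(records).to_csv(out_dir / "cohort_summary.csv", index=False)
        outputs += ["features.csv", "cohort_summary.csv"]

        stage = "associations"
        assoc, roc_table, assoc_note = stage_associations(features, config)
        assoc.to_csv(out_dir / "associations.csv", index=False)
        roc_table.to_csv(out_dir / "roc.csv", index=False)
        outputs += ["associations.csv", "roc.csv"]
        if assoc_note:
            manifest["associations_note"] = assoc_note

        stage = "survival"
        surv = stage_survival(features, config)
        surv["logrank"].to_csv(out_dir / "logrank.csv", index=False)
        outputs.append("logrank.csv")
        for outcome, res in surv["cox"].items():
            if res is None:
                continue
            uni = res.univariate.assign(stage="univariate", outcome=outcome)
            parts = [uni]
            if res.multivariate is not None:
                parts.append(res.multivariate.summary.assign(
                    stage="multivariate", outcome=outcome))
            pd.concat(parts, ignore_index=True).to_csv(
                out_dir / f"cox_{outcome}.csv", index=False)
            outputs.append(f"cox_{outcome}.csv")

        stage = "report"
        text = report(out_dir)
        (out_dir / "report.md").write_text(text)
        outputs.append("report.md")
    except TimeproxError:
        manifest.update(status="error", failed_stage=stage, outputs=outputs)
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise
    except Exception as exc:  # unexpected: still record the stage
        manifest.update(status="error", failed_stage=stage, outputs=outputs)
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise StageError(stage, str(exc)) from exc

    manifest.update(status="ok", outputs=outputs,
                    finished=datetime.datetime.now().isoformat(timespec="seconds"))
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def _fmt(v, nd=3):
    return "NA" if pd.isna(v) else f"{v:.{nd}f}"


def _read_csv_or_empty(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (FileNotFoundError, pd.errors.EmptyDataError):
        return pd.DataFrame()


def report(out_dir: str | Path) -> str:
    """Human-readable summary assembled from the results CSVs (no arithmetic
    beyond formatting)."""
    out_dir = Path(out_dir)
    lines = ["# Analysis report", ""]

    summary = pd.read_csv(out_dir / "cohort_summary.csv")
    lines += ["## Cohort summary", "", "| variable | category | n | % |",
              "|---|---|---|---|"]
    for _, r in summary.iterrows():
        lines.append(f"| {r['variable']} | {r['category']} | {r['count']:g} "
                     f"| {_fmt(r['pct'], 1)} |")

    assoc = _read_csv_or_empty(out_dir / "associations.csv")
    lines += ["", "## Top differential features (responder vs non-responder)", ""]
    if assoc.empty:
        lines.append("associations skipped (insufficient patients per response group)")
    else:
        top = assoc.nsmallest(10, "q_value")
        lines += ["| label | metric | p | q | direction |", "|---|---|---|---|---|"]
        for _, r in top.iterrows():
            lines.append(f"| {r['label']} | {r['metric']} | {_fmt(r['p_value'], 4)} "
                         f"| {_fmt(r['q_value'], 4)} | {r['direction']} |")

    roc = _read_csv_or_empty(out_dir / "roc.csv")
    if not roc.empty:
        lines += ["", "## Response prediction (AUC, responder-positive)", "",
                  "| feature | AUC |", "|---|---|"]
        for _, r in roc.iterrows():
            lines.append(f"| {r['feature']} | {_fmt(r['auc'], 3)} |")

    lr = _read_csv_or_empty(out_dir / "logrank.csv")
    if not lr.empty:
        lines += ["", "## Log-rank tests", "", "| outcome | split | chi2 | p |",
                  "|---|---|---|---|"]
        for _, r in lr.iterrows():
            lines.append(f"| {r['outcome']} | {r['split']} | {_fmt(r['statistic'])} "
                         f"| {_fmt(r['p_value'], 4)} |")

    for outcome in ("os", "pfs"):
        path = out_dir / f"cox_{outcome}.csv"
        if not path.exists():
            continue
        cox = pd.read_csv(path)
        lines += ["", f"## Cox regression ({outcome.upper()})", "",
                  "| stage | covariate | HR | 95% CI | p |", "|---|---|---|---|---|"]
        for _, r in cox.iterrows():
            lines.append(f"| {r['stage']} | {r['covariate']} | {_fmt(r['hr'], 2)} "
                         f"| {_fmt(r['ci_lower'], 2)}-{_fmt(r['ci_upper'], 2)} "
                         f"| {_fmt(r['p'], 4)} |")
    return "\n".join(lines) + "\n"
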