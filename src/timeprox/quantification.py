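"""Subregional densities, the 30 μm proximity score, and the patient
feature table.

The proximity score of a subpopulation is the mean number of pan-CK+ tumor
cells whose nucleus centroid lies within radius r (default 30 μm,
boundary-inclusive) of each member cell; it is undefined — propagated as
missing, never imputed 0 — when the subpopulation is absent from a slide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .errors import IntegrityError, TableValidationError
from .io import CellTable, PatientRecord, clinical_frame
from .phenotyping import INDEX_LABEL, MembershipMatrix
from .regions import RegionPartition

#: Metrics computed per slide x subpopulation.
METRICS = ("n_cells_tumor", "n_cells_stroma", "n_cells_total",
           "density_tumor", "density_stroma", "density_overall",
           "proximity_score", "present")


def count_neighbors_within(source_xy: np.ndarray, target_xy: np.ndarray,
                           r: float) -> np.ndarray:
    """Exact per-source count of targets within Euclidean distance <= r."""
    if r <= 0:
        raise ValueError("radius must be > 0")
    source_xy = np.asarray(source_xy, dtype=float).reshape(-1, 2)
    target_xy = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    if len(source_xy) == 0:
        return np.zeros(0, dtype=int)
    if len(target_xy) == 0:
        return np.zeros(len(source_xy), dtype=int)
    tree = cKDTree(target_xy)
    return np.asarray(tree.query_ball_point(source_xy, r, return_length=True),
                      dtype=int)


def proximity_score(member_xy: np.ndarray, panck_xy: np.ndarray,
                    r: float) -> float:
    """Mean pan-CK+ neighbor count over member cells; NaN for an empty subset."""
    member_xy = np.asarray(member_xy, dtype=float).reshape(-1, 2)
    if len(member_xy) == 0:
        return float("nan")
    return float(count_neighbors_within(member_xy, panck_xy, r).mean())


def subregional_density(n_tumor: int, n_stroma: int,
                        areas: tuple[float, float, float]) -> tuple[float, float, float]:
    """(tumor, stroma, overall) densities in cells/mm².

    A region with zero area and zero cells has density 0; cells counted in a
    zero-area region indicate an inconsistent partition and raise.
    """
    tumor_area, stroma_area, tissue_area = areas
    n_total = n_tumor + n_stroma

    def _one(n, a, name):
        if a <= 0:
            if n > 0:
                raise IntegrityError(f"{n} cells in zero-area {name} region")
            return 0.0
        return n / a

    return (_one(n_tumor, tumor_area, "tumor"),
            _one(n_stroma, stroma_area, "stroma"),
            _one(n_total, tissue_area, "tissue"))


def slide_metrics(table: CellTable, membership: MembershipMatrix,
                  partition: RegionPartition, config: AnalysisConfig) -> pd.DataFrame:
    """Per-subpopulation metrics for one slide (rows = the 88 labels).

    Tumor cells for the proximity score are *all* pan-CK+ cells regardless of
    the region mask: the score is defined against cells, not masks.
    """
    xy = table.coords()
    panck_xy = xy[membership.positivity["panCK"].to_numpy()]
    in_tumor = partition.cell_is_tumor
    areas = (partition.tumor_area_mm2, partition.stroma_area_mm2,
             partition.tissue_area_mm2)
    r = config.proximity_radius_um

    rows = []
    m = membership.matrix.to_numpy()
    for j, label in enumerate(membership.labels):
        members = m[:, j]
        n_tumor = int((members & in_tumor).sum())
        n_stroma = int((members & ~in_tumor).sum())
        d_tumor, d_stroma, d_overall = subregional_density(n_tumor, n_stroma, areas)
        rows.append({
            "label": label,
            "n_cells_tumor": n_tumor,
            "n_cells_stroma": n_stroma,
            "n_cells_total": n_tumor + n_stroma,
            "density_tumor": d_tumor,
            "density_stroma": d_stroma,
            "density_overall": d_overall,
            "proximity_score": proximity_score(xy[members], panck_xy, r),
            "present": bool(members.any()),
        })
    return pd.DataFrame(rows).set_index("label")


# --------------------------------------------------------------------------
# patient feature table
# --------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """One row per patient; columns ``<label>__<metric>`` plus clinical fields
    and the analysis splits for the index subset."""

    data: pd.DataFrame
    index_label: str = INDEX_LABEL

    def feature(self, label: str, metric: str) -> pd.Series:
        return self.data[f"{label}__{metric}"]


def median_split(scores: pd.Series) -> pd.Series:
    """Survival-rule proximity split: 'high' iff score >= cohort median.

    The median is taken over patients with a defined score; missing scores
    stay missing.  With an even cohort the median is the midpoint of the two
    central values.
    """
    med = scores.median(skipna=True)
    out = pd.Series(pd.NA, index=scores.index, dtype=object)
    defined = scores.notna()
    out[defined] = np.where(scores[defined] >= med, "high", "low")
    return out


def response_split(scores: pd.Series) -> pd.Series:
    """Response-rule proximity split among present patients: 'high' iff any
    tumor cell lies within r (score > 0), else 'low'."""
    out = pd.Series(pd.NA, index=scores.index, dtype=object)
    defined = scores.notna()
    out[defined] = np.where(scores[defined] > 0, "high", "low")
    return out


def build_feature_table(metrics_by_slide: dict[str, pd.DataFrame],
                        records: list[PatientRecord],
                        config: AnalysisConfig,
                        split_labels: tuple[str, ...] = (INDEX_LABEL,)) -> FeatureTable:
    """Assemble the patient x (subpopulation x metric) flat table.

    Each patient maps to exactly one slide; a patient without a slide is an
    error, a slide without a patient is excluded with a warning.  For every
    label in ``split_labels`` the presence group and both proximity splits
    are materialised.
    """
    clin = clinical_frame(records)
    missing = [r.patient_id for r in records if r.slide_id not in metrics_by_slide]
    if missing:
        raise TableValidationError(
            f"patients without a slide in inputs: {missing}")
    unused = set(metrics_by_slide) - set(clin["slide_id"])
    if unused:
        warnings.warn(f"slides without a patient record excluded: {sorted(unused)}")

    wide_rows = []
    for r in records:
        sm = metrics_by_slide[r.slide_id]
        row = {}
        for label in sm.index:
            for metric in METRICS:
                row[f"{label}__{metric}"] = sm.loc[label, metric]
        wide_rows.append(row)
    wide = pd.DataFrame(wide_rows)
    data = pd.concat([clin.reset_index(drop=True), wide], axis=1)
    data = data.set_index("patient_id", drop=False)

    for label in split_labels:
        present = data[f"{label}__present"].astype(bool)
        scores = data[f"{label}__proximity_score"]
        data[f"{label}__presence_group"] = np.where(present, "present", "absent")
        data[f"{label}__prox_group_response"] = response_split(scores)
        data[f"{label}__prox_group_survival"] = median_split(scores)
    return FeatureTable(data=data)
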