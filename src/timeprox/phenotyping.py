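"""Combinatorial phenotyping of single cells from marker intensities.

Cells are gated positive/negative per marker by a threshold (inclusive),
checkpoint-positive cells (PD-1, PD-L1) are further stratified into
low/mid/high expression tertiles, and every cell is assigned to the
subpopulation taxonomy: 8 lineage classes x 11 checkpoint selectors = 88
labels.  Lineage classes are deliberately *not* mutually exclusive — the
global CD8+ class overlaps its FoxP3+/- splits, because both the global
pool and the splits are analysed; only "other" (negative for CD8, FoxP3,
CD163 and pan-CK) is exclusive by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHECKPOINT_MARKERS, MARKERS, AnalysisConfig
from .errors import SchemaError
from .io import CellTable

#: Lineage classes, taxonomy-major order.
LINEAGES = (
    "CD8+",          # global cytotoxic T cells
    "CD8+FoxP3-",    # conventional CD8 T cells
    "CD8+FoxP3+",    # rare double-positive T cells (the index lineage)
    "FoxP3+",        # global regulatory-phenotype T cells
    "CD8-FoxP3+",    # conventional Tregs
    "CD163+",        # macrophages
    "panCK+",        # tumor (epithelial) cells
    "other",         # negative for all four lineage markers
)

#: Checkpoint-state selectors crossed with every lineage.
SELECTORS = (
    "any",
    "PD1-", "PD1+", "PD1low", "PD1mid", "PD1high",
    "PDL1-", "PDL1+", "PDL1low", "PDL1mid", "PDL1high",
)

#: The subset the biomarker analysis centres on.
INDEX_LABEL = "CD8+FoxP3+_PD1+"

LEVELS = ("neg", "low", "mid", "high")


def label_for(lineage: str, selector: str) -> str:
    return f"{lineage}_{selector}"


def enumerate_taxonomy() -> list[str]:
    """The 88 subpopulation labels, lineage-major deterministic order."""
    return [label_for(lin, sel) for lin in LINEAGES for sel in SELECTORS]


# --------------------------------------------------------------------------
# gating
# --------------------------------------------------------------------------

def gate_positivity(table: CellTable, thresholds: dict[str, float]) -> pd.DataFrame:
    """Boolean positivity per marker; threshold-inclusive (>=)."""
    bad = [m for m, t in thresholds.items() if t <= 0]
    if bad:
        raise SchemaError(f"non-positive threshold for {bad}")
    out = {}
    for m in MARKERS:
        out[m] = table.df[f"intensity_{m}"].to_numpy() >= thresholds[m]
    return pd.DataFrame(out, index=table.df.index)


def compute_tertiles(values: np.ndarray) -> tuple[float, float] | None:
    """Tertile boundaries (1/3 and 2/3 quantiles, linear interpolation) of
    positive-cell intensities for one checkpoint marker.

    Returns ``None`` when fewer than three positive cells exist: tertiles
    are undefined and all positives fall in the "low" level (a warning is
    emitted).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        warnings.warn("fewer than 3 positive cells: tertiles undefined, "
                      "all positives assigned 'low'")
        return None
    q_lo, q_hi = np.quantile(values, [1 / 3, 2 / 3])
    return float(q_lo), float(q_hi)


def assign_levels(intensity: np.ndarray, positive: np.ndarray,
                  tertiles: tuple[float, float] | None) -> np.ndarray:
    """Per-cell level in {neg, low, mid, high}.

    Ties at a boundary go downward (<= q_lo -> low, <= q_hi -> mid), so an
    all-identical positive population is entirely "low".
    """
    lev = np.full(intensity.shape, "neg", dtype=object)
    if tertiles is None:
        lev[positive] = "low"
        return lev
    q_lo, q_hi = tertiles
    pos = positive
    lev[pos & (intensity <= q_lo)] = "low"
    lev[pos & (intensity > q_lo) & (intensity <= q_hi)] = "mid"
    lev[pos & (intensity > q_hi)] = "high"
    return lev


@dataclass
class CheckpointGates:
    """Positivity thresholds and tertile boundaries for PD-1 and PD-L1."""

    thresholds: dict[str, float]
    tertiles: dict[str, tuple[float, float] | None]

    def __post_init__(self):
        for m, t in self.tertiles.items():
            if t is not None:
                q_lo, q_hi = t
                thr = self.thresholds[m]
                if not (q_lo <= q_hi and q_lo >= thr and q_hi >= thr):
                    raise SchemaError(
                        f"{m}: tertile boundaries must satisfy threshold <= q_lo <= q_hi")

    def to_dict(self) -> dict:
        return {"thresholds": dict(self.thresholds),
                "tertiles": {m: list(t) if t else None for m, t in self.tertiles.items()}}


def compute_gates(tables: list[CellTable], config: AnalysisConfig) -> CheckpointGates:
    """Checkpoint gates with cohort-pooled tertiles (``tertile_scope: cohort``).

    Positive-cell intensities of PD-1 / PD-L1 are pooled over every slide in
    the cohort before the tertile boundaries are taken, so "high" means high
    relative to the whole batch-processed cohort.
    """
    tertiles: dict[str, tuple[float, float] | None] = {}
    for m in CHECKPOINT_MARKERS:
        thr = config.thresholds[m]
        pooled = np.concatenate([
            t.df[f"intensity_{m}"].to_numpy(dtype=float) for t in tables
        ]) if tables else np.empty(0)
        tertiles[m] = compute_tertiles(pooled[pooled >= thr])
    return CheckpointGates(thresholds={m: config.thresholds[m] for m in CHECKPOINT_MARKERS},
                           tertiles=tertiles)


# --------------------------------------------------------------------------
# membership
# --------------------------------------------------------------------------

@dataclass
class MembershipMatrix:
    """Cells x 88 boolean membership plus the underlying flags and levels."""

    labels: list[str]
    matrix: pd.DataFrame            # cells x labels, bool
    positivity: pd.DataFrame        # cells x markers, bool
    levels: pd.DataFrame            # cells x checkpoint markers, {neg,low,mid,high}

    def counts(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    def members(self, label: str) -> np.ndarray:
        return self.matrix[label].to_numpy()


def _lineage_masks(pos: pd.DataFrame) -> dict[str, np.ndarray]:
    cd8 = pos["CD8"].to_numpy()
    foxp3 = pos["FoxP3"].to_numpy()
    cd163 = pos["CD163"].to_numpy()
    panck = pos["panCK"].to_numpy()
    return {
        "CD8+": cd8,
        "CD8+FoxP3-": cd8 & ~foxp3,
        "CD8+FoxP3+": cd8 & foxp3,
        "FoxP3+": foxp3,
        "CD8-FoxP3+": foxp3 & ~cd8,
        "CD163+": cd163,
        "panCK+": panck,
        "other": ~(cd8 | foxp3 | cd163 | panck),
    }


def _selector_masks(pos: pd.DataFrame, levels: pd.DataFrame,
                    n: int) -> dict[str, np.ndarray]:
    masks = {"any": np.ones(n, dtype=bool)}
    for m, tag in (("PD1", "PD1"), ("PDL1", "PDL1")):
        p = pos[m].to_numpy()
        lev = levels[m].to_numpy()
        masks[f"{tag}-"] = ~p
        masks[f"{tag}+"] = p
        for l in ("low", "mid", "high"):
            masks[f"{tag}{l}"] = p & (lev == l)
    return masks


def assign_memberships(table: CellTable, gates: CheckpointGates,
                       config: AnalysisConfig) -> MembershipMatrix:
    """Assign every cell its (multi-)membership across the 88 labels."""
    pos = gate_positivity(table, config.thresholds)
    levels = {}
    for m in CHECKPOINT_MARKERS:
        levels[m] = assign_levels(table.df[f"intensity_{m}"].to_numpy(dtype=float),
                                  pos[m].to_numpy(), gates.tertiles[m])
    levels = pd.DataFrame(levels, index=table.df.index)
    lin = _lineage_masks(pos)
    sel = _selector_masks(pos, levels, len(table.df))
    labels = enumerate_taxonomy()
    data = {label_for(l, s): lin[l] & sel[s] for l in LINEAGES for s in SELECTORS}
    matrix = pd.DataFrame(data, index=table.df.index, columns=labels)
    return MembershipMatrix(labels=labels, matrix=matrix, positivity=pos, levels=levels)


def membership_long(table: CellTable, membership: MembershipMatrix) -> pd.DataFrame:
    """Long-format (slide_id, cell_id, label) export of the membership matrix."""
    rows = []
    sid = table.df["slide_id"].to_numpy()
    cid = table.df["cell_id"].to_numpy()
    m = membership.matrix.to_numpy()
    for j, label in enumerate(membership.labels):
        idx = np.flatnonzero(m[:, j])
        rows.append(pd.DataFrame({"slide_id": sid[idx], "cell_id": cid[idx],
                                  "label": label}))
    return pd.concat(rows, ignore_index=True)
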