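"""On-disk data model: cell tables, clinical tables, cohort summaries.

The cell table is the post-segmentation product of a multiplexed-IHC
workflow: one row per nucleus, centroid coordinates in μm, one intensity
column per marker.  The clinical table holds one row per patient with
RECIST best response and OS/PFS follow-up.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MARKERS, AnalysisConfig
from .errors import SchemaError, TableValidationError

INTENSITY_COLUMNS = tuple(f"intensity_{m}" for m in MARKERS)
CELL_COLUMNS = ("slide_id", "cell_id", "x_um", "y_um") + INTENSITY_COLUMNS

SEX_LEVELS = ("male", "female")
SMOKING_LEVELS = (">=400", "<400")
HISTOLOGY_LEVELS = ("adenocarcinoma", "non-adenocarcinoma")
STAGE_LEVELS = ("IIIB/IIIC", "IV")
COMBINATION_LEVELS = ("mono", "anti-CTLA-4", "chemo")
RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")
RESPONDER_LEVELS = ("CR", "PR")  # RECIST objective response
TREATMENT_LINES = (1, 2, 3)

CLINICAL_COLUMNS = (
    "patient_id", "slide_id", "age", "sex", "smoking", "histology", "stage",
    "pdl1_tps", "treatment_line", "combination", "best_response",
    "os_months", "os_event", "pfs_months", "pfs_event",
)


# --------------------------------------------------------------------------
# cell tables
# --------------------------------------------------------------------------

class CellTable:
    """Validated per-cell table (possibly spanning several slides).

    Thin wrapper around a :class:`pandas.DataFrame`; unknown columns are
    preserved as opaque annotations and row order is kept as read.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            df = _validate_cells(df)
        self.df = df

    # -- construction -------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, config: AnalysisConfig | None = None) -> "CellTable":
        df = pd.read_csv(path)
        if config is not None and config.column_map:
            df = df.rename(columns=config.column_map)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    # -- convenience --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def slide_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["slide_id"]))

    def coords(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    def intensities(self) -> pd.DataFrame:
        return self.df[list(INTENSITY_COLUMNS)]

    def per_slide(self):
        """Yield (slide_id, CellTable) in first-appearance order."""
        for sid in self.slide_ids:
            yield sid, CellTable(self.df[self.df["slide_id"] == sid].reset_index(drop=True),
                                 validate=False)

    def equals(self, other: "CellTable", coord_tol: float = 1e-6) -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if c in ("x_um", "y_um") or c.startswith("intensity_"):
                if not np.allclose(a[c].to_numpy(float), b[c].to_numpy(float),
                                   atol=coord_tol, rtol=0):
                    return False
            elif not (a[c].astype(str).to_numpy() == b[c].astype(str).to_numpy()).all():
                return False
        return True


def _validate_cells(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing required column(s): {', '.join(missing)}")
    df = df.reset_index(drop=True)
    for c in ("x_um", "y_um") + INTENSITY_COLUMNS:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise TableValidationError(
                f"column {c} is non-numeric or non-finite", row=int(bad[0]))
        df[c] = vals.astype(float)
    for c in INTENSITY_COLUMNS:
        neg = np.flatnonzero(df[c].to_numpy() < 0)
        if neg.size:
            raise TableValidationError(f"negative intensity in {c}", row=int(neg[0]))
    dup = df.duplicated(subset=["slide_id", "cell_id"])
    if dup.any():
        raise TableValidationError("(slide_id, cell_id) not unique",
                                   row=int(np.flatnonzero(dup.to_numpy())[0]))
    return df


def read_cell_table(path: str | Path, config: AnalysisConfig | None = None) -> CellTable:
    """Read and validate a cell-table CSV (column_map from config applied)."""
    return CellTable.from_csv(path, config)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    table.to_csv(path)


# --------------------------------------------------------------------------
# clinical tables
# --------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One patient: baseline clinicopathologic features, response, survival."""

    patient_id: str
    slide_id: str
    age: float
    sex: str
    smoking: str
    histology: str
    stage: str
    pdl1_tps: float
    treatment_line: int
    combination: str
    best_response: str
    os_months: float
    os_event: int
    pfs_months: float
    pfs_event: int
    responder: bool = field(init=False)
    tps_stratum: str = field(init=False)

    def __post_init__(self):
        self.responder = self.best_response in RESPONDER_LEVELS
        self.tps_stratum = tps_stratum(self.pdl1_tps)


def tps_stratum(tps: float) -> str:
    """Clinical PD-L1 TPS strata: <1%, 1-49%, >=50%."""
    if tps < 1:
        return "<1"
    if tps < 50:
        return "1-49"
    return ">=50"


def _check_level(value, levels, name, row):
    if value not in levels:
        raise TableValidationError(f"unknown {name} category {value!r}", row=row)
    return value


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read and validate the per-patient clinical CSV."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s): {', '.join(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise TableValidationError(f"duplicate patient_id {dup!r}")
    records = []
    for i, row in df.iterrows():
        for tcol in ("os_months", "pfs_months"):
            if not np.isfinite(row[tcol]) or row[tcol] < 0:
                raise TableValidationError(f"{tcol} must be >= 0", row=int(i))
        if row["pfs_months"] > row["os_months"]:
            raise TableValidationError("pfs_months > os_months", row=int(i))
        if not 0 <= row["pdl1_tps"] <= 100:
            raise TableValidationError("pdl1_tps outside [0, 100]", row=int(i))
        for ev in ("os_event", "pfs_event"):
            if int(row[ev]) not in (0, 1):
                raise TableValidationError(f"{ev} must be 0/1", row=int(i))
        line = int(row["treatment_line"])
        if line not in TREATMENT_LINES:
            raise TableValidationError(f"unknown treatment_line {line}", row=int(i))
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            slide_id=str(row["slide_id"]),
            age=float(row["age"]),
            sex=_check_level(row["sex"], SEX_LEVELS, "sex", int(i)),
            smoking=_check_level(row["smoking"], SMOKING_LEVELS, "smoking", int(i)),
            histology=_check_level(row["histology"], HISTOLOGY_LEVELS, "histology", int(i)),
            stage=_check_level(row["stage"], STAGE_LEVELS, "stage", int(i)),
            pdl1_tps=float(row["pdl1_tps"]),
            treatment_line=line,
            combination=_check_level(row["combination"], COMBINATION_LEVELS,
                                     "combination", int(i)),
            best_response=_check_level(row["best_response"], RESPONSE_LEVELS,
                                       "best_response", int(i)),
            os_months=float(row["os_months"]),
            os_event=int(row["os_event"]),
            pfs_months=float(row["pfs_months"]),
            pfs_event=int(row["pfs_event"]),
        ))
    return records


def clinical_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Records -> DataFrame with derived responder flag and TPS stratum."""
    return pd.DataFrame([vars(r) for r in records])


def _pct(count: int, n: int) -> float:
    """Percentage with one decimal, round half up (clinical-table style)."""
    d = decimal.Decimal(count * 100) / decimal.Decimal(n)
    return float(d.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


_SUMMARY_VARS = {
    "sex": SEX_LEVELS,
    "smoking": SMOKING_LEVELS,
    "histology": HISTOLOGY_LEVELS,
    "stage": STAGE_LEVELS,
    "tps_stratum": ("<1", "1-49", ">=50"),
    "treatment_line": TREATMENT_LINES,
    "combination": COMBINATION_LEVELS,
    "best_response": RESPONSE_LEVELS,
}


def summarize_cohort(records: list[PatientRecord]) -> pd.DataFrame:
    """Counts and percentages per baseline category, plus the responder rate.

    Percentages are computed from the counts (one decimal, round half up);
    rows within one variable therefore sum to 100.0 up to rounding.
    """
    if not records:
        raise TableValidationError("summarize_cohort: empty record list")
    df = clinical_frame(records)
    n = len(df)
    rows = [("n", "patients", n, 100.0),
            ("age", "median", float(df["age"].median()), float("nan"))]
    for var, levels in _SUMMARY_VARS.items():
        counts = df[var].value_counts()
        for lvl in levels:
            c = int(counts.get(lvl, 0))
            rows.append((var, str(lvl), c, _pct(c, n)))
    n_resp = int(df["responder"].sum())
    rows.append(("responder", "CR+PR", n_resp, _pct(n_resp, n)))
    out = pd.DataFrame(rows, columns=["variable", "category", "count", "pct"])
    return out


def summary_lookup(summary: pd.DataFrame, variable: str, category: str) -> tuple[int, float]:
    row = summary[(summary["variable"] == variable) & (summary["category"] == category)]
    if row.empty:
        raise KeyError((variable, category))
    return int(row["count"].iloc[0]), float(row["pct"].iloc[0])


def match_patients_to_slides(records: list[PatientRecord],
                             slide_ids: list[str]) -> dict[str, str]:
    """Map patient_id -> slide_id; error on unmatched patients, warn+drop extras."""
    available = set(slide_ids)
    mapping = {}
    for r in records:
        if r.slide_id not in available:
            raise TableValidationError(
                f"patient {r.patient_id}: slide {r.slide_id} not found among inputs")
        mapping[r.patient_id] = r.slide_id
    unused = available - set(mapping.values())
    if unused:
        warnings.warn(f"slides without a patient record excluded: {sorted(unused)}")
    return mapping
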