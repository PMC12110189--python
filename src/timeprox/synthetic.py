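"""Synthetic mIHC cohorts with planted ground truth.

Each slide emulates the structure the analysis assumes: clustered pan-CK+
tumor nests (Thomas cluster process) in interstitial stroma, immune
lineages as uniform Poisson processes (CD163+ and CD8+ frequent, FoxP3+
sparse, CD8+FoxP3+ rare), bimodal log-normal marker intensities, and a
patient level where response and survival are linked to a planted
proximity effect: responders carry more CD8+FoxP3+PD-1+ cells and those
cells sit near tumor-nest centres, while non-responders place them
uniformly.  Survival follows an exponential proportional-hazards model
with a planted log-HR on the proximity group.

Everything is deterministic given the master seed (per-patient generators
are spawned from a SeedSequence), so a fixed seed reproduces byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MARKERS
from .io import CellTable

#: Marginal category frequencies of the reference 27-patient cohort.
REFERENCE_N = 27
REFERENCE_MARGINALS = {
    "sex": {"male": 17, "female": 10},
    "smoking": {">=400": 11, "<400": 16},
    "histology": {"adenocarcinoma": 13, "non-adenocarcinoma": 14},
    "stage": {"IIIB/IIIC": 3, "IV": 24},
    "tps_stratum": {"<1": 8, "1-49": 11, ">=50": 8},
    "treatment_line": {1: 12, 2: 13, 3: 2},
    "combination": {"mono": 16, "anti-CTLA-4": 3, "chemo": 8},
    "best_response": {"CR": 0, "PR": 11, "SD": 4, "PD": 12},
}


@dataclass
class SimulationParams:
    """Generator settings; the defaults are the simulated study conditions."""

    n_patients: int = 27
    extent_mm: float = 1.0                      # square slide side, mm
    # tumor nests: Thomas cluster process
    nest_intensity_per_mm2: float = 3.0         # parent (nest) rate kappa
    mean_cells_per_nest: float = 200.0          # offspring mean mu_n
    nest_sigma_um: float = 75.0                 # nest dispersion
    # immune abundance, cells/mm² (CD8+FoxP3+ is the rare index lineage)
    immune_density: dict[str, float] = field(default_factory=lambda: {
        "CD8+FoxP3-": 300.0, "CD8-FoxP3+": 60.0, "CD8+FoxP3+": 12.0,
        "CD163+": 250.0, "other": 200.0,
    })
    #: fraction of each lineage that is PD-1+ / PD-L1+
    pd1_fraction: dict[str, float] = field(default_factory=lambda: {
        "CD8+FoxP3-": 0.30, "CD8-FoxP3+": 0.40, "CD8+FoxP3+": 0.60,
        "CD163+": 0.20, "other": 0.10, "panCK+": 0.05,
    })
    pdl1_fraction: dict[str, float] = field(default_factory=lambda: {
        "CD8+FoxP3-": 0.20, "CD8-FoxP3+": 0.20, "CD8+FoxP3+": 0.40,
        "CD163+": 0.50, "other": 0.15,
    })  # panCK+ PD-L1 positivity is the patient's planted TPS
    #: responders: abundance multiplier on the CD8+FoxP3+PD-1+ index subset
    responder_index_multiplier: float = 2.5
    #: responders: index cells placed at |N(delta, sigma_d)| μm from a nest centre
    proximity_offset_um: float = 15.0
    proximity_offset_sd_um: float = 10.0
    #: bimodal log-normal intensity model (log-units); mu1 - mu0 = 3 keeps
    #: gating well separated so the spatial statistics are what is under test
    intensity_mu_neg: float = 0.0
    intensity_sigma_neg: float = 0.5
    intensity_mu_pos: float = 3.0
    intensity_sigma_pos: float = 0.5
    #: responder prevalence (11/27 in the reference cohort)
    responder_prevalence: float = 11 / 27
    cr_fraction_of_responders: float = 0.0      # reference cohort had CR 0, PR 11
    sd_fraction_of_nonresponders: float = 4 / 16
    #: exponential PH survival with log-HR on the (low) proximity group
    survival_log_hr: float = float(np.log(6.0))
    os_median_high_months: float = 24.0
    pfs_median_high_months: float = 10.0
    followup_window_months: tuple[float, float] = (18.0, 36.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.extent_mm <= 0:
            raise ValueError("n_patients >= 1 and extent_mm > 0 required")
        area = self.extent_mm ** 2
        if self.nest_intensity_per_mm2 * self.mean_cells_per_nest * area <= 0:
            raise ValueError("parameters yield an expected tumor-cell count of 0")
        if not 0 <= self.responder_prevalence <= 1:
            raise ValueError("responder_prevalence must be in [0, 1]")
        if self.intensity_mu_pos <= self.intensity_mu_neg:
            raise ValueError("positive intensity mode must exceed negative mode")
        if any(v <= 0 for v in self.immune_density.values()):
            raise ValueError("immune densities must be > 0")


@dataclass
class PlantedTruth:
    """Ground truth the generator committed to: per-patient flags and scores,
    and per-cell phenotypes per slide."""

    patients: pd.DataFrame                 # patient_id, responder, true_prox_high, ...
    cells: dict[str, pd.DataFrame]         # slide_id -> per-cell truth


@dataclass
class Cohort:
    clinical: pd.DataFrame
    slides: dict[str, CellTable]
    truth: PlantedTruth
    params: SimulationParams


# --------------------------------------------------------------------------
# slide generation
# --------------------------------------------------------------------------

def _thomas_points(rng, extent_um, kappa_per_mm2, mu, sigma):
    """Stationary Thomas process restricted to the window: parents are laid
    in a 4-sigma padded region so the expected in-window count is exactly
    kappa * mu * area."""
    pad = 4 * sigma
    lo, hi = -pad, extent_um + pad
    area_mm2 = ((hi - lo) / 1000.0) ** 2
    n_parents = rng.poisson(kappa_per_mm2 * area_mm2)
    parents = rng.uniform(lo, hi, size=(n_parents, 2))
    pts = []
    for p in parents:
        n = rng.poisson(mu)
        pts.append(p + rng.normal(0, sigma, size=(n, 2)))
    pts = np.concatenate(pts) if pts else np.empty((0, 2))
    inside = ((pts >= 0) & (pts <= extent_um)).all(axis=1)
    return pts[inside], parents


def _near_nest_points(rng, n, parents, extent_um, delta, sigma_d):
    """Index-cell placement for responders: |N(delta, sigma_d)| from a random
    nest centre, resampled (then clipped) to stay inside the window."""
    out = np.empty((n, 2))
    for i in range(n):
        for _ in range(20):
            c = parents[rng.integers(len(parents))]
            d = abs(rng.normal(delta, sigma_d))
            theta = rng.uniform(0, 2 * np.pi)
            pt = c + d * np.array([np.cos(theta), np.sin(theta)])
            if (pt >= 0).all() and (pt <= extent_um).all():
                break
        out[i] = np.clip(pt, 0, extent_um)
    return out


def generate_slide(params: SimulationParams, slide_id: str, responder: bool,
                   tps: float, rng: np.random.Generator) -> tuple[CellTable, pd.DataFrame]:
    """One slide: cell table plus the per-cell planted truth."""
    params.validate()
    L = params.extent_mm * 1000.0
    area = params.extent_mm ** 2

    tumor_xy, parents = _thomas_points(
        rng, L, params.nest_intensity_per_mm2, params.mean_cells_per_nest,
        params.nest_sigma_um)
    if len(parents) == 0:
        parents = np.array([[L / 2, L / 2]])

    xs, lineages, pd1, pdl1 = [tumor_xy], ["panCK+"] * len(tumor_xy), [], []
    pd1.append(rng.random(len(tumor_xy)) < params.pd1_fraction["panCK+"])
    pdl1.append(rng.random(len(tumor_xy)) < tps / 100.0)  # planted TPS

    for lineage, dens in params.immune_density.items():
        p1 = params.pd1_fraction[lineage]
        pl = params.pdl1_fraction[lineage]
        if lineage == "CD8+FoxP3+":
            # split the rare index lineage by PD-1 status so the planted
            # effect (abundance x placement) applies to the PD-1+ part only
            mult = params.responder_index_multiplier if responder else 1.0
            n_idx = rng.poisson(dens * p1 * mult * area)
            n_rest = rng.poisson(dens * (1 - p1) * area)
            if responder and n_idx:
                xy_idx = _near_nest_points(rng, n_idx, parents, L,
                                           params.proximity_offset_um,
                                           params.proximity_offset_sd_um)
            else:
                xy_idx = rng.uniform(0, L, size=(n_idx, 2))
            xy_rest = rng.uniform(0, L, size=(n_rest, 2))
            xs += [xy_idx, xy_rest]
            lineages += [lineage] * (n_idx + n_rest)
            pd1 += [np.ones(n_idx, bool), np.zeros(n_rest, bool)]
            pdl1.append(rng.random(n_idx + n_rest) < pl)
        else:
            n = rng.poisson(dens * area)
            xs.append(rng.uniform(0, L, size=(n, 2)))
            lineages += [lineage] * n
            pd1.append(rng.random(n) < p1)
            pdl1.append(rng.random(n) < pl)

    xy = np.concatenate(xs)
    lineage = np.array(lineages)
    pd1 = np.concatenate(pd1)
    pdl1 = np.concatenate(pdl1)
    n_cells = len(xy)

    positive = {
        "panCK": lineage == "panCK+",
        "CD163": lineage == "CD163+",
        "CD8": np.isin(lineage, ["CD8+FoxP3-", "CD8+FoxP3+"]),
        "FoxP3": np.isin(lineage, ["CD8-FoxP3+", "CD8+FoxP3+"]),
        "PD1": pd1,
        "PDL1": pdl1,
    }
    df = pd.DataFrame({
        "slide_id": slide_id,
        "cell_id": [f"c{i:05d}" for i in range(n_cells)],
        "x_um": np.round(xy[:, 0], 3),
        "y_um": np.round(xy[:, 1], 3),
    })
    for m in MARKERS:
        mu = np.where(positive[m], params.intensity_mu_pos, params.intensity_mu_neg)
        sd = np.where(positive[m], params.intensity_sigma_pos, params.intensity_sigma_neg)
        df[f"intensity_{m}"] = np.round(rng.lognormal(mu, sd), 4)

    truth = pd.DataFrame({
        "slide_id": slide_id,
        "cell_id": df["cell_id"],
        "lineage": lineage,
        "pd1_pos": pd1,
        "pdl1_pos": pdl1,
        "is_index": (lineage == "CD8+FoxP3+") & pd1,
    })
    return CellTable(df, validate=False), truth


# --------------------------------------------------------------------------
# clinical generation
# --------------------------------------------------------------------------

def _categorical(rng, n, levels, probs):
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)


def generate_clinical(params: SimulationParams,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Patient-level table with planted response, proximity group and survival.

    Clinicopathologic covariates are drawn from the reference cohort's
    marginal frequencies, independent of response (null covariates); PD-L1
    TPS is planted uninformative of response.  Returns the clinical table
    with the truth columns ``responder`` and ``true_prox_high`` attached.
    """
    params.validate()
    n = params.n_patients
    responder = rng.random(n) < params.responder_prevalence
    best = np.empty(n, dtype=object)
    r_idx = np.flatnonzero(responder)
    best[r_idx] = np.where(rng.random(len(r_idx)) < params.cr_fraction_of_responders,
                           "CR", "PR")
    nr_idx = np.flatnonzero(~responder)
    best[nr_idx] = np.where(rng.random(len(nr_idx)) < params.sd_fraction_of_nonresponders,
                            "SD", "PD")

    m = REFERENCE_MARGINALS

    def probs(var):
        c = m[var]
        tot = sum(c.values())
        return list(c.keys()), [v / tot for v in c.values()]

    sex_l, sex_p = probs("sex")
    smk_l, smk_p = probs("smoking")
    his_l, his_p = probs("histology")
    stg_l, stg_p = probs("stage")
    lin_l, lin_p = probs("treatment_line")
    cmb_l, cmb_p = probs("combination")
    tps_l, tps_p = probs("tps_stratum")
    stratum = _categorical(rng, n, tps_l, tps_p)
    tps = np.where(stratum == "<1", rng.uniform(0, 0.9, n),
                   np.where(stratum == "1-49", rng.uniform(1, 49, n),
                            rng.uniform(50, 100, n)))

    # planted proximity group: responders carry the near-nest placement
    true_prox_high = responder.copy()
    hr_mult = np.where(true_prox_high, 1.0, np.exp(params.survival_log_hr))
    lam_os = np.log(2) / params.os_median_high_months * hr_mult
    lam_prog = np.log(2) / params.pfs_median_high_months * hr_mult
    t_death = rng.exponential(1 / lam_os)
    t_prog = rng.exponential(1 / lam_prog)
    censor = rng.uniform(*params.followup_window_months, size=n)
    os_months = np.minimum(t_death, censor)
    os_event = (t_death <= censor).astype(int)
    t_pfs = np.minimum(t_prog, t_death)
    pfs_months = np.minimum(t_pfs, censor)
    pfs_event = (t_pfs <= censor).astype(int)

    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "slide_id": [f"S{i:03d}" for i in range(n)],
        "age": np.clip(np.round(rng.normal(58, 9, n)), 30, 85).astype(int),
        "sex": _categorical(rng, n, sex_l, sex_p),
        "smoking": _categorical(rng, n, smk_l, smk_p),
        "histology": _categorical(rng, n, his_l, his_p),
        "stage": _categorical(rng, n, stg_l, stg_p),
        "pdl1_tps": np.round(tps, 1),
        "treatment_line": _categorical(rng, n, lin_l, lin_p).astype(int),
        "combination": _categorical(rng, n, cmb_l, cmb_p),
        "best_response": best,
        "os_months": np.round(os_months, 3),
        "os_event": os_event,
        "pfs_months": np.round(pfs_months, 3),
        "pfs_event": pfs_event,
        "responder": responder,
        "true_prox_high": true_prox_high,
    })


def generate_cohort(params: SimulationParams, with_slides: bool = True) -> Cohort:
    """Full cohort: clinical table, one slide per patient, planted truth."""
    ss = np.random.SeedSequence(params.seed)
    clin_rng = np.random.default_rng(ss.spawn(1)[0])
    clinical = generate_clinical(params, clin_rng)

    slides: dict[str, CellTable] = {}
    cell_truth: dict[str, pd.DataFrame] = {}
    patient_truth = clinical[["patient_id", "slide_id", "responder",
                              "true_prox_high", "pdl1_tps"]].copy()
    if with_slides:
        child_seqs = ss.spawn(1 + params.n_patients)[1:]
        true_scores = []
        from .quantification import proximity_score  # local: avoid import cycle
        for i, row in clinical.iterrows():
            rng = np.random.default_rng(child_seqs[i])
            table, truth = generate_slide(params, row["slide_id"],
                                          bool(row["responder"]),
                                          float(row["pdl1_tps"]), rng)
            slides[row["slide_id"]] = table
            cell_truth[row["slide_id"]] = truth
            xy = table.coords()
            true_scores.append(proximity_score(
                xy[truth["is_index"].to_numpy()],
                xy[(truth["lineage"] == "panCK+").to_numpy()], 30.0))
        patient_truth["true_proximity_score"] = true_scores

    clinical_out = clinical.drop(columns=["responder", "true_prox_high"])
    return Cohort(clinical=clinical_out, slides=slides,
                  truth=PlantedTruth(patients=patient_truth, cells=cell_truth),
                  params=params)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the io-schema CSV dialects plus truth.json (byte-stable per seed)."""
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    for sid, table in cohort.slides.items():
        table.to_csv(outdir / "cells" / f"{sid}.csv")
        cohort.truth.cells[sid].to_csv(outdir / "cells" / f"{sid}.truth.csv",
                                       index=False)
    truth = {
        "seed": cohort.params.seed,
        "n_patients": cohort.params.n_patients,
        "survival_log_hr": cohort.params.survival_log_hr,
        "responder_index_multiplier": cohort.params.responder_index_multiplier,
        "patients": cohort.truth.patients.to_dict(orient="records"),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


# --------------------------------------------------------------------------
# fixed fixtures
# --------------------------------------------------------------------------

def disc_fixture(rng: np.random.Generator, n_tumor: int = 500,
                 disc_radius_um: float = 200.0, extent_um: float = 1000.0,
                 n_immune: int = 50) -> tuple[CellTable, np.ndarray]:
    """Planted two-compartment slide for region-delineation checks: pan-CK+
    cells uniform in a central disc, immune cells uniform in the surrounding
    frame.  Returns the table and the ground-truth in-disc flag."""
    c = extent_um / 2
    r = disc_radius_um * np.sqrt(rng.random(n_tumor))
    th = rng.uniform(0, 2 * np.pi, n_tumor)
    tumor = np.column_stack([c + r * np.cos(th), c + r * np.sin(th)])
    immune = []
    while len(immune) < n_immune:
        pt = rng.uniform(0, extent_um, 2)
        if np.hypot(pt[0] - c, pt[1] - c) > disc_radius_um:
            immune.append(pt)
    immune = np.array(immune)
    xy = np.vstack([tumor, immune])
    in_disc = np.r_[np.ones(n_tumor, bool), np.zeros(n_immune, bool)]
    df = pd.DataFrame({
        "slide_id": "disc",
        "cell_id": [f"c{i:04d}" for i in range(len(xy))],
        "x_um": xy[:, 0], "y_um": xy[:, 1],
    })
    for m in MARKERS:
        pos = in_disc if m == "panCK" else np.zeros(len(xy), bool)
        df[f"intensity_{m}"] = np.where(pos, 20.0, 1.0)
    return CellTable(df, validate=False), in_disc


def reference_clinical_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic transcription of the reference 27-patient cohort.

    Category *counts* per variable match the published baseline table
    exactly (17 male, 11 PR / 4 SD / 12 PD, 24 stage IV, ...) and the median
    age is 58; the joint combinations, TPS values within strata and the
    follow-up times are invented, as the per-patient table is not public.
    """
    n = REFERENCE_N
    rng = np.random.default_rng(seed)

    def column(counts: dict, representative=None):
        vals = []
        for lvl, c in counts.items():
            vals += [representative[lvl] if representative else lvl] * c
        vals = np.array(vals, dtype=object)
        rng.shuffle(vals)  # break cross-variable confounding, keep marginals
        return vals

    ages = np.array([42, 45, 47, 48, 50, 50, 52, 54, 56, 57, 58, 58, 58,
                     58, 59, 60, 62, 63, 64, 65, 65, 66, 68, 70, 72, 74, 75])
    m = REFERENCE_MARGINALS
    df = pd.DataFrame({
        "patient_id": [f"T{i:02d}" for i in range(n)],
        "slide_id": [f"TS{i:02d}" for i in range(n)],
        "age": ages,
        "sex": column(m["sex"]),
        "smoking": column(m["smoking"]),
        "histology": column(m["histology"]),
        "stage": column(m["stage"]),
        "pdl1_tps": column(m["tps_stratum"],
                           representative={"<1": 0.0, "1-49": 25.0, ">=50": 60.0}),
        "treatment_line": column(m["treatment_line"]).astype(int),
        "combination": column(m["combination"]),
        "best_response": column(m["best_response"]),
    })
    pfs = np.round(rng.uniform(1, 20, n), 1)
    os_ = np.round(pfs + rng.uniform(0, 18, n), 1)
    df["os_months"] = os_
    df["os_event"] = rng.integers(0, 2, n)
    df["pfs_months"] = pfs
    df["pfs_event"] = rng.integers(0, 2, n)
    return df
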