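# timeprox

Spatial quantification of the tumor immune microenvironment (TIME) from
multiplexed-immunohistochemistry (mIHC) single-cell tables, and the
statistical battery to evaluate TIME features as immunotherapy biomarkers.

The package is aimed at analysts working with cell-level exports from mIHC
platforms (HALO-style CSVs: one row per segmented nucleus with centroid
coordinates in μm and one fluorescence-intensity column per marker) for a
six-marker panel — pan-CK (tumor), CD163 (macrophages), CD8 (cytotoxic T
cells), FoxP3 (regulatory phenotype), PD-1 and PD-L1 (checkpoint
receptor/ligand) — matched with a per-patient clinical table (RECIST best
response, overall and progression-free survival).

## What it computes

**Phenotyping.** Cells are gated positive/negative per marker by a
threshold; PD-1/PD-L1-positive cells are stratified into low/mid/high
expression levels at the tertiles of the positive-cell intensity
distribution. Eight lineage classes (global CD8⁺, CD8⁺FoxP3⁻, CD8⁺FoxP3⁺,
global FoxP3⁺, CD8⁻FoxP3⁺, CD163⁺, pan-CK⁺, other) crossed with eleven
checkpoint-state selectors (any; PD-1 ⁻/⁺/low/mid/high; PD-L1
⁻/⁺/low/mid/high) define 88 subpopulations; each cell may belong to several
(the global CD8⁺ pool overlaps its FoxP3 splits).

**Regions.** Tumor parenchyma vs. stroma is delineated from pan-CK⁺ cell
aggregation: a Gaussian kernel density of pan-CK⁺ centroids on a grid,
thresholded at a fraction of its peak, small components dropped, holes
filled. Subpopulation densities (cells/mm²) are reported per tumor, stroma
and whole-tissue region.

**Proximity score.** For a subpopulation *S* on a slide with pan-CK⁺ cell
set *T*, and radius *r* = 30 μm,

```
proximity(S) = (1/|S|) Σ_{i∈S} |{ t ∈ T : ‖x_i − x_t‖ ≤ r }|
```

the mean number of tumor cells within 30 μm of each member cell's nucleus
centroid; undefined (missing, never 0) when *S* is absent.

**Biomarker statistics.** Responder (CR/PR) vs. non-responder comparisons by
Mann–Whitney U (Kruskal–Wallis + Dunn for k groups) with Benjamini–Hochberg
correction per feature family; rank-based ROC/AUC; Kaplan–Meier curves with
log-rank tests on presence and median-split proximity groups; and Cox
proportional-hazards regression (own Newton partial-likelihood fitter,
Breslow or Efron ties) with p < 0.1 univariate screening before the
multivariate fit.

**Synthetic cohorts.** A generator produces full cohorts with planted ground
truth: tumor nests from a Thomas cluster process, immune lineages as Poisson
processes, bimodal log-normal intensities, and a planted effect linking
response and survival to the proximity of CD8⁺FoxP3⁺PD-1⁺ cells — the rare
double-positive T-cell subset the analysis centres on.

## Worked example

```python
from timeprox import (AnalysisConfig, SimulationParams, generate_cohort,
                      write_cohort, run_all)
import pandas as pd

params = SimulationParams(n_patients=27, seed=7)
write_cohort(generate_cohort(params), "cohort")
run_all(AnalysisConfig(seed=7), "cohort", "run")
print(pd.read_csv("run/roc.csv").to_string(index=False))
```

prints

```
        feature      auc  n_responder  n_nonresponder
proximity_score 1.000000            9              18
density_overall 0.956790            9              18
       pdl1_tps 0.771605            9              18
```

The planted effect makes the CD8⁺FoxP3⁺PD-1⁺ proximity score (AUC 1.00) and
overall density (0.96) stronger predictors of response than the PD-L1 tumor
proportion score (0.77), which the generator plants as uninformative — the
TPS AUC is pure 27-patient sampling noise around 0.5. The same run's
`cox_pfs.csv` holds the screened multivariate model for progression-free
survival, e.g. the measured proximity-low group at HR 2.52 (95% CI
0.99–6.37): at n = 27 the point estimate of a strong planted hazard is
noisy, which is exactly why the test suite checks recovery at n = 300
(HR within [4, 9] for a planted HR of 6 in ≥ 90% of seeds).

The same workflow is available from the shell:

```
timeprox simulate --seed 7 --n-patients 27 --out cohort
timeprox run-all --inputs cohort --out run --seed 7 --plots
timeprox report --run-dir run
```

`run/report.md` assembles the cohort summary, top differential features by
q-value, the AUC table, log-rank tests and Cox tables, each traceable to a
results CSV.

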