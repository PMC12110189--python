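# Methods

## Data model and assumptions

The pipeline consumes post-segmentation cell tables: nucleus centroids in μm
(origin arbitrary per slide; all statistics are distance- or area-based, so
axis orientation is irrelevant) and one non-negative intensity per marker in
{pan-CK, CD163, CD8, FoxP3, PD-1, PD-L1}. Intensity units and dynamic range
are platform-dependent, so positivity thresholds are configuration, not
constants; the default (exp(1.5) ≈ 4.48) is the midpoint, in log space, of
the synthetic generator's bimodal intensity model and must be re-derived for
real exports. Clinical records carry RECIST best response (responder = CR or
PR), OS and PFS with event flags, and the baseline covariates used in the
survival screen.

## Phenotyping

Positivity is threshold-inclusive (intensity ≥ threshold) so boundary
behaviour is deterministic. PD-1/PD-L1-positive cells are split at the 1/3
and 2/3 quantiles of positive-cell intensity (linear-interpolation quantile
definition); ties at a boundary fall downward (≤ q_lo → low, ≤ q_hi → mid),
so an all-identical positive population is entirely "low". With fewer than
three positive cells the tertiles are undefined: all positives are assigned
"low" and a warning is emitted, keeping the low+mid+high = positive count
identity intact. Tertile scope defaults to cohort-pooled (`tertile_scope:
cohort`) on the assumption that batch-processed staining makes intensities
comparable across slides; per-slide scope is retained as an option because
either convention is defensible when batch effects are suspected.

The taxonomy is 8 lineage classes × 11 checkpoint selectors = 88 labels,
lineage-major order. Lineage classes are deliberately not mutually
exclusive: the analysis needs the global CD8⁺ (and FoxP3⁺) pools *and*
their double-positive/single-positive splits simultaneously, and a
hypothetical CD8⁺CD163⁺ cell belongs to both lineages. Only "other"
(negative for all four lineage markers) is exclusive by construction. The
membership matrix therefore satisfies, per slide: |CD8⁺| = |CD8⁺FoxP3⁻| +
|CD8⁺FoxP3⁺|; |FoxP3⁺| = |CD8⁺FoxP3⁺| + |CD8⁻FoxP3⁺|; and for every lineage
L and checkpoint c, |L×any| = |L×c⁻| + |L×c⁺| and |L×c⁺| = |L×low| +
|L×mid| + |L×high|. These identities are enforced by tests on simulated
slides.

## Tumor/stroma delineation

Segmentation-free region calling from pan-CK⁺ aggregation:

1. grid at `grid_step_um` (default 10 μm) over the cell bounding box padded
   by one bandwidth; half-open grid cells [x, x+step);
2. Gaussian kernel density of pan-CK⁺ centroids, bandwidth
   `kde_bandwidth_um` (default 30 μm, on the scale of 1–2 cell diameters);
3. tumor mask = density ≥ `threshold_fraction` (default 0.10) × peak
   density — a *relative* threshold, robust to the absolute intensity of
   the point pattern, at the cost of being undefined for an empty slide
   (zero pan-CK⁺ cells → zero tumor area, all cells stroma, warning);
4. 4-connected components below `min_region_area_um2` (default 2500 μm²,
   roughly a 3-cell cluster) are dropped; enclosed holes are filled;
5. the tissue mask applies the same fractional rule to the all-cell
   density and is forced to contain the tumor mask, which makes
   tumor + stroma = tissue areas additive by construction;
6. a cell is "tumor" iff its centroid's grid cell is in the tumor mask.

The procedure is translation-invariant, permutation-invariant in row order,
scale-equivariant when coordinates, step and bandwidth are scaled together,
and monotone in `threshold_fraction`. On planted disc-nest fixtures it
recovers the two compartments with balanced accuracy ≈ 0.95–0.98; the
residual error is a ~50 μm halo outside the true tumor boundary where the
thresholded kernel density still exceeds 10% of peak — an inherent property
of density-based region calling, not a bug, and the reason boundary-adjacent
stromal cells are the typical mislabels.

## Proximity score

Distance is centroid-to-centroid Euclidean, boundary-inclusive (≤ r,
default r = 30 μm). Nucleus-boundary distances are not available in a
centroid table; centroid distance is the reproducible surrogate. Tumor
cells for the score are *all* pan-CK⁺ cells regardless of their region
label — the score is defined against cells, not masks. Neighbor counts use
a k-d tree (`scipy.spatial.cKDTree`) and are exact; equality with the O(n²)
brute-force count is an acceptance test. An absent subpopulation has an
undefined score, propagated as missing and excluded pairwise from group
statistics — presence itself is analysed separately, so imputing 0 would
double-count absence as "low proximity".

Two patient-level splits of the index subset (CD8⁺FoxP3⁺PD-1⁺) are
materialised: the *response rule* (among patients with the subset present:
high iff any tumor cell within r, i.e. score > 0) and the *survival rule*
(high iff score ≥ cohort median; with an even cohort the median is the
midpoint of the two central values, and ties at the median go to "high").

## Statistics

* Mann–Whitney U: exact null enumeration when both groups ≤ 8 and no ties,
  otherwise normal approximation with tie and continuity corrections — at
  cohort scale (n ≈ 27) the asymptotic path is the one exercised.
* Kruskal–Wallis with tie correction; Dunn's pairwise z-tests on pooled
  ranks, BH-adjusted within the k(k−1)/2 family.
* Benjamini–Hochberg adjustment is applied within each declared family —
  one family per metric type (e.g. all 88 overall-density-vs-response
  tests), stated in the results rather than assumed.
* AUC is the rank statistic with half-credit ties (= U/(n₁n₀)), orientation
  fixed a priori (larger value → responder) so AUC < 0.5 is reportable
  rather than silently flipped.
* Kaplan–Meier via lifelines; log-rank across groups. No events, or a
  single group, yields a flagged result with NaN p, never a fabricated one.
* Cox proportional hazards: own Newton optimisation of the partial
  likelihood with Breslow (default) or Efron tie handling behind one
  switch; lifelines (Efron-only) serves as an independent cross-check in
  the tests, agreeing to ~1e-6. Covariates are centred for conditioning;
  step-halving guards the ascent; convergence and line-search tolerances
  are relative to 1 + |log-likelihood| (absolute tolerances stall on float
  noise once |ℓ| ~ 10³). Non-convergence or |β| > 15 (monotone likelihood /
  complete separation) flags the result; constant covariates and models
  with fewer events than parameters + 1 are rejected. HR = exp(β) with
  Wald 95% CI exp(β ± 1.96·se), se from the inverse observed information.
* Covariate screening: univariate Cox per candidate, retain p < 0.1, joint
  fit on the retained set; degenerate candidates are excluded with a
  warning and an empty retained set returns the univariate stage flagged.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with planted
truth emitted alongside every table. Defaults (the simulated study
conditions): 27 patients, one 1 mm² slide each; tumor nests from a Thomas
cluster process (parent rate 3/mm², mean 200 cells/nest, dispersion σ = 75
μm; parents laid in a 4σ-padded region so the in-window expectation is
exactly rate × mean × area = 600); immune lineages as uniform Poisson
processes (CD8⁺FoxP3⁻ 300/mm², CD163⁺ 250/mm², other 200/mm², CD8⁻FoxP3⁺
60/mm², CD8⁺FoxP3⁺ 12/mm² — the rare index lineage); marker intensities
log-normal with a 3-log-unit separation between negative and positive modes
so gating is not the bottleneck under test.

Response is drawn first (Bernoulli, prevalence 11/27) and the effect is
planted *conditionally on it*: responders get a ×2.5 abundance multiplier
on the CD8⁺FoxP3⁺PD-1⁺ subset and place those cells at |N(15, 10)| μm from
a random nest centre, while non-responders place them uniformly. For every
downstream association this conditional planting is equivalent to a
response-on-feature link and keeps the marginal responder count exactly
binomial. Survival is exponential proportional hazards on the planted
proximity group (log-HR = log 6 for the low group, on both death and
progression hazards; baseline medians 24 months OS / 10 months PFS for the
high group; administrative censoring uniform on 18–36 months; PFS =
min(progression, death) ≤ OS by construction). PD-L1 TPS is planted
*uninformative* of response, drawn from the reference strata frequencies
(8:11:8 across <1 / 1–49 / ≥50%). Clinicopathologic covariates are drawn
from the reference cohort's marginal frequencies, independent of outcome
(null covariates for the screen).

What the generator does **not** emulate: staining artifacts, spectral
bleed-through, segmentation error, intensity batch effects, within-patient
slide heterogeneity, or any correlation between clinical covariates and the
TIME. Passing tests therefore demonstrate that the pipeline recovers planted
effects under its own assumptions — not that those effects exist, or are of
this size, in real cohorts.

The transcribed reference clinical table (`reference_clinical_table`) is
synthetic: its per-variable category counts and median age match the
published baseline table of the 27-patient cohort exactly, but the joint
combinations, within-stratum TPS values and follow-up times are invented,
because the per-patient data are not public. It exists to exercise the
summary operation against known marginals, not to reproduce patient-level
results. One published inconsistency is deliberately not reproduced: the
source table prints "≥1%: 19 (73.4%)" although 19/27 = 70.4%; the summary
computes percentages from counts.

## Problem sizes used in the test suite

Simulation-based checks run at: type-I-error calibration 1000–2000 reps
(Mann–Whitney 25+25, Kruskal–Wallis 3×15, log-rank 30+30, Cox Wald n = 100),
judged against the 95% binomial envelope around 0.05; HR = 2 recovery at
n = 1000 over 200 seeds (within [1.7, 2.35] in ≥ 95%); HR = 6 recovery via
the screened multivariate Cox at n = 300 over 100 seeds (within [4, 9] in
≥ 90%); the AUC-ordering check over 100 simulated 27-patient cohorts; region
accuracy over 20 disc fixtures; membership identities over 50 simulated
slides. The spatial end-to-end path runs at the cohort's own scale (27
slides, ~1500 cells each); the survival-recovery arm uses the generator's
clinical stage directly, since the planted hazard acts on the patient-level
proximity group and re-simulating 300 slides per seed would only re-measure
the (separately tested) spatial stage.

## Known limitations

* Region delineation is density-based with five exposed parameters; there
  is no pixel-level tissue classifier and no manual ROI editing, and the
  ~1-bandwidth boundary halo biases stromal labels near nest edges.
* No automatic threshold learning (e.g. mixture-model gating); thresholds
  are user-supplied configuration.
* The 88-label taxonomy is one defensible factorisation (8 lineages × 11
  selectors) consistent with every subset the analysis names; other
  compositions of the same size exist.
* No proportional-hazards diagnostics, time-varying covariates or penalised
  Cox; at 27 patients the multivariate models are descriptive, not
  confirmatory.
* No nearest-neighbor distance distributions, Ripley's K or permutation
  neighborhood enrichment — the proximity score is the only spatial
  statistic.
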