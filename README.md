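# hexiht

Hexagonal-grid intratumoral heterogeneity indicators and survival modeling
for digital-pathology cell tables.

Quantitative immunohistochemistry pipelines report what fraction of tumor
cells express a marker (ER, PR, Ki67, HER2), but not *how that expression
is arranged in space*. Two tumors that are both "50% PR-positive" can be a
fine salt-and-pepper mixture or a mosaic of strongly positive and negative
regions — and the arrangement can carry prognostic information that the
global percentage misses. `hexiht` turns the cell-coordinate tables
exported by whole-slide image analysis (one row per detected cell:
coordinates in μm, tumor/stroma/background compartment, per-marker
positivity) into spatial heterogeneity indicators and runs the survival
analysis that evaluates them, for researchers studying prognostic
biomarkers in breast and other solid tumors.

## Method

The slide is subsampled by a **randomly positioned hexagonal grid**
(side 257 μm by default); hexagons with fewer than 50 cells are discarded
as insufficient sampling. Each retained hexagon's positivity percentage is
ranked into decile bins (0–10%, >10–20%, …), and a 10×10 symmetric
co-occurrence matrix **P** is accumulated over adjacent retained hexagon
pairs. From **P** the five Haralick texture features are computed:

- contrast `Σ (i−j)² P[i,j]`, dissimilarity `Σ |i−j| P[i,j]`
- entropy `−Σ P[i,j] ln P[i,j]`, energy `Σ P[i,j]²`
- homogeneity `Σ P[i,j] / (1+(i−j)²)`

Bimodality of the per-hexagon percentages is summarized by **Ashman's D**,
`D = √2·|μ₁−μ₂| / √(σ₁²+σ₂²)`, from a two-component Gaussian mixture
fitted by seeded multi-start EM (D ≳ 2 indicates clear bimodality).
Alongside these, the package computes global expression percentages
(HER2-positive meaning 2+/3+) and immune-cell densities (CD8+ and
CD8+SATB1+ per mm² of tumor or stroma).

The survival layer provides correlation pruning (|r| > 0.90), optimal
cutpoint scanning (minimum log-rank p with a minimum group fraction,
flagged as selection-biased), Kaplan–Meier/log-rank, multivariable Cox
proportional-hazards models (Efron ties) with likelihood-ratio statistics,
leave-one-out forward-selection subset frequencies, and a three-group
PR stratification (<20% / 20–80% / >80%). A synthetic-data module
generates cell maps with controlled spatial heterogeneity and cohorts
with planted hazards so every stage can be validated without patient data.

## Worked example

`examples/` holds one narrative script per capability. Running
`python examples/02_heterogeneity_indicators.py` compares two simulated
tumors with identical global PR positivity but different spatial
arrangement:

```
homogeneous: global PR 50.0 %  (223 hexagons)
  entropy 1.386  energy 0.250  contrast 0.52  dissimilarity 0.52  homogeneity 0.741  Ashman's D 0.00
patchy: global PR 52.8 %  (223 hexagons)
  entropy 3.978  energy 0.030  contrast 10.42  dissimilarity 2.34  homogeneity 0.409  Ashman's D 5.08
```

The global percentage cannot separate the two; the grid indicators can:
the patchy tumor's hexagons disagree with their neighbors (high entropy
and contrast, low energy/homogeneity) and their percentage distribution is
clearly bimodal (D ≈ 5 vs 0). `examples/03_expression_entropy_curve.py`
shows why heterogeneity is a *non-linear* companion of expression rate —
entropy is forced toward zero as global positivity approaches 0% or 100%
and peaks in the 20–80% band — and `examples/04_cohort_survival.py` runs
the full cohort layer on a simulated 101-case cohort, recovering planted
protective effects (CD8+SATB1+ density, PR entropy; HR < 1) and a harmful
bimodality effect (Ki67 Ashman's D; HR > 1), with the extended Cox model's
likelihood ratio far exceeding the conventional covariates' model.

A thin CLI mirrors the library: `hexiht simulate`, `hexiht indicators`,
`hexiht survive`, `hexiht all` (see `hexiht --help`).

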