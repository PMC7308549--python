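# Methods

## Input model

The pipeline consumes the tabular output of an upstream whole-slide image
analysis: per cell, coordinates in μm, a tissue-compartment label (tumor
epithelium, stroma, background), binary positivity flags per marker, and
for HER2 the clinical 0/1+/2+/3+ class. Compartment areas (mm²) arrive in
a sidecar record and are the only geometry the pipeline needs: the
upstream tissue classifier is out of scope, so areas must be supplied
explicitly (they are exact by construction for synthetic data). Three
conventions matter downstream:

- a cell with no flag for a marker was *not evaluated* for it (markers are
  commonly stained on different serial sections) and is excluded from that
  marker's denominator, never counted negative;
- background cells are retained in files but excluded from every
  indicator;
- an indicator with an empty denominator is *undefined*, reported as a
  missing value with a reason code, never as zero.

## Hexagonal subsampling

A pointy-top regular hexagonal lattice with side `s` (default 257 μm,
hexagon area `(3√3/2)s² ≈ 0.172 mm²`) is placed with a random offset drawn
uniformly over one lattice period, so the tiling phase is uniform over all
distinct placements and reproducible under a fixed seed. One random
placement is used per case and marker (no averaging over placements).
Cells are assigned by converting to fractional axial coordinates and
rounding to the nearest hexagon — equivalent to nearest-center assignment,
since the hexagons are the Voronoi cells of their centers; boundary ties
are resolved by the deterministic cube-rounding rule. Orientation is fixed
at pointy-top: results are rotation-insensitive in expectation and fixing
it makes runs reproducible.

Hexagons with fewer than `min_cells = 50` cells are discarded as
insufficient sampling. Discarded hexagons are excluded from *all*
downstream statistics, including adjacency: a retained pair separated by a
discarded hexagon is not adjacent. Heterogeneity hexagons count tumor-
compartment cells only by default; the compartment is a parameter.

## Heterogeneity indicators

Per-hexagon positivity percentages are ranked into ten decile bins
(bin 1 = [0, 10], bin k = (10(k−1), 10k]). Over every unordered adjacent
pair of retained hexagons with bins (a, b), equal mass is added at (a, b)
and (b, a) of a 10×10 matrix, which is normalized once to a probability
matrix P. The five Haralick features use the standard grey-level
co-occurrence definitions — energy is the angular second moment,
homogeneity the inverse difference moment, entropy in natural log (upper
bound ln 100 ≈ 4.605 on this support). These are the canonical
definitions; any monotone variant would preserve the downstream
cutoff-based stratification. The matrix is undefined with no adjacent
retained pair, and Ashman's D with fewer than 10 retained hexagons.

### Ashman's D estimation

D = √2·|μ₁−μ₂|/√(σ₁²+σ₂²) from a two-component univariate Gaussian
mixture fitted to the raw per-hexagon percentages by EM with 5 restarts
(means initialized at the 25%/75% quantiles, perturbed randomly per
restart), convergence at relative log-likelihood change < 1e−8 or 500
iterations, keeping the best likelihood. Two stabilizers prevent the
classic EM degeneracies, either of which would inflate D arbitrarily on
unimodal data: a variance floor (1e−4) against point-mass components, and
a minimum mixing weight (0.05) against a component shrinking onto a
handful of outliers. Finally the two-component fit is accepted only if its
BIC improves on a single Gaussian; otherwise the sample is treated as
unimodal and the components are reported coincident (D = 0). The gate
makes the estimator decisive — unimodal hexagon distributions score
exactly 0 rather than a noise-driven 0.3–1.5 — at the cost of a threshold
effect for very weakly bimodal samples, which is acceptable here because
D feeds a cutoff-based stratification. Validated behavior: samples from
0.5·N(20,5²)+0.5·N(80,5²) recover the closed form D = √2·60/√50 = 12.0
within 5%; unimodal normal samples score 0 across seeds.

## Survival layer

Kaplan–Meier estimation, log-rank testing and Cox proportional-hazards
fitting (Efron tie handling, the standard default; ties are not
informative here) are delegated to lifelines; the procedures around them
are implemented in the package and checked against independent oracles in
the tests (hand product-limit arithmetic, an independently coded
2-group variance formula, exhaustive cutpoint enumeration).

- **Correlation pruning**: greedy pass in a user-supplied priority order
  (default: conventional markers first); an indicator is dropped when its
  |Pearson r| with any already-retained indicator exceeds 0.90.
- **Optimal cutpoint**: candidates are midpoints of consecutive sorted
  unique values; splits leaving either group below 10% of cases are
  inadmissible; the scan minimizes the log-rank p (computed by a
  vectorized 2-sample O−E/variance form) and reports the winning split's
  hazard ratio. Because the scan optimizes significance, the reported p is
  selection-biased; the result carries an explicit flag and no
  multiplicity correction is applied by default (a Benjamini–Hochberg
  helper exists for users who want one).
- **Subset selection**: forward selection on the Cox partial likelihood
  with a likelihood-ratio entry test at p < 0.05, run inside leave-one-out
  cross-validation; subsets are ranked by how often they are selected
  across folds. Forward (rather than backward) selection is the
  open-design choice: with ~10 candidates and ~40 events it keeps every
  fitted model identifiable.
- **PR stratification**: <20% low, 20–80% moderate, >80% high — the
  moderate band is where the entropy curve peaks, so the three groups
  separate the non-linear prognostic effect of PR expression.
- **Model contrast**: a conventional Cox model (clinicopathology + global
  expression) versus an extended model adding the heterogeneity and
  immune-density indicators, compared by likelihood-ratio statistics.

## Synthetic data

The generator emulates the upstream export, not the slide image. Cell
positions are homogeneous Poisson per compartment; marker positivity is
Bernoulli with probability given by a spatial field (homogeneous,
gradient, patchy Voronoi mosaic of a coarse Poisson process, or
hotspots). The mosaic directly plants per-hexagon bimodality: with patch
scale above the hexagon size, hexagon percentages concentrate near the two
tile levels. Tissue layouts are a whole-section tumor or non-overlapping
circular tumor nodules in stroma, giving exact compartment areas. Survival
cohorts draw covariates from per-indicator generators and event times from
a proportional-hazards model (exponential or Weibull baseline) with
administrative censoring.

Defaults emulate an early hormone receptor-positive breast carcinoma
study: 8×8 mm sections, 2000 tumor cells/mm² (1000 in stroma), cohorts of
n = 101 followed at most 143 months, exponential baseline 0.004
events/month (≈40–45% observed deaths), and planted per-SD hazard ratios
of 0.30 (CD8+SATB1+ tumor density), 0.22 (PR entropy) and 3.26 (Ki67
bimodality), with weaker conventional effects (nodal status HR 2.3, PR%
0.29 per 100 points). Tests and the acceptance script use smaller tissue
sections (4–6 mm, 1200–1500 cells/mm²) — still ≈150–250 retained hexagons
of 200+ cells each, comfortably above the 50-cell floor — as the
package's chosen problem size for routine verification.

What the simulations do **not** emulate: nuclear morphology and stain
rendering, segmentation/classification errors (false positives, split
cells), irregular tissue boundaries and necrosis, spatial correlation
between markers, and any coupling between a case's spatial indicators and
its survival other than the planted log-linear hazards. Passing tests
therefore demonstrate that the estimators recover known ground truth under
the stated sampling models — not that the indicators are prognostic in any
particular patient population.

## Numerical choices and limitations

- Decile bin edges are closed on the right ((10(k−1), 10k]); 0% falls in
  bin 1, 100% in bin 10.
- Diagonal co-occurrence pairs receive double mass (once per direction),
  consistent with symmetrization of off-diagonal pairs.
- Hexagon assignment ties on boundaries follow cube rounding and are
  deterministic; translation of cells and offset together leaves all
  counts unchanged (tested exactly).
- The cutpoint scan's internal 2-sample log-rank matches the general
  k-sample implementation to ~1e−6 relative; the scan is exhaustive, not
  heuristic.
- Cox fits require ≥ 1 event and non-constant covariates and surface
  lifelines convergence failures as diagnostics naming the covariates.
- With n ≈ 100 and ~40 events, an 11-covariate extended model is at the
  edge of the events-per-variable rule of thumb; the package reports LR
  statistics rather than claiming calibrated per-covariate inference at
  that size.
- Undefined indicators propagate as NaN + reason codes end-to-end; the
  per-case runner logs and continues across markers.
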