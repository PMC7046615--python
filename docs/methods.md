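# Methods

This note documents the models and procedures implemented in `pondscape`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real data.

## The modelling chain

### Ensemble niche models

Presence-only distribution modelling is cast as presence vs
pseudo-absence (PA) classification. For each model run, a PA set is drawn
uniformly from eligible cell centers — all valid cells (`random` method)
or cells farther than an exclusion radius from every presence (`disk`
method, default radius 50 m, suited to small presence samples). Per-point
weights give the presence and PA classes equal total weight
(w_presence = 1, w_PA = n_presence/n_PA), so model fits are insensitive
to the PA sample size. Each run uses a fresh stratified split, 70%
training / 30% evaluation, and is scored on the held-out split by

* **AUC-ROC** — rank-based (Mann–Whitney) probability that a presence
  outscores a pseudo-absence, ties counting one half;
* **TSS** — max over candidate thresholds (the distinct score values,
  rule "score ≥ threshold ⇒ presence") of sensitivity + specificity − 1,
  ties broken toward the lower threshold.

Runs with TSS above the ensembling gate (default 0.7) are averaged,
unweighted, into the ensemble mean surface; the per-cell coefficient of
variation (population sd / mean, 0 where the mean is 0) is the
uncertainty surface. Learners are pluggable via a registry; the default
families are an unpenalised logistic regression (so duplicating points is
exactly equivalent to doubling weights) and a random forest
(100 trees, minimum leaf 5 to keep per-cell probabilities smooth).
The full design enumerates learners × PA sets × repeat runs; the
classical study-scale designs are 8 × 5 × 5 = 200 (climate step) and
8 × 10 × 5 = 400 (land-cover step) runs.

Variable importance is the classical SDM permutation measure: the mean
over permutations of 1 − Pearson r between predictions on the original
data and on data with one covariate shuffled (0 by convention for
constant predictions). Variable selection clusters covariates by single
linkage on 1 − |Pearson r| with radius 1 − 0.7 (any pair with |r| ≥ 0.7
lands in one cluster) and keeps the most important member of each
cluster. Response curves are evaluation strips: one covariate swept over
its observed range, the others held at training medians.

### Extrapolation (MESS)

For one variable with reference sample R (n values, f = percentage of R
strictly below v): similarity is 100·(v−min)/(max−min) when f = 0,
100·(max−v)/(max−min) when f = 100, 2f when f ≤ 50, else 2(100−f). The
surface takes the per-cell minimum over variables; negative cells mark
extrapolation. Note that with the empirical strict-below percentage the
score is a step function inside the reference range (steps of 2·100/n),
with linear ramps outside it; ties at reference values are resolved by
the strict comparison. This matches the classical formulation; a
smoothed, exactly continuous variant would require an interpolated
percentage, which we deliberately do not introduce.

### Habitat suitability index

HSI = climate probability × land-cover probability, cellwise, after
block-disaggregation of the coarse climate surface onto the fine grid
(every fine cell inherits its containing coarse cell's value, which
preserves the mean). Future HSI uses future climate with *current* land
cover. Two assumptions are inherited and not mitigated: independence of
the climate and land-cover effects, and no land-cover change in the
future. The spatial-autocorrelation diagnostic computes global Moran's I
(I = (n/W)·Σ w_ij z_i z_j / Σ z_i², row-standardised weights) on
residuals defined as 1 − HSI at occurrence cells — a declared stand-in,
since no fitting residual exists at this stage — with inverse-distance
weights among occurrence locations and a two-sided permutation p-value
p = (1 + #{|I_perm| ≥ |I_obs|})/(n_perm + 1).

### Landscape graphs and interaction flux

The binarisation threshold is the 10th percentile (linear-interpolation
definition, stated because percentile dialects differ) of HSI at presence
points: the least-suitable tenth of occupied locations is treated as
error or sink habitat. Patches are 8-connected components of suitable
cells, identified in deterministic row-major order, with capacity = mean
HSI and area = cell count × cell area. Resistance is
r(h) = 1 for h ≥ τ and r(h) = e^(ln 0.001 · h/τ)·10³ below, continuous at
τ and spanning exactly [1, 1000]. Cost distances use the geometric
minimum-cost-path convention: a move between adjacent cells costs
cell size × mean of the two cells' resistance, × √2 diagonally
(8-connected moves); patch-to-patch distance is the cheapest
boundary-to-boundary path, computed multi-source. Because resistance is 1
inside habitat, cost units equal metres in ideal terrain, and the
dispersal cap (default 1000 m, a field-calibrated maximum for newts) is
applied directly in cost units. The graph is complete-with-pruning: every
patch pair within the cap gets an edge.

Interaction flux: IF_i = Σ_{j≠i} a_i a_j e^(−α d_ij) over graph edges,
with pruned pairs contributing probability 0 and α = −ln(0.05)/d_max so
the interaction probability is 5% at the dispersal cap (the conventional
calibration; the capacity exponent is fixed at 1 and exposed in config).
The metric is interpolated to every cell: patch cells carry their patch's
IF; outside, the value is the exp(−α·cost-distance)-weighted mean of the
IF of patches within d_max (a weighted mean rather than a sum, so a
patch's value is recovered at its own edge); cells beyond d_max of every
patch are 0. Cost distance (not Euclidean distance) from patch edges is
used for consistency with the graph. Per-species maps are z-normalised
(population sd) before the unweighted cross-species average, since IF
scales depend on each species' graph; scenario change is future − current
on normalised maps.

## The synthetic landscape

The generator emulates the statistical structure the analysis assumes: a
coarse climate grid and an aligned fine land-cover grid (default 64 × 64
coarse cells of 200 m refined by a factor 4 to 50 m cells — the
fine-scale resolution of the local analysis, at an extent of ~13 km that
keeps every run in seconds), spatially autocorrelated standardised
variables (Gaussian-filtered white noise; sigma 8 coarse cells for
climate, 4 fine cells for land cover, so habitat varies at pond scale
beneath broad climate gradients), uniform random pond points (150),
habitat polygons from thresholding an extra field at its 90th percentile,
and future scenarios as additive shifts of the climate variables only
(+1 sd and +3 sd by default, a mild and a severe warming analogue).
Because raw random fields carry chance cross-correlations, the variables
are orthogonalised over cells (QR) — mirroring the modelling protocol's
premise of a selected, uncorrelated variable set.

Ground truth is logistic: suitability = σ(β·x + β₀). The default
magnitudes (‖β‖ ≈ 7.8, intercept −8 for the single-factor truth) give a
sharp niche occupying roughly a tenth of the landscape; this places an
ideal model's discrimination near AUC ≈ 0.94 / TSS ≈ 0.8, the evaluation
regime in which presence-only ensembles for pond-breeding amphibians
typically operate, and it is what makes the default TSS > 0.7 gate
meaningful on synthetic data. For the two-species pipeline the truth is a
*product* of two logistic components (climate × land cover) — exactly the
independence structure the HSI combination assumes, which keeps each
single-factor model well-specified. The first species' leading climate
coefficient is negative (a cool-adapted species at its warm range
margin), so warming trends reduce its suitability; the second species is
less climate-sensitive. Presences are drawn with probability proportional
to true suitability (cell centers, with replacement); every generator is
a pure function of (config, seed).

What the generator does **not** emulate: sampling bias and detection
error in occurrence data, interactions between climate and land cover,
temporal dynamics, land-cover change, non-logistic (e.g. unimodal-skewed)
response shapes, and anisotropic or long-range spatial structure. Passing
tests therefore demonstrate the correctness and internal consistency of
the pipeline under its own assumptions — not predictive validity for any
real landscape.

A known behaviour worth flagging: under strong additive climate shifts
the ensemble projects far outside its calibration domain, where fitted
responses are unconstrained (tree ensembles saturate; logistic members
extrapolate linearly in the link). Projections can then move in either
direction for weakly-identified coefficient combinations. This is the
extrapolation pathology the MESS surface exists to flag — in the default
synthetic runs the severe scenario is marked as ~100% extrapolated — and
mirrors the caution required for real projections under novel climates.

## Numerical choices and degenerate inputs

* Percentiles: numpy's linear-interpolation definition throughout.
* CV uses the population standard deviation.
* Stratified splits take round(0.7·n) per class (half-up rounding).
* PA draws are without replacement within a set; sets are independent
  streams spawned from the master seed. All seeds derive from a single
  integer via `numpy.random.SeedSequence`.
* Cell membership (rasterisation, point sampling) follows the half-open
  cell rule; cell-center-in-polygon (boundary inclusive, first patch in
  input order wins) decides SC rasterisation.
* Zero patches yield an empty-graph *result* (recorded as `"no-graph"` in
  the run manifest), not an exception; an all-zero IF map is left
  un-normalised and flagged; an empty PA-eligible set, single-class
  training data, constant Moran values, constant reference envelopes and
  zero-perimeter geometries raise explicit errors.
* Nodata is NaN end to end; nodata cells are impassable (infinite
  resistance) in cost-distance searches.

## Limitations

* Learners are representatives of two families, not re-implementations of
  the eight classical SDM algorithms; the pipeline, not the learner set,
  is the object of interest, and the registry accepts any
  sklearn-compatible classifier.
* Cost↔metric unit conversion assumes resistance 1 in habitat; there is
  no independent calibration of cost units against field movement data.
* The Moran diagnostic's residual definition and weighting scheme are
  declared conventions (see above), not canonical.
* Planar coordinates only; no geographic CRS handling or geodesic
  distances.
* Graph topology is complete-with-pruning; planar (Delaunay-constrained)
  topologies are not implemented.
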