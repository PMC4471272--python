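# Methods

This note documents the statistical machinery, the synthetic generating
model, the defaults and why they were chosen, and what the package's tests
do and do not establish.

## Presence–background estimation

The estimand is relative occurrence intensity: a distribution over landscape
cells, contrasted between presence records and a background sample, without
true absences. The model is the Gibbs/exponential family

P_λ(x) = exp(Σ_j λ_j f_j(x)) / Z,  Z = Σ_background exp(·),

fitted by minimizing the L1-penalized negative presence log-likelihood.
At β = 0 the optimum satisfies exact moment matching,
E_P[f_j] = mean_presence(f_j); the per-feature penalty β_j relaxes that
constraint to |E_P[f_j] − f̃_j| ≤ β_j, pruning features the presence sample
cannot support.

**Features.** Continuous predictors expand into linear, quadratic, pairwise
product, and hinge features (forward and reverse, knots at 20 background
quantiles per variable); binary predictors become a single categorical
indicator and are never expanded further. All scaling constants (min/max,
knots) come from the background only. Feature classes auto-enable by
presence count (≥80: linear+quadratic+product+hinge; 15–79: no products;
10–14: linear+quadratic; <10: linear), so a fit on ~85 training presences
uses the full set. Feature values are clamped to [0, 1]: inputs beyond the
background range saturate rather than extrapolate, which also guarantees
that presence feature means remain attainable by some background
distribution (no runaway coefficients when presences fall outside the
background hull).

**Penalty schedule.** β_j = c_class · sd_bg(f_j) / √m · B, with
c = 1.0 (linear, quadratic, product, threshold), 0.5 (hinge), 0.25
(categorical), m the presence count, and B a global multiplier (default 1).
These are deliberately simple documented constants, not the interpolated
tables of any particular legacy implementation.

**Optimizer.** Coordinate descent with a prox-Newton step and
soft-thresholding per feature, safeguarded by step halving so every accepted
update strictly decreases the penalized objective. Coordinates are visited
largest-estimated-gain first (a cyclic index order is available via
`selection="cyclic"`). The gain-first order matters for one reason:
percent contribution credits each update's objective gain to the updated
feature's source variable, and with correlated features the first feature
updated absorbs the shared credit. Gain-first ordering gives that credit to
the strongest predictor, which is what the diagnostic is meant to measure;
index ordering would hand it to whichever correlate was expanded first.
Convergence: best single-step gain in a full pass < 1e-6; cap of 2000
update steps. Stability comes from keeping the background distribution in
log space (logsumexp normalization; the logistic output is a sigmoid on the
log scale).

**Outputs.** Raw = normalized Gibbs mass per background cell (sums to 1 on
the training background). Logistic = e^H·raw / (1 + e^H·raw) with H the
entropy of the fitted raw distribution — the conventional 0–1 suitability
under an assumed prevalence of 0.5. The two outputs are monotone transforms
of each other, so rank-based indices (ROC AUC) are identical under either.

**Diagnostics.** Percent contribution: positive per-step gains credited to
source variables (product features split equally), scaled to 100.
Permutation importance: shuffle one variable across the combined
presence+background rows, measure the training-AUC drop (floored at 0),
average over n_perm (default 2–3) shuffles, scale to 100. Response curves
vary one predictor with the others held at their background means.

## Data preparation

* **Effort filter.** Stationary counts and specimens accepted; area counts
  accepted iff area < 1 km²; traveling counts iff distance < 5 km
  (thresholds strict — a record exactly at a limit is rejected); missing
  effort metadata or unknown protocols rejected, each with a
  machine-readable reason code.
* **Thinning.** Minimum pairwise great-circle separation (default 1 km,
  haversine on R = 6371.0088 km), enforced by randomized greedy elimination:
  repeatedly remove a uniformly chosen point among those with the most
  sub-threshold neighbors, then re-add any eliminated point that no longer
  conflicts (so the result is maximal); best of n_reps = 100 randomized
  restarts. Exact maximum retention is NP-hard; unit tests verify the
  heuristic attains the brute-force optimum on small instances.
* **Partition.** Random quarter holdout with |test| = floor(0.25·n), so 113
  records split 85/28.
* **Background.** 250 points drawn uniformly over non-nodata cells (placed
  at cell centers), presences not excluded. The same 250 points serve as
  the training background and as the pseudo-absence class in every
  evaluation index; a second independent draw is a configuration choice the
  package exposes but does not default to, since evaluation against the
  training background is the simplest self-consistent reading of a
  single-background design.

## Biotic layer

Resource-plant records become a binary raster: cell value 1 iff the cell
center lies within radius_km (default 20) great-circle kilometres of any
record, computed by exhaustive nearest-point distance over cell centers —
deterministic and resolution-independent. Cell-center membership with an
inclusive radius is one of the two defensible rasterization rules; the
buffer radius and the rule are both exposed.

## Evaluation

All threshold-dependent indices derive from the confusion matrix of test
presences vs pseudo-absences under "predicted present iff score ≥ t",
swept over 101 thresholds (0.00–1.00, step 0.01), and summarized by the
trapezoid area normalized by the grid span (a constant metric c integrates
to c). Kappa is left unclipped (it may be negative at extreme thresholds).
Degenerate margins: commission = 0 if fp+tn = 0, omission = 0 if
fn+tp = 0, kappa = 0 if expected agreement is 1. ROC AUC is the
Mann–Whitney statistic with half-credit ties, computed from midranks and
verified against exhaustive pair counting. Binarization uses the smallest
grid threshold attaining maximum kappa. "Best model" per index is highest
for ROC/kappa/overall/correlation and lowest for commission and omission.

## Synthetic generating model

The generator emulates the study geometry: a modeling window of 82–69°W,
7°S–11°N on a 0.1° grid (180×130 = 23,400 cells; the real analysis used 30
arc-second cells — the coarser grid keeps every experiment desk-scale while
preserving the geography), 19 climate-like layers of which 3 carry signal,
a resource range cut off at 1°N, and occurrence samples passed through the
same filters as real data.

* **Climate layers.** gradient + smoothed Gaussian noise, standardized.
  All gradients run east–west and the noise is stretched meridionally
  (correlation length 8 cells east–west, ×20 north–south): in a meridional
  mountain belt, climate varies across ridges and valleys, hardly along
  them. This is the load-bearing realism choice — it is exactly why the
  region south of the range cut is climatically indistinguishable from the
  occupied range, which is the premise the comparison tests. With isotropic
  noise the climate-only model can reconstruct latitude from the layers and
  the overprediction signal disappears.
* **Resource range.** latent = 0.6·z(climate score) + z(isotropic smooth
  noise, length 14 cells), thresholded at the quantile that makes the mask
  cover 4.6% of the cells north of the cut (≈600 cells ≈ 70,000 km² — a
  compact, patchy montane-plant footprint that 117 buffered records can
  mostly cover), then truncated at 1°N. The climate affinity encodes that a
  montane food plant tracks the same climate as the bird; the latitude cut
  is the biogeographic accident climate cannot express. The generator also
  returns the "control region": southern cells whose climate score exceeds
  the within-range median — the suitable-but-resource-free analog used to
  localize overprediction.
* **Truth and δ.** suitability = logistic(β₀ + Σaᵢxᵢ + Σbᵢxᵢ²) ·
  (δ·mask + (1−δ)). Default coefficients put quadratic optima on the three
  signal layers with moderate magnitudes, so suitable climate spans a broad
  band rather than a pinpoint. δ = 1 is the resource-dependent hypothesis;
  δ = 0 the negative control.
* **Occurrences.** Cells multinomial in suitability, uniform jitter within
  the cell (so 1-km thinning has real work on sub-cell clusters), protocol
  metadata drawn from a fixed mix (45% stationary, 25% traveling with
  0–10 km distances, 15% area with 0–2 km² areas, 5% specimen, 10%
  unknown) so the effort filter removes about a quarter of records. The
  default 160 raw records yield ≈85 training presences after filtering,
  thinning and the quarter holdout — the scale of the motivating study.
  This scale matters beyond fidelity: with several hundred presences the
  flexible feature set can memorize the resource footprint through the
  noise layers, erasing the commission contrast the comparison measures.
* **Resource records.** 117 points sampled uniformly from the mask and
  buffered at 20 km into the biotic predictor, so the model sees an
  imperfect proxy of the true range, as in real data.

Two deterministic stand-in datasets (`synthetic_woodpecker_records`,
`synthetic_oak_records`) reproduce the published data-preparation
bookkeeping of the motivating study — 319 focal records thinning to exactly
113 at 1 km (built as 113 well-separated clusters whose members are
pairwise closer than 1 km, so every maximal thinned subset has exactly one
point per cluster), and 117 resource records. They validate the counting,
thinning and partitioning machinery against published counts; they are
synthetic constructions, not the real coordinates.

**What passing tests do and do not show.** The synthetic landscape has no
observation bias, no spatial autocorrelation in sampling effort, no
detection failure, and climate fields far simpler than real bioclim
surfaces. Recovering the truth here shows the estimator and the comparison
logic are implemented correctly and behave as designed under the stated
conditions; it does not certify performance on real rasters, where
collinearity structure, sampling bias and resolution effects are harsher.

## Numerical choices and edge cases

Threshold grid and integration rule as above (config-exposed). Points on
cell boundaries belong to the cell whose center is nearest; exact midpoints
go to the higher column / lower row index (float-tolerant snapping).
Haversine on a sphere of radius 6371.0088 km everywhere; no projections.
Thinning reads "separated by a minimum distance of d" as ≥ d. Variables
constant on the background emit no features (warned). An empty training
trace makes percent contribution an error rather than a silent zero.
Permutation importances that are all zero return zeros rather than being
scaled. Seeds: every stochastic step (field generation, sampling, thinning
restarts, partitioning, permutation) takes an explicit seed; the pipeline
derives stage seeds from one master seed, and rerunning a config reproduces
every output bit-for-bit.

## Known limitations

The optimizer's gain trace, and hence percent contribution, is heuristic —
it depends on the visiting order by design and is not a variance
decomposition. The β schedule is simpler than legacy implementations, so
absolute coefficient values (and contribution percentages) will differ from
other software even on identical data; orderings are the meaningful output.
The biotic layer is binary presence/absence within a buffer — no kernel
density or abundance weighting. Evaluation pseudo-absences are random
landscape points, not verified absences, so commission is "predicted
presence on background", an index of overprediction rather than a true
false-positive rate.
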