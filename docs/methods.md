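# Methods

`fragmatrix` implements an analysis pipeline linking habitat fragmentation,
patch isolation and the condition of the habitat matrix to transitions in
species extinction risk, together with a synthetic-data generator that lets
the whole pipeline be exercised and validated without any external downloads.
This note records the models, conventions and numerical choices, and what the
synthetic experiments do and do not establish.

## Landscape representation and cleaning

Each species is described on one rectangular pixel grid by a categorical
habitat-suitability raster (high / medium / unsuitable, NODATA outside the
range) and two human-footprint rasters (integer pressure index 0–50) for the
epochs 2000 and 2013. Grids are assumed pre-aligned; reprojection and
resampling are out of scope. Rasters are read and written as single-band
uint8 TIFF with a fixed code table (unsuitable 0, medium 1, high 2, NODATA
255; footprint 0–50). No geo-referencing metadata is carried, because no
in-scope operation needs coordinates — all metrics are in pixel units scaled
by `pixel_size`.

**Small-group cleaning.** Contiguous groups of fewer than 4 pixels of one
suitability level (8-neighbour connectivity) are removed and replaced with
the value of the *largest and nearest* other group. Ordering of those two
criteria is a genuine design choice: we rank candidate replacement groups by
Euclidean distance from the removed group's centroid to the candidate's
nearest pixel, break distance ties by larger group, then by lower class
code. Candidates must be of a *different* class (replacing a group with its
own value cannot remove it) and are preferred at size ≥ 4. Each pass locates
all small groups against the pass's original labelling and reassigns them
together, so within-pass order cannot matter; passes iterate to a fixed
point, which is what makes the operation idempotent and guarantees the
post-condition that no class component has fewer than 4 pixels. In the
degenerate case of an isolated island surrounded by NODATA the pass sequence
can cycle between two classes; we detect the cycle and return its canonical
(byte-wise smallest) state, preserving determinism and idempotence.
Cleaning operates on the 3-level raster, before level combination.

**Binarization.** The main scenario takes suitable = {high, medium} and
matrix = {unsuitable}; the sensitivity scenario takes suitable = {high} and
matrix = {medium, unsuitable}. NODATA is preserved exactly.

## Landscape metrics

* **Degree of fragmentation** — mean Euclidean distance of suitable pixels
  to the nearest habitat edge (matrix pixel). Large values mean large
  compact patches, i.e. *low* fragmentation; the raw mean is returned and
  any inverse coding is presentation-only.
* **Degree of patch isolation** — mean Euclidean distance of matrix pixels
  to the nearest suitable pixel; large values mean isolated patches.
* **Matrix condition** — proportion of matrix pixels whose footprint is at
  or above an inclusive threshold (default 3 of 50); also computed within
  suitable patches. The *change* in that extent between epochs first
  replaces any cell whose footprint fell with its 2000 value (decreases in
  pressure are assumed to have no short-term effect on threat status), so
  the change is never negative.
* **Proportion suitable** — suitable / (suitable + matrix).

Distances use the exact Euclidean distance transform and default to the
pixel-centre-to-pixel-centre convention, matching common GIS behaviour; a
centre-to-boundary variant (half a pixel shorter, floored at zero) is
available for sensitivity. By default NODATA does *not* count as edge: the
metrics are within-range quantities. For ranges that are entirely suitable
(no matrix) the metrics are undefined; such species are excluded rather
than imputed, and `treat_range_boundary_as_edge` exists for the coastal /
fully-suitable corner case. All metrics are means or proportions, never
totals, so range size is not encoded in any predictor.

## Transition classification

With the Red List severity order LC < NT < VU < EN < CR, the (first, last)
categories of a species' 1996–2020 assessment history give a binary label:
retained LC or moved down → low-risk; retained NT-or-worse or moved up →
high-risk. A sensitivity mode uses the last two assessments instead of
first-and-last; the two agree whenever the history has exactly two
assessments. Species whose final in-window category is DD, EX, EW or NE are
excluded, *unless* their earlier modelled assessments already express a
defined transition. We require at least two modelled assessments for that
rescue: a single LC followed by extinction must not read as a low-risk
retention. Genuine-versus-non-genuine category changes are not
distinguished (synthetic histories are all genuine).

## Extinction-risk model

A Random-Forest classifier on 13 predictors: the seven landscape/pressure
metrics, biogeographic realm, body mass, diet, weaning age, gestation
length and taxonomic order. The number of trees and the number of
predictors sampled per split are tuned by three repeats of stratified
10-fold cross-validation on a 75 % training partition (default grids: trees
∈ {500, 1000, 2000}; predictors per split 2…⌈p/2⌉ ∪ ⌈√p⌉); the 25 %
holdout is used only for final evaluation. One master seed fixes the split,
the folds, the forest and the permutations. Class imbalance is left
unweighted. Categorical predictors are encoded as integer category codes so
each predictor stays a single column for the importance analysis (scikit-learn
forests do not accept factors natively); for tree ensembles this ordinal
encoding is a standard, mildly lossy device.

**Importance.** Mean decrease in accuracy (MDA) is permutation importance
on the holdout (10 repeats, accuracy scoring). Evaluating MDA on a holdout
rather than on out-of-bag samples is an equivalent formulation of the same
statistic. Negative MDA values — pure permutation noise — are clamped to
zero before rescaling to the model improvement ratio MIR = I_n / I_max, so
MIR ∈ [0, 1] with the top predictor at exactly 1; raw values are kept
alongside. Under a pure-noise link the appropriate null scale for MDA is
the binomial error of holdout accuracy (≈ √(0.25/n_test)), not the
permutation-repeat standard error, which only measures Monte-Carlo noise
around a dataset-fixed value.

**Performance.** Accuracy, sensitivity (correct high-risk), specificity
(correct low-risk) and TSS = sensitivity + specificity − 1, from the
holdout confusion matrix; the mean CV accuracy of the selected model is
reported alongside, since either could be quoted as "cross-validated"
performance.

**Partial dependence.** For each of 50 evenly spaced grid values over the
observed range, the predictor is set to that value in every training row
and predicted high-risk probabilities are averaged. A LOESS overlay
(span 0.75) is computed for display only. Categorical predictors get
per-level dependence.

## Matrix-quality stratification

The matrix-condition partial-dependence curve is compared with the marginal
high-risk rate: the low-quality cutoff is the smallest grid value at which
the curve exceeds the baseline and stays above it through the grid maximum;
the high-quality cutoff is its complement (the condition is a proportion).
A curve that never crosses from below — or whose crossing falls in the
lower half of the range, where the complementary tails would overlap —
raises a no-strata signal. Separate forests are fitted to the two tails
(each must contain both classes; fewer than 40 species triggers a warning,
not an error, since severely unbalanced tails are expected in practice).

Fragmentation and isolation are compared between risk classes within each
stratum by a one-sided Wilcoxon rank-sum test (alternative: high-risk
species are more fragmented / more isolated; the fragmentation comparison
therefore uses the *negated* edge distance, i.e. the degree of
fragmentation) and Cohen's d with the pooled unbiased SD. The exact
rank-sum distribution is used up to 50 per group and no ties; the
tie-corrected normal approximation otherwise. Percent change in MIR between
strata is reported under two labelled conventions — relative to the
low-quality MIR, and relative to the mean of the two — because a decrease
can exceed 100 % of the smaller value, which makes a single convention
ambiguous.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions for every test and experiment:

* **Landscapes** are thresholded smoothed Gaussian random fields (a
  neutral-landscape model): one autocorrelation length controls patch
  grain, and quantile thresholding pins the realised habitat fraction to
  the target. Medium suitability is an erosion band (default 1.5 px) inside
  suitable blobs. Defaults: 96×96 grid (64×64 in the heavier experiments),
  habitat proportion 0.4, autocorrelation length 4 px.
* **Footprint epochs** are autocorrelated integer fields centred on a base
  intensity (default 8, spread half the base); between epochs 25 % of cells
  gain pressure and a disjoint 5 % lose pressure, exercising the
  decrease-discarding rule.
* **Red List histories** encode a high-risk label drawn from a logistic
  link on standardised features. The default coefficients are −1.0 on mean
  edge distance (more fragmented → riskier), +0.6 on matrix condition,
  +0.3 on isolation, intercept −0.9, giving a marginal high-risk rate near
  one third — the magnitudes encode the effect hierarchy fragmentation >
  matrix condition > isolation. Histories are (first, last) pairs
  consistent with the drawn label, with optional cosmetic intermediate
  assessments; a custom link function can replace the coefficients (used
  for the interaction experiment, where the fragmentation effect is active
  only at matrix condition > 0.8 and the condition is uniform so both
  quality tails are populated).
* A global seed drives per-species substreams, so adding species never
  reshuffles earlier ones, and identical configurations are bit-identical.

For model-scale experiments (thousands of species) features are sampled
directly from distributions matching the raster pipeline's output
(log-normal distances, Beta proportions) rather than measured on grids;
the raster path itself is validated end-to-end at a few hundred species.

The generator makes no attempt at realistic biogeography: ranges are full
square grids, realms are uniform labels, traits are independent
log-normals, and the features entering the link are mutually independent
(no collinearity between fragmentation and habitat amount, which real
landscapes certainly have). Passing recovery experiments therefore show
that the pipeline *can* recover known effect structure from data of this
statistical shape — not that the real-data effect sizes or rankings are
correct, which would require the original global rasters and assessment
histories.

## Problem sizes and numerical choices

Experiments are sized for a desk-scale run: the end-to-end raster study
uses 400 species on 64×64 grids; the recovery experiments use 2000
directly-sampled species over 5 seeds with a reduced tuning grid (300
trees, 3 predictors per split) — tuning machinery is exercised separately
at small n. Distance metrics are validated against a brute-force all-pairs
oracle at relative tolerance 1e-9 on rasters up to 12×12. The Cohen's d
estimator at n = 30 per group has analytic SE ≈ 0.26 at d = 0.5, so its
sampling spread (~82 % within ±0.35) is a property of the statistic, not of
the implementation.

## Known limitations

* Ordinal encoding of categoricals can split levels in an arbitrary order;
  one-hot encoding would instead dilute per-predictor importance.
* Permutation importance on a single holdout inherits that holdout's
  sampling noise; under a pure-noise link individual MDA values of ±2
  binomial SE are expected and MIR is then meaningless (flagged, set to 0).
* The partial-dependence crossing rule is one defensible way to discretize
  a continuous effect; the derived cutoff depends on forest smoothing and
  the grid, and with a step interaction at 0.8 the forest's smoothed curve
  typically crosses well below the true step.
* Raster cleaning is quadratic in the number of small groups times grid
  pixels per pass; fine for the grids used here, not tuned for
  continental-scale rasters.
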