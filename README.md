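# fragmatrix

Habitat loss fragments what remains of a species' suitable habitat into
patches embedded in a *matrix* of unsuitable land — and the condition of
that matrix (how much of it is under intense human pressure) may govern how
strongly fragmentation translates into extinction risk. `fragmatrix` is an
analysis pipeline for that question, aimed at macroecologists and
conservation scientists working with categorical habitat-suitability
rasters, human-footprint maps and IUCN Red List assessment histories. It
provides:

* **raster preparation** — removal of spurious sub-threshold pixel groups
  (<4 eight-connected pixels of one suitability level, replaced by the
  largest-and-nearest group's value) and binarization into habitat/matrix
  under a main and a sensitivity level combination;
* **landscape metrics** — the degree of fragmentation
  (mean Euclidean distance of suitable pixels to the nearest habitat edge,
  large = unfragmented), the degree of patch isolation (mean distance of
  matrix pixels to the nearest habitat pixel), the extent of high human
  footprint (index ≥ 3 of 50) in matrix and patches, its 2000→2013 change
  with pressure decreases discarded, and the proportion of suitable
  habitat;
* **Red List transition classification** — with category order
  LC < NT < VU < EN < CR, a species' first and last in-window assessments
  give a binary label: retained LC or moved down → *low-risk*; retained
  NT-or-worse or moved up → *high-risk*; DD/EX/EW/NE-final histories are
  excluded unless an earlier defined transition exists;
* **a Random-Forest transition classifier** — hyperparameters tuned by
  3×10-fold stratified CV on a 75/25 split; permutation importance (mean
  decrease in accuracy, MDA) rescaled to the model improvement ratio
  MIR = I_n / I_max ∈ [0, 1]; performance as accuracy, sensitivity,
  specificity and the true skill statistic TSS = sensitivity +
  specificity − 1; partial-dependence curves with a LOESS overlay;
* **matrix-quality stratification** — quality cutoffs derived from where
  the matrix-condition partial dependence crosses the baseline high-risk
  rate, separate forests per stratum, and one-sided Wilcoxon rank-sum
  tests plus Cohen's d for fragmentation and isolation between risk
  classes in each stratum;
* **a synthetic-data generator** — neutral-landscape suitability rasters
  (thresholded smoothed Gaussian fields), autocorrelated footprint epochs,
  trait tables, and Red List histories whose high-risk probability follows
  a configurable logistic link on the species' features — so the entire
  pipeline is testable end to end without any external data.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Run the full synthetic study from the shell (generate 200 landscapes on a
48×48 grid, measure the metrics, draw Red List histories from the default
logistic link, tune and evaluate the forest):

```bash
$ fragmatrix pipeline --seed 7 --n-species 200 --grid-size 48 --trees-grid 300
species retained: 200
high-risk rate:   0.310
holdout accuracy 0.720  sensitivity 0.200  specificity 0.943  TSS 0.143
top predictor: frag_mean_edge_distance (MIR 1.00)
```

All 200 species had defined metrics; 31 % underwent a high-risk transition
(the default link's intercept targets roughly one third). The forest
classifies the 50-species holdout at 72 % accuracy — far better on
low-risk (specificity 0.943) than high-risk species (sensitivity 0.200),
a typical imbalance for unweighted fitting at this class ratio and sample
size — and the mean-edge-distance predictor carrying the strongest
generating coefficient is correctly ranked most important (MIR = 1).

The same study from Python:

```python
from fragmatrix import SimulationConfig, run_raster_study

res = run_raster_study(SimulationConfig(seed=7, n_species=200, grid_size=48),
                       trees_grid=(300,))
print(res.performance.tss)
print(res.importance.head())
```

Stage-by-stage CLI equivalents: `fragmatrix simulate`, `prep`, `metrics`,
`transitions`, `fit`, `stratify` (see `--help` on each).

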