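# Methods

## The model

`otoscape` estimates the natal origin of individual fish in two coupled
stages, mirroring a delta/hurdle design: a discrete stage decides *which*
nursery system a fish came from, and a continuous stage estimates *where
within* that system.

**Stage 1 — nominal assignment.** The baseline is a table of known-origin
juveniles with first-annulus otolith δ¹⁸O and δ¹³C (‰ VPDB), a contingent
label, and a year-class. Contingent counts are balanced within each
year-class by random oversampling with replacement (originals always
retained, so no isotope value is invented), and both predictors are
z-scored on the balanced baseline; the stored transform — never a refit —
is applied to unknown adults. Eleven classifiers are tuned by grid search
and scored by stratified 10-fold cross-validation (accuracy, AUC,
log-loss with probabilities clipped to [1e−15, 1−1e−15]). Members whose
mean CV accuracy strictly exceeds a cutoff (default 0.76), or the top K,
form an ensemble with accuracy-proportional weights normalized to sum to
one; the ensemble probability is the weighted member mean, so it is
always inside the member min/max. Assignment abstains unless
P(contingent) > τ (default 0.7, strict); abstaining fish are excluded
from the geographic stage.

**Stage 2 — continuous assignment.** Otolith δ¹⁸O is predicted per grid
cell from monthly temperature and salinity at one depth level:
salinity→seawater-δ¹⁸O by region-specific linear mixing lines
(0.55 S − 18.98 for the open Northwest Atlantic, 0.27 S − 10.3 for the
Gulf-of-St-Lawrence-type plume, whose masks must partition the valid
ocean), a three-month seasonal mean over the contingent's first growing
season (May–July southern, June–August northern), and the chub-mackerel
fractionation equation δ¹⁸O_oto = −0.25 T + 4.46 + δ¹⁸O_sw. The equation
adds VSMOW-scale water values to a VPDB-scale intercept by construction;
no additional scale conversion is layered on. Because every operator is
linear, averaging months before applying the fractionation equation
equals applying it monthly and averaging; we average first. The
assignment domain is contingent region ∩ continental shelf ∩ valid data.

Given a fish's measured δ¹⁸O value y, the posterior over domain cells is
a normal likelihood N(y; μᵢ, σ²_combined) times a uniform prior,
normalized to sum to one, with a max-scaled copy (max = 1) for
cross-individual display. σ_combined = √(σ²_analytical + σ²_within-pop)
combines independent error sources in quadrature.

Posterior surfaces are binarized *rank-based*: the top ⌈(1−q)·m⌉ of the m
defined cells are "likely" (default q = 0.75), ties broken
deterministically by ascending (lat index, lon index). Year-class summary
maps are the mean of the binary surfaces — the fraction of fish assigned
to each cell. Validation counts a known-origin fish correct when its
likely set intersects its collection-subregion mask; sweeping q over
0.05–0.95 traces the accuracy–precision trade-off, and the chosen
threshold is the largest q whose accuracy meets a user floor (default
0.7).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| abstention threshold τ | 0.7 | probability | conservative, reduces misclassification feeding stage 2 |
| member accuracy cutoff | 0.76 | CV accuracy | separates the "high" performance band; `top_k` available because the cutoff is dataset-dependent |
| CV folds | 10 | — | standard bias/variance compromise at baseline sizes of a few hundred |
| mixing lines | 0.55/−18.98; 0.27/−10.3 | ‰ per PSU; ‰ VSMOW | empirical open-ocean vs river-plume salinity–δ¹⁸O relations |
| fractionation γ, β | −0.25, 4.46 | ‰/°C; ‰ | congeneric chub-mackerel aragonite equation |
| σ_analytical | 0.1 | ‰ | repeatability of carbonate-standard IRMS measurements |
| σ_within-pop | 0.29 | ‰ | spread of otolith δ¹⁸O among same-site age-0 fish |
| binarization quantile q | 0.75 | rank percentile | balances accuracy against assignment area in the sweep |
| baseline age caps | southern 1, northern 2 | years | age-2 fish admitted only where juvenile immigration into the region is rare |

## Design choices

- **Mixed-effect logistic member (MELR).** Implemented as an L2-penalized
  logistic regression on per-year-class isotope-slope features. This is
  the MAP estimate of the Gaussian random-slopes model with a fixed prior
  variance (the ridge strength, tuned on the CV grid); it is
  deterministic, convex, and cannot fail to converge, which matters
  inside tuning × 10-fold CV. Other members receive year-class as one-hot
  dummies.
- **Replicate-aware folds.** Oversampling duplicates records; if
  replicates of one fish straddle the train/test boundary, flexible
  members memorize them and CV accuracy inflates badly (indistinguishable
  contingents scored ~0.73 instead of 0.5 in development). Folds are
  therefore grouped by fish id (stratified group k-fold), stratifying by
  contingent × year-class where cell sizes permit, else by contingent,
  refolding with a warning if a fold ends up single-class.
- **Tuning procedure.** Hyperparameters are chosen once by grid search
  over the same style of 10-fold split on the full balanced baseline,
  then the tuned classifier is cross-validated. Fully nested CV would
  remove a small optimism in member metrics but multiplies cost; with
  two isotope predictors and small grids the tuning dimension is minor.
- **Exact weight normalization.** The last ensemble weight is computed as
  1 − Σ(others), so the sum is exactly 1 in floating point.
- **Log-space posteriors.** Likelihoods are computed as log densities
  with max-subtraction before exponentiation, so a fish far outside the
  isoscape range still produces a normalized posterior instead of
  all-zero underflow. Degenerate inputs error early: σ_combined = 0,
  non-finite observations, empty domains, zero-variance predictors,
  year-classes with only one contingent.
- **Rank-percentile binarization.** "Upper 25% of cells" is read as a
  rank statement over defined cells, with ⌈·⌉ and a fixed lat/lon
  tie-break; this makes the likely count exact, reproducible, and the
  likely sets nested in q (which in turn forces validation accuracy to be
  non-increasing in q). Cells outside the shelf/domain mask never enter
  the ranking.
- **Grids.** Cell-center regular lat/lon grids, latitude ascending,
  longitude in [−180, 180); masks must share the grid exactly — mismatch
  is an error, never silent regridding. Gridded I/O is netCDF-3 via
  xarray's scipy engine.

## The synthetic study system

The generator emulates the statistical structure the framework assumes,
with known ground truth: two contingents as bivariate normals per
year-class (northern lower in δ¹⁸O, higher in δ¹³C; shared covariance; a
seeded per-year-class mean drift; a per-year-class separation scale whose
zero setting produces indistinguishable cohorts), adults drawn from the
same mixture with hidden labels, a 17×16-cell 1° ocean with a linear
latitudinal temperature gradient (1.4 °C per degree, the steep
shelf-summer regime), an August-peaked seasonal cycle, seeded interannual
anomalies, a fresh plume box governed by the second mixing line, a land
wedge, a shelf mask, and a 2×2 subregion partition of the southern shelf
(Mid-Atlantic-Bight / Southern-New-England / Gulf-of-Maine / Georges-Bank
analogues). Known-origin validation fish are drawn from isoscape cells
with Normal(0, σ_combined) observation noise. Default contingent means
are set so the Mahalanobis separation implies a Bayes accuracy near 0.85,
placing ensemble CV accuracy in the mid-80s — the regime reported for
real Northwest Atlantic mackerel baselines.

What the generator does **not** emulate: non-Gaussian and skewed isotope
distributions, spatially correlated within-population variance, eddies
and fronts (temperature varies only with latitude and season), dynamic
salinity–δ¹⁸O relations under multiple freshwater sources, sampling-gear
selectivity, and measurement batch effects. Passing tests therefore
demonstrate the machinery is correct under the model's own assumptions,
not that a particular real population meets them.

## Problem sizes

Default test and reproduction runs use 3 year-classes × 30 fish per
contingent cell (≈180 balanced baseline records), 120 unknown adults, a
17×16 grid (≈120 southern-domain cells), and 500 validation fish; the
full workflow completes in well under a minute on one CPU. Larger grids
and baselines scale linearly in cells and near-linearly in records.

## Known limitations

- The δ¹³C tracer is used only in the nominal stage; no δ¹³C isoscape is
  attempted (its drivers — diet, metabolism, DIC — are not reducible to
  T/S here).
- The uniform spatial prior ignores habitat suitability and spawning
  surveys; the posterior hook accepts any nonnegative prior grid if such
  information exists.
- Accuracy-proportional weights are a pragmatic stand-in for posterior
  model probabilities; members with near-equal accuracy get near-equal
  weights regardless of redundancy among them.
- The validation protocol scores subregion-level containment, not
  distance error, so its accuracy depends on the subregion partition's
  granularity.
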