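# Methods

## The model

The response is per-tree: out of the n_i bark samples taken from oak tree
i, y_i yielded *S. paradoxus* after enrichment culture. We assume
y_i ~ Binomial(n_i, p_i) with

logit p_i = x_i' beta,

where the design contains trunk girth (metres, a proxy for tree age),
summer temperature Tmax (degrees C, the daily maximum averaged over the
hottest month), a north/south region factor (or a three-level oak-type
factor that can be collapsed to it), an "other yeast" isolation-frequency
covariate, and interactions. Assumptions worth stating: samples within a
tree are exchangeable Bernoulli trials (no extra-binomial clustering within
trees), trees are independent given their covariates (no spatial
autocorrelation beyond the site-level Tmax), and Tmax enters linearly on
the logit scale within each region. Quasi-binomial overdispersion and
random site effects are deliberately out of scope.

### Fitting

IRLS with the canonical logit link: at each iteration, weighted least
squares with weights n_i p_i (1-p_i) and working response
eta_i + (y_i/n_i - p_i) / (p_i (1-p_i)). Start values are zero except the
intercept, set to the logit of the pooled rate; convergence is a relative
deviance change below 1e-8, capped at 25 iterations, with step-halving if a
step would increase the deviance. The deviance uses the saturated-model
convention with 0 log 0 = 0. Standard errors come from the inverse Fisher
information at the optimum. Rank-deficient designs are rejected with the
aliased columns named. A separation warning fires when any fitted logit
exceeds 15 in magnitude: separation manifests as diverging fitted logits,
whereas a raw coefficient threshold would misfire here because the region
offset legitimately reaches ~30-40 on the logit scale when Tmax is in
degrees C (the offset and the Tmax slope trade off almost exactly).

### Model simplification

Backward stepwise from the highest-order terms, respecting marginality: a
term is removable only if no retained higher-order term contains it. Each
round tests every removable term with a chi-square LRT on the deviance
drop; among deletions not significant at level alpha (default 0.05) the
highest-order term goes, ties broken by largest p. Every tested deletion is
logged (term, delta deviance, delta df, percent of null deviance, p,
deleted flag). All comparisons during one simplification run use the
complete cases of the *initial* specification, so nested tests share rows:
with girth anywhere in the model that means the 104 of 126 trees with
recorded girth, and the final six-parameter model has 98 residual df. At
alpha >= 1 no deletion can be significant, so the model collapses to the
intercept — a useful degenerate check.

Factor collapsing (three oak types to north/south) recodes the factor
inside every term that mentions it and compares the two fits by LRT; the
reported delta-df is the one the collapse actually induces in the supplied
specification (3 when the factor appears in a main effect and two
interactions). The collapse test is only well-calibrated inside a
specification rich enough to absorb the region-level structure; testing it
in a factor-only model confounds collapse error with omitted-covariate
misspecification.

Cook's distances use the standard one-step GLM approximation,
r_i^2 h_i / (k (1 - h_i)) with standardized Pearson residuals and the
weighted hat matrix; `refit_without` provides the exact leave-one-out refit
the approximation is checked against.

## Envelopes

An envelope is two closed Tmax intervals per species: optimum
(peak predicted isolation) inside occurrence (species present at all). The
published *S. paradoxus* bounds (optimum 22-28 C, occurrence 18-31 C) were
read off fitted response curves by inspection, not by a stated rule, so the
default policy ("paper") carries them as explicit configuration rather than
pretending an algorithm produced them. The alternative "threshold(theta)"
policy is fully reproducible: the optimum is where the pointwise-maximum
predicted probability across the conditioning curves reaches theta times
its peak, endpoints interpolated linearly and rounded outward to whole
degrees; occurrence defaults to the sampled Tmax span rounded outward.
The cross-species shift adds a constant (default +7 C, the laboratory
difference in optimal growth temperature between woodland strains of the
two species) to both intervals; interval intersection gives the predicted
sympatry band (25-31 C for the published bounds).

## Rasters and distances

Grids are regular geographic (WGS84 only) lattices storing Tmax in tenths
of degrees C — the storage dialect of the climatology they emulate — and
serialize as single-band ESRI ASCII grids, a plain-text format any GIS
reads. Conversion to degrees C happens exactly once, at extraction. Point
extraction takes the single containing pixel, no interpolation, with a
stated half-open rule: row = floor((lat_NW - lat)/cell), col =
floor((lon - lon_NW)/cell), so boundary points belong to the south/east
cell and every point belongs to exactly one cell. Distance to range is zero
when the point's own cell is in range, else the minimum haversine distance
to the *centers* of in-range cells (centers, not polygon edges — a
convention choice at the data's resolution, declared so replication
differences are explainable). The Earth radius is pinned at the IUGG mean
6371.0088 km for bit-reproducible distances.

## Significance tests

Fisher's exact test is two-sided by the probability-mass definition: sum
the hypergeometric probabilities of all tables with the observed margins
whose probability is at most that of the observed table times (1 + 1e-7) —
the relative tolerance convention of the R implementation these survey
comparisons were originally computed with. Probabilities are computed in
log space via log-gamma and combined by log-sum-exp. The Wilcoxon rank-sum
test uses exact null enumeration when the smaller sample has at most 10
untied values and otherwise the normal approximation with tie and
continuity corrections (delegated to scipy's Mann-Whitney implementation;
the exact small-sample path is verified against full enumeration in the
tests).

## Synthetic data

The survey generator reproduces the emulated study's fixed structure: 13
sites (9 north, 4 south) with per-site tree counts
(15,1,4,2,2,15,15,6,6 | 15,15,15,15) summing to 126 trees, 4 bark samples
per tree, and per-site Tmax fixed at the printed site means (north
19.6-21.6 C, south 27.3-30.9 C). Site Tmax is treated as survey structure,
not noise: with only four southern sites, drawing it uniformly leaves the
Tmax-by-region interaction unidentifiable in a substantial fraction of
replicates, which misrepresents the design the analysis actually had.
Girth is lognormal with median 1.3 m and log-sd chosen so the quartiles
bracket the printed 0.8/1.9 m (the printed quartiles are not exactly
lognormal; the median is matched exactly, the quartiles to ~5-8%). Exactly
22 of 126 trees have girth deleted completely at random — the generating
response uses the true girth first, so missingness is non-informative by
construction. The within-site girth distribution is a modelling choice;
nothing in the emulated survey constrains it beyond the quartiles.

Generating coefficients (logit scale, order: intercept, girth, Tmax,
south, girth x south, Tmax x south) default to
(-2.65, 0.35, 0, 39.1, 1.35, -1.45): northern isolation rates near 0.10
with a shallow positive girth effect and no Tmax effect, southern rates
near 0.17 with a steeper girth effect and a negative Tmax slope. They were
calibrated once, by simulation, to two joint targets: (i) the two
interaction effects are each recoverable by stepwise selection from a
single 126-tree survey in well over 90% of replicates, and (ii) their
deviance shares are close to the reported partition (girth-by-region and
Tmax-by-region each high single digits of the null deviance). These targets
are in tension with matching the reported *total* deviance explained (42%):
single-survey recovery power at 126 trees forces somewhat steeper effects,
and the synthetic surveys explain ~45-60% depending on seed. We prioritized
recovery power, since that is the property the test suite measures. The
other-yeast covariate is binomial noise independent of the response, so
simplification should discard it; starting the calibrated recovery check
from the paper-structured model plus the other-yeast *main effect* mirrors
the df = 1 at which that deletion was originally tested (from a 16-term
four-way factorial start, spurious retention of some interaction is a
multiple-testing certainty ~30% of the time at alpha = 0.05, which is a
property of the procedure, not of the generator).

The raster generator produces a latitudinal temperature gradient
(t_equator + gradient x |lat|, default 38 C - 0.5 C/degree) plus optional
Gaussian noise and nodata holes — monotone and unit-faithful, but with none
of the elevation or coastline structure of a real climatology. Strain
placement puts wild strains at random in-range cell centers displaced by an
exponential distance (median ~1 km, emulating approximate geocoding) and
human-associated strains anywhere, displaced on a ~500 km scale. Passing
tests therefore show the machinery is correct under the assumed model;
they do not show that real *S. cerevisiae* obeys a 25-38 C envelope —
that claim rests on the original strain compilation and climatology, which
are external data.

## Problem sizes

The test suite and acceptance script use: 20 small datasets for the
Newton-oracle coefficient check (tolerance 1e-6); 500 simulated surveys of
520 trees for Wald 95%-interval coverage (accepted band 93-97%); 100
126-tree surveys for stepwise recovery (>= 90% for interaction retention
and for other-yeast deletion); 50 random small rasters for the
distance-engine brute-force comparison (1e-9 km) plus equatorial
closed-form arcs (1e-3 km); and 120 wild + 60 human strains on a 120 x 80
continental grid, plus 150 wild strains on a fine ~2 km grid straddling the
range edge, for the end-to-end validation stand-in. These sizes keep the
whole suite under a minute while leaving the Monte Carlo margins
comfortable.

## Known limitations

- No overdispersion or random site effects: with site-level Tmax shared by
  all trees at a site, real data would likely show extra-binomial
  variation that the binomial GLM understates.
- The envelope's "paper" policy is configuration, not inference; the
  threshold policy is reproducible but is not how the published bounds were
  obtained.
- Distances are to cell centers on a sphere; against an ellipsoidal,
  edge-based computation differences of up to ~half a cell diagonal are
  expected.
- GeoTIFF input is not supported, only the plain-text ASCII grid dialect;
  a practitioner with GeoTIFF climatologies should convert them first
  (e.g. `gdal_translate -of AAIGrid`).
- The +7 C interspecies offset is a single laboratory constant; treating
  it as fixed within species is itself an assumption the original analysis
  flags.
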