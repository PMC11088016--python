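# Methods

## Problem and model

`stcluster` detects *space–time clusters* in a set of point-located events —
cases with a school/residence coordinate (decimal degrees, WGS-84) and a
calendar date at day resolution — and compares the clustered and
non-clustered cases. The motivating application is clustered adolescent
suicide, where events concentrated in a small area over a few weeks suggest
person-to-person influence and call for time-limited local intervention,
whereas events that pile up in a metropolis over years merely reflect
population density.

The procedure is deliberately simple and fully unsupervised:

1. **Embedding.** Longitude, latitude and day index are mapped into a 3-D
   space. The default `zscore` mode centers each axis and scales it to
   sample standard deviation 1 (ddof = 1), then multiplies by an axis weight
   (default 1, exposing the implicit space-vs-time trade-off). A `metric`
   mode is provided for interpretable units: an equirectangular projection
   about the mean latitude gives kilometres east/north (error < 0.5% versus
   great-circle distance at intra-country extents, verified against a
   haversine oracle in the tests), time in days, each divided by an explicit
   scale. All distances are Euclidean in the embedded space. Note that the
   two-point z-score under the sample-sd convention is ±1/√2, not ±1; the
   sample-sd convention matches `scale()` in R and is asserted in the tests.

2. **Radius selection.** The DBSCAN radius eps is read off the sorted
   k-nearest-neighbor distance curve (k = 3 by default, equal to the minimum
   cluster size). The knee is the point of maximum perpendicular deviation
   from the chord joining the curve's endpoints (ties to the smallest
   index). A constant or linear curve (max deviation < 1e-12 × range) raises
   a no-knee error instead of guessing; a manual `eps` always overrides.
   Because z-scored units are data-dependent, no eps value is hard-coded
   anywhere.

3. **DBSCAN.** Implemented from first principles with classical semantics:
   a point is core iff its *closed* eps-ball (boundary included, the point
   itself counted) contains at least `min_pts` points; clusters are the
   connected components of the core–core within-eps graph; non-core points
   within eps of a core are border; the rest is noise. `min_pts = 3`
   counting the point itself means three mutually close cases form a
   cluster. Border points reachable from several clusters go to the
   lowest-index core neighbor, which makes the labeling deterministic under
   input permutation (classical DBSCAN leaves this order-dependent).
   Neighborhoods use the full O(n²) distance matrix — exact, and entirely
   adequate at the few-thousand-event scale this method targets.

4. **Ranking and significance.** Each cluster is summarized by its size, its
   *mdis* (mean pairwise Euclidean distance among members in the full 3-D
   embedded space — the spatiotemporal closeness measure; an xy-only variant
   is available but non-default), date span, covariate composition, centroid
   (arithmetic mean of member longitudes/latitudes) and the convex-hull area
   of its spatial embedded coordinates (scipy's Qhull; degenerate hulls are
   0). Clusters are ranked ascending by mdis (ties to the smaller cluster
   id). The *meaningful* clusters are then selected either by a manual rank
   cutoff or by an elbow rule: the cutoff is the rank r (≥ `min_rank`) that
   maximizes metric(r+1)/metric(r) along the rank-ordered curve (metric:
   mdis by default; hull area and size are alternatives). A maximum ratio of
   at most `1 + jump_tol` counts as no jump and flags everything with a
   warning; the default `jump_tol = 1.0` means a genuine "rapid increase"
   must at least double the metric. This formalizes the visual cut that, in
   this kind of data, separates tight week-scale clusters from the large
   year-spanning density cluster of a metropolis.

5. **Group comparison.** Members of significant clusters versus everyone
   else: Pearson chi-square per categorical covariate (Yates continuity
   correction — |O−E| reduced by 0.5, floored at 0 — applied by default on
   2×2 tables only, matching the common statistical-package convention; note
   scipy lets the Yates shift overshoot zero, R floors as we do), pooled or
   Welch two-sample t-tests for the six SDQ scores, and a binary logistic
   regression of cluster membership fitted by IRLS (Newton–Raphson on the
   binomial log-likelihood; convergence when the max absolute coefficient
   change < 1e-8 within 50 iterations; Wald SEs from the inverse observed
   information; rank deficiency and complete separation raise explicit
   errors). Missingness is an explicit categorical level, never imputed:
   bivariate tests use pairwise-complete cases, the regression
   listwise-complete cases, and the n actually used is always reported.
   Economic status is binarized (poverty = "lower" vs non-poverty) in the
   regression only; the chi-square keeps all three levels.

## Synthetic data generator

Real case-level data of this kind are restricted, so end-to-end behavior is
established on synthetic event sets with ground truth. The generator
emulates the structure the pipeline assumes:

- **Window**: 1826 days (2016-01-01..2020-12-31).
- **Background** (560 events): locations from a Gaussian-mixture-plus-uniform
  intensity surface; dates uniform over the window. The default mixture has
  one dense metropolis (weight 0.50, sd 6 km — about half of South Korea's
  population lives in the capital region) plus four broad secondary
  concentrations (weights 0.06/0.05/0.04/0.04, sd 25–28 km) and 31% uniform
  background over the peninsula's bounding box. The dense metropolis is
  deliberate: it produces the characteristic large, temporally diffuse
  density cluster that the significance step must exclude. Secondary
  concentrations are kept broad because several *dense* centers generate
  chance space–time triples that no single rank cutoff can exclude.
- **Planted clusters** (15): anchors drawn from the mixture *excluding* the
  metropolis component — a planted cluster inside the dense core is
  density-connected to the ambient mega-cluster and therefore unidentifiable
  by any radius; this is an identifiability constraint of the method, not a
  convenience. Sizes uniform 3–9, spans uniform 7–59 days, members jittered
  isotropically with sd 3 km and dated uniformly within the span.
- **Covariates**: drawn independently per event given cluster membership
  (no correlation structure is imposed — a documented simplification).
  Baseline prevalences follow the published marginals of the application
  domain; cluster members receive log-odds shifts, by default +0.70 on
  poverty and −0.72 on psychiatric history. Per-variable missingness rates
  mimic uneven column totals (economic status 17%, others ≤ 1%). SDQ scores
  are generated only for events from 2018 onward, as in the source data.
- **Reproducibility**: one `numpy` generator, one seed, fixed draw order
  (background locations/dates/covariates event by event, then per-cluster
  anchor, size, span, member jitter); the same seed yields a bitwise
  identical event table.

Under these defaults the full pipeline (embed → knee → DBSCAN → rank →
elbow) attains median planted-cluster recovery of 100% and median adjusted
Rand index ≈ 0.97 over 20 seeds, with the metropolis mega-cluster (typically
~280 members spanning ~5 years) always excluded by the significance step.
The knee heuristic occasionally (roughly 1 seed in 20) locks onto the bend
between the sparse background and its extreme tail instead of the
dense-to-sparse transition, producing a much larger eps and a failed run;
this is an inherent ambiguity of single-knee selection on multi-scale data,
which is why a manual eps override exists.

What passing these tests does **not** show: performance on real geography
(population rasters, coastlines), on covariate-correlated cases, on
clusters embedded inside dense cities (excluded by construction, see above),
or on data where the time-to-space scaling differs materially from
z-scoring. The numeric radius and mdis values are data-dependent by design
and carry no units comparable across datasets.

## Numerical choices

- Sample (ddof = 1) standard deviations in the z-score embedding; zero
  variance on an axis is an error, not a silent skip.
- Closed eps-balls (≤, not <) so boundary ties are included.
- Knee/elbow tie-breaks: earliest index / smallest rank; both documented
  and tested.
- IRLS working weights floored at 1e-12; divergence (max |β| > 1e8) is
  reported as non-convergence rather than returning garbage.
- Chi-square with Yates floors the corrected deviation at zero (R's
  convention).
- Hull areas via Qhull; collinear or < 3-point member sets return area 0 and
  are flagged degenerate rather than erroring.

## Problem sizes

Defaults target the few-hundred-to-few-thousand-event regime of national
case-report datasets: the bundled scenario simulates ~650 events, the
end-to-end suites run 20 seeded replicates in a few seconds, and the
parameter-recovery check for the logistic model uses n = 5000. All are the
package's chosen reference conditions and are trivially configurable.
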