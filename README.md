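# stcluster

Space–time cluster detection for point-located events, built for
epidemiological case data: each event is a case with a location (decimal
degrees) and a calendar date, plus categorical covariates. The package finds
groups of cases that are unusually concentrated in space *and* time —
for example suicide clusters in a national case registry, where events
within a few kilometres and a few weeks of one another suggest
person-to-person influence — and separates them from the large, loose
agglomerations that merely trace dense urban population.

## Method

Events are standardized into a 3-D space–time coordinate system
(z-scored longitude, latitude and day index; a metric km/days mode is also
available). The analysis then proceeds:

1. **k-distance knee** — the DBSCAN radius ε is chosen at the knee (maximum
   chord deviation) of the sorted k-nearest-neighbor distance curve
   (k = 3 by default);
2. **DBSCAN** — a point is *core* iff its closed ε-ball contains ≥ minPts
   points (the point itself included; minPts = 3), clusters are maximal
   density-connected sets, remaining points are border or noise;
3. **ranking** — each cluster is summarized by its size n, date span, hull
   area and *mdis*, the mean pairwise embedded distance among members
   (lower = tighter), and ranked ascending by mdis;
4. **significance** — the meaningful clusters are selected by an elbow rule
   on the rank-ordered mdis curve (cut before the largest relative jump) or
   a manual rank cutoff, which excludes the metropolis-scale cluster that
   spans years;
5. **comparison** — clustered vs non-clustered cases via chi-square tests
   (Yates-corrected on 2×2), t-tests on SDQ behavioral scores, and binary
   logistic regression fitted by IRLS with Wald inference.

A fully seeded synthetic generator produces event sets with a dense
metropolis background, sparse rural background and planted space–time
clusters (sizes 3–9, spans 7–59 days) with ground truth, for end-to-end
validation. See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from stcluster import SimConfig, simulate, SpaceTimeClusterModel, evaluate_recovery

events, truth = simulate(SimConfig(seed=7))   # ~650 events, 15 planted clusters
results = SpaceTimeClusterModel(events).fit() # embed -> knee -> DBSCAN -> rank -> select
print(results.summary())
```

```
Space-time cluster detection results
====================================================
events:               659
embedding:            zscore
eps:                  0.118 (knee, k=3)
min_pts:              3
clusters detected:    15
noise points:         287
significant clusters: 14
clustered events:     97 (14.7%)
temporal range:       7-56 days

 rank  cluster_id  mdis   n  span_days  significant
    1           8 0.038   7          7         True
    2           9 0.046   8         11         True
    ...
   14           5 0.091   8         25         True
   15           1 1.189 275       1821        False
```

The radius 0.118 was chosen automatically at the k-distance knee. Fourteen
tight clusters (5–9 cases each, spans of 7–56 days) are flagged significant;
rank 15 is the metropolis artifact — 275 cases whose mdis is an order of
magnitude larger and whose span is the whole five-year window — and is
excluded by the elbow rule. Against the generator's ground truth:

```python
report = evaluate_recovery(truth, results.significant_labeling)
# 14/15 planted clusters recovered, adjusted Rand index 0.974

comparison = results.compare_groups()   # chi-squares, SDQ t-tests, logistic fit
print(comparison.summary())
# economic_status   chi2 = 7.89*  df = 2  p = 0.019   <- planted poverty effect
```

The same pipeline is scriptable from a shell:

```sh
stcluster simulate --seed 7 --out-dir run/
stcluster detect   --events run/events.csv --out-dir run/
stcluster compare  --events run/events.csv --labeling run/labeling.csv --out-dir run/
stcluster pipeline --seed 7 --out-dir run/     # all three stages
```

`detect` accepts `--eps`, `--min-pts`, `--k`, `--embed-mode zscore|metric`
and `--significance elbow|manual:N`; outputs are delimited text
(labeling, Table-style cluster summaries, the k-distance curve), GeoJSON
cluster hulls and a plain-text report.

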