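# Methods

`petrelniche` quantifies niche segregation between sympatric central-place
foragers — the motivating system is the two giant petrel species (northern,
NGP; southern, SGP) breeding side by side on a sub-Antarctic island — along
two axes: space use at sea (GPS tracking) and isotopic niche (blood-plasma
δ13C/δ15N). This note documents the models, the estimators, the synthetic
study generator, and the numerical choices, in that order.

## Track processing

**Speed filter.** Positions are cleaned with a forward-pass great-circle
speed filter: a fix is dropped when the speed implied from the last retained
fix exceeds `vmax` (default 30 m/s, far above sustained petrel flight).
This is deliberately simpler than full angle-and-speed telemetry filters:
with 60-min GPS sampling the angular criteria add little, and the forward
pass is idempotent. All distances are haversine on a sphere of radius
6371 km; at the scales that matter here (hundreds of metres to thousands of
km) the spherical/ellipsoidal discrepancy is irrelevant.

**Trip delineation.** A foraging trip is a maximal run of consecutive fixes
all further than `nest_radius` (default 200 m) from the nest whose time span
is at least `min_duration` (default 3 h). The span convention is last-away
minus first-away timestamp, so a run of N hourly fixes spans N−1 h; a 2-h
excursion is attendance, not foraging. Filtering precedes trip delineation
(the order is exposed in the pipeline config; the alternative ordering
changes nothing on clean data).

**Strategy classification.** Individuals split into a *nearby* strategy
(every trip within tens of km) and a *distant* strategy (pelagic excursions
of hundreds to thousands of km). The per-individual maximum trip distance is
classified into k=2 classes by exact Fisher–Jenks natural breaks computed on
log10 distance; the reported break is the geometric midpoint between the
adjacent class extremes, and an individual is *distant* iff its maximum
exceeds the break. The log scale is a deliberate choice: trip distances span
two orders of magnitude, and on the raw scale the within-class sum of
squares of the wide distant class dominates any between-class gap, so a k=2
SSD break lands *inside* the distant cluster rather than between the
strategies. On the log scale the k=2 boundary sits near the geometric
midpoint of the class means, which respects the gap whenever the distant
bulk has a characteristic scale (as both real giant-petrel data and the
generator do). Quantile classification (k=2 = median split) is provided as
the alternative; it agrees with natural breaks on balanced separable data
but not under strongly unequal group sizes.

**Fisher–Jenks.** `fisher_jenks_breaks` is the exact O(k·n²) dynamic
programme over prefix sums — not a heuristic — minimizing total within-class
SSD over contiguous partitions of the sorted values. It is validated against
exhaustive enumeration (all C(n−1, k−1) partitions) on random instances.
The same operation, applied on the raw scale to the pooled
preceding-displacement speeds, yields the transit-speed threshold used to
drop commuting fixes before utilization distributions are built (the study
system's value for this data-derived threshold is ~7 m/s; the pipeline also
accepts a fixed threshold).

## Spatial niche

**Utilization distributions.** A UD is an isotropic bivariate Gaussian
kernel density with bandwidth `h` in raw lon/lat degrees, evaluated on a
regular grid and renormalized to integrate to one. Working in degrees
matches the degree-valued bandwidths this literature reports (h = 0.8° for
all-trips UDs); the caveat is east–west metric distortion at high latitude
(at 47° S one longitude degree is ~76 km versus 111 km per latitude degree),
which is acceptable because every comparison uses the same grid and
bandwidth. A *group* UD is the equal-weight mean of its individuals'
normalized UDs: each individual contributes equally regardless of fix count,
matching the permutation unit (the individual).

**Bandwidth.** The default is fixed (0.8°). The ad-hoc selector is also
implemented: shrink h geometrically from a high start until the 95%
volume contour first splits into more than one 4-connected component, and
return the last h that kept it whole; degenerate cases (already split at
h0, or never splitting) are flagged, not fatal.

**Contours and overlap.** The L% volume contour is the smallest set of
cells by descending density whose cumulative probability reaches L/100 (so
the 50% "core area" is always nested in the 95% "foraging range").
Overlap is Bhattacharyya's affinity BA = Σ√(p·q) over cells. For the
"95% UD" and "50% UD" rows of the overlap table, each UD is first masked to
its *own* contour and renormalized before BA; the masking convention is a
package choice (exposed as config) since the convention is rarely stated in
the literature.

**Permutation test.** Segregation is tested by shuffling individual labels
(species or sex, as appropriate) *within year* — preserving per-year group
sizes, because interannual conditions shift space use — rebuilding both
group UDs, and recomputing BA, `n_perm` = 1000 times by default. The
p-value is the raw proportion of permutations the observed overlap
*exceeds* (small p ⇒ observed overlap lower than chance ⇒ segregation); a
(k+1)/(n+1)-corrected variant is available behind a flag. The 95% CI on p
is Clopper–Pearson. Years in which only one label is present cannot be
shuffled; they are warned about and carried unchanged.

## Isotopic niche

**Standard ellipses.** For a group's (δ13C, δ15N) sample with covariance Σ
(ddof = 1), SEA = π·√det Σ — the area of the 1-sd Mahalanobis ellipse,
containing ≈40% of a bivariate normal — and SEAc = SEA·(n−1)/(n−2) corrects
small samples. The SEAc boundary is the Mahalanobis-radius-√((n−1)/(n−2))
ellipse. Samples need n ≥ 3 and a nonsingular covariance; isotope values
outside typical marine plasma ranges (δ13C ∉ [−35, −10] ‰, δ15N ∉ [0, 25] ‰)
warn but do not fail.

**Overlap metric.** Two groups' SEAc ellipses are intersected by polygon
clipping of 361-vertex boundary approximations (area error ≲ 0.005%; a
Monte-Carlo point-counting oracle backs this in the tests). The metric is
I / ((A₁ − I) + (A₂ − I)) — intersection as a proportion of the summed
non-overlapping areas — computed from the same polygons so that identical
ellipses give a denominator of exactly zero, which is returned as `inf`
(the "effectively identical niches" flag). In permutation tests an infinite
permuted value counts against significance, never for it. Ellipses are
re-fitted from the raw samples under every label shuffle; shuffles are
year-constrained exactly as in the spatial test, while all other isotope
analyses pool years.

**Group tests.** Location differences use one-way MANOVA via Wilks'
Λ = det(W)/det(W+B) with Rao's F approximation (cross-checked against an
independent implementation to 1e−10 in the tests). Multivariate normality
is screened with Mardia's skewness (n·b₁,₂/6 against χ²₄) and kurtosis
(b₂,₂ standardized against N(8, 16/n), two-sided); the skewness double sum
is computed in row blocks so large samples stay in O(n) memory.

**Trophic position.** δ15N mixes trophic level with the baseline isoscape
gradient, which is carried mainly by δ13C. The correction regresses δ15N on
δ13C by OLS over the chosen cohort (all individuals, or distant-trippers
only) and reports *externally* studentized residuals (leave-one-out error
variance, leverage-adjusted) as relative trophic position; internal
studentization is available behind a flag. Exact-line data short-circuits
to all-zero residuals rather than 0/0.

## Habitat

At-sea fixes are annotated by nearest-cell lookup from the gridded fields:
daily variables matched to the fix's calendar date, chlorophyll-a to its
calendar month (ocean-colour products are too cloud-gappy for daily
matching), depth spatially only. Fixes on land or outside the raster extent
get per-covariate missing flags — nothing is imputed — and a completeness
report counts every gap. Covariates are screened for pairwise |Spearman|
correlation above 0.70, greedily dropping the member of an offending pair
with the larger mean absolute correlation. Group membership (species × sex)
is then classified from the retained covariates by a 1000-tree random
forest (standard implementation; the bespoke content of this module is the
matching rules, the screen and the report contract), scored out-of-bag
overall and per class, with mean-decrease-in-Gini importances. Importance
*values* depend on feature order through the forest's internal randomness;
the top-variable identity is stable and that is what the tests pin down.

## Synthetic study generator

The generator exists so the whole pipeline is testable end to end without
any data download; it is first-class, tested code.

**Movement.** Each individual is simulated at a 60-min interval over the
study window in (radius, azimuth) coordinates from the colony, converted to
lon/lat by the spherical direct problem (so a drawn trip extent is exactly
the realized great-circle displacement). Nearby individuals make a handful
of forays with apexes uniform in (8, 48) km at 2–6 m/s. Distant individuals
make 1–2 out-and-back excursions: transit at 8–12 m/s with small heading
wander, a multi-day slow forage bout at the apex (absolute, km-scale
positional jitter), and an inbound leg unwinding along the current azimuth;
trips are separated by ≥3-h at-nest bouts so trip segmentation has
unambiguous truth, and every track starts and ends at the nest (sub-60-m
jitter). Trip apexes are drawn lognormal (median 650 km, σ_log 0.35) and
clipped into the configured (69, 2344) km range: distant foraging has a
characteristic scale with a tail, rather than spreading log-uniformly over
the whole envelope — this is what makes the two strategies recoverable by
natural breaks as well as separable by construction. Group direction biases
are von Mises (NGP toward 325°, κ=8; SGP toward 185°, κ=2); females are
all-distant, males mostly nearby (p_distant 0.44 NGP, 0.18 SGP).

**Isotopes.** δ13C = −3.5 + 0.38·(mean track latitude) + N(0, 0.5²) ‰ — the
slope and intercept are back-solved so group means at the observed mean
latitudes land on the study system's group means; δ15N = 22 + 0.5·δ13C +
group trophic offset + N(0, 0.5²) ‰, with offsets (NGP♀ 2.35, NGP♂ 1.15,
SGP♀ 2.05, SGP♂ 1.05 ‰) producing the observed group ordering. Under these
defaults the latitude–δ13C Pearson correlation of a ~200-individual run
falls in [0.7, 0.95] (typically ~0.85, against a field value of ~0.83).

**Environment.** Seven variables on a shared 0.25° grid centred on the
colony: SST with a +0.6 °C/°lat equatorward gradient plus smooth noise
(daily); lognormal chlorophyll with an island-associated enhancement
(monthly); a static seamount depth field; and SSH anomaly, wind components
and EKE as trendless daily noise fields. A circular island of radius 25 km
defines the land mask; a grid coarser than the island diameter is rejected.
SST is deliberately the only strongly latitude-structured dynamic variable,
so the habitat classifier has an unambiguous ground-truth ranking.

**What the generator does *not* emulate.** Carrion availability,
behavioural states, tides, mesoscale eddies, device failure/gaps, and
location error. Passing tests therefore demonstrate that the estimators
recover known structure under clean, correctly-specified inputs — not that
the pipeline is robust to the pathologies of real telemetry or
mass-spectrometry data.

**Determinism.** Every operation is a pure function of (config, seed).
Per-individual generators derive from `SeedSequence((seed, stream, index))`
so tracks are reproducible under group reordering, and the track, isotope
and environment streams are independent.

## Numerical choices and problem sizes

- KDE is evaluated separably (lat-kernel × lon-kernel matrix product) and
  renormalized on the grid; grids cover the data with a 3h margin at ~h/3
  cell side (bounded to 150–400 cells per axis; tests use smaller grids).
- Volume contours use a stable descending sort; the contour mass overshoots
  the level by at most one cell's probability.
- Permutation engines precompute per-individual density rows once and
  re-average them per shuffle; p-values are raw proportions, so n_perm
  bounds their granularity (199 in calibration runs, 1000 in reports).
- The null-calibration and power checks in the test suite run 500 and 100
  simulated datasets at reduced size (5–6 individuals per group, 2–3-day
  windows, 40–48-cell grids, 199 permutations) — sizes chosen to make the
  sampling distributions informative while the whole suite stays quick.
- The acceptance script simulates 12 individuals per group (48 total,
  comparable to the motivating study's 94) over a 10-day window with 1000
  permutations and 1000 trees.
- Degenerate inputs fail loudly with named fields (empty point sets,
  non-positive bandwidths, singular covariances, constant regressors,
  unshufflable years warn-and-carry).

## Known limitations

- Degree-space KDE distorts east–west distances at high latitude; a
  projected variant would be the next step for polar colonies.
- The SSD-based k=2 strategy break is only meaningful when the distance
  distribution is bimodal with a characteristic distant scale; on data
  whose distant cluster spreads log-uniformly over orders of magnitude no
  contiguous-SSD break can sit in the between-strategy gap (the log-scale
  choice mitigates but cannot remove this).
- The ellipse-overlap permutation null re-fits ellipses from raw samples;
  alternatives that permute residual structure are not implemented.
- Habitat classification is per-location, ignoring serial autocorrelation
  along tracks; OOB error is therefore optimistic about independent-trip
  generalization.
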