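# Methods

This note documents the models and procedures implemented in
`alcatrack`, the assumptions behind them, the parameter choices that
matter, and what the synthetic-data generator does and does not
emulate.

## Coordinate handling

All planar work uses a spherical azimuthal-equidistant projection
centred on the colony (`alcatrack.geo.LocalProjection`, Earth radius
6 371 008.8 m).  Distances and bearings *from the projection centre*
are exact by construction, the inverse is closed form, and round-trip
error is pure floating point.  Planar distances between arbitrary
nearby points are accurate to well under 0.1 % at foraging ranges
(< 100 km), which is far below GPS noise.  Colony-relative bearings θ
are measured clockwise from true north in (−180°, 180°], with due south
mapping to +180 (never −180); an `origin_offset` rotates the convention
if a different zero direction is wanted.  The default colony is Skomer
Island at (−5.30°, 51.74°).

## Track processing

GPS fixes (nominal 5-min interval) are sorted, de-duplicated, projected
and interpolated with natural cubic splines through (t, x) and (t, y)
at 1 Hz; speed is the magnitude of the spline's planar derivative.
Natural boundary conditions are used because no boundary derivative is
observable.  Splines are broken at inter-fix gaps longer than 30 min:
splining across long dropouts invents motion.  Pieces with fewer than
four fixes fall back to linear interpolation.

The flight/surface speed threshold is the kernel-density valley between
the two largest modes of the speed distribution (drifting near 0 m/s,
flight an order of magnitude higher).  Peaks carrying less than 5 % of
the maximum density are ignored, and the valley must drop below 0.8 of
the smaller mode, otherwise the distribution is declared unimodal and a
manual threshold is required.  Per-second activity labels give dives
(from the TDR) precedence over speed labels, because pressure is a
direct observation and speed an inference.

## Trips

A foraging trip is a maximal run of fixes beyond a 1-km radius around
the colony.  Start and end times are refined by linearly interpolating
the radius crossing between the bracketing fixes (at a 5-min interval
this moves boundaries by up to ~2.5 min); both the interpolated and
fix-based durations are reported.  Trips with a single beyond-radius
fix are retained but flagged.  The outbound path runs from the trip
start through the maximum-range fix, earliest fix on ties; paths with
fewer than 10 fixes are excluded from route-similarity analysis.

Stage effects on trip duration and maximum range are tested with linear
mixed models (statsmodels `MixedLM`): response ~ stage with a per-bird
random intercept against an intercept-only null, both fitted by maximum
likelihood — REML likelihoods are not comparable across different fixed
effects — and compared by ΔAIC with |ΔAIC| > 2 as the evidence
threshold.

## Dives

Zero-offset correction is two-stage: a sliding-window low quantile
(default 10th percentile, 10-min window) gives a rough surface that is
robust even when dives occupy most of a window; samples more than 0.5 m
below it are masked as submerged, and the baseline is the running
median of the remaining surface samples with odd-reflection padding at
the series edges.  A single low-quantile pass was rejected because it
provably undershoots a drifting surface by ≈ 0.4 · drift · window
(0.24 m at 1 mm/s drift), while the masked median tracks linear drift
exactly.  The correction never raises a reading above its baseline
magnitude, and negative residuals are clipped to 0.

Dives are maximal runs of corrected depth above a 0.1 m surface band
(exact-zero crossings are unstable under sensor noise) whose maximum
depth exceeds 1 m; shallower submergences are treated as bathing.
Dive positions are the interpolated track position at the dive's
midpoint time; dives outside the track span are flagged unlocated.

Bout structure: inter-dive surface intervals are modelled as a
two-process exponential mixture p·Exp(λ_f) + (1−p)·Exp(λ_s), fitted by
EM on the raw intervals (efficient, and directly testable against the
closed form, unlike log-survivorship regression).  The bout-ending
criterion is t_bec = ln((p λ_f)/((1−p) λ_s))/(λ_f − λ_s); the fit is
flagged degenerate — and t_bec withheld — if either weight falls below
10⁻³ or the rate ratio is under 1.5.  Fewer than ~50 intervals warns.

## Route similarity

The NNA distance between two outbound paths is the mean distance from
each point of one path to the nearest point of the other, symmetrised
by averaging both directions (symmetrisation is configurable; it is a
premetric — the triangle inequality is not guaranteed).  Nearest
points come from a k-d tree, which is exactly equivalent to the
brute-force scan.  Resting fixes are excluded upstream by the flight
speed filter, so surface drift does not inflate similarity.

Trips are clustered agglomeratively (average linkage by default) on
Euclidean distances between the rows of the NNA matrix, i.e., each trip
is represented by its profile of NNA distances to all trips.  Node
support uses the multiscale bootstrap: the row-vector coordinates are
resampled with replacement at sample-size scales r ∈ {0.5, …, 1.4}
(1,000 replicates per scale by default), each original node's recovery
probability BP_r is recorded, z(r) = Φ⁻¹(1 − BP_r) is regressed — with
binomial information weights — on [1/√r, √r] to give the signed
distance v and curvature c, and AU = 100 · (1 − Φ(v − c)).  Nodes never
recovered get AU = 0; nodes recovered in every replicate at every scale
carry no gradient information and are reported at the resolution
ceiling, AU = 100, with a `saturated` flag.  Group recovery cuts the
tree at k clusters and reports, per label, the fraction of members in
the label's plurality cluster.

## Bearings and productivity

Stage comparisons of bearing distributions use the two-sample KS test
on the linear (−180, 180] scale; a Kuiper statistic is available for
circular sensitivity analysis but is off by default.  Chlorophyll-a is
sampled at dive locations by nearest grid cell and nearest time slice
within a configurable offset (default 1 day); bilinear smoothing is
deliberately avoided since the analysis reads cell values.  The ROI
defaults to lon ∈ [−5.73, −5.30], lat ∈ [51.65, 51.82] (closed box).
Three Welch t-tests are reported — inside vs outside the ROI in each
stage, and inside-ROI across stages — with Bonferroni correction
m = 3.  ROI enrichment is additionally tested by comparing the ROI mean
against the means of random ROI-sized boxes placed uniformly over the
raster away from the ROI; p is the fraction of null boxes at or above
the observed mean.  On a structureless field this p is Uniform(0, 1) by
exchangeability, so calibration statements concern its mean across
independent fields, not a single draw.

## Step-length analysis

Turchin discretisation on raw (pre-interpolation) fixes: a
reorientation occurs at every interior fix whose turning angle reaches
the threshold (mild π/4 or radical 7π/8); a step spans consecutive
reorientations; its length is the straight-line distance between its
endpoint fixes (along-path length available as an option).  The fix
sequence is split at inter-fix gaps over 8 min before steps are formed
— such gaps are typically GPS dropouts — so no step ever spans a gap.
Only flight-classified fixes enter, since drifting fixes masquerade as
tight turns.  Steps are pooled across birds and trips within a breeding
stage before fitting (per-bird fits optional).

The power-law CCDF (l/l_min)^(1−μ) and exponential CCDF
exp(−λ(l − l_min)) are fitted in linear space by nonlinear least
squares to the empirical CCDF evaluated at each unique observed length,
with l_min set to the minimum observed length.  The parameter SE comes
from the fit covariance and R² is reported, with no goodness-of-fit
cutoff imposed.  Fits are refused below 30 steps.  The least-squares
optimum matches a μ grid search at 10⁻³ resolution.  Classification:
1 < μ ≤ 3 heavy-tailed, μ > 3 exponential motion, μ ≤ 1 undefined
(flagged).

A known limitation of this classifier: an exponential walker is
reliably assigned μ > 3 only when its characteristic scale is small
relative to l_min (dimensionless rate λ·l_min ≳ 2).  A shifted
exponential whose mean excess is large compared to l_min produces a
shallow normalised CCDF that is indistinguishable from a low-μ power
law over the observable range.

## Synthetic data generator

The generator emulates the study conditions: a colony at Skomer, GPS
fixes every 300 s with isotropic Gaussian noise (SD 15 m per axis,
typical consumer-GPS accuracy), 1 Hz TDR depth with 0.02 m surface
noise and slow linear sensor drift, 18 birds with on average 3.1 ± 1.8
trips each (clipped to 1–7), and a chlorophyll raster at ~500 m
resolution with a hotspot inside the ROI (background 5 mg/m³, noise SD
1, hotspot +5).

Each trip has three phases: an outbound commute at 14 m/s along a
destination bearing; area-restricted search whose displacement lengths
are drawn from the configured kernel — power law with μ = 2 and
l_min = 1 km by default, truncated at 100 km for trip realism
(truncation recorded in the truth) — with uniform (−π, π] turning
angles; and an inbound commute.  Headings (never lengths) are resampled
if a hop would pass within 2 km of the colony, so every trip crosses
the 1-km radius exactly twice; chick-rearing birds are tethered within
12 km of a destination drawn near the hotspot centre, incubating birds
disperse over all bearings with ranges ~N(34, 9) km.  Rest bouts
(10–30 min of 0.3 m/s surface drift) are inserted at search waypoints.
Dives occur inside the search window as a renewal process whose surface
intervals come from the mixture 0.7·Exp(1/20 s) + 0.3·Exp(1/600 s),
giving recoverable bout structure.

The exponential search kernel draws l_min + Exp(mean 300 m): its
dimensionless scale λ·l_min ≈ 3.3 places it squarely in the
characteristic-scale regime the μ > 3 label denotes (see the limitation
above).

What the generator does *not* emulate: tides, wind, bathymetry or any
energetic realism; GPS dropout during submergence; heading persistence
in area-restricted search; prey fields beyond a single static
chlorophyll hotspot.  Passing tests therefore demonstrate correctness
of the algorithms under known ground truth, not ecological validity of
any particular parameter value on real deployments.

A note on scale recovery from fixes: true search steps shorter than the
distance flown in one fix interval (~4.2 km) are aggregated by the
5-min sampling, which biases fix-level μ estimates downward relative to
the generator's μ.  The pipeline's stage × scale table is therefore
read for its labels and stage contrast, while estimator-recovery
checks run on the generator's step samples directly.

## Problem sizes and numerical choices

Estimator-recovery and calibration checks use 100 seeds at 5,000 steps
(μ recovery, classification), 2,000 intervals (bout criterion), 500
tracks (segmentation), 49 trips with 1,000 bootstrap replicates per
scale (route recovery and AU), 12 × 12 null matrices with 200
replicates (AU calibration), and an 18-bird cohort end to end; these
sizes give stable medians and rates while keeping a full run in the
low minutes on one CPU.  Random draws all flow from
`numpy.random.default_rng` seeded explicitly; identical configuration
and seed reproduce outputs byte for byte.  Ties for the maximum-range
fix break to the earliest time; radius crossings interpolate linearly;
curve fits start from μ = 2 with bounds (1, 60]; EM stops at a 10⁻¹⁰
log-likelihood change.
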