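# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is validated on, in enough detail to audit or re-derive
any step.

## Coordinate system

All distances, speeds and errors are planar metres in a UTM zone
(WGS84 transverse Mercator, k0 = 0.9996), auto-selected from the centroid
of the node registry unless a CRS id is given.  The forward/inverse
transform uses the Krüger flattening series to fourth order in
n = f/(2−f), giving sub-millimetre accuracy in-zone; planar distances
agree with ellipsoidal geodesics to well under 0.1% at the ≤ 2 km scale of
a node grid (tested against an independent Vincenty implementation).
Projection, GPX parsing, and GeoTIFF geo-tags are implemented in the
package itself, keeping the geospatial dependency surface to shapely and
tifffile.

## Signal preparation

* **Matching**: each detection is assigned to the relocation with the
  smallest absolute time difference, unmatched if that difference exceeds
  `max_gap` (default 10 s — receiver delays plus GPS/node clock mismatch).
  A detection exactly equidistant between two fixes goes to the earlier
  one; the rule is arbitrary but deterministic.  No clock-drift correction
  is attempted.
* **Aggregation**: per relocation × node, `rss_max` is the maximum over all
  reads (robust to multipath dropouts); `rss_avg` is re-averaged after one
  pass removing reads at least `outlier_db` (default 4.33 dB, a
  configurable, data-derived value) away from the plain mean.  The pass is
  deliberately single, not iterated; if it would remove every read the
  plain mean is kept.

## Smoothing

Both smoothers operate on one series at a time — a (trial × node) RSS
series over relocation time, or one coordinate axis of a track — never
pooled across nodes.

* **Spline**: cubic smoothing spline with the penalty chosen by
  generalised cross-validation (`scipy.interpolate.make_smoothing_spline`),
  evaluated at the raw observation times.  Series with fewer than 5 points
  pass through unchanged and are flagged.
* **Local level / Kalman**: the series is first snapped to a regular grid
  at the tag's nominal emission interval (2 s life tags, 60 s power tags;
  the natural sampling rate), nearest slot, collisions keeping the
  strongest RSS (or the first coordinate), gaps explicit as missing.  The
  local-level model y_t = μ_t + ε_t, μ_t = μ_{t−1} + η_t has its two
  variances estimated by BFGS on the log-variances (an unconstrained
  parameterisation that enforces positivity), with exact diffuse
  initialisation: the first observation pins the level and contributes no
  likelihood term.  Starting values come from the first-difference moments
  (var Δy = σ²_level + 2σ²_obs, lag-1 autocovariance = −σ²_obs).  The
  fixed-interval (RTS) smoother fills missing slots; values are read back
  at the original times by nearest slot.  Series with fewer than 2
  observations pass through.  The filter/smoother and its likelihood were
  cross-checked against statsmodels' local-level model (agreement to ~4
  decimals in both likelihood and ML estimates).
  A boundary ML solution (one variance → 0) is common and legitimate; a
  variance floor of 1e−12 keeps the likelihood finite on constant series.

## Decay calibration

RSS(d) = a·exp(−S·d) + K, fitted by unweighted nonlinear least squares.
Self-start: K0 = min RSS, a0 = max − min RSS, and S0 from a log-linear
regression of log(RSS − K0 + ε) on distance with ε = 0.5 dB guarding
log(0); ε only affects starting values.  Fits with a ≤ 0 or S ≤ 0
(RSS not decreasing with distance) are rejected as non-physical.  The
two-step scheme fits the pooled data first, then refits per node or per
tag starting at the general estimates, all three parameters free; groups
with fewer than 10 points (3 parameters need headroom) or failed fits fall
back to the general model and are flagged.  Residual autocorrelation along
trials is acknowledged but not modelled.  Uncertainty: case-resampling
bootstrap (default 999 replicates; 199 in desk-scale checks), percentile
95% intervals, failed replicates dropped and counted, with a warning above
20% failures.

Separate calibrations are fitted for each RSS summary × smoother
combination, since the downstream workflow treats these as distinct
calibration datasets.

## Localisation

Distance inversion d = −ln((RSS − K)/a)/S is undefined at or below the
asymptote (such reads are excluded) and clamped to 0 m when RSS exceeds
a + K.  Relocations with fewer than 3 usable nodes are skipped.  Node
selection ties (equal RSS or equal estimated distance at the cut) break by
lexicographic node id and are counted.

Multilateration minimises Σ (d̂_i − ‖p − n_i‖)² with a hand-rolled
Levenberg–Marquardt (2 unknowns; analytic Jacobian; objective tolerance
1e−8; ≤ 200 iterations), started at the inverse-distance-weighted centroid
(weights 1/(d̂+1 m)).  Residuals are in distance space, not RSS space.
The objective is unweighted by default (a weighting hook exists but is
off).  On solver failure the position comes from a brute-force scan of the
node bounding box padded by 500 m — 20 m coarse grid, 1 m local grid,
Nelder–Mead polish — flagged as unconverged.  Collinear node subsets are
attempted but flagged.  Localisation is 2-D; tag altitude is treated as an
evaluation covariate, not a state variable.

Grouped k-means consensus: the ≤ 7 strongest nodes give at most
C(7,3)+…+C(7,7) = 99 subsets; each is multilaterated and the candidate
points clustered with k-means (10 restarts, seeded) for k = 1…min(5, n−1).
k is chosen by the smallest k whose incremental within-cluster
sum-of-squares gain over k−1 falls below 10% of the k = 1 WSS — the elbow
rule made explicit and testable.  The centroid of the largest cluster is
returned; size ties go to the tighter cluster.  Candidate sets agreeing to
~1 cm short-circuit to k = 1.

A structural fact worth knowing: under the *general* model scope the
strongest-3 and nearest-3 subsets coincide exactly, because estimated
distance is a monotone function of RSS through a single model.  The
methods only diverge under node- or tag-scope models, where the nearest-3
rule preferentially selects nodes whose (noisier, group-level) models
under-estimate distance — this is the mechanism behind its poor accuracy
in heterogeneous scenes, reproduced as a seeded regression test.

## Track post-processing and evaluation

Track smoothing applies the signal smoothers to x(t) and y(t)
independently; timestamps are never altered.  The speed filter's threshold
is either the 95% quantile of the track set's step speeds or a hard cap
(25 m/s default for hummingbird-like flight); each pass removes the end
fix of the first over-threshold step and re-measures, so a single teleport
(which inflates two adjacent steps) costs one fix.  The filter runs before
smoothing by default; the order is configurable.

Error is the planar distance between estimate and truth.  The
216-workflow factorial is emitted as a long table (relocation nested in
trial) for external mixed-model/AICc analysis — fitting those models is
deliberately out of scope, as is home-range (AKDE) estimation.

Random-track nulls are step-resampling surrogates: step lengths and
turning angles resampled independently with replacement, a random initial
heading, anchored at the trial centroid, clipped to the grid bounding box
padded 500 m.  This preserves duration, fix count and the step-speed
distribution (KS-checked) without fitting a continuous-time movement
model, which keeps the null self-contained.  "Random error" is the
distance from each true relocation to the time-index-matched surrogate
point; trials with fewer than 10 fixes are excluded.  The test is a paired
Wilcoxon signed-rank over trials of observed median error vs the mean
surrogate median.  Note the anchored surrogate is a *conservative* null
for slow, short trials (it stays near the track); separation is expected
for workflows with errors below the trial's spatial extent.

Spatial covariates per relocation: terrain ruggedness = sd of DEM cell
centres within a 100 m buffer (no partial-cell weighting; 30 m cells
dominate the resolution anyway); flight height = GPS elevation − bilinear
DEM; dominant vegetation class by occupied area in the buffer with the
fixed tie order grassland > paramo > dense > builtup; grid membership and
signed distance to the grid edge against the convex hull of node positions
(the hull is the one deterministic reading of "inside the grid").

## Synthetic scenes

The generator's defaults emulate the study system: a 7 × 7 lattice at
150 m spacing with three receivers dropped (46 nodes), life tags emitting
every 2 s (power tags 60 s), and three trial modes with field-realistic
kinematics — high flight (drone): 389 s, 3.57 ± 1.78 m/s, altitude
N(39, 16) m AGL; low flight (walking, tag raised): 261 s, 0.44 ± 0.12 m/s,
1 m; ground: 371 s, 0.31 ± 0.06 m/s, 0 m.  Tracks are correlated random
walks (lognormal step speeds matched to the mode's mean/sd, wrapped-normal
turning, reflective grid boundary).  The ground-truth decay law defaults
to a = 68 dB, S = 0.01 /m, K = −105 dB, consistent with field RSS ranges
of roughly −37 to −115 dB.

RSS per emission and node = decay law + fixed per-node offset
(sd 3 dB) − vegetation penalty − AR(1) noise (sd 2 dB, ρ = 0.6; the
autocorrelation exists precisely so the smoothing axis has signal
structure to exploit).  The vegetation penalty uses the class at the
emitter position only (no path integration) and scales with mode — full
for ground tags, half at 1 m, none for drones above canopy — the simplest
mechanism that reproduces height-dependent detectability.  Reads below the
detection floor (default −115 dB) are never emitted; with the default
floor 10 dB below the asymptote this censors almost nothing, so tests of
range-limited detectability raise the floor above K.  Detection timestamps
are jittered ≤ 1 s to exercise the matching step.  All randomness flows
from one scene seed through named substreams (DEM, offsets, tracks,
noise).

What the generator does **not** emulate: multipath interference and
antenna gain patterns, RSS spikes/heavy tails, path-integrated vegetation
attenuation, terrain obstruction of specific node-tag lines, clock drift,
and tag dropout near dusk.  Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the workflow machinery, not
field-accuracy guarantees.

## Problem sizes

The test-suite and acceptance-script scenes are scaled to desk size as the
package's own validation design: 5 × 5 grids, 2–8 trials of 40–390 s,
2 dB noise, 199-replicate bootstraps (vs 999 for field use), 99 random
tracks per trial, and the full 216-workflow factorial on ~60 relocations.
All are configurable upward; nothing in the implementation depends on
these sizes.

## Known limitations

* DEM rasters are assumed to be regular north-up grids in the working CRS;
  geographic-grid GeoTIFFs (e.g. raw GLO-30 tiles) must be resampled
  externally first.
* The local-level smoother is univariate; no cross-node information is
  shared.
* The multilateration objective is unweighted; with strongly heteroscedastic
  distance errors (reads near the asymptote) all-node multilateration can
  be dominated by distant nodes — visible in the synthetic results, where
  strongest-3 beats all-node.
* Mixed-effects modelling, AICc ranking and AKDE home ranges are exports,
  not computations.
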