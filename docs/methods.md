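# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `focimap`, and what the synthetic experiments do and do
not demonstrate.

## Observation model

A bipolar pair's LAT at activation *t* is modeled as
x<sub>i,j</sub>(t) ~ N(x<sup>EGM</sup><sub>i,j</sub>(t), σ²): the
extracted time (maximum signal change within the activation window) is
the mean of the true activation time's distribution. σ defaults to
1 ms — LAT annotation uncertainty of the order of one sample at clinical
sampling rates — and is configurable everywhere; the noise law is
Gaussian throughout, although the resampling machinery only requires a
way to perturb LATs, so other laws could be substituted at the
`resample_lats` seam.

Within a loop of D = 5 pairs, exactly one pair is first (one last) per
cycle; ties are broken toward the smaller pair index so that every
computation is deterministic. First/last events over T cycles are
multinomial; all inference operates on these order statistics, never on
raw LAT magnitudes, which is what makes the method robust to beat-to-beat
chaos.

## Empirical-likelihood bounds

Each pair's probability bound profiles its own binary indicator vector:
max/min of the weighted mean over weights w on the T observations with
−2 Σ log(T w<sub>t</sub>) ≤ χ²<sub>1,1−α</sub>. The implementation uses
the general Owen profile (inner bisection on the Lagrange multiplier of
the mean constraint, outer root search in the mean), so the binary
closed form — equal weights within the ones- and zeros-groups — remains
an independent oracle in the tests. Choices:

- **Per-pair, 1-dof calibration.** A joint constraint over all D weight
  vectors would couple the bounds; the per-pair profile is what the MLE
  box consumes, and 1 degree of freedom is the standard calibration for
  a scalar mean.
- **Degenerate samples.** An all-zeros indicator vector has a point-mass
  profile; the interval is widened one-sidedly to
  [0, 1 − exp(−χ²/(2T))], the continuity limit of the closed form, so a
  pair never observed first still gets a nonzero upper bound (symmetric
  for all-ones). This keeps the MLE box feasible in extreme samples.
- **α defaults to 0.1** for both the bounds and the significance test;
  the test treats p-values in the 0.06–0.07 range as evidence of a
  source, which only a 0.1-level threshold accommodates.

Exact coverage of the interval at T = 30, α = 0.05 is 95.3–96.2% for
Bernoulli means between 0.3 and 0.6 (computed from the binomial law);
the test suite checks the 95% ± 3% band empirically.

## Constrained multinomial MLE

The log-likelihood summed over the M resamples depends on the counts
only through their pooled sum, so the MLE solves
max Σ c<sub>j</sub> log p<sub>j</sub> on the simplex ∩ box. KKT
stationarity gives p<sub>j</sub> = clip(c<sub>j</sub>/λ, lb, ub) with a
scalar λ; Σ p(λ) is monotone, so Brent's method finds the root to 1e-14.
The printed optimization direction in the source material is a
minimization, but only maximization yields the stated closed form n/T,
so maximization is implemented. Feasibility (Σ lb ≤ 1 ≤ Σ ub) is checked
and violations are reported by side.

## Hypothesis test and source counting

The test statistic is the ratio of the estimated probability to the
chance level: z = D·p\*, referred to the upper tail of the standard
normal. This is statistically unconventional (it is not a variance-
scaled z-score) but is implemented exactly as specified because it
reproduces the reference probability-to-p-value tables entry for entry;
reporting rounds to 2 decimals with a floor of 0.01. p\* = 0 maps to
p-value 0.5, so the p-value range is (0, 0.5].

The source count is the maximum, over the four vectors (first/last ×
inner/outer), of the number of significant entries. The maximum — rather
than, say, the count in the entry vectors alone — is required because
two sources lying in the same direction from the catheter share entry
pairs and are distinguishable only in the exit statistics. A consequence
observed in simulation: when a wave's direction bisects two adjacent
pairs, events split between them and both turn significant, inflating
the count; the path-matched sample sizes T\* expose such duplicates.

## Path extraction

Ranks are paired positionally: path r takes the r-th largest entry of
each of the four vectors. A ranked entry whose probability falls below
chance (1/D) carries no directional information; the rank-1 pair is
substituted and the slot flagged (`reused_slots`). The ≥ 1/D rule is the
package's own resolution of an underdetermined corner: it reproduces
both bundled worked examples, including the shared-entry case where two
sources enter through the same pairs but exit differently, and the case
where a below-α exit entry (p-value 0.16) still anchors a second path.
Path entries that are individually non-significant are kept but flagged
in the report.

## Conduction velocity

Each of the 6 sensor pairs (a, b) on a path contributes
CV<sub>ab</sub> = Geo(s<sub>a</sub>, s<sub>b</sub>) / |median<sub>k</sub>(x<sub>b,k</sub> − x<sub>a,k</sub>)|;
the median over path-matched activations resists outlier beats. The
estimator assumes the wavefront travels along the sensor pair; a pair
the front crosses near-perpendicularly has a near-zero time difference
and an unboundedly inflated ratio. Pairs with |Δt| below
max(0.1 ms, 0.25 · max |Δt|) are therefore excluded (both thresholds
configurable). Even so the estimator is biased high — the inter-sensor
chord is at least the difference of source distances — by roughly 5–15%
when the source lies outside the catheter along the path axis, and by
more when the source is close to the array. This bias is the dominant
error source in localization and is deliberately left in: it is
intrinsic to the pairwise-ratio estimator.

## Localization

For fixed s₀ and CV the optimal onsets are closed-form:
t<sub>k</sub> = clip(mean<sub>e</sub>(x<sub>e,k</sub> − Geo/CV), 0, x<sub>FO,k</sub>),
so the outer problem is over location only.

- **Mesh mode** enumerates candidate vertices exhaustively. Distance
  fields are seeded at the 4 path sensors (Dijkstra once per sensor) and
  read back by geodesic symmetry, making the search
  O(4 Dijkstra + V·T\*) instead of one Dijkstra per candidate. A
  flatness diagnostic (objective range across the top decile of
  candidates) flags degenerate geometry.
- **Planar mode** scans a 41×41 grid over the candidate box with the
  same vectorized closed form, then polishes the best cells with
  L-BFGS-B. Monte-Carlo replicates warm-start from the first solution.
- **Constraints.** ρ (default 50 mm) bounds the source-to-sensor
  distance; the planar solver enforces it by quadratic penalty and
  reports near-boundary solutions via an `at_rho_boundary` diagnostic.
  A fit railed at ρ means the range was unidentifiable along the ray;
  the pipeline excludes localizations with ≥ 50% railed replicates from
  pooling.
- **Uncertainty propagation.** Each of M replicates redraws
  CV\* ~ N(μ, σ<sub>c</sub>²) truncated positive and bootstrap-resamples
  the matched activations. The point estimate is the mean of replicate
  locations (mesh mode: the vertex minimizing mean geodesic distance to
  them, so the estimate stays on the surface).

Range is ill-conditioned when the source is far: with aperture a and
range R, range information enters only through wavefront curvature
(~a²/2R), so a few-percent CV error produces tens of millimetres of
radial overshoot at R ≈ 2a. Estimates from placements that surround a
source overshoot in different directions, and their pooled mean cancels
the bias — the reason the method prescribes mapping from many catheter
positions.

## Synthetic data

The simulator generates: irregular onsets (mean interval 400 ms,
interval CV ≈ 0.2, refractory floor 150 ms), a per-cycle conduction
velocity from a truncated normal (default 1.0 ± 0.05 mm/ms, the scale of
atrial conduction), earliest-arrival collision when several sources fire
in one cycle, and i.i.d. Gaussian LAT noise. Onsets of distinct sources
are staggered so recordings interleave. What it does *not* model:
ionic-current electrogram morphology, fractionation, rotors or re-entry,
spatially varying or anisotropic conduction, and mesh-specific
propagation (waves travel at one speed per cycle along geodesics).
Passing recovery tests therefore demonstrate the statistical machinery
under its own assumptions, not clinical performance; the toy electrogram
path (Hann-windowed biphasic pulses + white noise, steepest-slope LAT
extraction with a 3-sample smoothed derivative) checks only that the
LAT-extraction convention round-trips.

## Reference experiment

`two_source_benchmark_config` fixes the package's parameter-recovery
conditions: two sources 24 mm apart, 16 catheter poses on a 20 mm ring
around their midpoint with seeded freehand orientations, 60 recorded
activations per pose, T = 30, M = 100 resamples and replicates,
σ = 0.5 ms, σ<sub>c</sub> = 5% of μ, ρ = 50 mm. The ring keeps both
sources within about two catheter radii of every pose — the regime where
activation order constrains geometry — and surrounds them, so radial
biases cancel in the pooled mean. Median pooled error over 10 master
seeds is ~3 mm per source (asserted ≤ 5 mm in the acceptance suite);
the noiseless single-source planar fit recovers the source to < 0.1 mm.
Problem sizes (16 poses, 10 seeds, M = 100) were chosen to keep the full
experiment around five minutes on one core.

## Seeding

A master seed spawns per-(placement, stage) child seeds via
`numpy.random.SeedSequence` spawn keys (all below 2³¹), so any stage can
be reproduced in isolation and the whole pipeline is bit-reproducible;
the manifest records every child seed.

## Known limitations

- The hypothesis test's normal calibration is heuristic; its p-values
  order evidence usefully but are not frequentist error rates.
- Source counting can over-count when a wave direction bisects adjacent
  pairs (see above) and under-count co-directional sources with
  coincident exits.
- The CV estimator's geometric bias makes single-placement range
  estimates unreliable beyond ~2 catheter radii; conclusions should rest
  on pooled multi-placement estimates.
- Edge-graph geodesics overestimate surface distance by a mesh-quality
  factor (≤ √2 on right-triangulated grids); adequate at this noise
  level, but not an exact polyhedral geodesic.
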