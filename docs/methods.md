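# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `retinads`, and what the synthetic validation does and
does not establish about real data.

## Spike-response model (synthetic generator)

Each synthetic cell responds to a bright bar crossing its receptive field
with two temporal response lobes: an ON lobe at the bar's leading edge and
an OFF lobe at the trailing edge (ON precedes OFF by construction; the
invariant is enforced). Per trial, the spike count in each lobe is Poisson
with mean

λ(θ, c) = r₀ + (g − r₀) · exp[κ(cos(θ − μ) − 1)] · s(c)

where g is the lobe gain (mean spikes per preferred-direction trial at the
reference contrast), r₀ the null-direction floor, μ and κ the von Mises
preferred direction and concentration (κ = 0 gives an untuned cell), and
s(c) = c(c₅₀ + c_ref) / (c_ref(c₅₀ + c)) a Naka-Rushton contrast response
normalized to 1 at the protocol's highest contrast c_ref, with
semisaturation c₅₀ = 20% Weber by default. Spike times are Gaussian around
the lobe peak (σ = 100 ms; peaks at 0.75 s and 2.25 s of a 3 s trial), plus
an optional homogeneous baseline. Any renewal process would serve; Poisson
is chosen for analytic tractability — the per-direction expected counts have
the closed form above, which the Monte-Carlo tests check to 3 SE.

Default protocol: 12 directions at 30° spacing, Weber contrasts
{5, 10, 20, 40, 80, 150, 300}%, 8 trials per condition, bar 1200 µm wide at
400 µm/s. The generators take one explicit seed each and thread all draws
through a named `numpy.random.Generator`; no global RNG state is touched,
and identical parameters + seed give byte-identical output.

What the generator does *not* emulate: adaptation and serial dependence
across trials, non-Poisson spike-count dispersion, receptive-field spatial
structure, correlated noise across cells, and electrode/sorting artifacts.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated statistical model, not robustness to every property of
recorded spike trains.

## Tuning statistics

- **DSI** = |Σ n_i **v**_i| / Σ n_i on total per-direction counts. An
  all-zero curve returns NaN with a warning (population pipelines proceed;
  degenerate cells are flagged rather than fatal).
- **Width** is the circular SD of the count-weighted direction
  distribution, σ_circ = √(−2 ln R̄). The square root is part of the
  standard circular-SD definition and is applied here; for counts
  proportional to a von Mises density, σ_circ = √(−2 ln(I₁(κ)/I₀(κ))),
  which the tests verify to 1% on dense samples. Width is computed on raw
  counts (nonparametric); the von Mises fit exists for display and
  parametric summaries only. Numerical guards: R̄ ≤ 1e−12 reports +inf
  (uniform), R̄ ≥ 1 − 1e−12 reports 0 (point mass) — float cancellation
  otherwise leaves spurious residuals of order 1e−8.
- **von Mises fit**: least squares of A·e^{κcos(θ−μ)}/(2π I₀(κ)),
  initialized at the circular mean and the Best-Fisher inversion of
  R̄ ≈ I₁(κ)/I₀(κ), κ bounded to [0, 500]; non-convergence returns the
  initialization flagged as a fallback.
- **Strength**: the preferred direction is the resultant-vector angle
  (continuous), not the argmax bin; because curves are sampled at 30°, the
  preferred (null) response is the cosine-weighted sum of the two sampled
  directions nearest the preferred (null) axis. Strength = (P−N)/(P+N),
  NaN with warning when P+N = 0.
- **ON/OFF segmentation**: the PSTH pooled over directions at the two
  highest contrasts is binned at 1 ms, smoothed with a Gaussian kernel
  (σ = 25 ms — the bin width is standard, the kernel width is this
  package's choice, configurable), and the two tallest peaks located; the
  boundary is their temporal midpoint and is intended to be reused across
  contrasts. Cells without two separable peaks raise a typed error and are
  classified not-ON-OFF downstream. Δϕ is the minimal circular difference
  between the per-phase resultant angles, reduced to [0°, 180°].

## Population classification

- **QC**: contamination = fraction of inter-spike intervals below a 1.5 ms
  refractory window (window configurable; the 10% contamination and 1 Hz
  rate cutoffs are the standard criteria). On simulated sets, ISIs are
  evaluated on a continuous timeline with trials laid end-to-end.
- **DSGC gating**: two-component 1-D Gaussian mixture (10 restarts, fixed
  random state) on the DSI histogram; threshold at the crossing of the two
  weighted component densities between the means (bracketed on a 512-point
  grid, refined by Brent's method). Bimodality check: mean separation must
  exceed the pooled (weight-averaged) SD; otherwise — or with fewer than 20
  cells, or a degenerate sample — the gate falls back to the fixed
  threshold 0.25 with a warning. Labels are a function of DSI and the
  returned threshold only.
- **ooDSGC isolation**: two separable PSTH peaks with smaller/larger peak
  height ≥ 0.2 (the ratio formalizes a qualitative criterion and is
  configurable).
- **Subtypes**: K-means on the circle — distance is minimal angular
  difference, centers update to the circular mean, seeds at 0/90/180/270°,
  empty clusters retain their seed.
- **Comparisons**: two-sample Kolmogorov-Smirnov test on the per-genotype
  metric vectors (group sizes differ, so a paired design is not possible).

## Mosaic regularity

VDRI = mean / SD (ddof = 1) of Voronoi domain areas. Cells whose domain is
unbounded or has a vertex outside the field bounds are excluded ("edge"
cells); a toroidal mode (3×3 periodic tiling) is available for simulation
nulls free of edge effects. Domain areas use the shoelace formula on
angularly ordered vertices of the (convex) cells. A perfect lattice has
zero area variance and an unbounded index; it is reported as the sentinel
1e9 with a `degenerate` flag. Fewer than 2 interior cells is an error;
fewer than 10 warns.

The random null is a hard-core (sequential rejection) process matched in
density, with exclusion radius d_min = 8 µm by default — a soma-diameter
scale; the radius is this package's reconstruction and is configurable.
Packing failure after a bounded number of tries raises a typed error.
Territory-size analyses bin interior-cell domain areas in 100 µm² bins with
open-ended first (<200 µm²) and last (>1100 µm²) bins, reporting per-bin
outcome rates with Wilson binomial intervals; empty bins are NaN, not zero.

## Anatomy

- Dendrite-angle classes partition [0°, 180°] at 45°/135° (quadrant cuts,
  configurable); under a uniform angle measure the tangential class has
  probability 1/2 and each polar class 1/4, which the tests use as an
  oracle.
- IPL profiles: mean across the ROI width per depth pixel, minimum
  subtracted, maximum normalized — invariant to affine intensity rescaling
  of the image. Depth runs 0% (INL border) to 100% (GCL border). Peaks are
  local maxima above a prominence floor (0.1 of the normalized range by
  default); a flat run of equal maxima is reported at the plateau center.
  Band distance uses each profile's primary (tallest) peak.
- Territory area orders tips by polar angle about their centroid and applies
  the shoelace formula — a deterministic formalization of manual tip-to-tip
  tracing, which has no unique algorithmic definition; for star-shaped tip
  sets it reproduces the traced polygon exactly.
- Plexus coverage binarizes with Otsu's threshold unless a fixed threshold
  is given ("thresholded" is otherwise underdetermined); boolean input is
  taken as already binarized.
- Contact rate counts a tip as contacting when its voxel lies in the target
  mask (optional 1-voxel dilation to emulate confocal resolution); the
  chance control recomputes after mirroring the target about both in-plane
  axes, preserving arbor density and geometry while destroying
  correspondence.

## Validation studies and problem sizes

The benchmark suite (`retinads.benchmarks`) uses: 200 cells (gain 30, κ ∈
{1, 2, 4}, 8 trials) for preferred-direction recovery; 100 repeated
experiments of 80 vs 74 cells (null rate 0.5 vs 6 spikes/trial) for
null-spiking mechanism detection at α = 0.01; 100 seeds of 500×500 µm
fields at 1000 cells/mm² for the lattice > hard-core > Poisson regularity
ordering; and 100 hard-core simulations for null envelopes. The generator's
rate-law convergence is exercised at 2,500 trials per condition at a 3-SE
tolerance. These sizes give stable statistics at desk scale; all are
parameters, not limits.

Note that hard-core and Poisson VDRI distributions overlap seed-to-seed at
the default exclusion radius: the three-way regularity ordering holds in
distribution (strictly ordered means across seeds), while lattice
dominance holds in essentially every seed.

## Known limitations

- Moving-bar responses stand in for drifting gratings in DSGC gating; both
  reduce to the same DSI computation on per-direction counts.
- The ooDSGC lobe-ratio (0.2), stratification-call windows, angular cuts
  and PSTH smoothing width are documented reconstructions of qualitative
  criteria; all are configurable.
- Edge exclusion makes VDRI estimates depend on field size for small
  fields; the toroidal mode removes this for simulations but is not
  applicable to imaged fields.
- The contrast response is abstract (Weber % in, saturating gain out);
  photoisomerization-level calibration is out of scope.
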