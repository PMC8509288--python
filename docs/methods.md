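# Methods

`albumag` analyzes how serum albumin and magnetite (Fe3O4) nanoparticle
colloids aggregate in solution and how that aggregation shows up in dried
protein films.  Because no measured dataset is deposited for this system,
every input is synthetic, generated by the package itself with the
statistical structure the study reports; the analyses then recover that
structure blind.  This note records the models, the parameters that
matter, and the numerical choices.

## Forward model of laser correlation spectroscopy

A dilute suspension of Brownian particles scatters coherent light whose
normalized field autocorrelation is a weighted sum of exponentials,

    g(tau) = sum_i F(q, D_i) exp(-q^2 D_i tau),

with wave vector `q = (4 pi n0 / lambda0) sin(theta/2)` and the
Stokes-Einstein relation `D = k_B T / (3 pi eta d)` mapping diffusion
coefficients to hydrodynamic diameters.  `F(q, D_i)` is the fraction of
scattered *power* per component — all distributions in this package are
intensity-weighted; number- and volume-weighting are out of scope.

Instrument defaults: lambda0 = 633 nm, theta = 90 deg, T = 300 K.  The
solvent refractive index (1.33) and viscosity (0.89 mPa s, water near
300 K) are not instrument observables; they are configurable and echoed
in every report.  k_B is the CODATA 2018 exact value and is not
configurable.  Correlator lag grids are log-spaced by default (70 points,
1 us - 0.2 s), spanning the decay times of everything from 6 nm monomers
(tens of us at this geometry) to micron complexes (tens of ms).

The forward model is treated as the normalized correlation that the
inversion consumes.  The Siegert relation `g2 = 1 + beta g1^2` is
available as an explicit, invertible operation so intensity-normalized
traces can be simulated and consumed; the inversion converts intensity
traces to field form first, estimating the baseline from the last decade
of lags and clipping (and counting) negative excursions before the
square root.

## Regularized inversion

Recovering `F` from `g` is a discretized inverse Laplace transform.  We
solve

    min || A f - g ||^2 + lambda || L f ||^2   s.t.  f >= 0

on a log-spaced diameter grid (default 1 nm - 10 um, 100 points, ~10%
spacing per cell) by non-negative least squares on the augmented system.
`L` is the second-difference operator by default (smooth distributions;
identity available).  `lambda` is quoted relative to the spectral norm of
`A^T A`.

**Choice of lambda.**  The default selector sweeps 40 log-spaced values
(1e-6 - 1e2 relative) and looks for the L-curve corner.  On discrete
non-negative sweeps the pointwise curvature of the (log residual, log
seminorm) curve is too ragged to maximize directly — the maximizer tends
to land on a spurious bend deep in the over-smoothed branch.  The corner
is therefore located as the *noise-plateau exit*: the largest lambda
whose residual stays within 10% of the residual floor.  On noiseless
traces the residual rises from the very first step, so the smallest
lambda of the sweep is returned (no smoothing is warranted); at 1%
measurement noise the plateau is long and the selected lambda is orders
of magnitude larger.  The residual is checked to be non-increasing as
lambda decreases on every sweep — a property of exact penalized solves
that doubles as a solver self-test.  A discrepancy-principle selector
(largest lambda with residual below twice the floor) is available behind
a config tag, and a degenerate (flat) sweep falls back to a documented
default lambda with a logged warning.

**Modes and d_max.**  The summary statistic of the titration is `d_max`,
the diameter of the largest mode of the recovered intensity
distribution.  Modes are local maxima with prominence at least 5% of the
maximum weight; basin boundaries sit at the minimum between adjacent
peaks, with shared boundary weight split evenly.  The mode position is
refined by quadratic interpolation in log diameter around the peak cell,
which removes most of the ~10% grid quantization from `d_max`.  Modes are
ordered by basin mass, exact ties broken toward the larger diameter
(aggregates are the object of study).

Resolution limits are inherent, not incidental: modes separated by a
factor of ~10 in diameter resolve cleanly at 1% noise; separations below
about x2 may merge into one basin.  At intermediate magnetite
concentrations the three base components (6, 20, 85 nm) sit within one
decade of each other and can merge into a single basin whose combined
power occasionally rivals the mixed-complex mode — which is why regime
detection ranks descending runs by total size drop (below), not run
length.

## Synthetic aggregation model

The mixture at magnetite concentration `n_MF` (mg/L) always contains the
three base components seen in the pure controls — albumin monomer
(6 nm), albumin self-aggregates (85 nm, within the reported 70-100 nm
band), magnetite particles (20 nm, within 10-30 nm) at a 0.35/0.40/0.25
power split — plus, above an onset of 0.1 ug/L, a mixed
albumin-magnetite complex.  The complex modal diameter follows log-log
interpolation through anchors (0.1 ug/L, 500 nm), (2 ug/L, 800 nm),
(100 ug/L, 250 nm), (1 mg/L, 1200 nm); the last anchor renders an open
">1000 nm" statement and is flagged as a representative choice, not a
reported value.  The non-monotonic shape — growth, a descending
stabilized segment, renewed growth — is the study's headline and is
asserted as a sign pattern in the tests.

The complex's power fraction grows logistically in log concentration
(center 1e-3 mg/L, slope 2 per decade) and saturates at 0.6; the study
describes relative concentrations only qualitatively, so this curve is a
documented modeling choice.  Components are rendered as log-normal bumps
(geometric sd 1.2) on a 160-point diameter grid; the study shows broad
peaks but gives no shape.

Traces get i.i.d. Gaussian noise with per-lag sd `noise_sd * g(tau)`
(default 1%); photon-counting statistics are out of scope.  Every
generated artifact is a pure function of (configuration, seed).

The Clausius-Clapeyron evaporation rate `n_a = b T^(1/2) exp(-l_a/k_B T)`
is implemented as the drying-time scale of the film scenario (defaults:
T = 308 K, the film-drying temperature; l_a = 6.8e-20 J ~ 0.42 eV,
typical of water).  It does not influence the rendered geometry.

## Film scenes and their analysis

Dried-film micrographs are emulated phenomenologically: a bright
background (0.8) with seeded correlated texture (Gaussian, sd 0.03,
2 px correlation length), dark logarithmic-spiral crack curves
`r = a e^{b phi}` and dark elliptical aggregate blobs.  No crack
mechanics or Marangoni flow is simulated — the scenes exist to carry
exact ground truth for the detector.

Spirals: growth rate b in [0.15, 0.35], 1.5-4 turns, anti-aliased
strokes 1-3 px wide with full-contrast cores, outer radius capped at
45 px (the growth rate is clipped downward when needed so at least 1.5
turns fit).  The core radius is additionally floored so the first
inter-turn gap `a (e^{2 pi b} - 1)` exceeds the stroke width — without
this the inner turns fuse into a solid disk that no analysis could call
a spiral.  Spiral count per scene is Poisson around a unimodal piecewise
log-linear curve: a pure-albumin baseline of 60 (a placeholder — the
study reports no numeric baseline), rising to 155 (midpoint of the
reported 150-160) at 1e-4 mg/L, nearly flat to the 0.05 mg/L decrease
onset, falling to 10 at 1 mg/L.  A `count_scale` factor shrinks scenes
for benchmarking; the in-repo benchmarks use scale 0.1 with 512-768 px
scenes, which preserves the rise-then-fall ordering at a tractable cost.
Aggregate blobs appear only with magnetite; their expected count grows
as `6 n^0.4` and their median equivalent diameter as `16 n^0.2` um (so
>= 10 um at 1 mg/L, where the study reports 10+ um aggregates); the
first planted blob takes the median diameter deterministically so
high-concentration scenes always carry a representative aggregate.

**Detector.**  (1) min-max contrast normalization (so counts are
invariant to global brightness offsets); (2) Otsu thresholding of the
inverted image, with a floor of 0.5 and a 25%-coverage cap guarding
against splitting pure texture; (3) connected components, size >= 25 px;
components with solidity > 0.8 are routed to aggregate measurement
(filled blobs approach 1.0, even tightly wound spirals stay below ~0.6);
(4) skeletonization, and from each skeleton endpoint a path ordering by
BFS geodesic distance; the log-spiral center is fit by Nelder-Mead
seeded at both ends of the path (the core may sit at the far end when
inner turns close into a loop), minimizing the RMS residual of the
linear fit `log r ~ phi` *divided by the winding span* — the
normalization removes decoy minima where an off-center candidate stops
winding and fits trivially well — with the search boxed to the component
neighborhood because a center at infinity makes `log r` spuriously
constant; (5) `spiral_score` = (fraction of the fitted arc within 2 px
of crack pixels) x (fraction of monotone winding steps) x a fit-quality
factor `exp(-2 rms)`; detections need score >= 0.6 and >= 0.75 turns;
(6) non-maximum suppression within the fitted core diameter (min 8 px).
The reported core diameter is the smallest fitted radius on the
traversed arc (the intercept `a` extrapolates to phi = 0, which may lie
off the arc).

Aggregates: components with solidity >= 0.8 and major/minor axis ratio
<= 4 (crack-line filter) are hole-filled and reported as
equivalent-circle diameters via the pixel size.

The reference-software behind the study's spiral counts is undescribed;
this detector is the package's own definition and no equivalence is
claimed.  Counts are reported per image; aggregation over dish-edge
rings is left to the caller.

## Regime detection and stoichiometry

Series logic runs on log10 concentration; a zero-concentration entry is
a labeled baseline excluded from log-axis fits.  The descending segment
is the maximal strictly-decreasing run of `d_max` between a local
maximum and the following local minimum, where "maximal" means the
largest total `d_max` drop (ties to the longer run, then the lower
concentration).  Ranking by drop rather than length keeps a long shallow
jitter among the small base modes from outranking the collapse of the
complex mode, which is the physical stabilization signature.  Plateaus
break runs (strictness).  Entry labels: entries inside the segment are
"stabilized", after it "destabilized", before it "baseline" when
`d_max <= 150 nm` (the base mixture tops out near 100 nm) and
"complex-growth" otherwise.

Stoichiometry uses two constants the study relies on but does not print:
HSA molar mass 66,500 g/mol and magnetite density 5.2 g/cm^3; both are
overridable and echoed.  The protein-per-nanoparticle ratio is the exact
closed form (protein number concentration via Avogadro over particle
number concentration via the mass of a 10 nm sphere).

## Problem sizes and runtime

The default suite and the acceptance script scale the study to sizes a
single CPU handles in minutes: 8-concentration series with 20 seeded
replicates, 50-seed monodisperse recovery, film benchmarks of 6-10
scenes at 512-1024 px with scaled-down spiral loads.  All random draws
descend from explicit seeds; identical seeds give byte-identical series
reports (floats serialized at 9 significant digits).

## What passing tests do and do not show

The synthetic data carry the reported *structure* — component sizes and
anchors, noise magnitude, count curves — but idealize everything else:
noise is Gaussian and uncorrelated across lags (real correlator noise is
correlated and baseline-drifting), mixture peaks are log-normal,
film backgrounds are smooth Gaussian texture rather than drying
gradients, cracks never branch, and spiral loads in benchmark scenes are
a tenth of a full dish edge.  Recovery and detection scores here
therefore bound what the algorithms can do under the stated conditions;
they do not certify performance on real micrographs or real correlator
output.  The study's own measured distributions come from undeposited
instrument data and cannot be reproduced; only in-text computable
numbers and property-level recovery are checked.
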