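"""Synthetic inputs with the statistical structure of the aggregation study.

No measured data are deposited for the albumin-magnetite system, so every
pipeline input is generated here with the features the study reports:

* a concentration-dependent mixture model for the intensity-weighted size
  distribution — albumin monomers (~6 nm), albumin self-aggregates
  (70-100 nm) and free magnetite particles (10-30 nm) are always present,
  and a mixed albumin-magnetite complex appears above an onset magnetite
  concentration, its modal diameter following the non-monotonic pattern
  500 nm (0.1 ug/L) -> 800 nm (2 ug/L) -> 250 nm (100 ug/L) -> >1000 nm
  (above 0.1 mg/L);
* noisy correlation traces from the forward model;
* dried-film micrographs with planted logarithmic-spiral crack structures
  and dark aggregate blobs, plus exact ground truth for benchmarking the
  detector.

Every artifact is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line_aa
from skimage.morphology import dilation, disk

from .dls_model import (
    BOLTZMANN_CONSTANT,
    CorrelationTrace,
    InstrumentConfig,
    SizeDistribution,
    forward_field_correlation,
)
from .errors import ParameterError

__all__ = [
    "Component",
    "ScenarioConfig",
    "AggregationModel",
    "EvaporationParams",
    "FilmGeometry",
    "PlantedSpiral",
    "PlantedAggregate",
    "FilmSceneTruth",
    "components_for_concentration",
    "render_components",
    "mixture_for_concentration",
    "generate_trace",
    "evaporation_rate",
    "spiral_count_model",
    "expected_aggregate_count",
    "aggregate_median_diameter_um",
    "generate_film_image",
    "truth_aggregate_mask",
]


# --------------------------------------------------------------------------
# mixture model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """One log-normal component of the intensity-weighted mixture."""

    label: str
    mode_diameter: float  # m
    geometric_sd: float = 1.2
    intensity_fraction: float = 0.0


#: Base components seen in pure-albumin and pure-magnetite controls:
#: ~6 nm albumin monomer, 70-100 nm albumin self-aggregates, 10-30 nm
#: magnetite particles.  Fractions are the zero-magnetite split; they are
#: rescaled by (1 - complex fraction) once the mixed complex appears.
BASE_COMPONENTS = (
    Component("albumin_monomer", 6e-9, 1.2, 0.35),
    Component("albumin_aggregate", 85e-9, 1.2, 0.40),
    Component("magnetite_particle", 20e-9, 1.2, 0.25),
)


@dataclass(frozen=True)
class AggregationModel:
    """Concentration dependence of the albumin-magnetite complex.

    ``anchor_points`` pin the complex modal diameter at reference
    magnetite concentrations (mg/L, m); between anchors the diameter is
    interpolated piecewise linearly in (log concentration, log diameter).
    The complex is absent below the first anchor (the onset).  Its
    scattered-power fraction grows logistically in log concentration up to
    ``complex_fraction_cap``.
    """

    anchor_points: tuple[tuple[float, float], ...] = (
        (1e-4, 500e-9),   # onset: a >500 nm peak appears at 0.1 ug/L
        (2e-3, 800e-9),   # grows to ~800 nm at 2 ug/L
        (1e-1, 250e-9),   # shrinks to ~250 nm at 100 ug/L (stabilized)
        (1e0, 1200e-9),   # >1000 nm above 0.1 mg/L; 1200 nm is a
                          # representative value for that open bound
    )
    base_components: tuple[Component, ...] = BASE_COMPONENTS
    complex_fraction_cap: float = 0.6
    logistic_center_log10: float = -3.0  # mg/L, log10
    logistic_slope: float = 2.0          # per decade

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.anchor_points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ParameterError("anchor concentrations must be strictly increasing")
        if not all(c > 0 and d > 0 for c, d in self.anchor_points):
            raise ParameterError("anchors must be positive")

    @property
    def onset(self) -> float:
        return self.anchor_points[0][0]

    def complex_diameter(self, n_mf: float) -> float:
        """Modal diameter of the mixed complex, m (log-log interpolation,
        clamped at the end anchors)."""
        logc = np.log10([c for c, _ in self.anchor_points])
        logd = np.log10([d for _, d in self.anchor_points])
        return float(10.0 ** np.interp(math.log10(n_mf), logc, logd))

    def complex_fraction(self, n_mf: float) -> float:
        if n_mf < self.onset:
            return 0.0
        x = math.log10(n_mf) - self.logistic_center_log10
        return self.complex_fraction_cap / (1.0 + math.exp(-self.logistic_slope * x))


def components_for_concentration(
    model: AggregationModel, n_mf: float
) -> list[Component]:
    """Discrete mixture components at magnetite concentration ``n_mf`` (mg/L)."""
    if n_mf < 0:
        raise ParameterError(f"mf concentration must be >= 0, got {n_mf}")
    f_complex = model.complex_fraction(n_mf)
    comps = [
        Component(c.label, c.mode_diameter, c.geometric_sd,
                  c.intensity_fraction * (1.0 - f_complex))
        for c in model.base_components
    ]
    if f_complex > 0:
        comps.append(
            Component("albumin_magnetite_complex", model.complex_diameter(n_mf),
                      1.2, f_complex)
        )
    return comps


def default_mixture_grid(n: int = 160) -> np.ndarray:
    return np.logspace(-9, -5, n)


def render_components(
    components: list[Component], grid: np.ndarray | None = None
) -> SizeDistribution:
    """Render discrete components as log-normal bumps on a diameter grid."""
    grid = default_mixture_grid() if grid is None else np.asarray(grid, dtype=float)
    logd = np.log(grid)
    w = np.zeros_like(grid)
    for c in components:
        sigma = math.log(c.geometric_sd)
        w += c.intensity_fraction * np.exp(
            -0.5 * ((logd - math.log(c.mode_diameter)) / sigma) ** 2
        )
    total = w.sum()
    if total <= 0:
        raise ParameterError("mixture has zero total intensity")
    return SizeDistribution(diameters=grid, weights=w / total)


def mixture_for_concentration(
    model: AggregationModel, n_mf: float, grid: np.ndarray | None = None
) -> SizeDistribution:
    """Intensity-weighted size distribution at magnetite concentration
    ``n_mf`` (mg/L), rendered on a log-spaced diameter grid."""
    return render_components(components_for_concentration(model, n_mf), grid)


# --------------------------------------------------------------------------
# correlation-trace generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated sample: mixture composition plus measurement noise.

    ``noise_sd`` is the relative standard deviation of the additive
    Gaussian noise on g(tau) (i.e. per-lag sd is ``noise_sd * g(tau)``).
    """

    mf_concentration: float  # mg/L
    components: tuple[Component, ...]
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mf_concentration < 0:
            raise ParameterError("mf_concentration must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        fracs = np.array([c.intensity_fraction for c in self.components])
        if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
            raise ParameterError("intensity fractions must be >= 0 and sum to 1")

    @classmethod
    def from_concentration(
        cls,
        n_mf: float,
        model: AggregationModel | None = None,
        noise_sd: float = 0.01,
        seed: int = 0,
    ) -> "ScenarioConfig":
        model = model or AggregationModel()
        return cls(
            mf_concentration=n_mf,
            components=tuple(components_for_concentration(model, n_mf)),
            noise_sd=noise_sd,
            seed=seed,
        )


def generate_trace(
    scenario: ScenarioConfig,
    config: InstrumentConfig,
    lags,
    grid: np.ndarray | None = None,
) -> CorrelationTrace:
    """Noisy correlation trace for a scenario (reproducible per seed)."""
    dist = render_components(list(scenario.components), grid)
    clean = forward_field_correlation(dist, config, lags)
    if scenario.noise_sd == 0:
        return clean
    rng = np.random.default_rng(scenario.seed)
    noise = scenario.noise_sd * clean.values * rng.standard_normal(clean.values.size)
    return CorrelationTrace(
        lags=clean.lags, values=clean.values + noise,
        kind="field", instrument=config,
    )


# --------------------------------------------------------------------------
# evaporation (drying-time scale for the film scenes)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaporationParams:
    """Clausius-Clapeyron evaporation parameters: temperature (K),
    per-particle evaporation work l_a (J) and thermal constant b
    (K^-1/2)."""

    temperature: float = 308.0  # drying temperature of the films
    evaporation_work: float = 6.8e-20  # ~0.42 eV, typical for water
    thermal_constant: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0")
        if self.evaporation_work < 0 or self.thermal_constant <= 0:
            raise ParameterError("evaporation parameters must be positive")


def evaporation_rate(params: EvaporationParams) -> float:
    """Particles evaporating per unit area and time (arbitrary scale):
    n_a = b * T^(1/2) * exp(-l_a / (k_B T)).  Used only to set the
    synthetic drying-time scale; strictly increasing in T."""
    T = params.temperature
    return params.thermal_constant * math.sqrt(T) * math.exp(
        -params.evaporation_work / (BOLTZMANN_CONSTANT * T)
    )


# --------------------------------------------------------------------------
# spiral-count and aggregate models
# --------------------------------------------------------------------------

#: (log10 n_mf [mg/L], expected spiral count) nodes of the piecewise
#: log-linear count curve.  The pure-albumin baseline (60) is a documented
#: placeholder: the study reports the count only relative to magnetite
#: concentration.  The curve rises to 155 (midpoint of the reported
#: 150-160) at 1e-4 mg/L, stays near the peak up to the 0.05 mg/L decrease
#: onset, and falls to ~10 at 1 mg/L.
SPIRAL_COUNT_NODES = (
    (-5.0, 60.0),
    (-4.0, 155.0),
    (math.log10(0.05), 150.0),
    (0.0, 10.0),
)

SPIRAL_BASELINE_COUNT = 60.0


def spiral_count_model(n_mf: float) -> float:
    """Expected number of spiral structures per film at magnetite
    concentration ``n_mf`` (mg/L); deterministic and unimodal in log
    concentration."""
    if n_mf < 0:
        raise ParameterError(f"mf concentration must be >= 0, got {n_mf}")
    if n_mf == 0:
        return SPIRAL_BASELINE_COUNT
    x = math.log10(n_mf)
    xs = [p[0] for p in SPIRAL_COUNT_NODES]
    ys = [p[1] for p in SPIRAL_COUNT_NODES]
    return float(np.interp(x, xs, ys))


def expected_aggregate_count(n_mf: float) -> float:
    """Expected planted film-aggregate blobs per scene; zero without
    magnetite, ~6 at 1 mg/L."""
    if n_mf < 0:
        raise ParameterError(f"mf concentration must be >= 0, got {n_mf}")
    return 0.0 if n_mf == 0 else 6.0 * n_mf**0.4


def aggregate_median_diameter_um(n_mf: float) -> float:
    """Median equivalent diameter of planted blobs, um; 16 um at 1 mg/L
    (the study reports aggregates of 10 um and more there)."""
    return 16.0 * max(n_mf, 1e-12) ** 0.2


# --------------------------------------------------------------------------
# film scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilmGeometry:
    height: int = 512
    width: int = 512
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.height < 256 or self.width < 256:
            raise ParameterError("film images must be at least 256x256 px")


@dataclass(frozen=True)
class PlantedSpiral:
    center: tuple[float, float]  # (row, col), px
    turns: float
    core_diameter: float  # um
    growth_rate: float    # log-spiral b
    chirality: int = 1
    phase: float = 0.0
    stroke_width: int = 1


@dataclass(frozen=True)
class PlantedAggregate:
    center: tuple[float, float]  # (row, col), px
    equivalent_diameter: float   # um
    axes_px: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0


@dataclass(frozen=True)
class FilmSceneTruth:
    planted_spirals: list[PlantedSpiral]
    planted_aggregates: list[PlantedAggregate]
    pixel_size: float  # um/px
    seed: int
    shape: tuple[int, int] = (512, 512)

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size,
            "seed": self.seed,
            "shape": list(self.shape),
            "spirals": [
                {
                    "center": list(s.center), "turns": s.turns,
                    "core_diameter_um": s.core_diameter,
                    "growth_rate": s.growth_rate,
                }
                for s in self.planted_spirals
            ],
            "aggregates": [
                {"center": list(a.center), "equivalent_diameter_um": a.equivalent_diameter}
                for a in self.planted_aggregates
            ],
        }


def _spiral_points(
    center: tuple[float, float], a: float, b: float, turns: float,
    chirality: int, phase: float,
) -> np.ndarray:
    """Sampled (row, col) polyline of r = a * exp(b * phi)."""
    pts = []
    phi = 0.0
    phi_end = 2.0 * math.pi * turns
    while phi <= phi_end:
        r = a * math.exp(b * phi)
        ang = chirality * phi + phase
        pts.append((center[0] + r * math.sin(ang), center[1] + r * math.cos(ang)))
        phi += min(0.25, 0.7 / max(r, 1.0))
    return np.array(pts)


def _stamp_spiral(darkness: np.ndarray, spiral: PlantedSpiral, a_px: float) -> None:
    """Render one spiral into the darkness canvas (max-composited)."""
    pts = _spiral_points(spiral.center, a_px, spiral.growth_rate,
                         spiral.turns, spiral.chirality, spiral.phase)
    r_out = a_px * math.exp(spiral.growth_rate * 2 * math.pi * spiral.turns)
    pad = int(r_out + spiral.stroke_width + 3)
    r0 = max(int(spiral.center[0]) - pad, 0)
    c0 = max(int(spiral.center[1]) - pad, 0)
    r1 = min(int(spiral.center[0]) + pad, darkness.shape[0] - 1)
    c1 = min(int(spiral.center[1]) + pad, darkness.shape[1] - 1)
    patch = np.zeros((r1 - r0 + 1, c1 - c0 + 1))
    ipts = np.round(pts).astype(int)
    for (ra, ca), (rb, cb) in zip(ipts[:-1], ipts[1:]):
        rr, cc, val = line_aa(ra - r0, ca - c0, rb - r0, cb - c0)
        keep = (rr >= 0) & (rr < patch.shape[0]) & (cc >= 0) & (cc < patch.shape[1])
        rr, cc, val = rr[keep], cc[keep], val[keep]
        np.maximum.at(patch, (rr, cc), val)
    # keep anti-aliased edges but give the stroke core full contrast so
    # thin cracks do not fragment under intensity thresholding
    patch = np.where(patch > 0.05, 0.5 + 0.5 * patch, 0.0)
    radius = (spiral.stroke_width - 1) // 2
    if radius > 0:
        patch = dilation(patch, disk(radius))
    np.maximum(darkness[r0:r1 + 1, c0:c1 + 1], patch,
               out=darkness[r0:r1 + 1, c0:c1 + 1])


def _place_centers(
    rng: np.random.Generator, n: int, shape: tuple[int, int],
    radii: np.ndarray, occupied: list[tuple[float, float, float]],
    margin: float, max_tries: int = 200,
) -> list[tuple[float, float]]:
    """Rejection-sample centers keeping footprints ``margin`` apart;
    gives up per item after ``max_tries`` (the truth then simply holds
    fewer items)."""
    centers: list[tuple[float, float]] = []
    for i in range(n):
        r_i = radii[i]
        for _ in range(max_tries):
            row = rng.uniform(r_i + 4, shape[0] - r_i - 4)
            col = rng.uniform(r_i + 4, shape[1] - r_i - 4)
            if all(
                math.hypot(row - ro, col - co) >= r_i + rr + margin
                for ro, co, rr in occupied
            ):
                centers.append((row, col))
                occupied.append((row, col, r_i))
                break
    return centers


def generate_film_image(
    n_mf: float,
    geometry: FilmGeometry | None = None,
    seed: int = 0,
    count_scale: float = 1.0,
    noise_sd: float = 0.03,
    n_spirals: int | None = None,
    n_aggregates: int | None = None,
    placement_margin: float = 6.0,
) -> tuple[np.ndarray, FilmSceneTruth]:
    """Synthetic dried-film micrograph plus exact ground truth.

    Dark logarithmic-spiral crack curves and dark elliptical aggregate
    blobs are composited over a bright background with seeded low-
    amplitude correlated texture.  Spiral counts are Poisson-jittered
    around ``count_scale * spiral_count_model(n_mf)`` unless ``n_spirals``
    is given; aggregate counts and sizes scale with ``n_mf`` (none at
    zero magnetite, median 16 um at 1 mg/L).  Returns a float image in
    [0, 1]; identical (arguments, seed) give identical rasters.
    """
    if n_mf < 0:
        raise ParameterError(f"mf concentration must be >= 0, got {n_mf}")
    geometry = geometry or FilmGeometry()
    shape = (geometry.height, geometry.width)
    px = geometry.pixel_size_um
    rng = np.random.default_rng(seed)

    # aggregates first; spirals avoid their footprints
    if n_aggregates is None:
        expected = count_scale * expected_aggregate_count(n_mf)
        n_agg = int(rng.poisson(expected))
        if expected >= 1.0:
            n_agg = max(n_agg, 1)
    else:
        n_agg = int(n_aggregates)
    med_um = aggregate_median_diameter_um(n_mf)
    diam_um = med_um * np.exp(math.log(1.25) * rng.standard_normal(max(n_agg, 1)))
    if n_agg > 0:
        diam_um[0] = med_um  # deterministic representative blob
    diam_um = diam_um[:n_agg]
    radii_px = (diam_um / 2.0) / px
    occupied: list[tuple[float, float, float]] = []
    agg_centers = _place_centers(rng, n_agg, shape, radii_px * 1.6, occupied,
                                 placement_margin)
    aggregates = []
    darkness = np.zeros(shape)
    for (row, col), d_um in zip(agg_centers, diam_um):
        area_px = math.pi * (d_um / 2.0 / px) ** 2
        aspect = rng.uniform(1.0, 1.8)
        b_ax = math.sqrt(area_px / (math.pi * aspect))
        a_ax = aspect * b_ax
        theta = rng.uniform(0, math.pi)
        rr, cc = draw_ellipse(row, col, a_ax, b_ax, shape=shape, rotation=theta)
        darkness[rr, cc] = 1.0
        aggregates.append(
            PlantedAggregate(center=(row, col), equivalent_diameter=float(d_um),
                             axes_px=(a_ax, b_ax), orientation=theta)
        )

    # spirals
    if n_spirals is None:
        n_spi = int(rng.poisson(count_scale * spiral_count_model(n_mf)))
    else:
        n_spi = int(n_spirals)
    spirals: list[PlantedSpiral] = []
    b_raw = rng.uniform(0.15, 0.35, size=n_spi)
    widths = rng.integers(1, 4, size=n_spi)
    r_max = 45.0
    params = []
    for i in range(n_spi):
        w_i = int(widths[i])
        # the first inter-turn gap a*(e^{2 pi b} - 1) must exceed the
        # stroke width or the core fuses into an unresolvable blob
        a_lo = max(2.0, (w_i + 1.5) / (math.exp(2 * math.pi * b_raw[i]) - 1.0))
        a_i = rng.uniform(min(a_lo, 4.4), 4.5)
        # keep >= 1.5 turns inside r_max by clipping the growth rate
        b_i = min(b_raw[i], math.log(r_max / a_i) / (2 * math.pi * 1.5))
        t_cap = math.log(r_max / a_i) / (2 * math.pi * b_i)
        t_i = rng.uniform(1.5, max(min(4.0, t_cap), 1.5 + 1e-9))
        params.append((a_i, b_i, t_i, w_i))
    r_out = np.array([a * math.exp(b * 2 * math.pi * t) for a, b, t, _ in params])
    spi_centers = _place_centers(rng, n_spi, shape, r_out, occupied, placement_margin)
    for (row, col), (a_i, b_i, t_i, w_i) in zip(spi_centers, params):
        spiral = PlantedSpiral(
            center=(row, col), turns=float(t_i),
            core_diameter=float(2 * a_i * px), growth_rate=float(b_i),
            chirality=int(rng.choice([-1, 1])),
            phase=float(rng.uniform(0, 2 * math.pi)),
            stroke_width=w_i,
        )
        _stamp_spiral(darkness, spiral, a_i)
        spirals.append(spiral)

    # background with correlated low-amplitude texture
    texture = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    sd = texture.std()
    if sd > 0:
        texture *= noise_sd / sd
    image = np.clip(0.8 + texture - 0.6 * darkness, 0.0, 1.0)
    truth = FilmSceneTruth(
        planted_spirals=spirals, planted_aggregates=aggregates,
        pixel_size=px, seed=seed, shape=shape,
    )
    return image, truth


def truth_aggregate_mask(truth: FilmSceneTruth) -> np.ndarray:
    """Ideal binary mask of the planted aggregate blobs."""
    mask = np.zeros(truth.shape, dtype=bool)
    for agg in truth.planted_aggregates:
        rr, cc = draw_ellipse(
            agg.center[0], agg.center[1], agg.axes_px[0], agg.axes_px[1],
            shape=truth.shape, rotation=agg.orientation,
        )
        mask[rr, cc] = True
    return mask


def write_film_scene(image: np.ndarray, truth: FilmSceneTruth, path_png, path_json) -> None:
    """8-bit grayscale PNG plus a JSON truth sidecar."""
    import imageio.v3 as iio

    iio.imwrite(path_png, (np.clip(image, 0, 1) * 255).astype(np.uint8))
    with open(path_json, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
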