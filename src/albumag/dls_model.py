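"""Forward physics of laser correlation spectroscopy (dynamic light scattering).

A dilute suspension of Brownian particles scatters coherent light whose
normalized field autocorrelation decays as a weighted sum of exponentials,

    g(tau) = sum_i F(q, D_i) * exp(-q^2 * D_i * tau),

where ``F(q, D_i)`` is the fraction of scattered power carried by the
component with translational diffusion coefficient ``D_i``, and the wave
vector ``q = (4 pi n0 / lambda0) sin(theta / 2)`` is fixed by the optical
geometry.  The Stokes-Einstein relation ``D = k_B T / (3 pi eta d)`` maps
each diffusion coefficient onto a hydrodynamic diameter ``d``, so an
intensity-weighted size distribution fully determines the trace.

All quantities are SI internally (metres, seconds, kelvin, Pa*s); helper
constructors accept the customary laboratory units (nm, degrees, mPa*s).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, StateError

#: Boltzmann constant, J/K (CODATA 2018 exact value). Not configurable.
BOLTZMANN_CONSTANT = 1.380649e-23

__all__ = [
    "BOLTZMANN_CONSTANT",
    "InstrumentConfig",
    "SizeDistribution",
    "CorrelationTrace",
    "wave_vector",
    "diffusion_coefficient",
    "diameter_from_diffusion",
    "forward_field_correlation",
    "field_to_intensity",
    "intensity_to_field",
    "default_lag_grid",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Optical and thermodynamic parameters of the spectrometer.

    Parameters
    ----------
    wavelength : float
        Vacuum laser wavelength, m.  Default 633 nm (He-Ne).
    angle : float
        Detection angle, rad.  Default 90 degrees.
    refractive_index : float
        Refractive index of the solvent.  Default 1.33 (water).
    temperature : float
        Sample temperature, K.  Default 300 K.
    viscosity : float
        Dynamic viscosity of the solvent, Pa*s.  Default 0.89e-3
        (water near 300 K).  The solvent viscosity and refractive index
        are not measured by the instrument; reports echo the values used.
    """

    wavelength: float = 633e-9
    angle: float = math.pi / 2
    refractive_index: float = 1.33
    temperature: float = 300.0
    viscosity: float = 0.89e-3

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise ParameterError(f"wavelength must be > 0, got {self.wavelength}")
        if not (0 < self.angle < math.pi):
            raise ParameterError(f"angle must lie in (0, pi), got {self.angle}")
        if not (self.refractive_index >= 1):
            raise ParameterError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )
        if not (self.temperature > 0):
            raise ParameterError(f"temperature must be > 0, got {self.temperature}")
        if not (self.viscosity > 0):
            raise ParameterError(f"viscosity must be > 0, got {self.viscosity}")

    @classmethod
    def from_lab_units(
        cls,
        wavelength_nm: float = 633.0,
        angle_deg: float = 90.0,
        refractive_index: float = 1.33,
        temperature_K: float = 300.0,
        viscosity_mPa_s: float = 0.89,
    ) -> "InstrumentConfig":
        return cls(
            wavelength=wavelength_nm * 1e-9,
            angle=math.radians(angle_deg),
            refractive_index=refractive_index,
            temperature=temperature_K,
            viscosity=viscosity_mPa_s * 1e-3,
        )

    def to_lab_units(self) -> dict:
        """Serializable dict with explicit unit suffixes."""
        return {
            "wavelength_nm": self.wavelength * 1e9,
            "angle_deg": math.degrees(self.angle),
            "refractive_index": self.refractive_index,
            "temperature_K": self.temperature,
            "viscosity_mPa_s": self.viscosity * 1e3,
        }

    @classmethod
    def from_mapping(cls, d: dict) -> "InstrumentConfig":
        return cls.from_lab_units(
            wavelength_nm=float(d.get("wavelength_nm", 633.0)),
            angle_deg=float(d.get("angle_deg", 90.0)),
            refractive_index=float(d.get("refractive_index", 1.33)),
            temperature_K=float(d.get("temperature_K", 300.0)),
            viscosity_mPa_s=float(d.get("viscosity_mPa_s", 0.89)),
        )


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ParameterError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SizeDistribution:
    """Intensity-weighted hydrodynamic size distribution.

    ``diameters`` (m, strictly increasing) carry the grid; ``weights`` are
    the dimensionless scattering-power fractions F(q, D_i), normalized to
    sum to one.
    """

    diameters: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        d = _as_float_array(self.diameters, "diameters")
        w = _as_float_array(self.weights, "weights")
        if d.size != w.size:
            raise ParameterError(
                f"diameters ({d.size}) and weights ({w.size}) differ in length"
            )
        if np.any(d <= 0):
            raise ParameterError("all diameters must be > 0")
        if np.any(np.diff(d) <= 0):
            raise ParameterError("diameters must be strictly increasing")
        if np.any(w < 0):
            raise ParameterError("weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError(f"weights must sum to 1 (got {w.sum():.12g})")
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_nm(cls, diameters_nm, weights) -> "SizeDistribution":
        return cls(np.asarray(diameters_nm, dtype=float) * 1e-9, weights)

    @property
    def diameters_nm(self) -> np.ndarray:
        return self.diameters * 1e9

    def __len__(self) -> int:
        return int(self.diameters.size)


@dataclass(frozen=True)
class CorrelationTrace:
    """Lag/value pairs of the correlation function with instrument context.

    ``kind`` is ``"field"`` for the normalized field correlation g1 or
    ``"intensity"`` for the Siegert-transformed g2 = 1 + beta * g1**2;
    ``coherence_factor`` is beta and is meaningful only for intensity
    traces.
    """

    lags: np.ndarray
    values: np.ndarray
    kind: str = "field"
    coherence_factor: float = 1.0
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)

    def __post_init__(self) -> None:
        lags = _as_float_array(self.lags, "lags")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size != lags.size:
            raise ParameterError("values must match lags in shape")
        if lags.size < 4:
            raise ParameterError(f"need >= 4 lag points, got {lags.size}")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ParameterError("lags must be strictly increasing and positive")
        if self.kind not in ("field", "intensity"):
            raise ParameterError(f"kind must be 'field' or 'intensity', got {self.kind!r}")
        if not (0 < self.coherence_factor <= 1):
            raise ParameterError(
                f"coherence_factor must lie in (0, 1], got {self.coherence_factor}"
            )
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.lags.size)


def wave_vector(config: InstrumentConfig) -> float:
    """Scattering wave vector q = (4 pi n0 / lambda0) sin(theta/2), 1/m."""
    return (
        4.0
        * math.pi
        * config.refractive_index
        / config.wavelength
        * math.sin(config.angle / 2.0)
    )


def diffusion_coefficient(diameter: float, config: InstrumentConfig) -> float:
    """Stokes-Einstein diffusion coefficient D = k_B T / (3 pi eta d), m^2/s."""
    if not (diameter > 0):
        raise ParameterError(f"diameter must be > 0, got {diameter}")
    return BOLTZMANN_CONSTANT * config.temperature / (
        3.0 * math.pi * config.viscosity * diameter
    )


def diameter_from_diffusion(D: float, config: InstrumentConfig) -> float:
    """Hydrodynamic diameter from a diffusion coefficient (exact inverse)."""
    if not (D > 0):
        raise ParameterError(f"diffusion coefficient must be > 0, got {D}")
    return BOLTZMANN_CONSTANT * config.temperature / (3.0 * math.pi * config.viscosity * D)


def decay_rates(diameters, config: InstrumentConfig) -> np.ndarray:
    """Per-component decay rates q^2 D_i, 1/s (vectorized over diameters)."""
    d = np.asarray(diameters, dtype=float)
    q = wave_vector(config)
    D = BOLTZMANN_CONSTANT * config.temperature / (3.0 * math.pi * config.viscosity * d)
    return q * q * D


def forward_field_correlation(
    dist: SizeDistribution, config: InstrumentConfig, lags
) -> CorrelationTrace:
    """Noiseless field correlation of a size distribution on a lag grid.

    Evaluates g(tau) = sum_i w_i exp(-q^2 D_i tau) with D_i from the
    Stokes-Einstein relation; g(0+) -> 1 by normalization of the weights.
    """
    lags = _as_float_array(lags, "lags")
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ParameterError("lags must be strictly increasing and positive")
    gamma = decay_rates(dist.diameters, config)  # (n_components,)
    values = np.exp(-np.outer(lags, gamma)) @ dist.weights
    return CorrelationTrace(lags=lags, values=values, kind="field", instrument=config)


def field_to_intensity(trace: CorrelationTrace, coherence_factor: float) -> CorrelationTrace:
    """Siegert relation: g2(tau) = 1 + beta * g1(tau)^2."""
    if trace.kind != "field":
        raise StateError("field_to_intensity requires a field trace")
    if not (0 < coherence_factor <= 1):
        raise ParameterError(
            f"coherence_factor must lie in (0, 1], got {coherence_factor}"
        )
    return replace(
        trace,
        values=1.0 + coherence_factor * trace.values**2,
        kind="intensity",
        coherence_factor=coherence_factor,
    )


def intensity_to_field(trace: CorrelationTrace, baseline: float | None = None) -> CorrelationTrace:
    """Invert the Siegert relation, g1 = sqrt((g2 - baseline)/beta).

    With ``baseline=None`` the theoretical baseline 1 is used.  Values that
    fall below the baseline (possible for noisy data) are clipped at zero.
    """
    if trace.kind != "intensity":
        raise StateError("intensity_to_field requires an intensity trace")
    b = 1.0 if baseline is None else float(baseline)
    g1sq = np.clip(trace.values - b, 0.0, None) / trace.coherence_factor
    return replace(trace, values=np.sqrt(g1sq), kind="field")


def default_lag_grid(
    n: int = 70, lag_min: float = 1e-6, lag_max: float = 0.2
) -> np.ndarray:
    """Log-spaced lag grid, s.

    The defaults span the decay times of everything the study reports:
    6 nm albumin monomers decay in tens of microseconds at the 633 nm /
    90 degree geometry, micron-scale complexes in tens of milliseconds.
    """
    if n < 4:
        raise ParameterError(f"need >= 4 lags, got {n}")
    if not (0 < lag_min < lag_max):
        raise ParameterError("require 0 < lag_min < lag_max")
    return np.logspace(math.log10(lag_min), math.log10(lag_max), n)


def write_trace_csv(trace: CorrelationTrace, path) -> None:
    """Two-column CSV (lag_s, g) with a ``# key: value`` JSON-ish header
    block carrying the trace kind and instrument context."""
    meta = {
        "kind": trace.kind,
        "coherence_factor": trace.coherence_factor,
        "instrument": trace.instrument.to_lab_units(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# albumag-trace " + json.dumps(meta) + "\n")
        fh.write("lag_s,g\n")
        for tau, g in zip(trace.lags, trace.values):
            fh.write(f"{tau:.12e},{g:.12e}\n")


def read_trace_csv(path) -> CorrelationTrace:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    meta = {}
    lines = []
    for line in text.splitlines():
        if line.startswith("# albumag-trace"):
            meta = json.loads(line[len("# albumag-trace"):])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            lines.append(line)
    import pandas as pd

    df = pd.read_csv(io.StringIO("\n".join(lines)))
    instrument = InstrumentConfig.from_mapping(meta.get("instrument", {}))
    return CorrelationTrace(
        lags=df["lag_s"].to_numpy(),
        values=df["g"].to_numpy(),
        kind=meta.get("kind", "field"),
        coherence_factor=float(meta.get("coherence_factor", 1.0)),
        instrument=instrument,
    )
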