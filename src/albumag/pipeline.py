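"""End-to-end orchestration: concentration series, regimes, stoichiometry.

The study's headline result is non-monotonic: as magnetite is titrated
into a 50 mg/mL albumin solution, the typical aggregate size d_max first
grows (mixed complex formation), then *decreases* over an intermediate
window (albumin stabilizes the dispersion — the "descending segment"),
then grows again past ~0.1 mg/L (magnetite self-aggregation), while the
spiral count in dried films peaks at low magnetite and collapses at high.
This module assembles per-concentration results into a series, finds those
regimes, and computes the supporting solution-chemistry numbers (protein
molarity, protein molecules per nanoparticle, pH).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .dls_inversion import (
    InversionConfig,
    ModeSummary,
    extract_modes,
    invert,
)
from .dls_model import InstrumentConfig, default_lag_grid
from .errors import DataError, ParameterError
from .synthetic import (
    AggregationModel,
    ScenarioConfig,
    generate_trace,
    spiral_count_model,
)

#: Avogadro constant, 1/mol (CODATA 2018 exact value).
AVOGADRO = 6.02214076e23

#: Defaults for constants the study uses but does not print; both are
#: overridable and echoed in reports.
HSA_MOLAR_MASS = 66_500.0  # g/mol
MAGNETITE_DENSITY = 5.2    # g/cm^3

__all__ = [
    "AVOGADRO",
    "HSA_MOLAR_MASS",
    "MAGNETITE_DENSITY",
    "StoichiometryInput",
    "SeriesEntry",
    "ConcentrationSeries",
    "RegimeReport",
    "protein_molarity",
    "molecules_per_nanoparticle",
    "ph_from_hplus",
    "build_series",
    "detect_regimes",
    "run_concentration_series",
]


# --------------------------------------------------------------------------
# solution chemistry
# --------------------------------------------------------------------------

def protein_molarity(mass_conc: float, molar_mass: float = HSA_MOLAR_MASS) -> float:
    """Molar concentration (mmol/L) of a protein at ``mass_conc`` mg/mL."""
    if not (mass_conc > 0) or not (molar_mass > 0):
        raise ParameterError("mass concentration and molar mass must be > 0")
    return mass_conc / molar_mass * 1e3  # (g/L) / (g/mol) -> mol/L -> mmol/L


@dataclass(frozen=True)
class StoichiometryInput:
    """Inputs of the protein-per-nanoparticle ratio."""

    mf_concentration: float  # mg/L
    protein_mass_concentration: float = 50.0  # mg/mL
    protein_molar_mass: float = HSA_MOLAR_MASS  # g/mol
    particle_diameter: float = 10e-9  # m
    particle_density: float = MAGNETITE_DENSITY  # g/cm^3

    def __post_init__(self) -> None:
        for name in (
            "protein_mass_concentration", "protein_molar_mass",
            "particle_diameter", "particle_density",
        ):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be > 0")
        if self.mf_concentration < 0:
            raise ParameterError("mf_concentration must be >= 0")


def molecules_per_nanoparticle(inp: StoichiometryInput) -> float:
    """Protein molecules per magnetite nanoparticle at the given mixing.

    Protein number concentration: (c_p / M) * N_A per litre.  Particle
    number concentration: c_mf divided by the mass of a density-``rho``
    sphere of the stated diameter.  Exact closed form; diverges as the
    magnetite concentration goes to zero.
    """
    if inp.mf_concentration == 0:
        raise DataError("molecules-per-nanoparticle ratio undefined at zero magnetite")
    protein_per_L = inp.protein_mass_concentration / inp.protein_molar_mass * AVOGADRO
    # mass of one particle in g: rho [g/cm^3] * (pi/6) d^3 [cm^3]
    d_cm = inp.particle_diameter * 1e2
    particle_mass_g = inp.particle_density * math.pi / 6.0 * d_cm**3
    particles_per_L = inp.mf_concentration * 1e-3 / particle_mass_g
    return protein_per_L / particles_per_L


def ph_from_hplus(h_conc: float) -> float:
    """pH = -log10 of the H+ concentration (mol/L)."""
    if not (h_conc > 0):
        raise ParameterError(f"H+ concentration must be > 0, got {h_conc}")
    return -math.log10(h_conc)


# --------------------------------------------------------------------------
# concentration series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesEntry:
    n_mf: float  # mg/L
    d_max: float  # m
    mode_summary: ModeSummary | None = None
    n_spirals: int | None = None


@dataclass(frozen=True)
class ConcentrationSeries:
    """Per-concentration results, sorted by n_mf with unique values."""

    entries: tuple[SeriesEntry, ...]

    def __post_init__(self) -> None:
        concs = [e.n_mf for e in self.entries]
        if len(set(concs)) != len(concs):
            raise DataError("duplicate magnetite concentrations in series")
        ordered = tuple(sorted(self.entries, key=lambda e: e.n_mf))
        object.__setattr__(self, "entries", ordered)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([e.n_mf for e in self.entries])

    @property
    def d_max_values(self) -> np.ndarray:
        return np.array([e.d_max for e in self.entries])


def build_series(runs: list[SeriesEntry]) -> ConcentrationSeries:
    """Validated, sorted series from per-concentration results."""
    if len({r.n_mf for r in runs}) < 2:
        raise ParameterError("a series needs >= 2 distinct concentrations")
    return ConcentrationSeries(entries=tuple(runs))


@dataclass(frozen=True)
class RegimeReport:
    """Regimes of a concentration series.

    ``descending_segment`` is the (start, end) concentration pair of the
    maximal strictly-decreasing run of d_max (the albumin-stabilization
    signature); ``spiral_peak`` the concentration with the highest spiral
    count; ``labels`` one of baseline / complex-growth / stabilized /
    destabilized per entry.
    """

    descending_segment: tuple[float, float] | None
    spiral_peak: float | None
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.descending_segment is not None:
            start, end = self.descending_segment
            if not (start < end):
                raise ParameterError("descending segment must have start < end")

    def to_dict(self) -> dict:
        return {
            "descending_segment_mg_L": (
                list(self.descending_segment) if self.descending_segment else None
            ),
            "spiral_peak_mg_L": self.spiral_peak,
            "labels": list(self.labels),
        }


#: d_max below this is taken as "no mixed complex dominates yet" when
#: labelling baseline entries (the base mixture tops out at ~100 nm).
BASELINE_DMAX = 150e-9


def detect_regimes(series: ConcentrationSeries) -> RegimeReport:
    """Find the descending segment and spiral peak of a series.

    The descending segment is the maximal strictly-decreasing run of
    d_max between a local maximum and the following local minimum
    (plateaus break a run); "maximal" means the run with the largest
    total d_max drop, which is the physically meaningful stabilization
    signature — a long shallow jitter among small base modes should not
    outrank the collapse of the complex mode.  Ties go to the longer
    run, then to the lower concentration.  Deterministic.
    """
    if len(series) < 4:
        raise ParameterError(f"regime detection needs >= 4 entries, got {len(series)}")
    d = series.d_max_values
    concs = series.concentrations
    # enumerate strictly decreasing runs
    best: tuple[int, int] | None = None  # (start_idx, end_idx)
    i = 0
    while i < len(d) - 1:
        if d[i + 1] < d[i]:
            j = i
            while j < len(d) - 1 and d[j + 1] < d[j]:
                j += 1
            if best is None:
                best = (i, j)
            else:
                cur_drop = d[i] - d[j]
                best_drop = d[best[0]] - d[best[1]]
                if cur_drop > best_drop or (
                    cur_drop == best_drop and j - i > best[1] - best[0]
                ):
                    best = (i, j)
            i = j
        else:
            i += 1
    segment = (float(concs[best[0]]), float(concs[best[1]])) if best else None

    counts = [e.n_spirals for e in series.entries]
    spiral_peak = None
    if any(c is not None for c in counts):
        valid = [(c, n) for c, n in zip(concs, counts) if n is not None]
        spiral_peak = float(max(valid, key=lambda t: t[1])[0])

    labels = []
    for k in range(len(d)):
        if best is not None and best[0] < k <= best[1]:
            labels.append("stabilized")
        elif best is not None and k > best[1]:
            labels.append("destabilized")
        elif d[k] <= BASELINE_DMAX:
            labels.append("baseline")
        else:
            labels.append("complex-growth")
    return RegimeReport(
        descending_segment=segment, spiral_peak=spiral_peak, labels=tuple(labels)
    )


# --------------------------------------------------------------------------
# end-to-end synthetic runs
# --------------------------------------------------------------------------

def run_concentration_series(
    concentrations,
    seed: int = 0,
    model: AggregationModel | None = None,
    instrument: InstrumentConfig | None = None,
    inv_config: InversionConfig | None = None,
    noise_sd: float = 0.01,
    lags: np.ndarray | None = None,
    with_spiral_counts: bool = True,
) -> ConcentrationSeries:
    """Simulate, invert and summarize one full concentration series.

    For each magnetite concentration a noisy trace is generated from the
    aggregation mixture model, inverted, and summarized by its d_max.
    Spiral counts come from the planted-count model with Poisson jitter
    (the image-level detector is benchmarked separately).  Child seeds are
    spawned deterministically from ``seed``.
    """
    model = model or AggregationModel()
    instrument = instrument or InstrumentConfig()
    inv_config = inv_config or InversionConfig()
    lags = default_lag_grid() if lags is None else lags
    children = np.random.SeedSequence(seed).spawn(len(list(concentrations)))
    entries = []
    for n_mf, child in zip(concentrations, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        scenario = ScenarioConfig.from_concentration(
            n_mf, model=model, noise_sd=noise_sd, seed=child_seed
        )
        trace = generate_trace(scenario, instrument, lags)
        result = invert(trace, inv_config, instrument)
        summary = extract_modes(result)
        n_spirals = None
        if with_spiral_counts:
            count_rng = np.random.default_rng(child_seed + 1)
            n_spirals = int(count_rng.poisson(spiral_count_model(n_mf)))
        entries.append(
            SeriesEntry(
                n_mf=float(n_mf), d_max=summary.d_max,
                mode_summary=summary, n_spirals=n_spirals,
            )
        )
    return build_series(entries)


def series_report(
    series: ConcentrationSeries,
    regimes: RegimeReport | None = None,
    instrument: InstrumentConfig | None = None,
    seed: int | None = None,
) -> dict:
    """JSON-serializable run report with fixed float precision."""
    regimes = regimes if regimes is not None else detect_regimes(series)
    instrument = instrument or InstrumentConfig()

    def _r(x):
        return None if x is None else float(f"{x:.9g}")

    return {
        "schema": "albumag-series-report/1",
        "seed": seed,
        "instrument": {k: _r(v) for k, v in instrument.to_lab_units().items()},
        "entries": [
            {
                "n_mf_mg_L": _r(e.n_mf),
                "d_max_nm": _r(e.d_max * 1e9),
                "n_spirals": e.n_spirals,
                "modes": (
                    [
                        {
                            "mode_diameter_nm": _r(m.mode_diameter * 1e9),
                            "mass_fraction": _r(m.mass_fraction),
                            "fwhm_nm": _r(m.full_width_half_max * 1e9),
                        }
                        for m in e.mode_summary.modes
                    ]
                    if e.mode_summary
                    else None
                ),
            }
            for e in series.entries
        ],
        "regimes": {
            "descending_segment_mg_L": (
                [_r(regimes.descending_segment[0]), _r(regimes.descending_segment[1])]
                if regimes.descending_segment
                else None
            ),
            "spiral_peak_mg_L": _r(regimes.spiral_peak),
            "labels": list(regimes.labels),
        },
    }


def write_series_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
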