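# albumag

Analysis of albumin-magnetite nanoparticle aggregation: dynamic light
scattering (laser correlation spectroscopy) simulation and inversion,
plus spiral-structure and aggregate analysis of dried protein films.

## The problem

When magnetite (Fe3O4) nanoparticle colloid is titrated into a
50 mg/mL human serum albumin solution, the mixture aggregates
non-monotonically: mixed protein-nanoparticle complexes appear above
~0.1 ug/L magnetite and grow to ~800 nm by 2 ug/L, then *shrink* to
~250 nm by 100 ug/L — albumin transiently stabilizes the dispersion —
before runaway magnetite self-aggregation past 0.1 mg/L pushes sizes
beyond 1000 nm.  The same titration shows up in films dried from these
solutions: the number of self-organized logarithmic-spiral crack
structures at the film edge (a film-stability proxy) rises to ~155 at
1e-4 mg/L and collapses to ~10 at 1 mg/L.

No measured data are deposited for this system, so `albumag` implements
the full analysis over synthetic data with the reported structure: a
concentration-dependent mixture model, noisy correlation traces, and
film micrographs with planted spirals and aggregate blobs — then
recovers that structure blind and checks it quantitatively.

## The core methods

**Sizing by correlation spectroscopy.**  The normalized field
autocorrelation of scattered light is a weighted sum of exponentials,

    g(tau) = sum_i F(q, D_i) exp(-q^2 D_i tau),
    q = (4 pi n0 / lambda0) sin(theta / 2),
    D_i = k_B T / (3 pi eta d_i),

so an intensity-weighted size distribution F determines the trace.
Recovering F from g is an ill-posed inverse Laplace transform;
`albumag.dls_inversion` solves the CONTIN-style program

    min ||A f - g||^2 + lambda ||L f||^2,  f >= 0,

on a 1 nm - 10 um log grid with second-difference smoothing and
L-curve-based selection of lambda, and summarizes the result by its
modes — `d_max`, the diameter of the largest mode, is the titration
statistic.

**Film analysis.**  `albumag.film` segments dark crack pixels, fits
logarithmic spirals `r = a e^{b phi}` around skeleton paths with a
coverage-and-monotone-winding score, and sizes compact dark blobs as
equivalent-circle diameters in um.

## Worked example

```python
import numpy as np
from albumag import (
    InstrumentConfig, InversionConfig, ScenarioConfig,
    default_lag_grid, generate_trace, invert, extract_modes,
)

instrument = InstrumentConfig()          # 633 nm, 90 deg, 300 K, water
scenario = ScenarioConfig.from_concentration(0.01, noise_sd=0.01, seed=3)
trace = generate_trace(scenario, instrument, default_lag_grid())
result = invert(trace, InversionConfig(), instrument)
summary = extract_modes(result)
print(f"d_max = {summary.d_max * 1e9:.0f} nm")
for m in summary.modes:
    print(f"  mode {m.mode_diameter * 1e9:7.1f} nm  power {m.mass_fraction:.2f}")
```

prints

```
d_max = 412 nm
  mode   412.5 nm  power 0.67
  mode    12.6 nm  power 0.33
```

At 0.01 mg/L magnetite the mixed albumin-magnetite complex (planted near
500 nm at this concentration) carries just over half the scattered power
and is recovered as the dominant mode — pulled somewhat low and broadened
by the smoothing regularization at this noise level; the small-diameter
mode collects the albumin monomers, albumin self-aggregates, and free
magnetite particles, which sit within one decade of each other and merge
at 1% noise.

The numbered drivers under `analysis/` run the full study:

```bash
python analysis/01_simulate_traces.py     # traces across 1e-5 - 1 mg/L
python analysis/02_invert_traces.py       # distributions and d_max per trace
python analysis/03_concentration_series.py  # regimes + figure
python analysis/04_film_analysis.py       # film scenes, detection, sizing
python analysis/05_stoichiometry.py       # solution-chemistry table
```

`03_concentration_series.py` ends with, e.g.:

```
descending (stabilization) segment: 1.39e-03 -> 3.73e-02 mg/L
spiral-count peak at 3.73e-02 mg/L
```

i.e. the recovered aggregate size falls across the 2-100 ug/L window
while the film spiral count peaks below the 0.05 mg/L decrease
threshold.

A CLI mirrors the drivers for single steps:
`albumag simulate|invert|film-detect|series|report --help`.

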