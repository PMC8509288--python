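import numpy as np
import pytest

from albumag.dls_model import CorrelationTrace, InstrumentConfig


@pytest.fixture(scope="session")
def instrument() -> InstrumentConfig:
    """633 nm / 90 degree / water-at-300-K geometry used throughout."""
    return InstrumentConfig()


def add_relative_noise(trace: CorrelationTrace, sd: float, seed: int) -> CorrelationTrace:
    """Gaussian noise with per-lag standard deviation ``sd * g(tau)``."""
    rng = np.random.default_rng(seed)
    values = trace.values * (1.0 + sd * rng.standard_normal(trace.values.size))
    return CorrelationTrace(
        lags=trace.lags, values=values, kind=trace.kind,
        coherence_factor=trace.coherence_factor, instrument=trace.instrument,
    )


def match_counts(detected, truth, tol_px: float):
    """True positives: planted spirals with a detection within ``tol_px``."""
    tc = np.array([s.center for s in truth.planted_spirals])
    if not detected:
        return 0, 0, len(tc)
    dc = np.array([s.center for s in detected])
    tp = sum(
        1 for t in tc if np.hypot(dc[:, 0] - t[0], dc[:, 1] - t[1]).min() <= tol_px
    )
    return tp, len(detected), len(tc)
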