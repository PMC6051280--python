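import numpy as np
import pytest

from voicefold import ModelParameters, SimulationConfig, integrate


@pytest.fixture(scope="session")
def std_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def sym_result():
    """Standard symmetric simulation shared across tests (500 ms)."""
    return integrate(ModelParameters(), SimulationConfig())


@pytest.fixture(scope="session")
def asym06_result():
    return integrate(ModelParameters(beta=0.6), SimulationConfig())


def triangle_train(f0, fs, duration, oq=0.6, peak_frac=0.4, amplitude=1.0):
    """Piecewise-linear pulse train with exactly known landmarks.

    Opens for oq*T0 with the peak at peak_frac*T0 from the opening;
    closed phase is exact zeros.
    """
    n = int(round(duration * fs))
    u = np.zeros(n)
    T0 = fs / f0
    pos = 0.0
    while pos + T0 < n - 1:
        o = int(round(pos))
        n_rise = int(round(peak_frac * T0))
        n_open = int(round(oq * T0))
        n_fall = n_open - n_rise
        u[o:o + n_rise + 1] = amplitude * np.arange(n_rise + 1) / n_rise
        u[o + n_rise + 1:o + n_open + 1] = amplitude * (
            1.0 - np.arange(1, n_fall + 1) / n_fall)
        pos += T0
    return u


@pytest.fixture(scope="session")
def vowel_grid():
    """(f0, formants) grid used for inverse-filtering validation."""
    tracts = (((700.0, 80.0), (1200.0, 90.0), (2600.0, 120.0)),   # /a/-like
              ((660.0, 80.0), (1700.0, 90.0), (2400.0, 120.0)),   # /ae/-like
              ((450.0, 80.0), (800.0, 90.0), (2830.0, 120.0)))    # /o/-like
    return [(f0, tr) for f0 in (100.0, 145.0, 200.0) for tr in tracts]


def xcorr_peak(a, b):
    """Peak normalized cross-correlation over all lags."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    c = np.correlate(a, b, mode="full")
    return float(c.max() / np.sqrt((a ** 2).sum() * (b ** 2).sum()))


@pytest.fixture(scope="session")
def iaif_grid_results(vowel_grid):
    """IAIF round trips over the 3 pitches x 3 tracts fixture suite."""
    from voicefold import SyntheticVowelSpec, iaif_extract, synth_vowel
    out = []
    for f0, formants in vowel_grid:
        spec = SyntheticVowelSpec(f0=f0, formants=formants, duration=1.0)
        rec, true_flow, _ = synth_vowel(spec)
        ug, model = iaif_extract(rec)
        out.append((f0, formants, ug, true_flow, model))
    return out
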