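"""Nonlinear-dynamics characterisation of two-mass-model simulations.

Spectra, fundamental-frequency estimation, small-signal eigenfrequency
analysis, bifurcation scans over the asymmetry parameter β, per-period
extrema ratios and phase portraits.  These are the tools used to map the
regimes of asymmetric fold vibration: limit cycles, subharmonic
entrainment (period tripling) and irregular oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .model import (ModelParameters, SimulationConfig, SimulationDiverged,
                    SimulationResult, integrate)
from .parameters import apply_asymmetry

__all__ = [
    "EigenFrequencies", "SpectrumResult", "BifurcationDiagram",
    "natural_frequencies", "estimate_f0", "spectrum", "spectral_peaks",
    "extrema_ratio", "bifurcation_scan", "phase_portrait", "overtone_frequency",
]


@dataclass(frozen=True)
class EigenFrequencies:
    """Small-signal natural frequencies (Hz) of each fold, low first."""

    left: tuple[float, float]
    right: tuple[float, float]


def _side_frequencies(m1, m2, k1, k2, kc) -> tuple[float, float]:
    # undamped 2x2 stiffness-over-mass system; eigenvalues in (1/ms)^2
    A = np.array([[(k1 + kc) / m1, -kc / m1],
                  [-kc / m2, (k2 + kc) / m2]])
    lam = np.sort(np.linalg.eigvals(A).real)
    f_khz = np.sqrt(lam) / (2.0 * np.pi)
    return float(f_khz[0] * 1000.0), float(f_khz[1] * 1000.0)


def natural_frequencies(params: ModelParameters) -> EigenFrequencies:
    """Eigenfrequencies of the uncoupled (no-flow, no-collision) folds.

    The right fold's pair is exactly β times the left's: dividing masses
    by β and multiplying stiffnesses by β scales K/M by β².
    """
    left, right = apply_asymmetry(params)
    return EigenFrequencies(
        left=_side_frequencies(left.m1, left.m2, left.k1, left.k2, left.kc),
        right=_side_frequencies(right.m1, right.m2, right.k1, right.k2, right.kc),
    )


def estimate_f0(x: np.ndarray, fs: float,
                fmin: float = 50.0, fmax: float = 500.0,
                voicing_threshold: float = 0.3) -> float | None:
    """Fundamental frequency by autocorrelation with parabolic refinement.

    Returns None ("no pitch") when no normalised autocorrelation peak in
    the 50–500 Hz search band reaches ``voicing_threshold``.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    lag_lo = int(np.floor(fs / fmax))
    lag_hi = int(np.ceil(fs / fmin))
    if lag_lo < 1 or n < 2 * lag_hi:
        return None
    r = sps.correlate(x, x, mode="full")[n - 1:]
    if r[0] <= 0:
        return None
    band = r[lag_lo:lag_hi + 1]
    k = int(np.argmax(band)) + lag_lo
    if r[k] < voicing_threshold * r[0]:
        return None
    # parabolic interpolation around the peak lag
    if 1 <= k < r.size - 1:
        denom = r[k - 1] - 2.0 * r[k] + r[k + 1]
        delta = 0.5 * (r[k - 1] - r[k + 1]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(fs / (k + delta))


@dataclass
class SpectrumResult:
    """Per-signal magnitude spectra, each normalised to its own maximum."""

    freq: np.ndarray                     # Hz
    magnitude: dict[str, np.ndarray]     # signal name -> |X(f)| / max
    natural: EigenFrequencies | None = None

    def peak_frequency(self, name: str, band: tuple[float, float]) -> float | None:
        """Frequency of the largest spectral peak inside an open band."""
        pk = spectral_peaks(self.freq, self.magnitude[name], band)
        return None if pk.size == 0 else float(pk[0])


def _magnitude(x: np.ndarray, nfft: int) -> np.ndarray:
    x = np.asarray(x, float)
    x = (x - x.mean()) * np.hanning(x.size)
    return np.abs(np.fft.rfft(x, nfft))


def spectrum(result: SimulationResult,
             signals: tuple[str, ...] = ("x1l", "x1r", "Ug"),
             min_nfft: int = 1 << 20) -> SpectrumResult:
    """Hann-windowed magnitude spectra of the post-transient trajectory.

    Zero-padding to ≥ 2²⁰ samples gives a grid finer than 0.03 Hz at
    25 kHz — enough to separate nearby overtones from the fold
    eigenfrequencies they sit between.
    """
    n = int(np.count_nonzero(result.transient_mask))
    nfft = max(min_nfft, int(2 ** np.ceil(np.log2(max(n, 2)))))
    freq = np.fft.rfftfreq(nfft, d=1.0 / result.fs)
    mags = {}
    for name in signals:
        m = _magnitude(result.signal(name), nfft)
        peak = m.max()
        mags[name] = m / peak if peak > 0 else m
    return SpectrumResult(freq=freq, magnitude=mags,
                          natural=natural_frequencies(result.params))


def spectral_peaks(freq: np.ndarray, mag: np.ndarray,
                   band: tuple[float, float],
                   min_rel_height: float = 1e-3) -> np.ndarray:
    """Frequencies of spectral peaks strictly inside ``band``, by height.

    Peaks are local maxima with prominence; anything below
    ``min_rel_height`` of the global spectrum maximum is noise-floor and
    discarded.  Returned sorted from strongest to weakest.
    """
    sel = (freq > band[0]) & (freq < band[1])
    idx = np.flatnonzero(sel)
    if idx.size < 3:
        return np.array([])
    seg = mag[idx]
    pk, props = sps.find_peaks(seg, height=min_rel_height * mag.max(),
                               prominence=0.5 * min_rel_height * mag.max())
    if pk.size == 0:
        return np.array([])
    order = np.argsort(props["peak_heights"])[::-1]
    return freq[idx[pk[order]]]


def overtone_frequency(result: SimulationResult, signal: str = "Ug",
                       band: tuple[float, float] = (40.0, 500.0),
                       guard_hz: float = 10.0,
                       min_rel_height: float = 5e-3) -> float | None:
    """Most prominent secondary (non-fundamental) spectral component.

    Asymmetric entrainment shows up as overtone lines beside the
    fundamental; this locates the strongest one.  Peaks within
    ``guard_hz`` of a stronger line are window-leakage sidelobes and are
    skipped, as is anything below ``min_rel_height`` of the spectrum
    maximum.  Returns None when only the fundamental line exists.
    """
    sp = spectrum(result, signals=(signal,))
    mag = sp.magnitude[signal]
    # the fundamental is the strongest line anywhere in the voice band
    wide = spectral_peaks(sp.freq, mag, (40.0, 500.0),
                          min_rel_height=min_rel_height)
    if wide.size == 0:
        return None
    fundamental = float(wide[0])
    cand = spectral_peaks(sp.freq, mag, band, min_rel_height=min_rel_height)
    accepted: list[float] = [fundamental]
    for f in cand:                      # strongest first
        if any(abs(f - g) < guard_hz for g in accepted):
            continue
        accepted.append(float(f))
        return float(f)
    return None


# ----------------------------------------------------------------------------
# extrema counting / bifurcation


def _smooth3(x: np.ndarray) -> np.ndarray:
    # light 3-sample moving average to suppress integration ripple;
    # 'valid' mode avoids zero-padded edges faking boundary maxima
    return np.convolve(x, np.ones(3) / 3.0, mode="valid")


def _local_max_indices(x: np.ndarray) -> np.ndarray:
    d = np.diff(x)
    return np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1


def repeat_period(x1l: np.ndarray, x1r: np.ndarray, fs: float,
                  threshold: float = 0.95,
                  fmin: float = 10.0, fmax: float = 500.0) -> int | None:
    """Repeating period (in samples) of the combined two-fold trajectory.

    The joint autocorrelation of (x1l, x1r) must recover ``threshold`` of
    its lag-0 value; the smallest such lag that is also a local maximum is
    the repeat period.  Returns None for aperiodic trajectories.
    """
    n = min(x1l.size, x1r.size)
    a = x1l[:n] - x1l[:n].mean()
    b = x1r[:n] - x1r[:n].mean()
    r = (sps.correlate(a, a, mode="full")[n - 1:]
         + sps.correlate(b, b, mode="full")[n - 1:])
    # unbiased-ish normalisation so long lags are not penalised
    counts = np.arange(n, 0, -1.0)
    rn = r / counts
    lag_lo = max(2, int(fs / fmax))
    lag_hi = min(n // 2, int(np.ceil(fs / fmin)))
    if lag_hi <= lag_lo:
        return None
    peaks = _local_max_indices(rn[:lag_hi + 1])
    peaks = peaks[(peaks >= lag_lo) & (rn[peaks] >= threshold * rn[0])]
    return int(peaks[0]) if peaks.size else None


def extrema_ratio(result: SimulationResult) -> tuple[int, int] | None:
    """Reduced count ratio of left:right lower-mass maxima per repeat period.

    1:1 for symmetric or weakly asymmetric vibration; n:m (e.g. 1:3) under
    subharmonic entrainment.  Returns None when no repeat period is found
    (aperiodic regime).
    """
    x1l = _smooth3(result.signal("x1l"))
    x1r = _smooth3(result.signal("x1r"))
    period = repeat_period(x1l, x1r, result.fs)
    if period is None:
        return None
    # average counts over the available whole repeats for robustness
    nrep = min((x1l.size - 2) // period, 8)
    if nrep < 1:
        return None
    ml = _local_max_indices(x1l)
    mr = _local_max_indices(x1r)
    lo, hi = 1, 1 + nrep * period
    cl = int(np.count_nonzero((ml >= lo) & (ml < hi)))
    cr = int(np.count_nonzero((mr >= lo) & (mr < hi)))
    cl = max(int(round(cl / nrep)), 0)
    cr = max(int(round(cr / nrep)), 0)
    if cl == 0 or cr == 0:
        return (cl, cr)
    g = np.gcd(cl, cr)
    return (cl // g, cr // g)


@dataclass
class BifurcationDiagram:
    """Distinct post-transient local maxima of an observable per β value."""

    beta: np.ndarray
    maxima: list[np.ndarray | None]   # None marks a divergent run (gap)
    observable: str

    def branch_count(self, i: int) -> int | None:
        m = self.maxima[i]
        return None if m is None else int(m.size)


def _cluster(values: np.ndarray, tol: float) -> np.ndarray:
    if values.size == 0:
        return values
    v = np.sort(values)
    reps = [v[0]]
    for x in v[1:]:
        if x - reps[-1] > tol:
            reps.append(x)
    return np.asarray(reps)


def bifurcation_scan(params: ModelParameters, beta_grid: np.ndarray,
                     observable: str = "x1l",
                     config: SimulationConfig | None = None,
                     cluster_tol: float = 1e-4) -> BifurcationDiagram:
    """Distinct steady-state maxima of ``observable`` across a β grid.

    A limit cycle yields a single cluster, a period-doubled orbit two,
    and so on.  Divergent simulations appear as gaps rather than errors.
    """
    maxima: list[np.ndarray | None] = []
    for b in np.asarray(beta_grid, float):
        try:
            res = integrate(params.replace(beta=float(b)), config)
        except SimulationDiverged:
            maxima.append(None)
            continue
        x = _smooth3(res.signal(observable))
        vals = x[_local_max_indices(x)]
        maxima.append(_cluster(vals, cluster_tol))
    return BifurcationDiagram(beta=np.asarray(beta_grid, float),
                              maxima=maxima, observable=observable)


def phase_portrait(result: SimulationResult) -> np.ndarray:
    """Post-transient planar trajectory in the (x1l, x1r) plane, shape (n, 2)."""
    return np.column_stack([result.signal("x1l"), result.signal("x1r")])
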