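"""Glottal-flow parameterisation and the waveform-matching objectives.

A glottal cycle is split at the opening instant; within one cycle the flow
rises to its peak and falls back to (near) zero at closing.  The classic
time-domain quotients — open quotient OQ, speed quotient SQ, closing
quotient ClQ and the normalised amplitude quotient NAQ — summarise the
pulse shape independently of its amplitude; cycle-to-cycle perturbation
(jitter-style J measures) summarises its stability.  The fitting
objectives combine relative errors of these statistics between a target
flow and a simulated one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlottalCycle", "GlottalQuotients", "PerturbationMeasures",
    "ObjectiveWeights", "InsufficientCycles",
    "detect_cycles", "compute_quotients", "cycle_series", "perturbation",
    "objective_fy", "objective_fyp",
]


class InsufficientCycles(ValueError):
    """Fewer complete glottal cycles than an operation requires."""


@dataclass(frozen=True)
class GlottalCycle:
    """Landmark positions and amplitudes of one glottal cycle.

    Opening/closing positions carry subsample precision (interpolated
    threshold crossings); the peak is an exact sample index.
    """

    opening: float      # start of the open phase (fractional sample)
    peak: int           # sample of maximum flow
    closing: float      # end of the open phase (fractional sample)
    next_opening: float  # opening of the following cycle
    amplitude: float    # peak flow above the cycle baseline
    dmin: float         # maximum negative flow derivative (flow units / s)
    peak_time: float = None  # parabolically refined peak position

    def __post_init__(self):
        if self.peak_time is None:
            object.__setattr__(self, "peak_time", float(self.peak))

    @property
    def period(self) -> float:
        return self.next_opening - self.opening


@dataclass(frozen=True)
class GlottalQuotients:
    """Cycle-averaged glottal statistics.

    F0 in Hz; OQ, ClQ, NAQ dimensionless in (0, 1]; SQ dimensionless > 0.
    """

    F0: float
    OQ: float
    SQ: float
    ClQ: float
    NAQ: float

    def as_dict(self) -> dict[str, float]:
        return {"F0": self.F0, "OQ": self.OQ, "SQ": self.SQ,
                "ClQ": self.ClQ, "NAQ": self.NAQ}


@dataclass(frozen=True)
class PerturbationMeasures:
    """Jitter-style cycle-to-cycle perturbations of each statistic (≥ 0)."""

    JF0: float
    JOQ: float
    JSQ: float
    JClQ: float
    JNAQ: float

    def as_dict(self) -> dict[str, float]:
        return {"JF0": self.JF0, "JOQ": self.JOQ, "JSQ": self.JSQ,
                "JClQ": self.JClQ, "JNAQ": self.JNAQ}


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights of the matching objectives.

    The defaults give the four equally-weighted time quotients (4 × 0.125)
    the same total influence as the single frequency term (0.5).
    """

    w1: float = 0.125
    w2: float = 0.5
    w3: float = 0.5
    w4: float = 0.5


# ----------------------------------------------------------------------------
# cycle detection


def _open_threshold(u: np.ndarray, rel: float) -> tuple[float, bool]:
    """Opening threshold above the baseline.

    Flows with a resolved closed phase (a run of samples pinned at the
    minimum, as the model produces: Ug = 0 while the glottis is closed)
    get a threshold just above that floor, so detected instants match the
    true opening to within one sample.  Measured flows, which lack exact
    zeros, use the conventional ``rel`` (5 %) of peak-to-peak.
    """
    # percentile bounds keep a stray filter/onset transient from dragging
    # the threshold off the pulse baseline
    lo, hi = (float(v) for v in np.percentile(u, [1.0, 99.0]))
    p2p = hi - lo
    if p2p <= 0:
        raise InsufficientCycles("constant signal")
    closed_frac = np.mean(np.abs(u - lo) <= 1e-9 * p2p)
    if closed_frac > 0.1:
        return lo + 1e-9 * p2p, True
    return lo + rel * p2p, False


def detect_cycles(u: np.ndarray, fs: float,
                  threshold_rel: float = 0.05,
                  min_cycles: int = 3) -> list[GlottalCycle]:
    """Segment a glottal flow into cycles via threshold crossings.

    Opening/closing instants are crossings of a threshold at
    ``threshold_rel`` (5 %) of the peak-to-peak amplitude.  Flows with an
    exactly-zero closed phase (model output) are handled by the same rule:
    the baseline is then the zero floor, so crossings are unambiguous.
    Raises :class:`InsufficientCycles` for fewer than ``min_cycles``
    complete cycles.
    """
    from scipy.signal import find_peaks

    u = np.asarray(u, dtype=float)
    if u.size < 8:
        raise InsufficientCycles("signal too short")
    thr, zero_floor = _open_threshold(u, threshold_rel)
    lo, hi = (float(v) for v in np.percentile(u, [1.0, 99.0]))
    p2p = hi - lo

    # anchor cycles on the major flow peaks, then place the opening at the
    # last up-crossing of the threshold before each peak and the closing at
    # the first down-crossing after it — residual formant ripple in the
    # closed phase of inverse-filtered flows then never fakes a landmark
    peaks, _ = find_peaks(u, height=lo + 0.5 * p2p, prominence=0.25 * p2p)
    if peaks.size >= 3:
        med = float(np.median(np.diff(peaks)))
        kept = [int(peaks[0])]
        for p in peaks[1:]:
            if p - kept[-1] >= 0.4 * med:
                kept.append(int(p))
            elif u[p] > u[kept[-1]]:
                kept[-1] = int(p)
        peaks = np.asarray(kept)
    above = u > thr
    edges = np.diff(above.astype(np.int8))
    up = np.flatnonzero(edges == 1) + 1
    down = np.flatnonzero(edges == -1) + 1

    def last_before(arr, i):
        j = np.searchsorted(arr, i) - 1
        return int(arr[j]) if j >= 0 else None

    def first_after(arr, i):
        j = np.searchsorted(arr, i, side="right")
        return int(arr[j]) if j < arr.size else None

    def refine_up(i):
        # subsample opening.  On an exactly-zero closed phase the first
        # open sample already sits above the floor, so extrapolate the
        # initial rise slope back to the true zero crossing; otherwise
        # interpolate the threshold crossing linearly.
        if zero_floor:
            if i + 1 < u.size and u[i + 1] > u[i] > 0:
                return float(np.clip(i - u[i] / (u[i + 1] - u[i]),
                                     i - 1.0, float(i)))
            return float(i)
        if i >= 1 and u[i] > u[i - 1]:
            return i - 1 + (thr - u[i - 1]) / (u[i] - u[i - 1])
        return float(i)

    def refine_down(i):
        # i is the first sample back at/below the threshold
        if zero_floor:
            if i >= 2 and u[i - 2] > u[i - 1] > 0:
                return float(np.clip(i - 1 + u[i - 1] / (u[i - 2] - u[i - 1]),
                                     float(i - 1), float(i)))
            return float(i)
        if i >= 1 and u[i - 1] > u[i]:
            return i - 1 + (u[i - 1] - thr) / (u[i - 1] - u[i])
        return float(i)

    cycles: list[GlottalCycle] = []
    for i in range(peaks.size - 1):
        pk, pk_next = int(peaks[i]), int(peaks[i + 1])
        o = last_before(up, pk)
        c = first_after(down, pk)
        o_next = last_before(up, pk_next)
        if o is None or c is None or o_next is None:
            continue
        if not (o < pk < c <= o_next and o_next > o):
            continue
        seg = u[o:o_next]
        p = o + int(np.argmax(seg))          # true maximum within the cycle
        if not (o < p < c):
            p = pk
        d = np.diff(u[o:o_next + 1]) * fs
        dmin = float(np.min(d))
        if dmin >= 0:
            continue
        # parabolic refinement of the peak suppresses sampling-grid jitter
        # in SQ/ClQ/NAQ of near-periodic flows
        pt, amp = float(p), float(u[p])
        if 1 <= p < u.size - 1:
            denom = u[p - 1] - 2.0 * u[p] + u[p + 1]
            if denom < 0:
                delta = 0.5 * (u[p - 1] - u[p + 1]) / denom
                pt = p + float(np.clip(delta, -0.5, 0.5))
                amp = float(u[p] - 0.25 * (u[p - 1] - u[p + 1]) * (pt - p))
        baseline = float(np.min(seg))
        cycles.append(GlottalCycle(opening=refine_up(o), peak=p,
                                   closing=refine_down(c),
                                   next_opening=refine_up(o_next),
                                   amplitude=amp - baseline,
                                   dmin=dmin, peak_time=pt))
    if len(cycles) < min_cycles:
        raise InsufficientCycles(
            f"found {len(cycles)} cycles, need >= {min_cycles}")
    return cycles


def cycle_series(cycles: list[GlottalCycle], fs: float) -> dict[str, np.ndarray]:
    """Per-cycle statistic series (inputs to perturbation analysis)."""
    out = {k: [] for k in ("F0", "OQ", "SQ", "ClQ", "NAQ")}
    for c in cycles:
        T0 = c.period / fs
        open_t = (c.closing - c.opening) / fs
        rise = (c.peak_time - c.opening) / fs
        fall = (c.closing - c.peak_time) / fs
        if fall <= 0 or rise <= 0:
            warnings.warn("degenerate cycle skipped (zero rise or fall time)")
            continue
        out["F0"].append(1.0 / T0)
        out["OQ"].append(open_t / T0)
        out["SQ"].append(rise / fall)
        out["ClQ"].append(fall / T0)
        out["NAQ"].append((c.amplitude / abs(c.dmin)) / T0)
    return {k: np.asarray(v) for k, v in out.items()}


def compute_quotients(cycles: list[GlottalCycle], fs: float) -> GlottalQuotients:
    """Cycle-averaged quotients; F0 is the reciprocal of the mean period."""
    if not cycles:
        raise InsufficientCycles("no cycles")
    s = cycle_series(cycles, fs)
    if s["OQ"].size == 0:
        raise InsufficientCycles("all cycles degenerate")
    mean_T0 = float(np.mean([c.period for c in cycles])) / fs
    return GlottalQuotients(F0=1.0 / mean_T0,
                            OQ=float(s["OQ"].mean()),
                            SQ=float(s["SQ"].mean()),
                            ClQ=float(s["ClQ"].mean()),
                            NAQ=float(s["NAQ"].mean()))


# ----------------------------------------------------------------------------
# perturbation


def _jitter(x: np.ndarray) -> float:
    # mean absolute successive difference relative to the mean level
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientCycles("need >= 3 cycles for perturbation")
    m = float(np.mean(x))
    if m == 0:
        raise ValueError("mean of the series is zero; perturbation undefined")
    return float(np.mean(np.abs(np.diff(x))) / abs(m))


def perturbation(series: dict[str, np.ndarray]) -> PerturbationMeasures:
    """Jitter-style relative perturbation of each per-cycle statistic.

    J_X = mean_k |X(k+1) − X(k)| / mean_k X(k): zero for any
    constant-per-cycle sequence, and 2|a−b|/(a+b) for an alternating one.
    """
    return PerturbationMeasures(JF0=_jitter(series["F0"]),
                                JOQ=_jitter(series["OQ"]),
                                JSQ=_jitter(series["SQ"]),
                                JClQ=_jitter(series["ClQ"]),
                                JNAQ=_jitter(series["NAQ"]))


# ----------------------------------------------------------------------------
# objectives


def _relerr(target: float, sim: float, name: str) -> float:
    if target <= 0:
        raise ValueError(f"target {name} must be positive")
    return abs(target - sim) / target


def objective_fy(target: GlottalQuotients, sim: GlottalQuotients,
                 w: ObjectiveWeights | None = None) -> float:
    """Normal-voice matching objective.

    FY = w1 Σ_time |X − X′|/X + w2 |F0 − F0′|/F0 over the four time
    quotients, with the unprimed (target) statistic in each denominator.
    Zero iff all five statistics match; invariant to flow amplitude.
    """
    w = w or ObjectiveWeights()
    t_sum = sum(_relerr(getattr(target, q), getattr(sim, q), q)
                for q in ("OQ", "SQ", "ClQ", "NAQ"))
    return w.w1 * t_sum + w.w2 * _relerr(target.F0, sim.F0, "F0")


def objective_fyp(target: GlottalQuotients, sim: GlottalQuotients,
                  target_pert: PerturbationMeasures,
                  sim_pert: PerturbationMeasures,
                  w: ObjectiveWeights | None = None) -> float:
    """Pathological-voice objective: FYp = w3 FY + w4 Σ |J − J′|/J.

    Perturbation terms whose target J is exactly zero (a perfectly
    periodic target) are dropped with a warning, since their relative
    error is undefined.
    """
    w = w or ObjectiveWeights()
    j_sum = 0.0
    for name in ("JOQ", "JSQ", "JClQ", "JNAQ", "JF0"):
        jt = getattr(target_pert, name)
        js = getattr(sim_pert, name)
        if jt == 0:
            warnings.warn(f"target {name} is zero; term dropped from FYp")
            continue
        j_sum += abs(jt - js) / jt
    return w.w3 * objective_fy(target, sim, w) + w.w4 * j_sum
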