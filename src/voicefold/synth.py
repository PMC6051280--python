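"""Synthetic fixtures: model-based targets, pulse trains and vowels.

Three generators cover the test surface of the whole pipeline with no
external data:

* :func:`model_target` — a forward-simulated glottal flow with known
  generating parameters, for parameter-recovery experiments;
* :func:`lf_pulse_train` — a raised-cosine (Rosenberg-style) pulse train
  whose time quotients (OQ, SQ, ClQ, NAQ) are known in closed form, for
  validating the feature extractors and inverse filtering;
* :func:`synth_vowel` — pulse train → all-pole vocal tract → radiation,
  the forward speech chain that inverse filtering runs in reverse, with
  the true flow retained as ground truth.

All randomness is seeded; a fixture regenerates bit-identically from its
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .features import InsufficientCycles, compute_quotients, detect_cycles
from .model import ModelParameters, SimulationConfig, integrate
from .waveform import GlottalWaveform, VoiceRecording

__all__ = [
    "SyntheticVowelSpec", "model_target", "lf_pulse_train", "synth_vowel",
    "formant_filter_coeffs", "FixtureSet", "make_fixture_set", "RADIATION_LEAK",
]

#: Real zero of the radiation model (1 − λ z⁻¹); its inverse is the leaky
#: integrator used for radiation compensation.
RADIATION_LEAK = 0.99

#: /a/-like default formants (Hz) and bandwidths (Hz).
DEFAULT_FORMANTS = ((700.0, 80.0), (1200.0, 90.0), (2600.0, 120.0))


@dataclass
class SyntheticVowelSpec:
    """Recipe for one synthetic sustained vowel."""

    f0: float = 145.0                       # Hz
    oq: float = 0.6                         # open fraction of the period
    sq: float = 2.0                         # opening/closing time ratio
    amplitude: float = 1.0
    formants: tuple = DEFAULT_FORMANTS      # ((freq, bandwidth), ...) in Hz
    radiation: bool = True
    noise_level: float = 0.0                # rms noise / rms signal
    jitter: float = 0.0                     # relative period perturbation
    duration: float = 1.0                   # s
    fs: float = 25000.0                     # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f >= self.fs / 2 for f, _ in self.formants):
            raise ValueError("formant frequencies must be below Nyquist")
        if self.noise_level < 0 or self.jitter < 0:
            raise ValueError("noise level and jitter must be >= 0")


def model_target(params: ModelParameters,
                 config: SimulationConfig | None = None,
                 ) -> tuple[GlottalWaveform, dict]:
    """Simulated glottal flow with its generating ground truth attached.

    Rejects parameter sets whose simulation does not produce at least
    three glottal cycles (non-oscillating folds).
    """
    config = config or SimulationConfig()
    res = integrate(params, config)
    u = res.signal("Ug")
    try:
        cycles = detect_cycles(u, res.fs)
    except InsufficientCycles as exc:
        raise ValueError("parameters do not produce sustained "
                         f"oscillation: {exc}") from exc
    q = compute_quotients(cycles, res.fs)
    truth = {"params": params, "beta": params.beta, "quotients": q}
    return GlottalWaveform(u, res.fs, source="simulated"), truth


def lf_pulse_train(f0: float, fs: float, duration: float,
                   oq: float = 0.6, sq: float = 2.0, amplitude: float = 1.0,
                   jitter: float = 0.0, seed: int = 0,
                   ) -> tuple[GlottalWaveform, dict]:
    """Rosenberg-style raised-cosine pulse train with closed-form quotients.

    Each period of length T0 opens for oq·T0: the flow rises as
    ½A(1 − cos(πt/Tr)) over Tr = oq·T0·sq/(1+sq), then falls as
    A·cos(½π t/Tf) over Tf = oq·T0/(1+sq); the remainder of the period is
    closed (exact zeros).  Closed forms: ClQ = OQ/(1+SQ) and, because the
    steepest slope of the falling quarter-cosine is A·π/(2 Tf),
    NAQ = (2/π)·ClQ.  This smooth pulse is the standard synthetic glottal
    source for validating inverse filtering (a triangle's spectral nulls
    defeat LP-based tract estimation).  Optional jitter perturbs each
    period by a uniform relative amount with a seeded generator; the
    realised per-cycle period sequence is returned in the ground truth.
    """
    if not (0 < oq <= 1) or sq <= 0 or f0 <= 0:
        raise ValueError("need 0 < oq <= 1, sq > 0, f0 > 0")
    clq = oq / (1.0 + sq)
    if clq > oq:
        raise ValueError("infeasible quotient combination (ClQ > OQ)")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration * fs))
    u = np.zeros(n_total)
    T0 = fs / f0
    periods = []
    pos = 0.0
    while pos + T0 * (1 + jitter) < n_total - 1:
        Tk = T0 * (1.0 + (jitter * rng.uniform(-1.0, 1.0) if jitter else 0.0))
        n_open = int(round(oq * Tk))
        n_rise = int(round(oq * Tk * sq / (1.0 + sq)))
        n_fall = n_open - n_rise
        o = int(round(pos))
        if n_rise >= 1 and n_fall >= 1:
            tr = np.arange(n_rise + 1)
            idx_r = o + tr
            keep = idx_r < n_total
            u[idx_r[keep]] = 0.5 * amplitude * (1.0 - np.cos(np.pi * tr[keep]
                                                             / n_rise))
            tf = np.arange(1, n_fall + 1)
            idx_f = o + n_rise + tf
            keep = idx_f < n_total
            u[idx_f[keep]] = amplitude * np.cos(0.5 * np.pi * tf[keep] / n_fall)
        periods.append(Tk)
        pos += Tk
    truth = {"F0": f0, "OQ": oq, "SQ": sq, "ClQ": clq,
             "NAQ": clq * 2.0 / np.pi,
             "amplitude": amplitude, "periods": np.asarray(periods),
             "seed": seed, "jitter": jitter}
    return GlottalWaveform(u, fs, source="simulated"), truth


def formant_filter_coeffs(formants, fs: float) -> np.ndarray:
    """All-pole vocal-tract denominator from (frequency, bandwidth) pairs."""
    poles = []
    for f, bw in formants:
        r = np.exp(-np.pi * bw / fs)
        th = 2.0 * np.pi * f / fs
        poles += [r * np.exp(1j * th), r * np.exp(-1j * th)]
    a = np.poly(poles).real
    return a


def synth_vowel(spec: SyntheticVowelSpec,
                ) -> tuple[VoiceRecording, GlottalWaveform, dict]:
    """Synthesize a sustained vowel and keep its true glottal flow.

    The chain is pulse train → all-pole tract 1/A(z) → radiation
    (1 − λ z⁻¹), the model that inverse filtering inverts.  Returns
    (recording, true flow, ground truth).
    """
    flow, truth = lf_pulse_train(spec.f0, spec.fs, spec.duration,
                                 oq=spec.oq, sq=spec.sq,
                                 amplitude=spec.amplitude,
                                 jitter=spec.jitter, seed=spec.seed)
    a = formant_filter_coeffs(spec.formants, spec.fs) if spec.formants else np.array([1.0])
    if np.any(np.abs(np.roots(a)) >= 1.0):
        raise ValueError("unstable vocal-tract filter")
    s = sps.lfilter([1.0], a, flow.samples)
    if spec.radiation:
        s = sps.lfilter([1.0, -RADIATION_LEAK], [1.0], s)
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed + 1)
        s = s + spec.noise_level * np.std(s) * rng.standard_normal(s.size)
    peak = np.max(np.abs(s))
    if peak > 0:
        s = s / peak * 0.9
    truth = dict(truth, formants=tuple(spec.formants), tract_a=a,
                 radiation=spec.radiation, noise_level=spec.noise_level)
    return VoiceRecording(s, spec.fs), flow, truth


@dataclass
class FixtureSet:
    """A reproducible batch of (waveform, ground truth) pairs."""

    items: list
    manifest: dict


def make_fixture_set(seed: int = 0, n_normal: int = 4, n_pathological: int = 4,
                     config: SimulationConfig | None = None) -> FixtureSet:
    """Model-generated targets mimicking a small normal/pathological corpus.

    Normal-like voices are near-symmetric (β close to 1); pathological-like
    voices are strongly asymmetric with raised coupling stiffness, the
    regime associated with unilateral paralysis.  Every target's generating
    parameters are recorded in the manifest.
    """
    rng = np.random.default_rng(seed)
    config = config or SimulationConfig(duration=400.0)
    items, manifest = [], {"seed": seed, "entries": []}
    specs = []
    for i in range(n_normal):
        specs.append(("normal", ModelParameters(
            beta=float(rng.uniform(0.9, 1.0)),
            Ps=float(rng.uniform(0.006, 0.01)))))
    for i in range(n_pathological):
        specs.append(("pathological", ModelParameters(
            beta=float(rng.uniform(0.45, 0.6)),
            kc=float(rng.uniform(0.03, 0.06)),
            Ps=float(rng.uniform(0.006, 0.012)))))
    for label, params in specs:
        flow, truth = model_target(params, config)
        truth["label"] = label
        items.append((flow, truth))
        manifest["entries"].append({"label": label, **params.to_dict()})
    return FixtureSet(items=items, manifest=manifest)
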