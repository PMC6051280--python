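"""Biomechanical voice-source inversion: the Model/Results interface.

:class:`VoiceSourceModel` wraps a target glottal flow (simulated, loaded
from CSV, or extracted from a recording by inverse filtering) together
with the matching objective; its :meth:`~VoiceSourceModel.fit` runs the
GPSO global search followed by quasi-Newton refinement and returns a
:class:`VoiceSourceFitResults` carrying the estimated parameter vector
Φ ⊕ β, diagnostics and a ``summary()`` table.

The fit vector holds the left (healthy) fold's constants plus the
subglottal pressure; the right fold is derived through β, mirroring the
clinical picture of a unilateral lesion.  An ``independent_sides`` flag
widens the search to fully independent folds for exploration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .features import (GlottalQuotients, InsufficientCycles, ObjectiveWeights,
                       PerturbationMeasures, compute_quotients, cycle_series,
                       detect_cycles, objective_fy, objective_fyp, perturbation)
from .model import (ModelParameters, SimulationConfig, SimulationDiverged,
                    SimulationResult, integrate, integrate_sides)
from .optimize import OptimizerConfig, SearchBounds, gpso, qn_refine
from .parameters import SideParameters
from .waveform import GlottalWaveform, VoiceRecording

__all__ = ["VoiceSourceModel", "VoiceSourceFitResults", "default_bounds"]

_PHI_NAMES = ("m1", "m2", "k1", "k2", "kc", "r1", "r2", "Ps")
_SIDE_NAMES = ("m1", "m2", "k1", "k2", "kc", "r1", "r2")
# β may not reach its lower search bound exactly (open interval); nudge by eps
_BETA_EPS = 1e-9


def default_bounds(independent_sides: bool = False) -> SearchBounds:
    """Search intervals: masses/stiffnesses/damping in [0.001, 0.5] g or
    g/ms² or g/ms, Ps in [0.001, 0.05] (0.1–5 kPa), β in [0.4, 1]."""
    if independent_sides:
        names = tuple(f"{n}_l" for n in _SIDE_NAMES) + \
                tuple(f"{n}_r" for n in _SIDE_NAMES) + ("Ps", "beta")
        lo = [0.001] * 14 + [0.001, 0.4]
        hi = [0.5] * 14 + [0.05, 1.0]
    else:
        names = _PHI_NAMES + ("beta",)
        lo = [0.001] * 7 + [0.001, 0.4]
        hi = [0.5] * 7 + [0.05, 1.0]
    return SearchBounds(names=names, lower=np.array(lo), upper=np.array(hi))


class VoiceSourceModel:
    """Inverse model for one target glottal waveform.

    Parameters
    ----------
    target : GlottalWaveform or array
        The flow to reproduce.  Arrays need ``fs``.
    mode : {"normal", "pathological"}
        Objective selection: the plain quotient objective, or the
        quotient-plus-perturbation objective used for unstable voices.
    weights : ObjectiveWeights, optional
    sim_config : SimulationConfig, optional
        Forward-simulation settings used for every candidate evaluation.
        The default simulates 350 ms and discards a 100 ms transient.
    """

    def __init__(self, target: GlottalWaveform | np.ndarray,
                 fs: float | None = None, mode: str = "normal",
                 weights: ObjectiveWeights | None = None,
                 sim_config: SimulationConfig | None = None,
                 bounds: SearchBounds | None = None,
                 independent_sides: bool = False):
        if isinstance(target, GlottalWaveform):
            self.target = target
        else:
            if fs is None:
                raise ValueError("fs required for a bare array target")
            self.target = GlottalWaveform(np.asarray(target, float), fs)
        if mode not in ("normal", "pathological"):
            raise ValueError("mode must be 'normal' or 'pathological'")
        self.mode = mode
        self.weights = weights or ObjectiveWeights()
        self.sim_config = sim_config or SimulationConfig(
            duration=350.0, transient=100.0)
        self.independent_sides = independent_sides
        self.bounds = bounds or default_bounds(independent_sides)

        cycles = detect_cycles(self.target.samples, self.target.fs)
        self.target_quotients: GlottalQuotients = compute_quotients(
            cycles, self.target.fs)
        self.target_perturbation: PerturbationMeasures | None = None
        if mode == "pathological":
            self.target_perturbation = perturbation(
                cycle_series(cycles, self.target.fs))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_recording(cls, recording: VoiceRecording, **kwargs):
        """Extract the glottal flow by inverse filtering, then build."""
        from .inverse_filter import iaif_extract
        iaif_keys = {k: kwargs.pop(k) for k in ("iterations", "tract_order",
                                                "glottal_order")
                     if k in kwargs}
        ug, _ = iaif_extract(recording, **iaif_keys)
        return cls(ug, **kwargs)

    @classmethod
    def from_wav(cls, path, **kwargs):
        from .io import read_wav
        return cls.from_recording(read_wav(path), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs):
        from .io import read_flow_csv
        return cls(read_flow_csv(path), **kwargs)

    # -- candidate evaluation ----------------------------------------------

    def candidate_params(self, x: np.ndarray):
        """Decode a search vector into simulation inputs."""
        x = np.asarray(x, float)
        if self.independent_sides:
            lv = dict(zip(_SIDE_NAMES, x[:7]))
            rv = dict(zip(_SIDE_NAMES, x[7:14]))
            Ps, beta = x[14], max(x[15], 0.4 + _BETA_EPS)
            left = SideParameters(**lv, c1=3 * lv["k1"], c2=3 * lv["k2"])
            right = SideParameters(**rv, c1=3 * rv["k1"], c2=3 * rv["k2"])
            common = ModelParameters(Ps=Ps, beta=beta)
            return left, right, common
        vals = dict(zip(_PHI_NAMES, x[:8]))
        beta = max(x[8], 0.4 + _BETA_EPS)
        return ModelParameters(beta=beta, **vals)

    def simulate_candidate(self, x: np.ndarray) -> SimulationResult:
        decoded = self.candidate_params(x)
        if self.independent_sides:
            left, right, common = decoded
            return integrate_sides(left, right, common, self.sim_config)
        return integrate(decoded, self.sim_config)

    def evaluate(self, x: np.ndarray) -> float:
        """Objective of one candidate; +inf encodes simulation failure."""
        try:
            res = self.simulate_candidate(x)
            u = res.signal("Ug")
            cycles = detect_cycles(u, res.fs)
            sim_q = compute_quotients(cycles, res.fs)
            if self.mode == "pathological":
                sim_p = perturbation(cycle_series(cycles, res.fs))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return objective_fyp(self.target_quotients, sim_q,
                                         self.target_perturbation, sim_p,
                                         self.weights)
            return objective_fy(self.target_quotients, sim_q, self.weights)
        except (SimulationDiverged, InsufficientCycles, ValueError):
            return float("inf")

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0,
            config: OptimizerConfig | None = None) -> "VoiceSourceFitResults":
        """GPSO global search + quasi-Newton polish; deterministic per seed."""
        from dataclasses import replace as _replace
        cfg = _replace(config or OptimizerConfig(), seed=seed)
        rng = np.random.default_rng(seed)
        swarm = gpso(self.evaluate, self.bounds, cfg, rng=rng)
        x_ref, f_ref = qn_refine(self.evaluate, swarm.x, self.bounds, cfg)
        try:
            sim_q = self._quotients_of(x_ref)
        except (SimulationDiverged, InsufficientCycles, ValueError):
            sim_q = None
        return VoiceSourceFitResults(
            model=self, x=np.asarray(x_ref), names=self.bounds.names,
            objective=float(f_ref), gpso_objective=float(swarm.fun),
            qn_delta=float(swarm.fun - f_ref), trace=swarm.trace,
            n_evaluations=swarm.n_evaluations, seed=seed,
            fitted_quotients=sim_q)

    def _quotients_of(self, x) -> GlottalQuotients:
        res = self.simulate_candidate(x)
        cycles = detect_cycles(res.signal("Ug"), res.fs)
        return compute_quotients(cycles, res.fs)


@dataclass
class VoiceSourceFitResults:
    """Estimates and diagnostics of one inversion."""

    model: VoiceSourceModel
    x: np.ndarray
    names: tuple[str, ...]
    objective: float
    gpso_objective: float
    qn_delta: float
    trace: np.ndarray
    n_evaluations: int
    seed: int
    fitted_quotients: GlottalQuotients | None

    @property
    def beta(self) -> float:
        return float(self.x[list(self.names).index("beta")])

    @property
    def params(self):
        """Decoded ModelParameters (or side tuple for independent fits)."""
        return self.model.candidate_params(self.x)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.x)))

    def simulate(self, config: SimulationConfig | None = None) -> SimulationResult:
        """Forward-simulate the fitted parameters."""
        if config is None:
            return self.model.simulate_candidate(self.x)
        saved = self.model.sim_config
        try:
            self.model.sim_config = config
            return self.model.simulate_candidate(self.x)
        finally:
            self.model.sim_config = saved

    def sensitivity(self, rel: float = 0.01) -> dict[str, float]:
        """Objective change for a +1 % bump of each estimate (local)."""
        out = {}
        for i, name in enumerate(self.names):
            xp = self.x.copy()
            xp[i] = min(xp[i] * (1 + rel), self.model.bounds.upper[i])
            out[name] = float(self.model.evaluate(xp) - self.objective)
        return out

    def summary(self) -> str:
        """Plain-text report: estimates, objective, statistic match."""
        lines = []
        mode = self.model.mode
        lines.append("Voice-source inversion results")
        lines.append("=" * 58)
        lines.append(f"mode: {mode:<14s} objective: {self.objective:.6f}")
        lines.append(f"seed: {self.seed:<14d} evaluations: {self.n_evaluations}")
        lines.append(f"GPSO best: {self.gpso_objective:.6f}   "
                     f"QN improvement: {self.qn_delta:.6f}")
        lines.append("-" * 58)
        lines.append(f"{'parameter':<10s}{'estimate':>12s}{'lower':>10s}{'upper':>10s}")
        for name, v, lo, hi in zip(self.names, self.x,
                                   self.model.bounds.lower,
                                   self.model.bounds.upper):
            lines.append(f"{name:<10s}{v:>12.5f}{lo:>10.3f}{hi:>10.3f}")
        lines.append("-" * 58)
        tq = self.model.target_quotients
        lines.append(f"{'statistic':<10s}{'target':>12s}{'fitted':>12s}")
        fq = self.fitted_quotients
        for q in ("F0", "OQ", "SQ", "ClQ", "NAQ"):
            tv = getattr(tq, q)
            fv = getattr(fq, q) if fq is not None else float("nan")
            lines.append(f"{q:<10s}{tv:>12.4f}{fv:>12.4f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        doc = {"estimates": self.as_dict(), "objective": self.objective,
               "gpso_objective": self.gpso_objective, "qn_delta": self.qn_delta,
               "seed": self.seed, "n_evaluations": self.n_evaluations,
               "mode": self.model.mode,
               "target_quotients": self.model.target_quotients.as_dict(),
               "fitted_quotients": (self.fitted_quotients.as_dict()
                                    if self.fitted_quotients else None),
               "trace": self.trace.tolist()}
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
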