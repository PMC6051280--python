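"""Hybrid global/local optimisation: GPSO with quasi-Newton refinement.

The inverse problem — find biomechanical parameters whose simulated flow
matches a target's statistics — is nonconvex with many local minima, so
a population method does the global search: particle-swarm updates
augmented with genetic-algorithm-style roulette selection and arithmetic
crossover each generation (GPSO).  The swarm's best candidate is then
polished by a bounded quasi-Newton step with finite-difference gradients.

Everything is deterministic given the seed; the per-generation best score
is non-increasing by elitist bookkeeping, and the refinement never
returns a worse point than its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["SearchBounds", "OptimizerConfig", "GPSOResult", "gpso", "qn_refine"]

_PENALTY = 1e6   # finite stand-in for "simulation failed" during refinement


@dataclass
class SearchBounds:
    """Per-coordinate closed intervals."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if not (len(self.names) == self.lower.size == self.upper.size):
            raise ValueError("bounds length mismatch")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be < upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class OptimizerConfig:
    """GPSO-QN settings.

    Defaults: 30 particles, 400 generations, learning factors c1 = c2 = 2
    and inertia annealed over [0.5, 0.9].  ``selection_count`` (M) defaults
    to the full population; crossover probability 0.7.  The search stops
    early once the best objective drops below ``threshold``.
    """

    population: int = 30
    generations: int = 400
    c1: float = 2.0
    c2: float = 2.0
    inertia: tuple[float, float] = (0.5, 0.9)
    crossover_prob: float = 0.7
    selection_count: int | None = None
    velocity_clamp: float = 0.2   # fraction of each search interval
    threshold: float = 1e-3
    seed: int = 0
    qn_max_iter: int = 40
    qn_rel_step: float = 1e-4


@dataclass
class GPSOResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray             # per-generation best objective
    n_evaluations: int
    seed: int


def gpso(objective, bounds: SearchBounds,
         config: OptimizerConfig | None = None,
         rng: np.random.Generator | None = None) -> GPSOResult:
    """Particle swarm with genetic selection/crossover.

    Each generation: (1) inertia-weighted velocity/position update with
    velocities clamped to ``velocity_clamp`` of each interval and
    positions clipped to the bounds; (2) roulette-wheel (Monte Carlo)
    selection of M individuals with fitness 1/(score + ε), followed by
    arithmetic crossover of selected pairs, the offspring replacing all
    particles except the current best (elitism).  Terminates when the
    best score falls below the threshold or the generation budget is
    exhausted.
    """
    cfg = config or OptimizerConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    n, dim = cfg.population, bounds.dim
    M = cfg.selection_count or n
    vmax = cfg.velocity_clamp * bounds.span

    X = rng.uniform(bounds.lower, bounds.upper, size=(n, dim))
    V = np.zeros((n, dim))
    scores = np.array([objective(x) for x in X])
    n_eval = n
    pbest_x, pbest_f = X.copy(), scores.copy()
    g = int(np.argmin(scores))
    gbest_x, gbest_f = X[g].copy(), float(scores[g])
    trace = [gbest_f]

    w_lo, w_hi = cfg.inertia
    for gen in range(cfg.generations):
        if gbest_f <= cfg.threshold:
            break
        # inertia annealed from the top of the range down
        frac = gen / max(cfg.generations - 1, 1)
        w = w_hi - (w_hi - w_lo) * frac
        r1 = rng.random((n, dim))
        r2 = rng.random((n, dim))
        V = (w * V + cfg.c1 * r1 * (pbest_x - X)
             + cfg.c2 * r2 * (gbest_x - X))
        V = np.clip(V, -vmax, vmax)
        X = bounds.clip(X + V)

        # genetic step: Monte Carlo selection + arithmetic crossover
        fitness = 1.0 / (np.array([objective(x) for x in X]) + 1e-9)
        n_eval += n
        fitness = np.where(np.isfinite(fitness), fitness, 0.0)
        if fitness.sum() > 0:
            prob = fitness / fitness.sum()
        else:
            prob = np.full(n, 1.0 / n)
        chosen = rng.choice(n, size=M, p=prob)
        offspring = X[chosen].copy()
        for i in range(0, M - 1, 2):
            if rng.random() < cfg.crossover_prob:
                lam = rng.random()
                a, b = offspring[i].copy(), offspring[i + 1].copy()
                offspring[i] = lam * a + (1.0 - lam) * b
                offspring[i + 1] = lam * b + (1.0 - lam) * a
        scores_new = np.array([objective(x) for x in offspring[:n]])
        n_eval += min(M, n)

        # elitism: keep the incumbent best in the population
        worst = int(np.argmax(np.where(np.isfinite(scores_new),
                                       scores_new, np.inf)))
        offspring[worst] = gbest_x
        scores_new[worst] = gbest_f
        X = offspring[:n]
        scores = scores_new

        improved = scores < pbest_f
        pbest_x[improved] = X[improved]
        pbest_f[improved] = scores[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        trace.append(gbest_f)

    return GPSOResult(x=gbest_x, fun=gbest_f, trace=np.asarray(trace),
                      n_evaluations=n_eval, seed=cfg.seed)


def _fd_gradient(f, x, bounds: SearchBounds, rel_step: float):
    g = np.empty(x.size)
    h = rel_step * np.maximum(np.abs(x), 1e-3 * bounds.span)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] = min(x[i] + h[i], bounds.upper[i])
        xm[i] = max(x[i] - h[i], bounds.lower[i])
        denom = xp[i] - xm[i]
        g[i] = (f(xp) - f(xm)) / denom if denom > 0 else 0.0
    return g


def qn_refine(objective, start: np.ndarray, bounds: SearchBounds,
              config: OptimizerConfig | None = None) -> tuple[np.ndarray, float]:
    """Bounded quasi-Newton (L-BFGS-B) polish with central differences.

    The simulate→quotients map has no analytic gradient, so gradients are
    central finite differences with a relative step that balances
    integration ripple against curvature.  Returns the better of the
    start point and the refined point — never a worse one.
    """
    cfg = config or OptimizerConfig()
    start = bounds.clip(np.asarray(start, float))
    f0 = objective(start)
    if not np.isfinite(f0):
        import warnings
        warnings.warn("objective not finite at start; refinement skipped")
        return start, float(f0)

    def safe(x):
        v = objective(bounds.clip(x))
        return float(v) if np.isfinite(v) else _PENALTY

    res = minimize(safe, start, method="L-BFGS-B",
                   jac=lambda x: _fd_gradient(safe, bounds.clip(x), bounds,
                                              cfg.qn_rel_step),
                   bounds=list(zip(bounds.lower, bounds.upper)),
                   options={"maxiter": cfg.qn_max_iter})
    x_ref = bounds.clip(res.x)
    f_ref = objective(x_ref)
    if np.isfinite(f_ref) and f_ref < f0:
        return x_ref, float(f_ref)
    return start, float(f0)
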