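"""Forward simulation of the asymmetric two-mass (Steinecke–Herzel) vocal-fold model.

Each vocal fold is idealised as two coupled mass–spring–damper oscillators.
The lower masses are driven by the Bernoulli pressure of the glottal jet;
once a glottal slit closes (negative area) an additional collision spring
pushes the folds apart.  Unilateral pathology is modelled by the asymmetry
parameter β which scales one fold's masses by 1/β and stiffnesses by β,
detuning its natural frequencies by a factor β.

All quantities are in the cm–g–ms unit system (see :mod:`voicefold.parameters`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rk4 import NPAR, integrate_rk4
from .parameters import ModelParameters, SideParameters, apply_asymmetry

__all__ = [
    "StateVector", "SimulationConfig", "SimulationResult", "SimulationDiverged",
    "heaviside", "smooth_switch", "glottal_areas", "driving_pressure",
    "glottal_flow", "collision_forces", "derivatives", "integrate", "TwoMassModel",
]


class SimulationDiverged(RuntimeError):
    """Raised when a trajectory leaves the physical domain (|x| > bound)."""

    def __init__(self, t: float, message: str | None = None):
        self.t = t
        super().__init__(message or f"simulation diverged at t = {t:.3f} ms")


@dataclass
class StateVector:
    """Displacements (cm) and velocities (cm/ms) of the four masses."""

    x1l: float = 0.01
    x2l: float = 0.01
    x1r: float = 0.01
    x2r: float = 0.01
    v1l: float = 0.0
    v2l: float = 0.0
    v1r: float = 0.0
    v2r: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x1l, self.x2l, self.x1r, self.x2r,
                         self.v1l, self.v2l, self.v1r, self.v2r])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*np.asarray(y, dtype=float))


@dataclass
class SimulationConfig:
    """Integration settings.

    dt = 0.04 ms gives a 25 kHz sample rate for Ug, matching the sampling
    rate commonly used for sustained-vowel recordings, so simulated and
    measured flows are directly comparable.
    """

    dt: float = 0.04           # ms
    duration: float = 500.0    # ms
    transient: float = 100.0   # ms discarded by analyses (samples retained)
    initial_state: StateVector = field(default_factory=StateVector)
    divergence_bound: float = 10.0  # cm
    hard_switch: bool = False  # Θ instead of Ω in the pressure gating

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.transient < self.duration):
            raise ValueError("transient must satisfy 0 <= transient < duration")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz implied by the step size."""
        return 1000.0 / self.dt

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


# ----------------------------------------------------------------------------
# elementary pieces of the vector field (NumPy reference implementation)

def heaviside(x: float) -> float:
    """Unit step Θ: 1 for x > 0, else 0.

    Θ(0) = 0 by convention: the glottis is treated as closed at exact zero
    area, consistent with zero flow at contact.
    """
    return np.where(np.asarray(x) > 0.0, 1.0, 0.0)[()]


def smooth_switch(x: float, x0: float) -> float:
    """Smoothed aperture switch Ω(x) = tanh(50 x / x0) for x > 0, else 0."""
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    x = np.asarray(x, dtype=float)
    return np.where(x > 0.0, np.tanh(50.0 * x / x0), 0.0)[()]


def glottal_areas(state: StateVector | np.ndarray,
                  params: ModelParameters) -> tuple[float, float, float]:
    """Lower/upper glottal areas a_i = a0i + L (x_il + x_ir) and their minimum.

    Negative areas are meaningful: they indicate fold collision.
    """
    y = state.as_array() if isinstance(state, StateVector) else np.asarray(state)
    a1 = params.a01 + params.L * (y[0] + y[2])
    a2 = params.a02 + params.L * (y[1] + y[3])
    return a1, a2, min(a1, a2)


def driving_pressure(a1: float, amin: float, params: ModelParameters,
                     hard_switch: bool = False) -> float:
    """Bernoulli pressure P1 on the lower masses.

    P1 = Ps [1 − Ω(amin) (amin/a1)²] Ω(a1) with supraglottal pressure 0.
    Bernoulli flow exists below the narrowest gap only; above it a jet at
    constant pressure forms, so the upper masses feel no aerodynamic force.
    """
    sw = (lambda x: float(heaviside(x))) if hard_switch else \
         (lambda x: float(smooth_switch(x, params.x0)))
    gate = sw(a1)
    if gate <= 0.0:
        return 0.0
    q = amin / max(a1, 1e-12)
    return params.Ps * (1.0 - sw(amin) * q * q) * gate


def glottal_flow(amin: float, params: ModelParameters) -> float:
    """Glottal volume flow Ug = √(2 Ps / ρ) · amin · Θ(amin) (cm³/ms)."""
    if amin <= 0.0:
        return 0.0
    return np.sqrt(2.0 * params.Ps / params.rho) * amin


def collision_forces(a1: float, a2: float,
                     left: SideParameters, right: SideParameters,
                     beta: float, L: float, symmetric_form: bool = False,
                     ) -> tuple[float, float, float, float]:
    """Collision accelerations (I1l, I2l, I1r, I2r), zero while a_i > 0.

    The default form distributes the contact force between the two folds
    with weights β/(β+1) (left) and 1/(β+1) (right), which balances the
    momentum the collision transfers between folds of unequal mass
    (Newton's third law).  With ``symmetric_form=True`` the classical
    symmetric expression I = −Θ(−a)(c/m) a/(2L) is used; the two coincide
    at β = 1.
    """
    if symmetric_form:
        wl = wr = 0.5
    else:
        wl = beta / (beta + 1.0)
        wr = 1.0 / (beta + 1.0)
    I1l = I2l = I1r = I2r = 0.0
    if a1 < 0.0:
        I1l = -(left.c1 / left.m1) * (a1 / L) * wl
        I1r = -(right.c1 / right.m1) * (a1 / L) * wr
    if a2 < 0.0:
        I2l = -(left.c2 / left.m2) * (a2 / L) * wl
        I2r = -(right.c2 / right.m2) * (a2 / L) * wr
    return I1l, I2l, I1r, I2r


def derivatives(state: StateVector | np.ndarray,
                params: ModelParameters,
                hard_switch: bool = False) -> np.ndarray:
    """Time derivative of the state vector (reference implementation).

    v̇1α = F1α + I1α − (1/m1α)[r1α v1α + k1α x1α + kcα (x1α − x2α)]
    v̇2α =        I2α − (1/m2α)[r2α v2α + k2α x2α + kcα (x2α − x1α)]

    F (Bernoulli) and I (collision) are acceleration terms: they carry the
    1/m factors internally.
    """
    y = state.as_array() if isinstance(state, StateVector) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    left, right = apply_asymmetry(params)
    a1, a2, amin = glottal_areas(y, params)
    P1 = driving_pressure(a1, amin, params, hard_switch)
    L, d, b = params.L, params.d, params.beta

    wl = b / (b + 1.0)
    wr = 1.0 / (b + 1.0)
    I1l = -heaviside(-a1) * (left.c1 / left.m1) * (a1 / L) * wl
    I1r = -heaviside(-a1) * (right.c1 / right.m1) * (a1 / L) * wr
    I2l = -heaviside(-a2) * (left.c2 / left.m2) * (a2 / L) * wl
    I2r = -heaviside(-a2) * (right.c2 / right.m2) * (a2 / L) * wr

    x1l, x2l, x1r, x2r, v1l, v2l, v1r, v2r = y
    dy = np.empty(8)
    dy[0], dy[1], dy[2], dy[3] = v1l, v2l, v1r, v2r
    dy[4] = L * d * P1 / left.m1 + I1l - (left.r1 * v1l + left.k1 * x1l
                                          + left.kc * (x1l - x2l)) / left.m1
    dy[5] = I2l - (left.r2 * v2l + left.k2 * x2l + left.kc * (x2l - x1l)) / left.m2
    dy[6] = L * d * P1 / right.m1 + I1r - (right.r1 * v1r + right.k1 * x1r
                                           + right.kc * (x1r - x2r)) / right.m1
    dy[7] = I2r - (right.r2 * v2r + right.k2 * x2r + right.kc * (x2r - x1r)) / right.m2
    return dy


# ----------------------------------------------------------------------------
# integration


def _pack(params: ModelParameters, hard_switch: bool) -> np.ndarray:
    left, right = apply_asymmetry(params)
    p = np.empty(NPAR)
    p[0:9] = left.as_array()
    p[9:18] = right.as_array()
    p[18:27] = (params.a01, params.a02, params.L, params.d, params.Ps,
                params.rho, params.x0, params.beta, 1.0 if hard_switch else 0.0)
    return p


@dataclass
class SimulationResult:
    """Trajectory of a forward simulation plus derived aerodynamic signals.

    Arrays share a common time grid.  ``transient`` marks the initial span
    that analyses skip; the samples themselves are retained.
    """

    t: np.ndarray                # ms
    states: np.ndarray           # (n, 8): x1l, x2l, x1r, x2r, v1l..v2r
    a1: np.ndarray               # cm²
    a2: np.ndarray               # cm²
    Ug: np.ndarray               # cm³/ms
    P1: np.ndarray               # g cm⁻¹ ms⁻²
    params: ModelParameters
    config: SimulationConfig

    columns = ("x1l", "x2l", "x1r", "x2r", "v1l", "v2l", "v1r", "v2r")

    @property
    def fs(self) -> float:
        return self.config.fs

    @property
    def amin(self) -> np.ndarray:
        return np.minimum(self.a1, self.a2)

    @property
    def transient_mask(self) -> np.ndarray:
        return self.t >= self.config.transient

    def signal(self, name: str, post_transient: bool = True) -> np.ndarray:
        """Fetch one named signal, by default with the transient removed."""
        if name in self.columns:
            x = self.states[:, self.columns.index(name)]
        elif name in ("Ug", "a1", "a2", "amin", "P1", "t"):
            x = getattr(self, name)
        else:
            raise KeyError(name)
        return x[self.transient_mask] if post_transient else x

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "t", self.t)
        df["a1"], df["a2"], df["Ug"], df["P1"] = self.a1, self.a2, self.Ug, self.P1
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_wav(self, path) -> None:
        """Write the normalized flow as 16-bit PCM for listening checks."""
        from .io import write_wav
        u = self.signal("Ug")
        u = u - u.mean()
        peak = np.max(np.abs(u))
        if peak > 0:
            u = u / peak * 0.9
        write_wav(path, u, int(round(self.fs)))


def integrate_sides(left: SideParameters, right: SideParameters,
                    params: ModelParameters,
                    config: SimulationConfig | None = None) -> SimulationResult:
    """Integrate with explicitly given side parameters.

    Bypasses the β-scaling of :func:`apply_asymmetry` so fully
    independent left/right constants can be explored; ``params`` still
    supplies the shared geometry, pressure and the β used to weight the
    contact force between the sides.
    """
    config = config or SimulationConfig()
    nsteps = int(round(config.duration / config.dt))
    p = np.empty(NPAR)
    p[0:9] = left.as_array()
    p[9:18] = right.as_array()
    p[18:27] = (params.a01, params.a02, params.L, params.d, params.Ps,
                params.rho, params.x0, params.beta,
                1.0 if config.hard_switch else 0.0)
    Y, A1, A2, UG, P1, n_ok = integrate_rk4(config.initial_state.as_array(),
                                            p, config.dt, nsteps,
                                            config.divergence_bound)
    if n_ok <= nsteps:
        raise SimulationDiverged(n_ok * config.dt)
    t = np.arange(nsteps + 1) * config.dt
    return SimulationResult(t=t, states=Y, a1=A1, a2=A2, Ug=UG, P1=P1,
                            params=params, config=config)


def integrate(params: ModelParameters,
              config: SimulationConfig | None = None) -> SimulationResult:
    """Integrate the model with fixed-step RK4.

    Raises :class:`SimulationDiverged` if any displacement exceeds the
    configured bound — during parameter searches this flags unphysical
    candidate parameter sets.
    """
    config = config or SimulationConfig()
    nsteps = int(round(config.duration / config.dt))
    y0 = config.initial_state.as_array()
    p = _pack(params, config.hard_switch)
    Y, A1, A2, UG, P1, n_ok = integrate_rk4(y0, p, config.dt, nsteps,
                                            config.divergence_bound)
    if n_ok <= nsteps:
        raise SimulationDiverged(n_ok * config.dt)
    t = np.arange(nsteps + 1) * config.dt
    return SimulationResult(t=t, states=Y, a1=A1, a2=A2, Ug=UG, P1=P1,
                            params=params, config=config)


class TwoMassModel:
    """Object-style façade over the forward model.

    >>> res = TwoMassModel(ModelParameters(beta=0.8)).simulate()
    """

    def __init__(self, params: ModelParameters | None = None):
        self.params = params or ModelParameters()

    def simulate(self, config: SimulationConfig | None = None) -> SimulationResult:
        return integrate(self.params, config)

    def natural_frequencies(self):
        from .dynamics import natural_frequencies
        return natural_frequencies(self.params)
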