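"""Biomechanical parameters of the asymmetric two-mass vocal-fold model.

Internal unit system is cm–g–ms (lengths in cm, masses in g, time in ms).
In these units pressure comes out in g·cm⁻¹·ms⁻², i.e. units of 100 kPa,
so the standard subglottal pressure ``Ps = 0.008`` corresponds to 0.8 kPa.
Frequencies are kHz internally and reported in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Iterator

import numpy as np

__all__ = ["ModelParameters", "SideParameters", "apply_asymmetry", "BETA_RANGE"]

#: Clinically motivated admissible range for the asymmetry parameter β.
BETA_RANGE = (0.4, 1.0)


@dataclass(frozen=True)
class ModelParameters:
    """Symmetric base constants of the two-mass model plus the asymmetry β.

    Defaults are the standard parameter set of the Steinecke–Herzel model.
    The left fold always carries the base values; the right fold is derived
    from them through β (see :func:`apply_asymmetry`): masses divide by β,
    stiffnesses (including the collision and coupling springs) multiply by β.

    Attributes
    ----------
    m1, m2 : float
        Lower/upper mass (g).
    k1, k2 : float
        Lower/upper spring constants (g/ms²).
    kc : float
        Coupling spring between the two masses of one fold (g/ms²).
    r1, r2 : float
        Damping constants (g/ms).
    a01, a02 : float
        Rest areas of the lower/upper glottal slit (cm²).
    L : float
        Vocal-fold length (cm).
    d : float
        Thickness of the lower mass (cm).
    Ps : float
        Subglottal pressure (g·cm⁻¹·ms⁻², 0.008 ≡ 0.8 kPa).
    rho : float
        Air density (g/cm³).
    beta : float
        Left/right asymmetry parameter, 0.4 < β ≤ 1; β = 1 is symmetric.
    x0 : float
        Scale of the smoothed aperture switch Ω(x) = tanh(50 x / x0) (cm²).
    """

    m1: float = 0.125
    m2: float = 0.025
    k1: float = 0.08
    k2: float = 0.008
    kc: float = 0.025
    r1: float = 0.02
    r2: float = 0.02
    a01: float = 0.05
    a02: float = 0.05
    L: float = 1.4
    d: float = 0.25
    Ps: float = 0.008
    rho: float = 0.00113
    beta: float = 1.0
    x0: float = 0.05

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "k1", "k2", "kc", "r1", "r2",
                     "a01", "a02", "L", "d", "Ps", "rho", "x0"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive finite number, "
                                 f"got {getattr(self, name)!r}")
        lo, hi = BETA_RANGE
        if not (lo < self.beta <= hi):
            raise ValueError(f"beta must lie in ({lo}, {hi}], got {self.beta!r}")

    # Collision springs are always derived, never stored: c_i = 3 k_i.
    @property
    def c1(self) -> float:
        return 3.0 * self.k1

    @property
    def c2(self) -> float:
        return 3.0 * self.k2

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass(frozen=True)
class SideParameters:
    """Effective per-side constants after applying the asymmetry scaling."""

    m1: float
    m2: float
    k1: float
    k2: float
    kc: float
    c1: float
    c2: float
    r1: float
    r2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m1, self.m2, self.k1, self.k2, self.kc,
                         self.c1, self.c2, self.r1, self.r2])

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


def apply_asymmetry(params: ModelParameters) -> tuple[SideParameters, SideParameters]:
    """Split base parameters into (left, right) effective side parameters.

    The left fold is taken as healthy (base values).  A lesion on the right
    fold is modelled by β: right masses are divided by β while right
    stiffnesses — k, the coupling spring kc and the collision springs c —
    are multiplied by β.  At β = 1 the two sides are identical, and the
    right fold's natural frequencies scale as exactly β times the left's
    (K/M picks up a factor β²).
    """
    p = params
    left = SideParameters(m1=p.m1, m2=p.m2, k1=p.k1, k2=p.k2, kc=p.kc,
                          c1=p.c1, c2=p.c2, r1=p.r1, r2=p.r2)
    b = p.beta
    right = SideParameters(m1=p.m1 / b, m2=p.m2 / b,
                           k1=b * p.k1, k2=b * p.k2, kc=b * p.kc,
                           c1=b * p.c1, c2=b * p.c2,
                           r1=p.r1, r2=p.r2)
    return left, right
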