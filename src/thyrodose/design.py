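"""Discrete-time controller synthesis for the monthly dosing loop.

The plant is discretized with the impulse-invariant method (one tablet
per day motivates matching the sampled impulse response).  Because the
visit interval Td is large compared with both time constants, the product
q1*q2 of the discrete poles is negligible and the plant reduces to a
first-order form A*p1 / (z - p2).  The linear rate-limiter block
Krz(z) = kr/(z - Delta) is absorbed into a second-order "total plant",
and a first-order controller R(z) = (b1 z + b0)/(z + a0) is obtained by
placing all three closed-loop poles at z0 via the Diophantine identity
a(z) v(z) + b(z) mu(z) = (z - z0)^3, solved by coefficient matching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .model import ThyroidParams

__all__ = [
    "DiscretePlant",
    "RateLimiterTF",
    "TotalPlant",
    "ControllerTF",
    "DesignSpec",
    "discretize_impulse_invariant",
    "rate_limiter",
    "design_controller",
    "total_plant",
]


@dataclass(frozen=True)
class DiscretePlant:
    """Impulse-invariant discretization of the dose-to-FT4 path.

    A  = kreac / (ksec - kexc)   (discretization gain)
    q1 = exp(-ksec Td), q2 = exp(-kexc Td)
    p1 = q2 - q1, p2 = q1 + q2

    Full form:    G(z) = A p1 z / (z^2 - p2 z + q1 q2)
    Reduced form: G(z) = A p1 / (z - p2)      (q1 q2 neglected)

    With ksec < kexc both A and p1 are negative, so the effective
    first-order gain A*p1 is positive.
    """

    Td: float
    A_gain: float
    q1: float
    q2: float
    reduced: bool

    @property
    def p1(self) -> float:
        return self.q2 - self.q1

    @property
    def p2(self) -> float:
        return self.q1 + self.q2

    @property
    def gain(self) -> float:
        """Effective reduced-form gain A * p1 (positive)."""
        return self.A_gain * self.p1


@dataclass(frozen=True)
class RateLimiterTF:
    """Linear rate-limiter block.

    Open loop Kr(z) = kr/(z - 1); closing unity feedback around it gives
    Krz(z) = kr/(z - Delta), Delta = 1 - kr, i.e. the recursion
    y[k+1] = Delta y[k] + kr u[k], a first-order lag with unit DC gain.
    """

    kr: float

    def __post_init__(self) -> None:
        if not 0 < self.kr <= 1:
            raise ValueError("kr must lie in (0, 1]")

    @property
    def delta(self) -> float:
        return 1.0 - self.kr

    def step(self, y_prev: float, u: float) -> float:
        return self.delta * y_prev + self.kr * u


@dataclass(frozen=True)
class TotalPlant:
    """Second-order design plant Gp(z) = mu0 / (z^2 + v1 z + v0)."""

    mu0: float
    v1: float
    v0: float
    mu1: float = 0.0

    def __post_init__(self) -> None:
        if self.mu0 == 0:
            raise ValueError("total-plant gain mu0 must be nonzero")

    @property
    def denominator(self) -> np.ndarray:
        """Ascending coefficients of v(z)."""
        return np.array([self.v0, self.v1, 1.0])

    @property
    def numerator(self) -> np.ndarray:
        return np.array([self.mu0, self.mu1])


@dataclass(frozen=True)
class ControllerTF:
    """First-order controller R(z) = (b1 z + b0) / (a1 z + a0)."""

    b1: float
    b0: float
    a1: float = 1.0
    a0: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 == 0:
            raise ValueError("controller denominator leading coefficient is zero")

    def to_json(self, path, **extra) -> None:
        payload = {"a1": self.a1, "a0": self.a0, "b1": self.b1, "b0": self.b0}
        payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ControllerTF":
        with open(path) as fh:
            d = json.load(fh)
        return cls(b1=d["b1"], b0=d["b0"], a1=d["a1"], a0=d["a0"])


@dataclass(frozen=True)
class DesignSpec:
    """Controller design settings.

    z0: location of the (triple) desired closed-loop pole.  Poles near 0
        react deadbeat-fast, poles near +/-1 overshoot; -0.01 is a slow,
        overshoot-free compromise.
    Td: visit interval in hours (default 28 days).
    kr: smoothing gain of the linear rate-limiter block.
    neglect_threshold: bound below which q1*q2 is dropped.
    """

    z0: float = -0.01
    Td: float = 672.0
    kr: float = 0.5
    neglect_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if not abs(self.z0) < 1:
            raise ValueError("desired pole must lie inside the unit circle")
        if self.Td <= 0:
            raise ValueError("Td must be positive")

    @property
    def target_poly(self) -> np.ndarray:
        """Monic target (z - z0)^3, ascending coefficients w0..w3."""
        return npoly.polyfromroots([self.z0] * 3)


def discretize_impulse_invariant(
    params: ThyroidParams, Td: float = 672.0, threshold: float = 1e-6
) -> DiscretePlant:
    """Impulse-invariant discretization of the dose path at interval Td."""
    if Td <= 0:
        raise ValueError("Td must be positive")
    if params.kexc == params.ksec:
        raise ValueError("kexc = ksec: discretization gain A is undefined")
    q1 = float(np.exp(-params.ksec * Td))
    q2 = float(np.exp(-params.kexc * Td))
    A = params.kreac / (params.ksec - params.kexc)
    reduced = q1 * q2 < threshold
    if not reduced:
        warnings.warn(
            f"q1*q2 = {q1 * q2:.3g} is not negligible at Td = {Td} h; "
            "the full second-order form is retained but the pole-placement "
            "design path requires the reduced form",
            RuntimeWarning,
        )
    return DiscretePlant(Td=Td, A_gain=A, q1=q1, q2=q2, reduced=reduced)


def rate_limiter(kr: float) -> RateLimiterTF:
    """Rate-limiter block with smoothing gain kr in (0, 1]."""
    return RateLimiterTF(kr)


def total_plant(plant: DiscretePlant, limiter: RateLimiterTF) -> TotalPlant:
    """Cascade of reduced plant and closed-loop limiter Krz(z)."""
    if not plant.reduced:
        raise ValueError("pole-placement design requires the reduced plant form")
    delta = limiter.delta
    return TotalPlant(
        mu0=plant.gain * limiter.kr,
        v1=-(plant.p2 + delta),
        v0=plant.p2 * delta,
    )


def design_controller(plant: DiscretePlant, spec: DesignSpec) -> ControllerTF:
    """Pole placement: solve a(z) v(z) + b(z) mu0 = (z - z0)^3.

    With monic a(z) = z + a0 and v(z) = z^2 + v1 z + v0, matching the
    coefficients of the cubic target gives, in descending order of z,
    a0 = w2 - v1, b1 = (w1 - v0 - a0 v1)/mu0, b0 = (w0 - a0 v0)/mu0.
    """
    gp = total_plant(plant, rate_limiter(spec.kr))
    mu0, v1, v0 = gp.mu0, gp.v1, gp.v0
    w0, w1, w2, _ = spec.target_poly
    a0 = w2 - v1
    b1 = (w1 - v0 - a0 * v1) / mu0
    b0 = (w0 - a0 * v0) / mu0
    ctrl = ControllerTF(b1=b1, b0=b0, a1=1.0, a0=a0)

    achieved = npoly.polyadd(
        npoly.polymul([a0, 1.0], gp.denominator), [b0 * mu0, b1 * mu0]
    )
    if np.max(np.abs(achieved - spec.target_poly)) > 1e-10:  # pragma: no cover
        raise ArithmeticError("pole-placement identity violated")
    return ctrl
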