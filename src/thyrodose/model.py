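"""Two-state model of exogenous-T4 / FT4 dynamics.

The plant couples an oral LT4 compartment ``x1`` (total exogenous T4 in
blood serum, umol) to the free-thyroxine output ``x2``::

    dx1/dt = d - kexc * x1
    dx2/dt = vmax * TSH / (km + TSH) + kreac * x1 - ksec * x2

``d`` is the dosing input.  Once-daily tablets are modelled as impulses
into ``x1`` (the default); a constant-rate infusion variant is available.
Between dosing and TSH-update events the system is linear and
time-invariant, so trajectories are propagated with the exact closed-form
solution rather than a numerical integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .units import MOLAR_MASS_LT4

__all__ = [
    "ThyroidParams",
    "PlantState",
    "DoseSchedule",
    "TshSignal",
    "Trajectory",
    "RationalTF",
    "simulate_plant",
    "system_matrices",
    "continuous_tf",
]


@dataclass(frozen=True)
class ThyroidParams:
    """The five plant constants.

    kexc : elimination rate of the oral LT4 compartment, 1/h
    ksec : natural FT4 elimination rate, 1/h
    vmax : maximal endogenous production rate, umol/h
    km   : Michaelis constant of the TSH drive, umol
    kreac: gain from the oral compartment to FT4 (dimensionless "ppm")
    """

    kexc: float
    ksec: float
    vmax: float
    km: float
    kreac: float
    check: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.check:
            return
        for name in ("kexc", "ksec", "vmax", "km", "kreac"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive and finite")
        if self.kexc == self.ksec:
            raise ValueError(
                "kexc must differ from ksec (the discrete gain "
                "A = kreac/(ksec - kexc) is undefined otherwise)"
            )

    def replace(self, **changes) -> "ThyroidParams":
        d = {n: getattr(self, n) for n in ("kexc", "ksec", "vmax", "km", "kreac")}
        d.update(changes)
        return ThyroidParams(**d)


@dataclass(frozen=True)
class PlantState:
    """x1: exogenous T4 in serum (umol); x2: FT4 output (model units)."""

    x1: float = 0.0
    x2: float = 0.0

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("plant state must be nonnegative")


@dataclass(frozen=True)
class DoseSchedule:
    """Impulsive oral doses: strictly increasing times (h) and amounts.

    Amounts are micrograms by default and are converted to umol via the
    LT4 molar mass; ``bioavailability`` scales the absorbed fraction.
    ``unit='umol'`` bypasses the mass conversion.
    """

    times_h: np.ndarray
    doses: np.ndarray
    bioavailability: float = 1.0
    unit: str = "ug"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        d = np.asarray(self.doses, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "doses", d)
        if t.shape != d.shape:
            raise ValueError("times and doses must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("dose times must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("doses must be nonnegative")
        if not 0 < self.bioavailability <= 1:
            raise ValueError("bioavailability must lie in (0, 1]")
        if self.unit not in ("ug", "umol"):
            raise ValueError("unit must be 'ug' or 'umol'")

    @property
    def amounts_umol(self) -> np.ndarray:
        """Absorbed impulse amounts entering x1, umol."""
        scale = self.bioavailability
        if self.unit == "ug":
            scale /= MOLAR_MASS_LT4
        return self.doses * scale

    @classmethod
    def daily(
        cls,
        daily_doses_ug: Sequence[float],
        bioavailability: float = 1.0,
        start_h: float = 0.0,
    ) -> "DoseSchedule":
        """One tablet per day: dose ``i`` is taken at ``start_h + 24 i``."""
        d = np.asarray(daily_doses_ug, dtype=float)
        t = start_h + 24.0 * np.arange(d.size)
        return cls(t, d, bioavailability=bioavailability)

    @classmethod
    def empty(cls) -> "DoseSchedule":
        return cls(np.empty(0), np.empty(0))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.times_h, "dose_ug": self.doses}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, bioavailability: float = 1.0) -> "DoseSchedule":
        df = pd.read_csv(path)
        return cls(
            df["time_h"].to_numpy(),
            df["dose_ug"].to_numpy(),
            bioavailability=bioavailability,
        )


@dataclass(frozen=True)
class TshSignal:
    """Piecewise-constant TSH record.

    ``values`` are held constant over each interval of the simulation
    grid (zero-order hold on the left sample).  A scalar gives a constant
    signal.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise ValueError("TSH must be nonnegative and finite")

    def on_grid(self, n: int) -> np.ndarray:
        if self.values.size == 1:
            return np.full(n, self.values[0])
        if self.values.size != n:
            raise ValueError(
                f"TSH record length {self.values.size} does not match grid ({n})"
            )
        return self.values

    @classmethod
    def constant(cls, value: float) -> "TshSignal":
        return cls(np.asarray([value]))


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course on a strictly increasing hour grid."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    tsh: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x1) == len(self.x2) == len(self.tsh) == n):
            raise ValueError("trajectory columns must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def y(self) -> np.ndarray:
        """Plant output (FT4 in model units): y = x2."""
        return self.x2

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_h": self.t, "x1_umol": self.x1, "ft4": self.x2, "tsh": self.tsh}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            df["time_h"].to_numpy(),
            df["x1_umol"].to_numpy(),
            df["ft4"].to_numpy(),
            df["tsh"].to_numpy(),
        )


@dataclass(frozen=True)
class RationalTF:
    """Rational transfer function, coefficients in descending powers."""

    num: np.ndarray
    den: np.ndarray
    domain: str = "s"

    def __post_init__(self) -> None:
        object.__setattr__(self, "num", np.asarray(self.num, dtype=float))
        object.__setattr__(self, "den", np.asarray(self.den, dtype=float))
        if self.den.size == 0 or self.den[0] == 0:
            raise ValueError("denominator leading coefficient must be nonzero")
        if self.domain not in ("s", "z"):
            raise ValueError("domain must be 's' or 'z'")

    def __call__(self, x: complex) -> complex:
        return np.polyval(self.num, x) / np.polyval(self.den, x)


def _step_factors(params: ThyroidParams, dt: np.ndarray):
    """Per-interval propagation factors of the exact solution."""
    e1 = np.exp(-params.kexc * dt)
    e2 = np.exp(-params.ksec * dt)
    cross = params.kreac * (e1 - e2) / (params.ksec - params.kexc)
    return e1, e2, cross


def simulate_plant(
    params: ThyroidParams,
    doses: DoseSchedule,
    tsh: TshSignal,
    x0: PlantState,
    t_grid: Sequence[float],
    dosing_mode: str = "impulse",
) -> Trajectory:
    """Exact simulation of the plant on ``t_grid``.

    Doses are impulsive increments of ``x1`` at their scheduled times
    (which must coincide with grid points); TSH is held piecewise constant
    per grid interval.  Under those conventions each interval has a
    closed-form solution, so the trajectory is exact to rounding.
    Reported samples at dose times are post-impulse.

    ``dosing_mode='rate'`` instead spreads each scheduled amount as a
    constant infusion over the 24 h following its time (non-default).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("t_grid must be a 1-D array of at least one time")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if dosing_mode not in ("impulse", "rate"):
        raise ValueError("dosing_mode must be 'impulse' or 'rate'")

    tsh_vals = tsh.on_grid(t.size)
    u = params.vmax * tsh_vals / (params.km + tsh_vals)

    n = t.size
    impulses = np.zeros(n)
    if doses.times_h.size:
        idx = np.searchsorted(t, doses.times_h)
        ok = (idx < n) & np.isclose(
            t[np.minimum(idx, n - 1)], doses.times_h, rtol=0.0, atol=1e-9
        )
        if not np.all(ok):
            bad = doses.times_h[~ok]
            raise ValueError(f"dose times {bad} are not on the simulation grid")
        np.add.at(impulses, idx, doses.amounts_umol)

    dt = np.diff(t)
    e1, e2, cross = _step_factors(params, dt)

    if dosing_mode == "rate":
        rate = np.zeros(n - 1) if n > 1 else np.zeros(0)
        for time, amount in zip(doses.times_h, doses.amounts_umol):
            lo = np.searchsorted(t, time, side="left")
            hi = np.searchsorted(t, time + 24.0, side="left")
            rate[lo:hi] += amount / 24.0
        impulses[:] = 0.0

    x1 = np.empty(n)
    x2 = np.empty(n)
    x1[0] = x0.x1 + impulses[0]
    x2[0] = x0.x2

    uniform = n > 1 and np.allclose(dt, dt[0], rtol=1e-12, atol=1e-12)
    if dosing_mode == "impulse" and uniform:
        # Both states are first-order linear recurrences with constant
        # coefficients on a uniform grid; evaluate them with lfilter.
        imp = impulses.copy()
        imp[0] += x0.x1
        x1 = lfilter([1.0], [1.0, -e1[0]], imp)
        w = u[:-1] / params.ksec * (1.0 - e2) + x1[:-1] * cross
        x2[1:] = lfilter([1.0], [1.0, -e2[0]], w + np.concatenate(
            ([x0.x2 * e2[0]], np.zeros(n - 2))
        ))
        x2[0] = x0.x2
    else:
        for k in range(n - 1):
            forced = u[k]
            if dosing_mode == "rate":
                c = rate[k] / params.kexc
                x1_eff = x1[k] - c
                x1[k + 1] = c + x1_eff * e1[k]
                x2[k + 1] = (
                    x2[k] * e2[k]
                    + (forced + params.kreac * c) / params.ksec * (1.0 - e2[k])
                    + x1_eff * cross[k]
                )
            else:
                x1[k + 1] = x1[k] * e1[k]
                x2[k + 1] = (
                    x2[k] * e2[k]
                    + forced / params.ksec * (1.0 - e2[k])
                    + x1[k] * cross[k]
                )
            x1[k + 1] += impulses[k + 1]

    return Trajectory(t, x1, x2, tsh_vals)


def system_matrices(params: ThyroidParams):
    """State-space form (A, b, V, c), eigenvalues and controllability.

    The state equation is ``x' = A x + b d + V p`` with the TSH
    disturbance ``p = TSH/(km + TSH)`` and output ``y = c^T x``.
    The eigenvalues are ``-kexc`` and ``-ksec``; the pair (A, b) is
    controllable iff the controllability determinant (= kreac) is nonzero.
    """
    A = np.array([[-params.kexc, 0.0], [params.kreac, -params.ksec]])
    b = np.array([1.0, 0.0])
    V = np.array([0.0, params.vmax])
    c = np.array([0.0, 1.0])
    eigenvalues = np.array([-params.kexc, -params.ksec])
    ctrb = np.column_stack([b, A @ b])
    controllable = bool(abs(np.linalg.det(ctrb)) > 0.0)
    return A, b, V, c, eigenvalues, controllable


def continuous_tf(params: ThyroidParams):
    """Continuous transfer functions from dose and TSH drive to output.

    G(s) = kreac / (s^2 + (ksec + kexc) s + ksec kexc)  (dose path)
    S(s) = vmax / (s + ksec)                            (TSH drive path)
    """
    G = RationalTF(
        [params.kreac],
        [1.0, params.ksec + params.kexc, params.ksec * params.kexc],
        "s",
    )
    S = RationalTF([params.vmax], [1.0, params.ksec], "s")
    return G, S
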