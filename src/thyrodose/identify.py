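"""Least-squares identification of the patient-specific plant constants.

Only the fitted triple (kreac, km, vmax) is estimated; the elimination
rates kexc and ksec are fixed from literature values (oral kinetics and
the 9-10 day T4 half-life).  The cost is the sum of squared residuals
between the recorded FT4 output and the model output simulated under the
recorded dosing and TSH signals.

The search is a derivative-free Nelder-Mead simplex in log-parameter
space (which enforces positivity), with a quadratic penalty above the
upper bounds and a small number of seeded restarts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import DoseSchedule, PlantState, ThyroidParams, TshSignal, simulate_plant
from .units import (
    KEXC_NOMINAL,
    KM_NOMINAL,
    KREAC_NOMINAL,
    KSEC_NOMINAL,
    VMAX_NOMINAL,
)

__all__ = [
    "ParamVector",
    "IdentData",
    "cost_J",
    "identify",
    "IdentResult",
    "make_identification_record",
]

_PARAM_NAMES = ("kreac", "km", "vmax")


@dataclass(frozen=True)
class ParamVector:
    """The fitted triple with its upper bounds (lower bound is 0+)."""

    kreac: float
    km: float
    vmax: float
    kreac_max: float = 10.0 * KREAC_NOMINAL
    km_max: float = 10.0 * KM_NOMINAL
    vmax_max: float = 10.0 * VMAX_NOMINAL

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            v, hi = getattr(self, name), getattr(self, f"{name}_max")
            if not 0 < v <= hi:
                raise ValueError(f"{name}={v} outside (0, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.kreac, self.km, self.vmax])

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.kreac_max, self.km_max, self.vmax_max])

    def to_params(self, kexc: float, ksec: float) -> ThyroidParams:
        return ThyroidParams(
            kexc=kexc, ksec=ksec, vmax=self.vmax, km=self.km, kreac=self.kreac
        )


@dataclass(frozen=True)
class IdentData:
    """Hourly identification record: dose impulses, TSH and observed FT4."""

    time_h: np.ndarray
    dose_ug: np.ndarray
    tsh: np.ndarray
    ft4: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("time_h", "dose_ug", "tsh", "ft4"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        n = arrays["time_h"].size
        if n < 2:
            raise ValueError("identification record needs at least 2 samples")
        if any(a.size != n for a in arrays.values()):
            raise ValueError("record columns must have equal length")
        if np.any(arrays["tsh"] < 0):
            raise ValueError("TSH must be nonnegative")

    @property
    def tsh_is_constant(self) -> bool:
        return bool(np.ptp(self.tsh) == 0.0)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_h": self.time_h,
                "dose_ug": self.dose_ug,
                "tsh_mU_L": self.tsh,
                "ft4": self.ft4,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IdentData":
        df = pd.read_csv(path)
        return cls(
            df["time_h"].to_numpy(),
            df["dose_ug"].to_numpy(),
            df["tsh_mU_L"].to_numpy(),
            df["ft4"].to_numpy(),
        )


@dataclass(frozen=True)
class IdentResult:
    estimate: ParamVector
    cost: float
    converged: bool
    n_evaluations: int

    def to_json(self, path) -> None:
        payload = {
            "kreac": self.estimate.kreac,
            "km": self.estimate.km,
            "vmax": self.estimate.vmax,
            "cost": self.cost,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _model_output(
    p: np.ndarray, data: IdentData, kexc: float, ksec: float
) -> np.ndarray:
    kreac, km, vmax = p
    params = ThyroidParams(kexc=kexc, ksec=ksec, vmax=vmax, km=km, kreac=kreac)
    nz = data.dose_ug > 0
    doses = DoseSchedule(data.time_h[nz], data.dose_ug[nz])
    traj = simulate_plant(
        params, doses, TshSignal(data.tsh), PlantState(0.0, float(data.ft4[0])),
        data.time_h,
    )
    return traj.y


def cost_J(
    p: ParamVector,
    data: IdentData,
    kexc: float = KEXC_NOMINAL,
    ksec: float = KSEC_NOMINAL,
) -> float:
    """Sum of squared output residuals J(p) = sum_i (y_i - ym_i)^2."""
    ym = _model_output(p.as_array(), data, kexc, ksec)
    return float(np.sum((data.ft4 - ym) ** 2))


def _penalised_log_cost(
    q: np.ndarray, data: IdentData, kexc: float, ksec: float, bounds: np.ndarray
) -> float:
    p = np.exp(q)
    excess = np.maximum(p / bounds - 1.0, 0.0)
    penalty = 1e6 * float(np.sum(excess**2)) * (1.0 + np.sum(data.ft4**2))
    ym = _model_output(np.minimum(p, bounds), data, kexc, ksec)
    return float(np.sum((data.ft4 - ym) ** 2)) + penalty


def identify(
    data: IdentData,
    init: ParamVector,
    kexc: float = KEXC_NOMINAL,
    ksec: float = KSEC_NOMINAL,
    n_restarts: int = 3,
    seed: int = 0,
    maxiter: int = 20000,
) -> IdentResult:
    """Fit (kreac, km, vmax) to an identification record.

    Nelder-Mead in log space keeps the parameters positive; values above
    the stated upper bounds are pulled back by a quadratic penalty.  The
    search restarts ``n_restarts`` times from jittered copies of the best
    point found so far (restarting a collapsed simplex is the standard
    cure for premature convergence); the best cost is kept.  The returned
    cost never exceeds J(init).
    """
    if data.tsh_is_constant:
        raise ValueError(
            "TSH is constant over the whole record: km and vmax are not "
            "separately identifiable (only vmax*TSH/(km+TSH) is determined); "
            "provide a record with a varying TSH signal"
        )
    bounds = init.bounds
    rng = np.random.default_rng(seed)

    def objective(q: np.ndarray) -> float:
        return _penalised_log_cost(q, data, kexc, ksec, bounds)

    best_q = np.log(init.as_array())
    best_f = objective(best_q)
    init_cost = best_f
    n_eval = 1
    converged = False
    opts = dict(maxiter=maxiter, maxfev=maxiter, fatol=1e-24, xatol=1e-12)
    for attempt in range(1 + n_restarts):
        q0 = best_q if attempt == 0 else best_q + rng.normal(0.0, 0.05, 3)
        res = minimize(objective, q0, method="Nelder-Mead", options=opts)
        n_eval += res.nfev
        if res.fun < best_f:
            best_f, best_q = res.fun, res.x
        converged = converged or bool(res.success)

    p_hat = np.minimum(np.exp(best_q), bounds)
    if best_f > init_cost:  # pragma: no cover - monotonicity safeguard
        p_hat, best_f = init.as_array(), init_cost
    estimate = ParamVector(
        *p_hat,
        kreac_max=init.kreac_max,
        km_max=init.km_max,
        vmax_max=init.vmax_max,
    )
    if not converged:
        warnings.warn("simplex search did not report convergence", RuntimeWarning)
    return IdentResult(estimate, float(best_f), converged, n_eval)


def make_identification_record(
    params: ThyroidParams | None = None,
    days: int = 90,
    staircase_ug: tuple[float, float, float] = (50.0, 80.0, 110.0),
) -> IdentData:
    """Noiseless synthetic identification record.

    Dosing is the three-month staircase (one month per level, one tablet
    per day).  The synthetic TSH sweeps smoothly over a range commensurate
    with the Michaelis constant so the saturating endogenous term is
    exercised through its nonlinear range; this is what makes km and vmax
    separately identifiable from a noiseless record.
    """
    if params is None:
        params = ThyroidParams(
            kexc=KEXC_NOMINAL,
            ksec=KSEC_NOMINAL,
            vmax=VMAX_NOMINAL,
            km=KM_NOMINAL,
            kreac=KREAC_NOMINAL,
        )
    t = np.arange(days * 24 + 1, dtype=float)
    dose = np.zeros_like(t)
    daily = t % 24 == 0
    month = np.minimum((t // (30 * 24)).astype(int), len(staircase_ug) - 1)
    dose[daily] = np.asarray(staircase_ug)[month[daily]]
    dose[-1] = 0.0
    tsh = (
        0.6 * params.km
        + 0.4 * params.km * np.sin(2 * np.pi * t / (30.0 * 24.0))
        + 0.15 * params.km * np.sin(2 * np.pi * t / (7.0 * 24.0))
    )
    tsh = np.maximum(tsh, 0.0)
    nz = dose > 0
    traj = simulate_plant(
        params,
        DoseSchedule(t[nz], dose[nz]),
        TshSignal(tsh),
        PlantState(0.0, 0.0),
        t,
    )
    return IdentData(t, dose, tsh, traj.y)
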