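"""Robust Schur stability of the closed dosing loop.

The closed-loop characteristic polynomial is the cubic
a(z) v(z) + b(z) mu(z), with the plant quantities A, p1, p2 re-evaluated
at each value of the uncertain oral-elimination rate kexc while the
controller stays fixed at its design point.  Schur stability of the whole
one-parameter family over an interval is established with the
Jury-Pavlidis conditions:

  (i)   the polynomial at one anchor point is Schur-stable;
  (ii)  p(1, q)  != 0 for all q in the interval;
  (iii) p(-1, q) != 0 for all q in the interval;
  (iv)  det(X(q) - Y(q)) != 0 for all q in the interval,

where X collects the leading and Y the trailing coefficients in banded
triangular/Hankel patterns of size (n-1).  Conditions (ii)-(iv) are
continuous in q and are verified on a dense sign-change-monitored grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .design import ControllerTF
from .model import ThyroidParams

__all__ = [
    "PolyFamily",
    "StabilityReport",
    "closed_loop_charpoly",
    "jury_matrices",
    "is_schur",
    "family_stability_check",
    "kexc_family",
]

#: Relative tolerance below which a boundary value counts as zero.
_ZERO_RTOL = 1e-12


@dataclass(frozen=True)
class PolyFamily:
    """Continuously parameterized polynomial family over an interval.

    ``poly_of`` maps the uncertain parameter q to ascending coefficients.
    """

    poly_of: Callable[[float], np.ndarray]
    q_min: float
    q_max: float
    q_nominal: float

    def __post_init__(self) -> None:
        if not self.q_min < self.q_max:
            raise ValueError("degenerate uncertainty interval")
        if not self.q_min <= self.q_nominal <= self.q_max:
            raise ValueError("nominal parameter outside the interval")


@dataclass(frozen=True)
class StabilityReport:
    """Per-condition outcome of the family check, with grid traces."""

    grid: np.ndarray
    p_at_1: np.ndarray
    p_at_minus1: np.ndarray
    det_s: np.ndarray
    cond_nominal_schur: bool
    cond_p1_nonzero: bool
    cond_pm1_nonzero: bool
    cond_det_nonzero: bool
    q_nominal: float = field(default=np.nan)

    @property
    def verdict(self) -> bool:
        return (
            self.cond_nominal_schur
            and self.cond_p1_nonzero
            and self.cond_pm1_nonzero
            and self.cond_det_nonzero
        )

    def to_json(self, path) -> None:
        payload = {
            "verdict": self.verdict,
            "conditions": {
                "nominal_schur": self.cond_nominal_schur,
                "p_at_1_nonzero": self.cond_p1_nonzero,
                "p_at_minus1_nonzero": self.cond_pm1_nonzero,
                "det_S_nonzero": self.cond_det_nonzero,
            },
            "interval": [float(self.grid[0]), float(self.grid[-1])],
            "q_nominal": None if np.isnan(self.q_nominal) else self.q_nominal,
            "grid_points": int(self.grid.size),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def traces_to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "kexc": self.grid,
                "p_at_1": self.p_at_1,
                "p_at_minus1": self.p_at_minus1,
                "det_S": self.det_s,
            }
        ).to_csv(path, index=False)


def closed_loop_charpoly(
    ctrl: ControllerTF,
    params: ThyroidParams,
    Td: float = 672.0,
    kr: float = 0.5,
) -> np.ndarray:
    """Characteristic cubic a(z) v(z) + b(z) mu(z), ascending coefficients.

    The reduced-form plant quantities are re-evaluated at ``params`` (in
    particular at its kexc), while the controller coefficients stay fixed.
    """
    if params.kexc == params.ksec:
        raise ValueError("kexc = ksec: plant gain undefined")
    q1 = np.exp(-params.ksec * Td)
    q2 = np.exp(-params.kexc * Td)
    A = params.kreac / (params.ksec - params.kexc)
    p1, p2 = q2 - q1, q1 + q2
    delta = 1.0 - kr
    g = A * p1 * kr
    a1, a0, b1, b0 = ctrl.a1, ctrl.a0, ctrl.b1, ctrl.b0
    return np.array(
        [
            a0 * p2 * delta + b0 * g,
            a1 * p2 * delta - a0 * (p2 + delta) + g * b1,
            a0 - a1 * (p2 + delta),
            a1,
        ]
    )


def jury_matrices(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The (n-1)x(n-1) matrices X (leading) and Y (trailing coefficients).

    For a cubic a3 z^3 + a2 z^2 + a1 z + a0:
    X = [[a3, a2], [0, a3]],  Y = [[0, a0], [a0, a1]].
    """
    p = np.asarray(p, dtype=float)
    n = p.size - 1
    if n < 2:
        raise ValueError("polynomial degree must be at least 2")
    if p[-1] == 0:
        raise ValueError("leading coefficient must be nonzero")
    X = np.zeros((n - 1, n - 1))
    Y = np.zeros((n - 1, n - 1))
    for i in range(n - 1):
        for j in range(n - 1):
            if j >= i:
                X[i, j] = p[n - (j - i)]
            k = i + j + 2 - n
            if 0 <= k <= n:
                Y[i, j] = p[k]
    return X, Y


def is_schur(p: np.ndarray) -> bool:
    """True iff all roots lie strictly inside the unit circle."""
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        return True
    roots = npoly.polyroots(p)
    return bool(np.max(np.abs(roots)) < 1.0)


def _nonzero_on_grid(values: np.ndarray, scale: float) -> bool:
    """No near-zero value and no sign change between adjacent grid points."""
    tol = _ZERO_RTOL * (1.0 + scale)
    if np.any(np.abs(values) <= tol):
        return False
    return bool(np.all(np.sign(values[1:]) == np.sign(values[:-1])))


def family_stability_check(
    family: PolyFamily, grid_size: int = 1001
) -> StabilityReport:
    """Evaluate the four Jury-Pavlidis conditions over the interval.

    Conditions (ii)-(iv) are continuous scalar traces of q; they are
    sampled on a uniform grid and fail on any near-zero value or sign
    change between neighbours.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    grid = np.linspace(family.q_min, family.q_max, grid_size)
    polys = [np.asarray(family.poly_of(q), dtype=float) for q in grid]
    scale = max(float(np.max(np.abs(p))) for p in polys)

    p1 = np.array([npoly.polyval(1.0, p) for p in polys])
    pm1 = np.array([npoly.polyval(-1.0, p) for p in polys])
    det_s = np.array([np.linalg.det(np.subtract(*jury_matrices(p))) for p in polys])

    report = StabilityReport(
        grid=grid,
        p_at_1=p1,
        p_at_minus1=pm1,
        det_s=det_s,
        cond_nominal_schur=is_schur(family.poly_of(family.q_nominal)),
        cond_p1_nonzero=_nonzero_on_grid(p1, scale),
        cond_pm1_nonzero=_nonzero_on_grid(pm1, scale),
        cond_det_nonzero=_nonzero_on_grid(det_s, scale),
        q_nominal=family.q_nominal,
    )
    return report


def kexc_family(
    ctrl: ControllerTF,
    params: ThyroidParams,
    kexc_min: float = 0.16,
    kexc_max: float = 0.36,
    Td: float = 672.0,
    kr: float = 0.5,
) -> PolyFamily:
    """The single-parameter family over the kexc uncertainty interval.

    ksec and the fitted constants are held at their values in ``params``;
    only kexc varies (bioavailability uncertainty maps onto the oral
    elimination path).  The interval is interpreted in 1/h.
    """

    def poly_of(kexc: float) -> np.ndarray:
        return closed_loop_charpoly(
            ctrl, params.replace(kexc=kexc), Td=Td, kr=kr
        )

    return PolyFamily(
        poly_of=poly_of, q_min=kexc_min, q_max=kexc_max, q_nominal=params.kexc
    )
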