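"""Discrete-time dosing loop: controller recursion plus dose shaping.

At each visit the patient's FT4 is measured (24-h mean of the hourly
output over the preceding day), the controller difference equation is
advanced, and the raw recommendation is shaped into a prescribable dose:
rate-clipped to at most ``max_step`` away from the previous dose,
quantized to the tablet quantum (nearest multiple, ties rounded down) and
saturated into [0, dose_max].  While the measurement lies inside the
euthyroid band and the reference has not changed, the previous dose is
held unchanged (the steady-state requirement): a non-integrating linear
loop with quantization would otherwise chatter around the band.

The controller itself was designed in the plant model's native units;
measured FT4 (ng/L) and the raw dose command (ug/day) are converted at
the loop boundary with the packaged calibration scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd

from .design import ControllerTF
from .units import DOSE_SCALE_UG, EUTHYROID_BAND, FT4_SCALE_NGL

__all__ = [
    "TherapyLimits",
    "ReferenceSchedule",
    "ControllerState",
    "SimulationResult",
    "controller_step",
    "shape_dose",
    "run_closed_loop",
]


@dataclass(frozen=True)
class TherapyLimits:
    """Prescription constraints.

    dose_max     : hard daily ceiling, ug/day (doses above require a
                   physician; 200 by default, well below the 500 ug adult
                   toxicity bound)
    dose_quantum : tablet increment, ug
    max_step     : largest per-visit dose change, ug (12.5-25 allowed)
    range_lo/hi  : euthyroid FT4 band, ng/L
    """

    dose_max: float = 200.0
    dose_quantum: float = 12.5
    max_step: float = 12.5
    range_lo: float = EUTHYROID_BAND[0]
    range_hi: float = EUTHYROID_BAND[1]

    def __post_init__(self) -> None:
        if not 0 < self.dose_quantum <= self.max_step <= self.dose_max:
            raise ValueError("require 0 < dose_quantum <= max_step <= dose_max")
        if not self.range_lo < self.range_hi:
            raise ValueError("require range_lo < range_hi")

    def in_band(self, ft4: float) -> bool:
        return self.range_lo <= ft4 <= self.range_hi


@dataclass(frozen=True)
class ReferenceSchedule:
    """Piecewise-constant FT4 reference r(t), ng/L.

    ``switch_times_h`` and ``values`` give the value holding from each
    switch time onward; the first switch time must be 0.
    """

    switch_times_h: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.switch_times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "switch_times_h", t)
        object.__setattr__(self, "values", v)
        if t.size == 0 or t.size != v.size:
            raise ValueError("need matching, nonempty switch times and values")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("switch times must start at 0 and increase")

    @classmethod
    def constant(cls, value: float) -> "ReferenceSchedule":
        return cls(np.array([0.0]), np.array([float(value)]))

    def value_at(self, t_h: float) -> float:
        idx = int(np.searchsorted(self.switch_times_h, t_h, side="right") - 1)
        return float(self.values[idx])


@dataclass
class ControllerState:
    """Recursion memory of R(z), the smoothing lag and the last dose."""

    e_prev: float = 0.0
    u_prev: float = 0.0
    u_smooth: float = 0.0
    prev_dose: float = 0.0
    visit: int = 0


class Patient(Protocol):
    """Anything the loop can treat: measure FT4, advance under a dose."""

    def measure(self) -> float: ...

    def advance(self, daily_dose_ug: float, hours: float) -> None: ...


def controller_step(
    state: ControllerState, ctrl: ControllerTF, r: float, y: float
) -> float:
    """One step of u_k = b1 e_k + b0 e_{k-1} - a0 u_{k-1} (monic a1 = 1)."""
    if ctrl.a1 != 1.0:
        raise ValueError("controller must be normalized to a1 = 1")
    e = r - y
    u = ctrl.b1 * e + ctrl.b0 * state.e_prev - ctrl.a0 * state.u_prev
    state.e_prev = e
    state.u_prev = u
    state.visit += 1
    return u


def _quantize(x: float, quantum: float) -> float:
    """Nearest multiple of ``quantum``; exact ties round down."""
    return math.ceil(x / quantum - 0.5) * quantum


def shape_dose(
    u: float,
    prev_dose: float,
    limits: TherapyLimits,
    y: float,
    in_band: bool,
) -> float:
    """Turn the raw controller output into a prescribable dose.

    In-band visits hold the previous dose.  Otherwise the raw command is
    rate-clipped to prev_dose +/- max_step, quantized to the tablet
    quantum and saturated into [0, dose_max].
    """
    if in_band:
        return prev_dose
    clipped = min(max(u, prev_dose - limits.max_step), prev_dose + limits.max_step)
    dose = _quantize(clipped, limits.dose_quantum)
    dose = min(max(dose, 0.0), limits.dose_max)
    # quantization may not widen the step beyond the clip bound
    dose = min(max(dose, prev_dose - limits.max_step), prev_dose + limits.max_step)
    return dose


@dataclass
class SimulationResult:
    """Closed-loop run log.

    ``visits`` has one row per visit (time_h, ft4_measured, reference,
    u_raw_ug, dose_ug); hourly FT4/TSH cover the whole run; the daily
    dose series mirrors what the patient actually took.
    """

    visits: pd.DataFrame
    hourly_ft4: np.ndarray
    hourly_tsh: np.ndarray
    daily_dose_ug: np.ndarray
    Td: float
    final_ft4: float = field(default=np.nan)

    @property
    def doses(self) -> np.ndarray:
        return self.visits["dose_ug"].to_numpy()

    def month_end_ft4(self) -> np.ndarray:
        """24-h mean FT4 at the end of each visit interval."""
        n_visits = len(self.visits)
        hours_per = int(self.Td)
        out = np.empty(n_visits)
        for k in range(n_visits):
            end = (k + 1) * hours_per + 24  # run-in offset
            out[k] = float(np.mean(self.hourly_ft4[end - 24 : end]))
        return out

    def to_csv(self, visits_path, hourly_path) -> None:
        self.visits.to_csv(visits_path, index=False)
        pd.DataFrame(
            {
                "time_h": np.arange(self.hourly_ft4.size, dtype=float),
                "ft4_ng_L": self.hourly_ft4,
                "tsh_mU_L": self.hourly_tsh,
            }
        ).to_csv(hourly_path, index=False)


def run_closed_loop(
    patient: Patient,
    ctrl: ControllerTF,
    refs: ReferenceSchedule,
    limits: TherapyLimits | None = None,
    Td: float = 672.0,
    duration_h: float = 12 * 672.0,
    ft4_scale: float = FT4_SCALE_NGL,
    dose_scale: float = DOSE_SCALE_UG,
    initial_dose: float = 0.0,
    kr: float = 0.5,
) -> SimulationResult:
    """Run the periodic-visit dosing loop against a patient simulator.

    Therapy starts from dose ``initial_dose`` (default 0, a new patient)
    with zero controller state, after a one-day run-in on that dose (the
    first measurement needs a day of history).  At each visit the raw
    controller output passes through the linear smoothing lag
    Krz(z) = kr/(z - (1 - kr)) -- the block the controller was designed
    around -- before the hard rate clip, quantizer and saturator decide
    the dose, which is then held constant daily until the next visit.  A patient
    continuing an established regimen (``initial_dose > 0``) who measures
    inside the band keeps that regimen from the first visit onward.
    ``duration_h`` must be a whole number of visit intervals.
    """
    if limits is None:
        limits = TherapyLimits()
    n_visits = duration_h / Td
    if abs(n_visits - round(n_visits)) > 1e-9:
        raise ValueError("duration must be a multiple of the visit interval Td")
    n_visits = int(round(n_visits))

    state = ControllerState(prev_dose=initial_dose)
    patient.advance(initial_dose, 24.0)  # run-in measurement day
    records = []
    last_ref: float | None = refs.value_at(0.0) if initial_dose > 0 else None
    for k in range(n_visits):
        t_visit = k * Td
        y = patient.measure()
        r = refs.value_at(t_visit)
        in_band = limits.in_band(y) and (last_ref is not None and r == last_ref)
        u_model = controller_step(state, ctrl, r / ft4_scale, y / ft4_scale)
        state.u_smooth = (1.0 - kr) * state.u_smooth + kr * u_model
        u_ug = state.u_smooth * dose_scale
        dose = shape_dose(u_ug, state.prev_dose, limits, y, in_band)
        state.prev_dose = dose
        last_ref = r
        records.append(
            {
                "time_h": t_visit,
                "ft4_measured": y,
                "reference": r,
                "u_raw_ug": u_ug,
                "dose_ug": dose,
            }
        )
        patient.advance(dose, Td)
    final = patient.measure()

    visits = pd.DataFrame.from_records(records)
    hourly_ft4 = np.asarray(getattr(patient, "ft4_history", []), dtype=float)
    hourly_tsh = np.asarray(getattr(patient, "tsh_history", []), dtype=float)
    daily = np.repeat(visits["dose_ug"].to_numpy(), int(Td // 24))
    return SimulationResult(
        visits=visits,
        hourly_ft4=hourly_ft4,
        hourly_tsh=hourly_tsh,
        daily_dose_ug=daily,
        Td=Td,
        final_ft4=final,
    )
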