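"""Synthetic hypothyroid virtual patients and cohort-level evaluation.

The virtual patient is a deliberately small surrogate for a full
physiological simulator: it wraps the two-state plant and adds only the
externally relevant behaviours of a treated Hashimoto patient -- a
circadian ripple on the displayed FT4, a TSH signal under negative
feedback (a decreasing Hill function of FT4, fed back into the
Michaelis-Menten drive with a one-hour lag), residual thyroid secretion
at 17% of a normal gland, and an oral LT4 bioavailability in
[0.64, 0.83].  Display units are calibrated once so that the nominal
patient on 100 ug/day settles at 13 ng/L FT4.

Cohorts are seeded and reproducible: patient ``i`` of master seed ``s``
is always the same draw.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, discretize_impulse_invariant, design_controller
from .loop import ReferenceSchedule, TherapyLimits, run_closed_loop
from .model import ThyroidParams
from .units import (
    BIOAVAILABILITY_RANGE,
    ENDOGENOUS_SCALE,
    FT4_SCALE_NGL,
    KM_NOMINAL,
    KREAC_NOMINAL,
    KSEC_NOMINAL,
    KEXC_NOMINAL,
    MOLAR_MASS_LT4,
    TSH_HALF_SAT_NGL,
    TSH_HILL,
    TSH_MAX_NOMINAL,
    VMAX_NOMINAL,
)

__all__ = [
    "VirtualPatient",
    "CohortConfig",
    "CohortSummary",
    "nominal_patient",
    "generate_patient",
    "patient_output",
    "run_cohort",
]


def nominal_params() -> ThyroidParams:
    return ThyroidParams(
        kexc=KEXC_NOMINAL,
        ksec=KSEC_NOMINAL,
        vmax=VMAX_NOMINAL,
        km=KM_NOMINAL,
        kreac=KREAC_NOMINAL,
    )


@dataclass
class VirtualPatient:
    """Hourly-stepped virtual hypothyroid patient.

    The smooth FT4 core is the exact plant propagation; the displayed
    FT4 multiplies it by ``1 + amplitude * sin(2 pi t / 24 + phase)``.
    TSH follows ``tsh_max * h^n / (h^n + FT4^n)`` with half-saturation
    ``h`` and Hill exponent ``n`` (strictly decreasing in FT4), applied
    to the endogenous drive at the next hourly step.
    """

    params: ThyroidParams = field(default_factory=nominal_params)
    bioavailability: float = 0.83
    residual_secretion_frac: float = 0.17
    circadian_amplitude: float = 0.05
    circadian_phase: float = 0.0
    tsh_max: float = TSH_MAX_NOMINAL
    tsh_half_sat: float = TSH_HALF_SAT_NGL
    tsh_hill: float = TSH_HILL
    ft4_scale: float = FT4_SCALE_NGL
    endogenous_scale: float = ENDOGENOUS_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = BIOAVAILABILITY_RANGE
        if not lo <= self.bioavailability <= hi:
            raise ValueError(f"bioavailability must lie in [{lo}, {hi}]")
        if not 0 <= self.circadian_amplitude <= 0.2:
            raise ValueError("circadian amplitude must lie in [0, 0.2]")
        self.reset()

    def reset(self) -> None:
        """Return to the untreated steady state with empty history.

        A chronic hypothyroid patient presents at their untreated
        equilibrium, so the FT4/TSH fixed point of the residual-secretion
        feedback loop is solved here rather than starting from zero.
        """
        p = self.params
        self._e1 = math.exp(-p.kexc)
        self._e2 = math.exp(-p.ksec)
        self._cross = p.kreac * (self._e1 - self._e2) / (p.ksec - p.kexc)
        self._x1 = 0.0
        self._t = 0
        tsh = self.tsh_max
        x2 = 0.0
        hs = self.tsh_half_sat**self.tsh_hill
        for _ in range(200):  # fixed-point iteration, converges geometrically
            drive = (
                self.residual_secretion_frac
                * self.endogenous_scale
                * p.vmax
                * tsh
                / (p.km + tsh)
            )
            x2 = drive / p.ksec
            ft4 = x2 * self.ft4_scale
            tsh = self.tsh_max * hs / (hs + ft4**self.tsh_hill)
        self._x2 = x2
        self._tsh = tsh
        self.ft4_history: list[float] = []
        self.tsh_history: list[float] = []

    def _display_ft4(self) -> float:
        ripple = 1.0 + self.circadian_amplitude * math.sin(
            2.0 * math.pi * self._t / 24.0 + self.circadian_phase
        )
        return self._x2 * self.ft4_scale * ripple

    def advance(self, daily_dose_ug: float, hours: float) -> None:
        """Step forward hourly under one tablet of ``daily_dose_ug`` per day."""
        p = self.params
        impulse = daily_dose_ug * self.bioavailability / MOLAR_MASS_LT4
        n = int(round(hours))
        hs = self.tsh_half_sat**self.tsh_hill
        for _ in range(n):
            if self._t % 24 == 0:
                self._x1 += impulse
            drive = (
                self.residual_secretion_frac
                * self.endogenous_scale
                * p.vmax
                * self._tsh
                / (p.km + self._tsh)
            )
            x2_new = (
                self._x2 * self._e2
                + drive / p.ksec * (1.0 - self._e2)
                + self._x1 * self._cross
            )
            self._x1 *= self._e1
            self._x2 = x2_new
            self._t += 1
            ft4 = self._display_ft4()
            self._tsh = self.tsh_max * hs / (hs + ft4**self.tsh_hill)
            self.ft4_history.append(ft4)
            self.tsh_history.append(self._tsh)

    def measure(self) -> float:
        """24-h mean of the displayed FT4 over the preceding day, ng/L."""
        if len(self.ft4_history) < 24:
            raise RuntimeError("need at least 24 h of history before measuring")
        return float(np.mean(self.ft4_history[-24:]))

    def parameters_dict(self) -> dict:
        p = self.params
        return {
            "kexc": p.kexc,
            "ksec": p.ksec,
            "kreac": p.kreac,
            "km": p.km,
            "vmax": p.vmax,
            "bioavailability": self.bioavailability,
            "circadian_amplitude": self.circadian_amplitude,
            "circadian_phase": self.circadian_phase,
            "seed": self.seed,
        }


def nominal_patient(**overrides) -> VirtualPatient:
    """The calibration-anchor patient (nominal plant, 83% absorption)."""
    return VirtualPatient(**overrides)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sampling and shared-therapy settings."""

    n_patients: int = 50
    master_seed: int = 42
    kexc_range: tuple[float, float] = (0.16, 0.36)
    half_life_days_range: tuple[float, float] = (9.0, 10.0)
    log_cv: float = 0.30
    bioavailability_range: tuple[float, float] = BIOAVAILABILITY_RANGE
    circadian_amplitude: float = 0.05
    reference_ngl: float = 13.0
    months: int = 12
    limits: TherapyLimits = field(default_factory=TherapyLimits)
    design: DesignSpec = field(default_factory=DesignSpec)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("cohort needs at least one patient")


def generate_patient(config: CohortConfig, index: int) -> VirtualPatient:
    """Deterministic patient draw under (master seed, index).

    kexc ~ U(kexc_range); T4 half-life ~ U(9, 10) days -> ksec; the three
    fitted constants are log-normal around their nominal values with the
    configured coefficient of variation (median at the nominal value);
    bioavailability ~ U(0.64, 0.83); circadian phase ~ U(0, 2 pi).
    """
    rng = np.random.default_rng([config.master_seed, index])
    kexc = rng.uniform(*config.kexc_range)
    half_life = rng.uniform(*config.half_life_days_range)
    ksec = math.log(2.0) / (half_life * 24.0)
    sigma = math.sqrt(math.log(1.0 + config.log_cv**2))
    kreac = KREAC_NOMINAL * math.exp(rng.normal(0.0, sigma))
    vmax = VMAX_NOMINAL * math.exp(rng.normal(0.0, sigma))
    km = KM_NOMINAL * math.exp(rng.normal(0.0, sigma))
    bio = rng.uniform(*config.bioavailability_range)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    return VirtualPatient(
        params=ThyroidParams(kexc=kexc, ksec=ksec, vmax=vmax, km=km, kreac=kreac),
        bioavailability=bio,
        circadian_amplitude=config.circadian_amplitude,
        circadian_phase=phase,
        seed=index,
    )


def patient_output(
    patient: VirtualPatient, daily_doses_ug, duration_h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Hourly FT4 and TSH of a (reset) patient under a daily dose series.

    ``daily_doses_ug`` is a scalar (constant regimen) or a per-day
    sequence; it must cover ``duration_h``.
    """
    patient.reset()
    n_days = int(math.ceil(duration_h / 24.0))
    doses = np.broadcast_to(
        np.asarray(daily_doses_ug, dtype=float), (n_days,)
    ) if np.ndim(daily_doses_ug) == 0 else np.asarray(daily_doses_ug, dtype=float)
    if doses.size < n_days:
        raise ValueError("dose series shorter than the requested duration")
    remaining = int(round(duration_h))
    for day in range(n_days):
        h = min(24, remaining)
        patient.advance(float(doses[day]), h)
        remaining -= h
    return np.asarray(patient.ft4_history), np.asarray(patient.tsh_history)


@dataclass
class CohortSummary:
    """Monthly cross-patient statistics plus per-patient endpoints."""

    months: np.ndarray
    ft4_mean: np.ndarray
    ft4_std: np.ndarray
    dose_mean: np.ndarray
    dose_std: np.ndarray
    final_ft4: np.ndarray
    final_dose: np.ndarray
    failures: list[int]
    patients: list[dict]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "month": self.months,
                "ft4_mean": self.ft4_mean,
                "ft4_std": self.ft4_std,
                "dose_mean": self.dose_mean,
                "dose_std": self.dose_std,
            }
        ).to_csv(path, index=False)

    def patients_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.patients, fh, indent=2)


def run_cohort(config: CohortConfig) -> CohortSummary:
    """Treat every generated patient with the shared nominal controller.

    The controller is designed once from the nominal plant; each patient
    is run through the closed loop for ``config.months`` monthly visits
    at the shared constant reference.  Individual failures are recorded
    in the summary instead of aborting the cohort.
    """
    plant = discretize_impulse_invariant(
        nominal_params(), Td=config.design.Td,
        threshold=config.design.neglect_threshold,
    )
    ctrl = design_controller(plant, config.design)
    refs = ReferenceSchedule.constant(config.reference_ngl)
    Td = config.design.Td

    ft4 = np.full((config.n_patients, config.months), np.nan)
    dose = np.full((config.n_patients, config.months), np.nan)
    failures: list[int] = []
    patients: list[dict] = []
    for i in range(config.n_patients):
        patient = generate_patient(config, i)
        patients.append(patient.parameters_dict())
        try:
            result = run_closed_loop(
                patient,
                ctrl,
                refs,
                limits=config.limits,
                Td=Td,
                duration_h=config.months * Td,
            )
        except Exception:  # noqa: BLE001 - cohort robustness by contract
            failures.append(i)
            continue
        ft4[i] = result.month_end_ft4()
        dose[i] = result.doses

    ok = ~np.isnan(ft4[:, 0])
    months = np.arange(1, config.months + 1)
    return CohortSummary(
        months=months,
        ft4_mean=np.nanmean(ft4, axis=0),
        ft4_std=np.nanstd(ft4, axis=0),
        dose_mean=np.nanmean(dose, axis=0),
        dose_std=np.nanstd(dose, axis=0),
        final_ft4=ft4[ok, -1],
        final_dose=dose[ok, -1],
        failures=failures,
        patients=patients,
    )
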