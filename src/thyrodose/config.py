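"""Run configuration: schema, defaults, validation and (de)serialization.

Configs are JSON or YAML with nested sections mirroring the package's
domain types.  Unknown keys are rejected by name; omitted keys take the
packaged defaults, so an empty file is a complete nominal configuration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .units import EUTHYROID_BAND, KEXC_NOMINAL, KM_NOMINAL, KREAC_NOMINAL, \
    KSEC_NOMINAL, VMAX_NOMINAL, kreac_from_ppm

__all__ = ["RunConfig", "load_config"]

SCHEMA_VERSION = 1

#: Daily doses above this are associated with life-threatening toxicity
#: in adults; configs may exceed the default ceiling but are warned.
ADULT_TOXICITY_BOUND_UG = 500.0


@dataclass
class ModelSection:
    kexc: float = KEXC_NOMINAL
    ksec: float = KSEC_NOMINAL
    kreac_ppm: float = KREAC_NOMINAL
    km: float = KM_NOMINAL
    vmax: float = VMAX_NOMINAL
    ppm_interpretation: str = "raw"

    @property
    def kreac(self) -> float:
        return kreac_from_ppm(self.kreac_ppm, self.ppm_interpretation)


@dataclass
class DesignSection:
    Td: float = 672.0
    z0: float = -0.01
    kr: float = 0.5
    neglect_threshold: float = 1e-6


@dataclass
class LimitsSection:
    dose_max: float = 200.0
    dose_quantum: float = 12.5
    max_step: float = 12.5
    range_lo: float = EUTHYROID_BAND[0]
    range_hi: float = EUTHYROID_BAND[1]


@dataclass
class ReferenceSection:
    switch_times_h: list = field(default_factory=lambda: [0.0])
    values: list = field(default_factory=lambda: [13.0])


@dataclass
class StabilitySection:
    kexc_min: float = 0.16
    kexc_max: float = 0.36
    grid_size: int = 1001


@dataclass
class SimulateSection:
    months: int = 12


@dataclass
class CohortSection:
    n_patients: int = 50
    master_seed: int = 42
    months: int = 12
    reference_ngl: float = 13.0
    log_cv: float = 0.30
    circadian_amplitude: float = 0.05


@dataclass
class RunConfig:
    """Validated, fully defaulted configuration for every subcommand."""

    model: ModelSection = field(default_factory=ModelSection)
    design: DesignSection = field(default_factory=DesignSection)
    limits: LimitsSection = field(default_factory=LimitsSection)
    reference: ReferenceSection = field(default_factory=ReferenceSection)
    stability: StabilitySection = field(default_factory=StabilitySection)
    simulate: SimulateSection = field(default_factory=SimulateSection)
    cohort: CohortSection = field(default_factory=CohortSection)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.limits.dose_max > 200.0:
            warnings.warn(
                f"dose_max = {self.limits.dose_max} ug exceeds the default "
                f"200 ug ceiling; daily doses above "
                f"{ADULT_TOXICITY_BOUND_UG:.0f} ug may produce serious "
                "toxicity in adults",
                UserWarning,
            )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError("configuration root must be a mapping")
        kwargs = {}
        section_types = {f.name: f.type for f in fields(cls)}
        sections = {
            "model": ModelSection,
            "design": DesignSection,
            "limits": LimitsSection,
            "reference": ReferenceSection,
            "stability": StabilitySection,
            "simulate": SimulateSection,
            "cohort": CohortSection,
        }
        for key, value in data.items():
            if key == "schema_version":
                kwargs[key] = int(value)
                continue
            if key not in sections:
                raise ValueError(f"unknown configuration section: {key!r}")
            sec_cls = sections[key]
            known = {f.name for f in fields(sec_cls)}
            for sub in value or {}:
                if sub not in known:
                    raise ValueError(
                        f"unknown key {sub!r} in section {key!r} "
                        f"(known: {sorted(known)})"
                    )
            kwargs[key] = sec_cls(**(value or {}))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML configuration file.

    An empty file yields the all-defaults configuration.  JSON is a
    subset of YAML, so both parse through the same loader.
    """
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        # not JSON: fall back to YAML (which would misread JSON's bare
        # scientific notation like 1e-06 as a string)
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse configuration {path}: {exc}") from exc
    return RunConfig.from_dict(data)
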