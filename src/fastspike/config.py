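"""Pipeline configuration: one YAML document drives every knob.

Sections mirror the package's configuration dataclasses; unknown keys
anywhere are an error listing the offenders, so typos never silently
fall back to defaults.  The resolved configuration is echoed verbatim
into every results directory, making runs self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import FastSpikingClassifier
from .intrinsic import FeatureConfig
from .simulate import SimProtocol
from .synaptic import DetectorConfig
from .synth import CohortSpec, SynapticScenario, default_cohort_profile

__all__ = ["PipelineConfig"]


def _dataclass_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    return data


_CLASSIFIER_KEYS = {"half_width_ms", "max_freq_hz", "fahp_mv", "sfa"}
_COHORT_KEYS = {"n_cells", "fs_fraction", "noise_sd"}
_SIM_KEYS = {"models", "gbar_values"}


@dataclass
class PipelineConfig:
    """Resolved configuration for all pipeline commands."""

    seed: int = 0
    features: dict = field(default_factory=dict)     # FeatureConfig overrides
    classifier: dict = field(default_factory=dict)   # FastSpikingClassifier cutoffs
    detector: dict = field(default_factory=dict)     # DetectorConfig overrides
    protocol: dict = field(default_factory=dict)     # SimProtocol overrides
    scenario: dict = field(default_factory=dict)     # SynapticScenario overrides
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    simulate: dict = field(default_factory=dict)     # models, gbar_values
    pulse_times: list = field(default_factory=list)  # evoked-mode schedule, ms

    def __post_init__(self) -> None:
        _dataclass_section(FeatureConfig, self.features, "features")
        _dataclass_section(DetectorConfig, self.detector, "detector")
        _dataclass_section(SimProtocol, self.protocol, "protocol")
        _dataclass_section(SynapticScenario, self.scenario, "scenario")
        for section, valid in (("classifier", _CLASSIFIER_KEYS),
                               ("cohort", _COHORT_KEYS),
                               ("simulate", _SIM_KEYS)):
            unknown = set(getattr(self, section)) - valid
            if unknown:
                raise ValueError(f"unknown keys in section {section!r}: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    # -- builders -------------------------------------------------------------
    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(**self.features)

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(**self.detector)

    def sim_protocol(self) -> SimProtocol:
        kw = dict(self.protocol)
        if "step_currents" in kw:
            kw["step_currents"] = tuple(float(c) for c in kw["step_currents"])
        return SimProtocol(**kw)

    def classifier_(self) -> FastSpikingClassifier:
        return FastSpikingClassifier(**self.classifier).fit()

    def synaptic_scenario(self) -> SynapticScenario:
        kw = dict(self.scenario)
        kw.setdefault("seed", self.seed)
        return SynapticScenario(**kw)

    def cohort_spec(self) -> CohortSpec:
        kw = dict(self.cohort)
        kw.setdefault("n_cells", 20)
        kw.setdefault("fs_fraction", 0.3)
        return CohortSpec(seed=self.seed, profile=default_cohort_profile(), **kw)
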