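"""Validated pipeline configuration loaded from JSON or YAML.

Unknown keys are rejected outright: a typo in a config file should fail
loudly before any PDF is touched, not silently fall back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from pdfecg.calibrate import CalibrationParams, FilterSpec

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalibrationConfig(_Strict):
    mm_per_second: float = 25.0
    mm_per_mV: float = 10.0
    sample_spacing_mm: float = 0.05
    sampling_rate_hz: float = 500.0
    amplitude_quantum_uV: float = 4.88
    strip_seconds: float = 2.5

    def to_params(self) -> CalibrationParams:
        return CalibrationParams(
            mm_per_second=self.mm_per_second,
            mm_per_mV=self.mm_per_mV,
            sample_spacing_mm=self.sample_spacing_mm,
            sampling_rate_hz=self.sampling_rate_hz,
            amplitude_quantum_uV=self.amplitude_quantum_uV,
            strip_seconds=self.strip_seconds,
        )


class FilterConfig(_Strict):
    enabled: bool = False            # vendor pages are pre-filtered
    hp_cutoff_hz: float | None = 0.5
    lp_cutoff_hz: float | None = 150.0
    notch_hz: float | None = None

    def to_spec(self) -> FilterSpec | None:
        if not self.enabled:
            return None
        return FilterSpec(hp_cutoff_hz=self.hp_cutoff_hz,
                          lp_cutoff_hz=self.lp_cutoff_hz,
                          notch_hz=self.notch_hz)


class ClassifierConfig(_Strict):
    C: float = 1.0
    kernel: str = "rbf"
    n_runs: int = 100
    seed: int = 0
    decimate: int = 4


class PipelineConfig(_Strict):
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    rate_convention: str = "intervals"
    reference_lead: str = "II"
    output_dir: str = "out"
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    """Read a config file (.json / .yaml / .yml) into a validated object."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.model_validate(data or {})
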