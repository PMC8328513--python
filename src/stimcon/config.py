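"""Run configuration: a validated, file-backed view of the model defaults.

The default configuration reproduces the reference parameterisation exactly:
4 Hz oscillation of unit amplitude with its peak anchored to the first
word's input maximum, base inhibition −0.2 with a 20 ms excitation window
and 100 ms recovery, threshold 1, 125 ms linear ramps at a 250 ms SOA, and
feedback at 0.9 cycles delay, 0.01/ms decay and gain 1.5.  The random seed
is consumed only by the fixture generators — the simulator itself is
deterministic.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .core import (
    FeedbackParams,
    InhibitionParams,
    ModelParams,
    OscillationParams,
)

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OscillationConfig(_Strict):
    amplitude: float = 1.0
    frequency_hz: float = 4.0

    @field_validator("amplitude")
    @classmethod
    def _amp(cls, v):
        if v < 0:
            raise ValueError("amplitude must be non-negative")
        return v

    @field_validator("frequency_hz")
    @classmethod
    def _freq(cls, v):
        if v <= 0:
            raise ValueError("frequency must be positive")
        return v


class InhibitionConfig(_Strict):
    base_inhib: float = -0.2
    excitation_window_ms: float = 20.0
    recovery_ms: float = 100.0
    activation_threshold: float = 1.0


class FeedbackConfig(_Strict):
    delay_cycles: float = 0.9
    decay_per_ms: float = 0.01
    gain: float = 1.5


class StimulusConfig(_Strict):
    words: list[str] = ["I", "eat", "cake"]
    soa_ms: float = 250.0
    intensities: Union[float, list[float]] = 1.0
    shifts_ms: Union[float, list[float]] = 0.0
    shape: Literal["ramp", "gaussian"] = "ramp"
    ramp_duration_ms: float = 125.0
    gaussian_sd_ms: float = 42.0


class RunConfig(_Strict):
    oscillation: OscillationConfig = OscillationConfig()
    inhibition: InhibitionConfig = InhibitionConfig()
    feedback: FeedbackConfig = FeedbackConfig()
    stimulus: StimulusConfig = StimulusConfig()
    dt_ms: float = 1.0
    seed: int = 0
    output_dir: str = "."

    def model_params(self, phase_rad: float = 0.0) -> ModelParams:
        """Materialise the validated blocks as simulator parameters."""
        return ModelParams(
            oscillation=OscillationParams(
                self.oscillation.amplitude, self.oscillation.frequency_hz, phase_rad
            ),
            inhibition=InhibitionParams(
                self.inhibition.base_inhib,
                self.inhibition.excitation_window_ms,
                self.inhibition.recovery_ms,
                self.inhibition.activation_threshold,
            ),
            feedback=FeedbackParams(
                self.feedback.delay_cycles,
                self.feedback.decay_per_ms,
                self.feedback.gain,
            ),
            dt_ms=self.dt_ms,
        )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML or JSON config; an empty file yields all defaults.

    Unknown keys and invariant violations raise a descriptive
    ``ValueError`` (pydantic validation error).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml", ""} else json.loads(text or "{}")
    if data is None:
        data = {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    data = config.model_dump()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=1), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
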