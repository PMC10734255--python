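"""Temperature forcing scenarios: constant, daily fluctuation, and heatwave.

Scenarios are defined in user units (degrees Celsius, days) and evaluated in
kelvin for the model core. The daily fluctuation is sinusoidal with period
one day, sine phase (temperature equals the mean at t = 0 and rises), and
``amplitude`` is the half-range: a mean of 12 degC with amplitude 4 degC
oscillates between 8 and 16 degC. A heatwave is a rectangular additive
offset of ``hw_intensity`` applied over the half-open window
``[hw_start, hw_start + hw_duration)`` on top of the fluctuating baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .parameters import CELSIUS_OFFSET

KINDS = ("constant", "daily_fluctuation", "heatwave")

_REQUIRED_KEYS = {
    "constant": {"kind", "base_mean", "t_end"},
    "daily_fluctuation": {"kind", "base_mean", "amplitude", "t_end"},
    "heatwave": {
        "kind",
        "base_mean",
        "amplitude",
        "hw_start",
        "hw_duration",
        "hw_intensity",
        "t_end",
    },
}
_OPTIONAL_KEYS = {
    "constant": set(),
    "daily_fluctuation": {"phase"},
    "heatwave": {"phase"},
}


class ScenarioConfigError(ValueError):
    """Raised for an invalid or inconsistent scenario definition."""


@dataclass(frozen=True)
class TemperatureScenario:
    """Time-dependent temperature forcing.

    Parameters
    ----------
    kind : {"constant", "daily_fluctuation", "heatwave"}
        Scenario category.
    base_mean : float
        Mean temperature of the baseline, degrees Celsius.
    amplitude : float
        Half-range of the daily sinusoid, degrees Celsius (0 for constant).
    hw_start, hw_duration : float
        Heatwave window start and length, days (heatwave only).
    hw_intensity : float
        Additive temperature offset during the heatwave, degrees Celsius.
    t_end : float
        End of the scenario domain, days.
    phase : float
        Phase offset of the sinusoid in days (0 = sine phase, rising
        through the mean at t = 0).
    """

    kind: str
    base_mean: float
    t_end: float
    amplitude: float = 0.0
    hw_start: float = 0.0
    hw_duration: float = 0.0
    hw_intensity: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ScenarioConfigError(
                f"unknown scenario kind {self.kind!r}; expected one of {KINDS}"
            )
        if not (self.t_end > 0):
            raise ScenarioConfigError(f"t_end must be > 0, got {self.t_end!r}")
        if self.amplitude < 0:
            raise ScenarioConfigError("amplitude must be >= 0")
        if self.kind == "heatwave":
            if self.hw_duration < 0 or self.hw_intensity < 0 or self.hw_start < 0:
                raise ScenarioConfigError(
                    "heatwave start, duration and intensity must be >= 0"
                )
            if self.hw_start + self.hw_duration > self.t_end:
                raise ScenarioConfigError(
                    "heatwave window exceeds scenario end: "
                    f"{self.hw_start} + {self.hw_duration} > {self.t_end}"
                )

    # -- evaluation ---------------------------------------------------------

    def temperature_celsius(self, t):
        """Temperature in degrees Celsius at time(s) ``t`` (days)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.t_end):
            raise ValueError(
                f"time outside scenario domain [0, {self.t_end}]: {t!r}"
            )
        temp = np.full_like(t, self.base_mean, dtype=float)
        if self.kind in ("daily_fluctuation", "heatwave") and self.amplitude > 0:
            temp = temp + self.amplitude * np.sin(2.0 * np.pi * (t - self.phase))
        if self.kind == "heatwave" and self.hw_duration > 0:
            in_window = (t >= self.hw_start) & (t < self.hw_start + self.hw_duration)
            temp = np.where(in_window, temp + self.hw_intensity, temp)
        return temp if temp.ndim else float(temp)

    def evaluate(self, t):
        """Temperature in kelvin at time(s) ``t`` (days)."""
        temp = self.temperature_celsius(t)
        return temp + CELSIUS_OFFSET

    @property
    def is_constant(self) -> bool:
        """True when the forcing is time-invariant over the whole domain."""
        if self.kind == "constant":
            return True
        if self.amplitude > 0:
            return False
        return not (self.kind == "heatwave" and self.hw_duration > 0 and self.hw_intensity > 0)

    @property
    def max_celsius(self) -> float:
        """Upper bound of the forcing over the domain, degrees Celsius."""
        peak = self.base_mean + self.amplitude
        if self.kind == "heatwave" and self.hw_duration > 0:
            peak += self.hw_intensity
        return peak


def scenario_from_config(document: Union[dict, str, Path]) -> TemperatureScenario:
    """Build a scenario from a config mapping or a YAML/JSON file path.

    Unknown keys and missing required keys raise :class:`ScenarioConfigError`.
    """
    if isinstance(document, (str, Path)):
        text = Path(document).read_text()
        document = yaml.safe_load(text)
    if not isinstance(document, dict):
        raise ScenarioConfigError(
            f"scenario config must be a mapping, got {type(document).__name__}"
        )
    kind = document.get("kind")
    if kind not in KINDS:
        raise ScenarioConfigError(
            f"scenario config needs a 'kind' in {KINDS}, got {kind!r}"
        )
    keys = set(document)
    required = _REQUIRED_KEYS[kind]
    allowed = required | _OPTIONAL_KEYS[kind]
    missing = required - keys
    if missing:
        raise ScenarioConfigError(f"missing required key(s) {sorted(missing)} for kind {kind!r}")
    unknown = keys - allowed
    if unknown:
        raise ScenarioConfigError(f"unknown key(s) {sorted(unknown)} for kind {kind!r}")
    values = {k: (v if k == "kind" else float(v)) for k, v in document.items()}
    for key, value in values.items():
        if key != "kind" and not math.isfinite(value):
            raise ScenarioConfigError(f"key {key!r} must be finite, got {value!r}")
    return TemperatureScenario(**values)


def scenario_to_config(scenario: TemperatureScenario) -> dict:
    """Serialize a scenario to a plain mapping that round-trips losslessly."""
    full = asdict(scenario)
    keep = _REQUIRED_KEYS[scenario.kind] | _OPTIONAL_KEYS[scenario.kind]
    out = {k: full[k] for k in ("kind", "base_mean", "amplitude", "hw_start",
                                "hw_duration", "hw_intensity", "t_end", "phase")
           if k in keep}
    if out.get("phase") == 0.0:
        out.pop("phase", None)
    return out


def write_scenario(scenario: TemperatureScenario, path: Union[str, Path]) -> None:
    """Write a scenario config to a YAML (or, by extension, JSON) file."""
    path = Path(path)
    config = scenario_to_config(scenario)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
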