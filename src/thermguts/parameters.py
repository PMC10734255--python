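"""Model parameters for the temperature damage model.

Five constants govern the model: the dominant rate ``k_T`` controlling both
damage accrual and repair kinetics, the temperature scaling coefficient
``alpha``, the critical temperature ``T_c`` above which damage accumulates,
the background hazard rate ``h_b``, and the killing rate ``b_T`` converting
above-baseline damage into hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature in degrees Celsius to kelvin."""
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    """Convert a temperature in kelvin to degrees Celsius."""
    return t_kelvin - CELSIUS_OFFSET


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the temperature damage model.

    Attributes
    ----------
    k_T : float
        Dominant rate for damage accrual and repair, per day.
    alpha : float
        Scaling parameter for the temperature effect, per kelvin.
    T_c : float
        Critical temperature where damage accumulation starts, kelvin.
    h_b : float
        Background hazard rate, per day.
    b_T : float
        Killing rate converting damage into hazard, per day.
    """

    k_T: float
    alpha: float
    T_c: float
    h_b: float
    b_T: float

    def __post_init__(self) -> None:
        for name in ("k_T", "alpha", "T_c", "h_b", "b_T"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value!r}")
        if self.T_c <= 0:
            raise ValueError(f"T_c is an absolute temperature and must be > 0, got {self.T_c!r}")

    def with_(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return asdict(self)


#: Reference calibration for Gammarus pulex acute thermal stress
#: (constant 10/15/20/25 degC survival assays, T_c fixed at 11 degC).
GAMMARUS_PULEX_PARAMS = ModelParameters(
    k_T=5.76,       # per day
    alpha=0.033,    # per kelvin
    T_c=284.15,     # kelvin (11 degC)
    h_b=0.004,      # per day
    b_T=0.127,      # per day
)
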