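"""Damage dynamics, hazard and survival under an arbitrary temperature forcing.

The damage state ``D_T`` is dimensionless with ``D_T = 1`` meaning "no
damage". It relaxes as a first-order process with dominant rate ``k_T``
towards a temperature-dependent accrual target::

    dD/dt = k_T * (F(T) - D),    F(T) = max(1, exp(alpha * (T - T_c)))

so above the critical temperature ``T_c`` damage accrues exponentially with
temperature, and below ``T_c`` existing damage is repaired back towards the
baseline 1 (never below it). Damage above the baseline produces a hazard
``h_T = b_T * (D - 1)``; together with the background hazard ``h_b`` the
survival probability is the exponential of the negative cumulative hazard::

    S_T(t) = exp( - integral_0^t [ b_T * (D(s) - 1) + h_b ] ds )

The cumulative hazard is co-integrated with the damage ODE as an auxiliary
state, avoiding post-hoc quadrature error. For constant forcing the linear
ODE has a closed form, exposed here as an analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ModelParameters
from .scenarios import TemperatureScenario

#: Internal solver resolution for time-varying forcings: at least 48 points
#: per day so that daily sinusoids and rectangular heatwave edges are resolved.
MAX_STEP_FLUCTUATING = 1.0 / 48.0

_RTOL = 1e-8
_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to integrate a scenario."""


# ---------------------------------------------------------------------------
# pointwise model functions
# ---------------------------------------------------------------------------

def accrual_target(T, params: ModelParameters):
    """Damage accrual target F(T) = max(1, exp(alpha * (T - T_c))).

    Above ``T_c`` the target grows exponentially with temperature; at or
    below ``T_c`` it is clamped at the no-damage baseline 1, so existing
    damage relaxes back to 1. Continuous in ``T`` at ``T = T_c``.

    Parameters
    ----------
    T : float or array
        Absolute temperature, kelvin.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError(f"temperature must be finite, got {T!r}")
    if np.any(T <= 0):
        raise ValueError(f"temperature must be > 0 K, got {T!r}")
    target = np.exp(params.alpha * np.maximum(T - params.T_c, 0.0))
    return target if target.ndim else float(target)


def damage_rate(D, T, params: ModelParameters):
    """Instantaneous damage rate dD/dt = k_T * (F(T) - D), per day.

    Positive while the accrual target exceeds the current damage (accrual),
    negative when damage exceeds the target (repair).
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 1):
        raise ValueError(f"damage must be >= 1 (1 means no damage), got {D!r}")
    rate = params.k_T * (accrual_target(T, params) - D)
    return rate if rate.ndim else float(rate)


def hazard_from_damage(D, params: ModelParameters):
    """Temperature hazard h_T = b_T * max(0, D - 1), per day.

    The hazard threshold is the no-damage level ``D = 1``: only damage in
    excess of the baseline kills. Background hazard is added separately.
    """
    D = np.asarray(D, dtype=float)
    hazard = params.b_T * np.maximum(D - 1.0, 0.0)
    return hazard if hazard.ndim else float(hazard)


# ---------------------------------------------------------------------------
# closed forms for constant forcing (analytic oracles)
# ---------------------------------------------------------------------------

def constant_damage_closed_form(T: float, t, params: ModelParameters):
    """Damage at time ``t`` under constant forcing: F + (1 - F) exp(-k_T t)."""
    t = np.asarray(t, dtype=float)
    F = accrual_target(T, params)
    D = F + (1.0 - F) * np.exp(-params.k_T * t)
    return D if D.ndim else float(D)


def constant_survival_closed_form(T: float, t, params: ModelParameters):
    """Survival at time ``t`` under constant forcing.

    The cumulative temperature hazard integrates analytically::

        integral_0^t b_T (D(s) - 1) ds = b_T (F - 1) [ t - (1 - e^{-k_T t}) / k_T ]

    to which the background contribution ``h_b * t`` is added.
    """
    t = np.asarray(t, dtype=float)
    F = accrual_target(T, params)
    k = params.k_T
    if k > 0:
        lag = -np.expm1(-k * t) / k  # (1 - e^{-kt}) / k, stable for small k*t
    else:
        lag = np.asarray(t, dtype=float)  # k -> 0: damage never moves off 1
    cum_hazard = params.b_T * (F - 1.0) * (t - lag) + params.h_b * t
    S = np.exp(-cum_hazard)
    return S if S.ndim else float(S)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

def _check_times(times: np.ndarray) -> None:
    if times.size == 0:
        raise ValueError("empty time grid")
    if times[0] != 0.0:
        raise ValueError(f"time grid must start at 0, got {times[0]!r}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")


@dataclass(frozen=True)
class DamageTrajectory:
    """Time series of the dimensionless damage state D_T."""

    times: np.ndarray
    damage: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "damage", np.asarray(self.damage, dtype=float))
        _check_times(self.times)
        if self.times.shape != self.damage.shape:
            raise ValueError("times and damage must have the same length")


@dataclass(frozen=True)
class SurvivalCurve:
    """Time series of the survival probability S_T."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        _check_times(self.times)
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have the same length")

    def at(self, t) -> np.ndarray:
        """Interpolate the curve at arbitrary times inside the grid."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.survival)


@dataclass(frozen=True)
class HazardSeries:
    """Time series of the total hazard rate h_T + h_b, per day."""

    times: np.ndarray
    hazard: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "hazard", np.asarray(self.hazard, dtype=float))
        if self.times.shape != self.hazard.shape:
            raise ValueError("times and hazard must have the same length")
        if np.any(self.hazard < 0):
            raise ValueError("hazard rates must be >= 0")


# ---------------------------------------------------------------------------
# numerical integration
# ---------------------------------------------------------------------------

def _resolve_grid(scenario, t_end, output_grid):
    if t_end is None:
        t_end = scenario.t_end
    if not (0 < t_end <= scenario.t_end):
        raise ValueError(
            f"t_end must lie in (0, {scenario.t_end}], got {t_end!r}"
        )
    if output_grid is None:
        n = max(201, int(math.ceil(t_end * 8)) + 1)
        output_grid = np.linspace(0.0, t_end, n)
    output_grid = np.asarray(output_grid, dtype=float)
    _check_times(output_grid)
    if output_grid[-1] > t_end:
        raise ValueError("output grid extends beyond t_end")
    return t_end, output_grid


def _integrate(scenario: TemperatureScenario, params: ModelParameters,
               t_end: float, output_grid: np.ndarray):
    """Co-integrate damage and cumulative hazard; return (D, cumhaz) arrays."""

    domain_end = scenario.t_end

    def rhs(t, y):
        D = y[0]
        # solvers may probe marginally outside the integration span
        t = min(max(t, 0.0), domain_end)
        F = math.exp(params.alpha * max(scenario.evaluate(t) - params.T_c, 0.0))
        return (params.k_T * (F - D),
                params.b_T * max(D - 1.0, 0.0) + params.h_b)

    max_step = np.inf if scenario.is_constant else MAX_STEP_FLUCTUATING
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [1.0, 0.0],
        method="LSODA",
        t_eval=output_grid,
        rtol=_RTOL,
        atol=_ATOL,
        max_step=max_step,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed for scenario {scenario!r}: {sol.message}"
        )
    damage = np.maximum(sol.y[0], 1.0)  # clip solver noise below baseline
    cum_hazard = np.maximum.accumulate(np.maximum(sol.y[1], 0.0))
    return damage, cum_hazard


def simulate_damage(scenario: TemperatureScenario, params: ModelParameters,
                    t_end: float | None = None,
                    output_grid=None) -> DamageTrajectory:
    """Integrate the damage ODE from D_T(0) = 1 over a temperature scenario.

    Parameters
    ----------
    scenario : TemperatureScenario
        Temperature forcing.
    params : ModelParameters
        Model constants.
    t_end : float, optional
        Integration horizon in days; defaults to the scenario's domain end.
    output_grid : array-like, optional
        Strictly increasing output times starting at 0; defaults to a grid
        of at least 8 points per day.
    """
    t_end, output_grid = _resolve_grid(scenario, t_end, output_grid)
    damage, _ = _integrate(scenario, params, t_end, output_grid)
    return DamageTrajectory(times=output_grid, damage=damage)


def simulate_survival(scenario: TemperatureScenario, params: ModelParameters,
                      t_end: float | None = None,
                      output_grid=None) -> SurvivalCurve:
    """Survival probability S_T(t) over a temperature scenario.

    The cumulative hazard is integrated alongside the damage state, and
    ``S_T(t) = exp(-cumulative hazard)``; the curve starts at 1 and is
    nonincreasing.
    """
    t_end, output_grid = _resolve_grid(scenario, t_end, output_grid)
    _, cum_hazard = _integrate(scenario, params, t_end, output_grid)
    return SurvivalCurve(times=output_grid, survival=np.exp(-cum_hazard))


def hazard_series(scenario: TemperatureScenario, params: ModelParameters,
                  t_end: float | None = None,
                  output_grid=None) -> HazardSeries:
    """Total hazard rate h_T(t) + h_b along the damage trajectory."""
    trajectory = simulate_damage(scenario, params, t_end, output_grid)
    hazard = hazard_from_damage(trajectory.damage, params) + params.h_b
    return HazardSeries(times=trajectory.times, hazard=hazard)


def survival_at_times(scenario: TemperatureScenario, params: ModelParameters,
                      times) -> np.ndarray:
    """Survival probabilities at given observation times.

    Uses the constant-forcing closed form when the scenario is constant
    (exact and fast; this is the hot path of the calibration likelihood),
    otherwise the ODE solver.
    """
    times = np.asarray(times, dtype=float)
    if scenario.is_constant:
        return np.asarray(
            constant_survival_closed_form(scenario.evaluate(0.0), times, params),
            dtype=float,
        )
    grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    curve = simulate_survival(scenario, params, t_end=float(grid[-1]),
                              output_grid=grid)
    return curve.survival if times[0] == 0.0 else curve.survival[1:]
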