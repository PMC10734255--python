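"""Maximum-likelihood calibration of the temperature damage model.

Survival count data are modelled with the conditional multinomial likelihood
standard in GUTS-style calibration: for each replicate cohort the numbers of
deaths in successive observation intervals, plus the number of final
survivors, follow a multinomial distribution whose cell probabilities are
the model-implied interval death probabilities ``S(t_{j-1}) - S(t_j)`` and
the final survival ``S(t_m)``.

The parameter space is explored with Latin hypercube sampling on log-scaled
parameters, multi-start Nelder-Mead polishing, and profile-likelihood
refinement around the optimum. Confidence intervals are likelihood-ratio
intervals: the extremes of all sampled parameter sets whose log-likelihood
lies within ``chi2(1, level) / 2`` of the maximum (1.92 for 95%). A bound
that coincides with the edge of the searched box is flagged, mirroring the
identifiability diagnostics of parameter-space-explorer calibrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2, qmc
from statsmodels.stats.proportion import proportion_confint

from .parameters import ModelParameters
from .scenarios import TemperatureScenario
from .core_model import survival_at_times

PARAM_ORDER = ("k_T", "alpha", "T_c", "h_b", "b_T")

#: Default search box, log-scale. Rate-type parameters k_T and b_T are capped
#: at 100 / day (fast-kinetics regimes beyond that are indistinguishable on
#: sub-daily observation grids).
DEFAULT_BOUNDS = {
    "k_T": (1e-3, 100.0),
    "alpha": (1e-6, 1.0),
    "T_c": (273.15, 313.15),
    "h_b": (1e-6, 1.0),
    "b_T": (1e-3, 100.0),
}

#: T_c is fixed, not fitted, by default: 284.15 K = 11 degC, chosen from
#: rearing-temperature evidence rather than estimated from survival data.
DEFAULT_FIXED = {"T_c": 284.15}

PROB_FLOOR = 1e-12

#: log10 distance below which a CI bound counts as sitting on the search box.
_BOUNDARY_TOL_DEX = 0.02


class CalibrationError(RuntimeError):
    """Raised when no finite-likelihood parameter set is found."""


# ---------------------------------------------------------------------------
# observation container and CSV dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Replicate:
    """One cohort observed over time: number alive at each observation."""

    replicate_id: str
    obs_times: np.ndarray
    n_alive: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "obs_times", np.asarray(self.obs_times, dtype=float))
        object.__setattr__(self, "n_alive", np.asarray(self.n_alive, dtype=int))
        if self.obs_times.size != self.n_alive.size or self.obs_times.size < 2:
            raise ValueError("replicate needs >= 2 aligned observations")
        if self.obs_times[0] != 0.0:
            raise ValueError("observation times must start at 0")
        if np.any(np.diff(self.obs_times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if self.n_alive[0] <= 0:
            raise ValueError("initial cohort size must be > 0")
        if np.any(np.diff(self.n_alive) > 0):
            raise ValueError(
                f"replicate {self.replicate_id!r}: alive counts increase over time"
            )
        if np.any(self.n_alive < 0):
            raise ValueError("alive counts must be >= 0")


@dataclass(frozen=True)
class Treatment:
    """A temperature scenario with its replicated survival observations."""

    treatment_id: str
    scenario: TemperatureScenario
    replicates: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(self.replicates))
        if not self.replicates:
            raise ValueError("treatment needs at least one replicate")
        for rep in self.replicates:
            if rep.obs_times[-1] > self.scenario.t_end:
                raise ValueError(
                    f"treatment {self.treatment_id!r}: observation at "
                    f"t={rep.obs_times[-1]} outside scenario domain "
                    f"[0, {self.scenario.t_end}]"
                )


@dataclass(frozen=True)
class SurvivalObservations:
    """Replicated survival counts over time across treatments."""

    treatments: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if not self.treatments:
            raise ValueError("need at least one treatment")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trt in self.treatments:
            for rep in trt.replicates:
                for t, n in zip(rep.obs_times, rep.n_alive):
                    rows.append((trt.treatment_id, rep.replicate_id, t, int(n)))
        return pd.DataFrame(rows, columns=["treatment_id", "replicate_id",
                                           "time_days", "n_alive"])

    def total_individuals(self) -> int:
        return int(sum(rep.n_alive[0] for trt in self.treatments
                       for rep in trt.replicates))


def write_survival_csv(obs: SurvivalObservations, path: Union[str, Path]) -> None:
    """Write observations in the survival CSV dialect.

    Columns: ``treatment_id, replicate_id, time_days, n_alive``.
    """
    obs.to_frame().to_csv(path, index=False)


def _scenario_from_treatment_id(treatment_id: str, t_end: float) -> TemperatureScenario:
    """Interpret ids like ``10C`` / ``const_12.5`` as constant scenarios."""
    text = treatment_id.strip()
    if text.lower().startswith("const_"):
        text = text[6:]
    if text.upper().endswith("C"):
        text = text[:-1]
    try:
        temp = float(text)
    except ValueError:
        raise ValueError(
            f"cannot infer a scenario from treatment id {treatment_id!r}; "
            "provide an explicit treatment -> scenario mapping"
        ) from None
    return TemperatureScenario(kind="constant", base_mean=temp, t_end=t_end)


def read_survival_csv(path: Union[str, Path],
                      scenarios: Optional[Mapping[str, TemperatureScenario]] = None,
                      ) -> SurvivalObservations:
    """Read survival observations from CSV.

    Expects columns ``treatment_id, replicate_id, time_days, n_alive``.
    When ``scenarios`` is omitted, treatment ids of the form ``<temp>C``
    (e.g. ``10C``, ``const_12.5``) are interpreted as constant scenarios at
    that temperature in degrees Celsius.
    """
    df = pd.read_csv(path)
    required = {"treatment_id", "replicate_id", "time_days", "n_alive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV missing column(s) {sorted(missing)}")
    treatments = []
    for trt_id, trt_df in df.groupby("treatment_id", sort=False):
        reps = []
        for rep_id, rep_df in trt_df.groupby("replicate_id", sort=False):
            rep_df = rep_df.sort_values("time_days")
            try:
                reps.append(Replicate(str(rep_id),
                                      rep_df["time_days"].to_numpy(),
                                      rep_df["n_alive"].to_numpy()))
            except ValueError as exc:
                first_row = int(rep_df.index[0]) + 2  # header is line 1
                raise ValueError(
                    f"invalid replicate {rep_id!r} of treatment {trt_id!r} "
                    f"(rows near line {first_row}): {exc}"
                ) from exc
        t_max = max(rep.obs_times[-1] for rep in reps)
        if scenarios is not None and str(trt_id) in scenarios:
            scenario = scenarios[str(trt_id)]
        else:
            scenario = _scenario_from_treatment_id(str(trt_id), t_end=t_max)
        treatments.append(Treatment(str(trt_id), scenario, tuple(reps)))
    return SurvivalObservations(tuple(treatments))


# ---------------------------------------------------------------------------
# multinomial likelihood
# ---------------------------------------------------------------------------

def interval_probabilities(params: ModelParameters,
                           scenario: TemperatureScenario,
                           obs_times: np.ndarray) -> np.ndarray:
    """Multinomial cell probabilities for one observation grid.

    Returns ``m + 1`` probabilities: death in each of the ``m`` observation
    intervals, then survival to the final time. They sum to 1 exactly
    (before any flooring) because survival starts at 1.
    """
    S = survival_at_times(scenario, params, obs_times)
    deaths = -np.diff(S)
    return np.concatenate([deaths, [S[-1]]])


def log_likelihood(params: ModelParameters, obs: SurvivalObservations,
                   include_combinatorial: bool = False) -> float:
    """Multinomial log-likelihood of the observed survival counts.

    Each replicate cohort contributes an independent multinomial term
    ``sum_j d_j ln(S(t_{j-1}) - S(t_j)) + n_alive(t_m) ln S(t_m)`` over its
    interval death counts and final survivors. By default the
    parameter-independent multinomial coefficient is omitted (the GUTS
    convention; the value is then invariant under splitting a replicate into
    sub-cohorts with the same pooled counts). With
    ``include_combinatorial=True`` the log coefficient is added and the
    value is the exact log-probability of the observed counts, matching a
    brute-force enumeration over per-individual death-time assignments.
    Cell probabilities are floored at 1e-12 before taking logs so that an
    impossible observation yields a very unfavourable but finite value.
    """
    total = 0.0
    for trt in obs.treatments:
        cache: dict = {}
        for rep in trt.replicates:
            key = rep.obs_times.tobytes()
            if key not in cache:
                cache[key] = interval_probabilities(params, trt.scenario,
                                                    rep.obs_times)
            probs = cache[key]
            deaths = -np.diff(rep.n_alive)
            counts = np.concatenate([deaths, [rep.n_alive[-1]]])
            total += float(
                np.dot(counts, np.log(np.maximum(probs, PROB_FLOOR)))
            )
            if include_combinatorial:
                total += float(gammaln(rep.n_alive[0] + 1.0)
                               - np.sum(gammaln(counts + 1.0)))
    return total


# ---------------------------------------------------------------------------
# calibration result
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CIBound:
    """Likelihood-ratio interval for one parameter, with boundary flags."""

    lower: float
    upper: float
    lower_at_boundary: bool = False
    upper_at_boundary: bool = False


@dataclass
class CalibrationResult:
    """Outcome of a model calibration."""

    best_fit: ModelParameters
    fixed: dict
    free_names: tuple
    bounds: dict
    log_likelihood: float
    ci_bounds: dict = field(default_factory=dict)
    gof: dict = field(default_factory=dict)
    #: every evaluated parameter set (columns = free parameters, plus logL)
    samples: Optional[pd.DataFrame] = None
    level: float = 0.95

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.log_likelihood

    def accepted_samples(self, level: Optional[float] = None) -> pd.DataFrame:
        """Sampled parameter sets within the likelihood-ratio cutoff."""
        level = self.level if level is None else level
        cutoff = chi2.ppf(level, df=1) / 2.0
        keep = self.samples["logL"] >= self.samples["logL"].max() - cutoff
        return self.samples[keep]

    def report(self) -> dict:
        """Structured calibration report (JSON-serializable)."""
        params = {}
        for name in PARAM_ORDER:
            entry = {"value": getattr(self.best_fit, name)}
            if name in self.fixed:
                entry["status"] = "set value"
            else:
                ci = self.ci_bounds[name]
                entry["status"] = "fitted"
                entry["ci_lower"] = ci.lower
                entry["ci_upper"] = ci.upper
                entry["lower_at_boundary"] = ci.lower_at_boundary
                entry["upper_at_boundary"] = ci.upper_at_boundary
            params[name] = entry
        return {
            "parameters": params,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_free_parameters": self.n_free,
            "ci_level": self.level,
            "gof": dict(self.gof),
        }


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

class _Objective:
    """Negative log-likelihood over log10-scaled free parameters, recording
    every evaluation for likelihood-ratio CI construction."""

    def __init__(self, obs, free_names, fixed_values, bounds):
        self.obs = obs
        self.free_names = free_names
        self.fixed_values = fixed_values
        self.lo = np.log10([bounds[n][0] for n in free_names])
        self.hi = np.log10([bounds[n][1] for n in free_names])
        self.thetas: list = []
        self.logls: list = []

    def params_at(self, theta_log10: np.ndarray) -> ModelParameters:
        values = dict(self.fixed_values)
        for name, v in zip(self.free_names, 10.0 ** np.asarray(theta_log10)):
            values[name] = float(v)
        return ModelParameters(**values)

    def __call__(self, theta_log10: np.ndarray) -> float:
        theta = np.clip(theta_log10, self.lo, self.hi)
        logl = log_likelihood(self.params_at(theta), self.obs)
        self.thetas.append(np.asarray(theta, dtype=float).copy())
        self.logls.append(logl)
        return -logl


def _profile_refine(objective: _Objective, best_theta: np.ndarray,
                    best_logl: float) -> None:
    """Profile-likelihood scans around the optimum.

    For each free parameter, walk outward from the best fit on the log10
    scale, re-optimizing the remaining parameters at each fixed value, until
    the profile drops well below the 95% likelihood-ratio cutoff or the
    search boundary is reached. All evaluations land in the objective's
    sample store, sharpening the CI extremes.
    """
    n = len(best_theta)
    stop_drop = chi2.ppf(0.95, df=1) / 2.0 + 2.0
    for i in range(n):
        others = [j for j in range(n) if j != i]

        def profile_at(value_i: float, start: np.ndarray) -> tuple:
            if not others:
                nll = objective(np.array([value_i]))
                return -nll, start
            def sub(theta_sub):
                full = np.empty(n)
                full[i] = value_i
                full[others] = theta_sub
                return objective(full)
            res = minimize(sub, start[others], method="Nelder-Mead",
                           options={"maxfev": 120, "xatol": 1e-4,
                                    "fatol": 1e-4})
            full = np.empty(n)
            full[i] = value_i
            full[others] = res.x
            return -res.fun, full

        for direction in (-1.0, 1.0):
            step = 0.08
            value = best_theta[i]
            start = best_theta.copy()
            bound = objective.hi[i] if direction > 0 else objective.lo[i]
            for _ in range(40):
                value = value + direction * step
                if direction * (value - bound) >= 0:
                    value = bound
                logl, start = profile_at(value, start)
                if value == bound or logl < best_logl - stop_drop:
                    break
                step = min(step * 1.4, 0.4)


def fit(obs: SurvivalObservations,
        fixed: Optional[Mapping[str, float]] = None,
        bounds: Optional[Mapping[str, tuple]] = None,
        seed: int = 0,
        n_lhs: int = 6000,
        n_starts: int = 6,
        n_refine: int = 4000,
        level: float = 0.95,
        profile: bool = True,
        compute_gof: bool = True) -> CalibrationResult:
    """Fit free model parameters to survival counts by maximum likelihood.

    Parameters
    ----------
    obs : SurvivalObservations
        Replicated survival counts with their temperature scenarios.
    fixed : mapping, optional
        Parameter name -> value held constant. Defaults to fixing ``T_c`` at
        284.15 K (11 degC); the free set is then {k_T, alpha, h_b, b_T}.
    bounds : mapping, optional
        Parameter name -> (lo, hi) search box; searched on the log10 scale.
    seed : int
        Seed for the Latin hypercube and refinement sampling.
    n_lhs, n_starts, n_refine : int
        Space-filling sample size, number of Nelder-Mead polishing starts,
        and number of refinement samples around the optimum.
    level : float
        Confidence level for the likelihood-ratio intervals.
    profile : bool
        Run profile-likelihood scans to sharpen the CI extremes.
    compute_gof : bool
        Attach R^2 / NRMSE / AIC goodness-of-fit statistics.
    """
    fixed = dict(DEFAULT_FIXED if fixed is None else fixed)
    search_bounds = {**DEFAULT_BOUNDS, **(dict(bounds) if bounds else {})}
    free_names = tuple(n for n in PARAM_ORDER if n not in fixed)
    if not free_names:
        raise ValueError("at least one parameter must be free")
    for name, (lo, hi) in search_bounds.items():
        if not (0 < lo < hi):
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    objective = _Objective(obs, free_names, fixed, search_bounds)
    rng = np.random.default_rng(seed)

    # 1. space-filling exploration (Latin hypercube on the log10 scale)
    sampler = qmc.LatinHypercube(d=len(free_names),
                                 seed=rng.integers(2**31 - 1))
    unit = sampler.random(n=n_lhs)
    thetas = objective.lo + unit * (objective.hi - objective.lo)
    lhs_logls = np.array([-objective(t) for t in thetas])
    if not np.any(np.isfinite(lhs_logls)):
        raise CalibrationError("no finite-likelihood point found in bounds")

    # 2. multi-start derivative-free polishing from the best LHS points
    order = np.argsort(lhs_logls)[::-1]
    nm_bounds = list(zip(objective.lo, objective.hi))
    for idx in order[:n_starts]:
        minimize(objective, thetas[idx], method="Nelder-Mead",
                 bounds=nm_bounds,
                 options={"maxfev": 600, "xatol": 1e-6, "fatol": 1e-8})

    def current_best():
        logls = np.asarray(objective.logls)
        i = int(np.argmax(logls))
        return objective.thetas[i].copy(), float(logls[i])

    best_theta, best_logl = current_best()

    # 3. refinement cloud around the optimum (shrinking Gaussian in log10)
    span = objective.hi - objective.lo
    for scale in (0.10, 0.04):
        pts = best_theta + rng.normal(scale=scale, size=(n_refine // 2,
                                                         len(free_names))) * span
        pts = np.clip(pts, objective.lo, objective.hi)
        for t in pts:
            objective(t)
        best_theta, best_logl = current_best()

    # 4. final polish + profile scans for the CI extremes
    res = minimize(objective, best_theta, method="Nelder-Mead",
                   bounds=nm_bounds,
                   options={"maxfev": 800, "xatol": 1e-7, "fatol": 1e-9})
    best_theta, best_logl = current_best()
    if profile:
        _profile_refine(objective, best_theta, best_logl)
        best_theta, best_logl = current_best()

    samples = pd.DataFrame(
        10.0 ** np.vstack(objective.thetas), columns=list(free_names)
    )
    samples["logL"] = objective.logls

    result = CalibrationResult(
        best_fit=objective.params_at(best_theta),
        fixed=fixed,
        free_names=free_names,
        bounds={n: tuple(search_bounds[n]) for n in free_names},
        log_likelihood=best_logl,
        samples=samples,
        level=level,
    )
    result.ci_bounds = profile_ci(result, level)
    if compute_gof:
        result.gof = goodness_of_fit(result, obs)
    return result


def profile_ci(result: CalibrationResult, level: float = 0.95) -> dict:
    """Likelihood-ratio confidence intervals from the sampled parameter sets.

    For each free parameter the bound is the min/max over all evaluated
    parameter sets whose log-likelihood is within ``chi2(1, level) / 2`` of
    the maximum. A bound within numerical reach of the search box edge is
    flagged as boundary-limited (the data do not constrain it there).
    """
    if result.samples is None or len(result.samples) < 2:
        warnings.warn("fewer than 2 samples available; CI is degenerate")
        return {
            name: CIBound(getattr(result.best_fit, name),
                          getattr(result.best_fit, name))
            for name in result.free_names
        }
    accepted = result.accepted_samples(level)
    if len(accepted) < 2:
        warnings.warn("fewer than 2 accepted samples; CI is degenerate")
    out = {}
    for name in result.free_names:
        lo_search, hi_search = result.bounds[name]
        lower = float(accepted[name].min())
        upper = float(accepted[name].max())
        out[name] = CIBound(
            lower=lower,
            upper=upper,
            lower_at_boundary=math.log10(lower / lo_search) <= _BOUNDARY_TOL_DEX,
            upper_at_boundary=math.log10(hi_search / upper) <= _BOUNDARY_TOL_DEX,
        )
    return out


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def gof_statistics(observed: Iterable[float], predicted: Iterable[float],
                   n_free_params: Optional[int] = None,
                   log_likelihood_value: Optional[float] = None) -> dict:
    """R^2, NRMSE (and AIC if a likelihood is given) for paired observations.

    ``R^2 = 1 - SSE / SStot`` on the raw observed-vs-predicted pairs;
    ``NRMSE`` is the root-mean-square error normalized by the mean of the
    observations (the convention of EFSA-style model-fit reporting).
    """
    obs_arr = np.asarray(list(observed), dtype=float)
    pred_arr = np.asarray(list(predicted), dtype=float)
    if obs_arr.shape != pred_arr.shape or obs_arr.size == 0:
        raise ValueError("observed and predicted must be nonempty and aligned")
    sse = float(np.sum((obs_arr - pred_arr) ** 2))
    sstot = float(np.sum((obs_arr - obs_arr.mean()) ** 2))
    if sstot == 0.0:
        warnings.warn("zero variance in observations; R^2 undefined")
        r_squared = float("nan")
    else:
        r_squared = 1.0 - sse / sstot
    rmse = math.sqrt(sse / obs_arr.size)
    mean_obs = float(obs_arr.mean())
    nrmse = rmse / mean_obs if mean_obs != 0 else float("nan")
    out = {"r_squared": r_squared, "nrmse": nrmse}
    if log_likelihood_value is not None and n_free_params is not None:
        out["aic"] = 2.0 * n_free_params - 2.0 * log_likelihood_value
    return out


def goodness_of_fit(result: CalibrationResult,
                    obs: SurvivalObservations) -> dict:
    """Goodness of fit of a calibration on its data.

    Observed and predicted numbers of survivors are pooled across all
    treatments, replicates and observation times.
    """
    observed, predicted = [], []
    for trt in obs.treatments:
        cache: dict = {}
        for rep in trt.replicates:
            key = rep.obs_times.tobytes()
            if key not in cache:
                cache[key] = survival_at_times(trt.scenario, result.best_fit,
                                               rep.obs_times)
            S = cache[key]
            observed.extend(rep.n_alive.tolist())
            predicted.extend((rep.n_alive[0] * S).tolist())
    return gof_statistics(observed, predicted,
                          n_free_params=result.n_free,
                          log_likelihood_value=result.log_likelihood)


def wilson_interval(alive: int, total: int, level: float = 0.95) -> tuple:
    """Wilson score interval for the survival fraction ``alive / total``."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= alive <= total):
        raise ValueError(f"need 0 <= alive <= total, got {alive}/{total}")
    lower, upper = proportion_confint(alive, total, alpha=1.0 - level,
                                      method="wilson")
    # degenerate proportions have exact one-sided endpoints
    lower = 0.0 if alive == 0 else max(0.0, float(lower))
    upper = 1.0 if alive == total else min(1.0, float(upper))
    return float(lower), float(upper)
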