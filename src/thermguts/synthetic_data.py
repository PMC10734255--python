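"""Synthetic survival count data with the structure the calibration assumes.

Deaths are generated by the conditional-binomial scheme the multinomial
likelihood implies: given ``n`` individuals alive at observation ``t_{j-1}``,
the number still alive at ``t_j`` is binomial with success probability
``S(t_j) / S(t_{j-1})``, the model-implied conditional survival over that
interval. This is distributionally identical to sampling independent death
times per individual, but cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters
from .scenarios import TemperatureScenario
from .core_model import survival_at_times
from .calibration import SurvivalObservations, Treatment, Replicate


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a survival study: scenarios, replication and sampling grid."""

    scenarios: tuple
    replicates_per_scenario: int
    individuals_per_replicate: int
    obs_times: np.ndarray
    treatment_ids: tuple = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "obs_times",
                           np.asarray(self.obs_times, dtype=float))
        if self.replicates_per_scenario <= 0 or self.individuals_per_replicate <= 0:
            raise ValueError("replicate and cohort counts must be > 0")
        if self.obs_times.size < 2 or self.obs_times[0] != 0.0:
            raise ValueError("obs_times must start at 0 with >= 2 points")
        if np.any(np.diff(self.obs_times) <= 0):
            raise ValueError("obs_times must be strictly increasing")
        if self.treatment_ids is None:
            ids = tuple(_default_id(s) for s in self.scenarios)
            object.__setattr__(self, "treatment_ids", ids)
        elif len(self.treatment_ids) != len(self.scenarios):
            raise ValueError("treatment_ids must match scenarios")


def _default_id(scenario: TemperatureScenario) -> str:
    if scenario.kind == "constant":
        return f"{scenario.base_mean:g}C"
    return f"{scenario.kind}_{scenario.base_mean:g}C"


def default_henry_design(t_end: float = 8.0,
                         individuals: int = 10,
                         replicates: int = 3) -> StudyDesign:
    """The acute thermal-stress assay layout used for the G. pulex calibration.

    Four constant temperature treatments (10, 15, 20, 25 degC), three
    replicates of ten individuals each, survival recorded twice daily over
    eight days (17 observation times including t = 0).
    """
    temps = (10.0, 15.0, 20.0, 25.0)
    scenarios = tuple(
        TemperatureScenario(kind="constant", base_mean=T, t_end=t_end)
        for T in temps
    )
    obs_times = np.arange(0.0, t_end + 0.25, 0.5)
    return StudyDesign(
        scenarios=scenarios,
        replicates_per_scenario=replicates,
        individuals_per_replicate=individuals,
        obs_times=obs_times,
    )


def generate(design: StudyDesign, params: ModelParameters,
             seed: int) -> SurvivalObservations:
    """Simulate survival counts under a study design.

    Per replicate, interval deaths are drawn sequentially:
    ``alive(t_j) ~ Binomial(alive(t_{j-1}), S(t_j) / S(t_{j-1}))``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    treatments = []
    for trt_id, scenario in zip(design.treatment_ids, design.scenarios):
        S = survival_at_times(scenario, params, design.obs_times)
        if np.any((S[:-1] <= 0) & (S[1:] > 0)):
            raise RuntimeError("survival hit zero with later mass remaining")
        cond = np.ones_like(S)
        nonzero = S[:-1] > 0
        cond[1:][nonzero] = S[1:][nonzero] / S[:-1][nonzero]
        cond[1:][~nonzero] = 0.0
        cond = np.clip(cond, 0.0, 1.0)
        reps = []
        for r in range(design.replicates_per_scenario):
            alive = design.individuals_per_replicate
            counts = [alive]
            for p in cond[1:]:
                alive = int(rng.binomial(alive, p))
                counts.append(alive)
            reps.append(Replicate(f"rep{r + 1}", design.obs_times,
                                  np.asarray(counts)))
        treatments.append(Treatment(trt_id, scenario, tuple(reps)))
    return SurvivalObservations(tuple(treatments))
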