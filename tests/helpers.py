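"""Shared test oracles."""

import itertools
import math

import numpy as np

from thermguts.calibration import interval_probabilities


def enumerate_log_prob(params, obs):
    """Exact log-probability of the observed counts by brute force.

    Each individual independently lands in one multinomial cell (death in
    observation interval j, or survival to the end); sum the probabilities
    of all per-individual assignments whose aggregate counts match the
    data. Tractable only for tiny cohorts.
    """
    total = 0.0
    for trt in obs.treatments:
        for rep in trt.replicates:
            probs = interval_probabilities(params, trt.scenario, rep.obs_times)
            deaths = -np.diff(rep.n_alive)
            target = tuple(deaths) + (rep.n_alive[-1],)
            n = rep.n_alive[0]
            prob = 0.0
            for assignment in itertools.product(range(len(probs)), repeat=n):
                cells = tuple(assignment.count(j) for j in range(len(probs)))
                if cells == target:
                    prob += float(np.prod(probs[list(assignment)]))
            total += math.log(prob)
    return total
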