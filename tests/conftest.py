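import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mcdmeg.mcd_core import MCDParams, EventSequence
from mcdmeg.stimulus_design import sample_sequence_pool, select_stimulus_set

P1 = MCDParams(tau_a=84, tau_v=130, tau_av=519)


@pytest.fixture(scope="session")
def small_sset():
    """A 6-stimulus set selected from a small pool (fast shared fixture)."""
    pool = sample_sequence_pool(1500, rng_seed=0)
    return select_stimulus_set(pool, k=6, rho_max=0.2, rng_seed=0)


@pytest.fixture(scope="session")
def random_sequences():
    """20 random 5+5-event one-second sequences."""
    rng = np.random.default_rng(7)
    seqs = []
    for i in range(20):
        a = np.sort(rng.uniform(0, 0.99, 5))
        v = np.sort(rng.uniform(0, 0.99, 5))
        seqs.append(EventSequence(tuple(a), tuple(v), 1.0, f"r{i}"))
    return seqs


def simulate_trials(z_corr, z_lag, link, sigma_b, n_participants, trials_per_cell,
                    seed):
    """Logistic-observer trial table over a set of per-stimulus z values."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for task, (b0, b1) in link.items():
            b = rng.normal(0, sigma_b)
            x = z_corr if task == "causality" else z_lag
            for s, xv in enumerate(x):
                pr = expit(b0 + b1 * xv + b)
                for r in rng.binomial(1, pr, trials_per_cell):
                    rows.append((p, task, f"s{s}", int(r)))
    return pd.DataFrame(rows, columns=["participant", "task", "stimulus",
                                       "response"])
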