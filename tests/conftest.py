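import itertools

import numpy as np
import pytest

from solphos.simulate import (
    PhosphoSimSpec,
    SimulationConfig,
    simulate_phospho_dataset,
    simulate_solubility_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(n_proteins=400, noise_sd=0.15, seed=42)
    table, truth = simulate_solubility_dataset(cfg)
    return table, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    cfg = SimulationConfig(n_proteins=300, noise_sd=0.0, seed=7)
    table, truth = simulate_solubility_dataset(cfg)
    return table, truth


@pytest.fixture(scope="session")
def noiseless_phospho(noiseless_dataset):
    _, truth = noiseless_dataset
    spec = PhosphoSimSpec(mean_sites_per_protein=1.0, qc_fail_fraction=0.0)
    return simulate_phospho_dataset(truth, spec)


def brute_force_delta_max(n_plus, n_minus, n_zero, blob):
    """Exhaustive-permutation delta_max oracle (test-side, independent)."""
    from solphos.seqfeat import delta

    comp = [1.0] * n_plus + [-1.0] * n_minus + [0.0] * n_zero
    best = 0.0
    for arr in set(itertools.permutations(comp)):
        best = max(best, delta(np.array(arr), blob))
    return best


def brute_force_bh(pvals):
    """Literal step-up BH: adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj
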