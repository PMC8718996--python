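"""Shared fixtures: small cohorts, planted networks, exact-posterior oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sbmpheno import (BehavioralTable, SimilarityNetwork, StochasticBlockModel,
                      simulate_sbm_network)
from sbmpheno.sbm import SBMConfig, canonical_relabel, collapsed_log_posterior


@pytest.fixture
def cohort_csv(tmp_path):
    """Factory writing a small cohort CSV and returning its path."""

    def make(rows, header="id,site,m1,m2", name="cohort.csv"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return make


@pytest.fixture
def two_site_table():
    """4 subjects, 2 sites, one measure with an obvious site offset."""
    data = pd.DataFrame({
        "subject_id": ["a", "b", "c", "d"],
        "site": ["A", "A", "B", "B"],
        "m1": [0.0, 2.0, 10.0, 12.0],
    })
    return BehavioralTable(data=data, measures=["m1"])


@pytest.fixture
def planted_network():
    """Two 30-node blocks, dense within (0.5), sparse between (0.02)."""
    theta = np.array([[0.5, 0.02], [0.02, 0.5]])
    net, z = simulate_sbm_network(z=np.repeat([1, 2], 30), theta=theta, seed=7)
    return net, z, theta


def exact_canonical_posterior(net, K=2, alpha=1.0, beta1=1.0, beta2=1.0):
    """Enumerate all K^n labelings; return exact canonical-partition probs.

    Independent oracle for the Gibbs sampler: the collapsed posterior of each
    labeling is exponentiated, normalized over the full label space, and
    aggregated by canonical partition.
    """
    cfg = SBMConfig(k=K, alpha=alpha, beta1=beta1, beta2=beta2,
                    n_iter=2, n_burn=1)
    lps, keys = [], []
    for z in itertools.product(range(1, K + 1), repeat=net.n):
        z = np.array(z)
        lps.append(collapsed_log_posterior(net, z, cfg))
        keys.append(tuple(canonical_relabel(z)))
    lps = np.asarray(lps)
    w = np.exp(lps - lps.max())
    w /= w.sum()
    probs: dict = {}
    for key, p in zip(keys, w):
        probs[key] = probs.get(key, 0.0) + p
    return probs


def empirical_canonical_frequencies(samples):
    """Relative frequency of each stored canonical labeling."""
    uniq, cnt = np.unique(samples.z, axis=0, return_counts=True)
    return {tuple(int(v) for v in u): c / samples.z.shape[0]
            for u, c in zip(uniq, cnt)}


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
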