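import numpy as np
import pandas as pd
import pytest

from adiponet import synthetic


@pytest.fixture(scope="session")
def two_tissue_bundle():
    """Moderate-size two-tissue simulation shared across tests."""
    spec = synthetic.CoexpressionSimSpec(
        n_samples=100,
        n_genes=400,
        module_sizes=[80, 60, 50],
        membership_range=(0.5, 0.9),
        inter_tissue_eigengene_cor=0.8,
        seed=11,
    )
    expr1, expr2, truth, latents = synthetic.simulate_two_tissue_expression(spec)
    annot = synthetic.simulate_traits(
        latents["tissue1"],
        binary_effects={"M1": 2.0},
        quant_effects={"waist": {"M1": 1.0}},
        seed=12,
    )
    return {
        "spec": spec,
        "expr1": expr1,
        "expr2": expr2,
        "truth": truth,
        "latents": latents,
        "annot": annot,
    }


@pytest.fixture(scope="session")
def twin_bundle():
    spec = synthetic.TwinSimSpec(
        n_mz_pairs=40,
        n_dz_pairs=20,
        n_visits_per_pair=2,
        replicate_fraction=0.2,
        variance_components=(0.4, 0.1, 0.2, 0.1, 0.1, 0.1),
        n_probesets=30,
        seed=21,
    )
    expr, design = synthetic.simulate_twin_expression(spec)
    return {"spec": spec, "expr": expr, "design": design}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_adjacency(rng):
    """Random symmetric adjacency with unit diagonal, values in [0, 1]."""

    def make(n=20, seed=None):
        gen = np.random.default_rng(seed) if seed is not None else rng
        a = gen.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        return a

    return make


def bh_oracle(pvals):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, clipped."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[i] = min(1.0, min(candidates))
    return np.array(q)


def tom_oracle(a):
    """O(n^3) literal TOM computation."""
    n = a.shape[0]
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            omega[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return omega
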