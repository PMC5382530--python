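"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (nested loops, exhaustive
enumeration) and written without reference to the package internals, so
they can serve as an independent check of the vectorized code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import microsucc as ms

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree() -> ms.PhylogeneticTree:
    return ms.PhylogeneticTree.from_newick(TOY_NEWICK)


@pytest.fixture
def toy_dists(toy_tree):
    return ms.patristic_distances(toy_tree)


@pytest.fixture(scope="session")
def small_experiment():
    """One small strong-disturbance simulated dataset for integration tests."""
    cfg = ms.SimulationConfig(
        n_taxa=80, n_replicates=3, read_depth=600,
        time_points=(0, 1, 4, 18, 49), seed=5,
    )
    table, tree, meta, qpcr, truth = ms.simulate_experiment(cfg)
    return cfg, table, tree, meta, qpcr, truth


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_beta_mntd(
    abund_a: dict[str, float],
    abund_b: dict[str, float],
    dists,
    weighted: bool = True,
) -> float:
    """Naive betaMNTD: explicit loops over every taxon pair."""
    a = {t: v for t, v in abund_a.items() if v > 0}
    b = {t: v for t, v in abund_b.items() if v > 0}
    za, zb = sum(a.values()), sum(b.values())
    a = {t: v / za for t, v in a.items()}
    b = {t: v / zb for t, v in b.items()}
    lut = {t: i for i, t in enumerate(dists.ids)}

    def nearest(taxon, other):
        return min(dists.data[lut[taxon], lut[o]] for o in other)

    if weighted:
        term_a = sum(f * nearest(t, b) for t, f in a.items())
        term_b = sum(f * nearest(t, a) for t, f in b.items())
    else:
        term_a = sum(nearest(t, b) for t in a) / len(a)
        term_b = sum(nearest(t, a) for t in b) / len(b)
    return 0.5 * (term_a + term_b)


def brute_force_permanova_exhaustive(dist, labels: list[str]) -> tuple[float, float]:
    """Pseudo-F and exact p over all distinct label assignments, computed
    from first principles (centroid-free sums of squares)."""
    d2 = np.asarray(dist.data) ** 2
    n = len(labels)
    uniq = sorted(set(labels))
    k = len(uniq)
    ss_total = d2.sum() / (2 * n)

    def f_of(assign):
        ss_w = 0.0
        for g in uniq:
            idx = [i for i, lab in enumerate(assign) if lab == g]
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ss_w += sub.sum() / (2 * len(idx))
        return ((ss_total - ss_w) / (k - 1)) / (ss_w / (n - k))

    f_obs = f_of(labels)
    assignments = set(itertools.permutations(labels))
    count = sum(1 for a in assignments if f_of(a) >= f_obs - 1e-12)
    return f_obs, count / len(assignments)


def random_tree_and_pair(rng: np.random.Generator, max_taxa: int = 8):
    """Small random tree plus a random community pair living on it."""
    n = int(rng.integers(3, max_taxa + 1))
    tree = ms.simulate.simulate_tree(n, seed=int(rng.integers(2**31)))
    tips = tree.tip_labels
    ka = int(rng.integers(1, n + 1))
    kb = int(rng.integers(1, n + 1))
    a = {t: float(rng.random() + 0.01) for t in rng.choice(tips, ka, replace=False)}
    b = {t: float(rng.random() + 0.01) for t in rng.choice(tips, kb, replace=False)}
    return tree, a, b
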