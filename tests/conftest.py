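"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's pruning code path: pattern
probabilities are computed by brute-force enumeration over all internal-node
state assignments, and the two-state comparison model is written directly
from the binary CTMC transition formula.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phylolex.covarion import TransitionKernel, build_q_matrix, root_frequencies
from phylolex.simulate import ClockModel, effective_branch_lengths
from phylolex.trees import TimeTree, simulate_yule_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def enumeration_log_probability(pattern, tree, clock, params, m=1.0):
    """Brute-force pattern probability: explicit sum over every assignment of
    the four covarion states to the internal nodes, marginalising tip hidden
    states directly."""
    q = build_q_matrix(params, normalize=True).q
    p_mats = TransitionKernel(q)(effective_branch_lengths(tree, clock, m))
    root_p = root_frequencies(params)
    internals = [int(v) for v in tree.postorder()]
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internals)):
        st = dict(zip(internals, assign))
        pr = root_p[st[tree.root]]
        for v in range(tree.n_nodes):
            par = int(tree.parent[v])
            if par < 0:
                continue
            if v < tree.n_tips:
                obs = int(pattern[v])
                pr *= p_mats[v][st[par], obs] + p_mats[v][st[par], obs + 2]
            else:
                pr *= p_mats[v][st[par], st[v]]
        total += pr
    return np.log(total)


def binary_ctmc_log_probability(pattern, tree, clock, pi_obs, m=1.0):
    """Independent two-state CTMC oracle (no hidden classes), normalised to
    one expected substitution per unit branch length: q01 = pi1, q10 = pi0,
    scaled by 1/(2 pi0 pi1)."""
    pi0, pi1 = pi_obs
    scale = 1.0 / (2 * pi0 * pi1)

    def p_matrix(t):
        e = np.exp(-(pi0 + pi1) * scale * t)
        return np.array(
            [[pi0 + pi1 * e, pi1 * (1 - e)], [pi0 * (1 - e), pi1 + pi0 * e]]
        )

    eff = effective_branch_lengths(tree, clock, m)
    p_mats = [p_matrix(t) for t in eff]
    internals = [int(v) for v in tree.postorder()]
    total = 0.0
    for assign in itertools.product(range(2), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for tip in range(tree.n_tips):
            st[tip] = int(pattern[tip])
        pr = (pi0, pi1)[st[tree.root]]
        for v in range(tree.n_nodes):
            par = int(tree.parent[v])
            if par >= 0:
                pr *= p_mats[v][st[par], st[v]]
        total += pr
    return np.log(total)


@pytest.fixture
def enumeration_oracle():
    return enumeration_log_probability


@pytest.fixture
def binary_oracle():
    return binary_ctmc_log_probability


@pytest.fixture
def small_tree(rng):
    """A 4-tip Yule tree with a relaxed clock."""
    tree = simulate_yule_tree(0.4, 4, rng)
    clock = ClockModel(mu=0.05, sigma=0.3, branch_rates=rng.lognormal(-0.045, 0.3, tree.n_nodes))
    return tree, clock


def unit_clock(tree: TimeTree, mu: float = 0.05) -> ClockModel:
    return ClockModel(mu=mu, sigma=1e-9, branch_rates=np.ones(tree.n_nodes))
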