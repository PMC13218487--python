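"""Rooted ultrametric time trees.

Trees are stored in flat arrays for fast likelihood evaluation and cheap
copying inside MCMC: node ids ``0..n-1`` are tips (age 0), ``n..2n-2`` are
internal nodes, and ``parent``/``child1``/``child2`` encode the topology.
Branch *durations* are in time units; expected-substitution lengths are the
product duration x clock rate x branch-rate multiplier x partition rate and
live in the likelihood layer.

Newick serialization goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class TimeTree:
    tip_labels: list[str]
    parent: np.ndarray  # (2n-1,), -1 for root
    child1: np.ndarray  # (2n-1,), -1 for tips
    child2: np.ndarray
    ages: np.ndarray  # (2n-1,), tips at 0

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.child1 = np.asarray(self.child1, dtype=int)
        self.child2 = np.asarray(self.child2, dtype=int)
        self.ages = np.asarray(self.ages, dtype=float)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def n_branches(self) -> int:
        """Number of branches (2n-2); the root has no branch above it."""
        return 2 * self.n_tips - 2

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def height(self) -> float:
        return float(self.ages[self.root])

    def durations(self) -> np.ndarray:
        """Per-node branch duration (parent age - node age); 0 for the root."""
        d = np.zeros(self.n_nodes)
        non_root = self.parent >= 0
        d[non_root] = self.ages[self.parent[non_root]] - self.ages[non_root]
        return d

    @property
    def length(self) -> float:
        """Total tree length (sum of branch durations) in time units."""
        return float(self.durations().sum())

    def postorder(self) -> np.ndarray:
        """Internal nodes sorted children-before-parents (by age, valid for
        ultrametric trees where parents are strictly older)."""
        internals = np.flatnonzero(self.child1 >= 0)
        return internals[np.argsort(self.ages[internals], kind="stable")]

    def validate(self) -> None:
        d = self.durations()
        non_root = self.parent >= 0
        if np.any(d[non_root] <= 0):
            raise ValueError("parent ages must exceed child ages")
        if not np.allclose(self.ages[: self.n_tips], 0.0):
            raise ValueError("tips must sit at age 0")

    def copy(self) -> "TimeTree":
        return TimeTree(
            self.tip_labels,
            self.parent.copy(),
            self.child1.copy(),
            self.child2.copy(),
            self.ages.copy(),
        )

    # -- clades -----------------------------------------------------------
    def clade_bitmasks(self) -> dict[int, int]:
        """Bitmask of subtended tips (canonical = sorted tip labels) for every
        internal node, root included."""
        order = np.argsort(self.tip_labels)
        bit = np.zeros(self.n_tips, dtype=object)
        for canon_pos, tip in enumerate(order):
            bit[tip] = 1 << canon_pos
        mask: dict[int, int] = {t: int(bit[t]) for t in range(self.n_tips)}
        for v in self.postorder():
            mask[int(v)] = mask[int(self.child1[v])] | mask[int(self.child2[v])]
        return {int(v): mask[int(v)] for v in self.postorder()}

    def clades(self, include_root: bool = False) -> set[int]:
        """Non-trivial clades as tip bitmasks (root excluded by default)."""
        masks = self.clade_bitmasks()
        root = self.root
        return {m for v, m in masks.items() if include_root or v != root}

    # -- newick -----------------------------------------------------------
    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if self.child1[v] < 0:
                label = self.tip_labels[v].replace(" ", "_")
            else:
                label = ""
            if self.parent[v] >= 0:
                bl = self.ages[self.parent[v]] - self.ages[v]
                suffix = f":{bl:.10g}"
            else:
                suffix = ""
            if self.child1[v] < 0:
                return f"{label}{suffix}"
            return f"({rec(int(self.child1[v]))},{rec(int(self.child2[v]))}){suffix}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, tip_labels: list[str] | None = None) -> "TimeTree":
        t = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(t, tip_labels)

    @classmethod
    def from_dendropy(
        cls, t: dendropy.Tree, tip_labels: list[str] | None = None
    ) -> "TimeTree":
        leaves = [lf for lf in t.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
        if tip_labels is None:
            tip_labels = labels
        n = len(tip_labels)
        tip_idx = {lab: i for i, lab in enumerate(tip_labels)}
        ids: dict[object, int] = {}
        next_internal = n
        for node in t.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label if node.taxon else node.label
                ids[node] = tip_idx[lab]
            else:
                if len(node.child_nodes()) != 2:
                    raise ValueError("tree must be binary")
                ids[node] = next_internal
                next_internal += 1
        parent = np.full(2 * n - 1, -1, dtype=int)
        child1 = np.full(2 * n - 1, -1, dtype=int)
        child2 = np.full(2 * n - 1, -1, dtype=int)
        depth: dict[int, float] = {}
        for node in t.preorder_node_iter():
            i = ids[node]
            if node.parent_node is None:
                depth[i] = 0.0
            else:
                parent[i] = ids[node.parent_node]
                depth[i] = depth[parent[i]] + (node.edge.length or 0.0)
                if child1[parent[i]] < 0:
                    child1[parent[i]] = i
                else:
                    child2[parent[i]] = i
        max_depth = max(depth[i] for i in range(n))
        ages = np.zeros(2 * n - 1)
        for i, d in depth.items():
            ages[i] = max_depth - d
        ages[:n] = 0.0  # snap tiny rounding
        tree = cls(list(tip_labels), parent, child1, child2, ages)
        tree.validate()
        return tree


def simulate_yule_tree(
    birth_rate: float, n_tips: int, rng: np.random.Generator, labels: list[str] | None = None
) -> TimeTree:
    """Yule pure-birth tree conditioned on ``n_tips``.

    Constructed from the present backwards: while ``k`` lineages exist the
    internode interval is Exponential(k * birth_rate) and a uniformly chosen
    pair merges; this yields exactly n-1 exponential intervals and, for two
    tips, a root age ~ Exponential(2 * birth_rate).
    """
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    if n_tips < 2:
        raise ValueError("need at least two tips")
    n = n_tips
    labels = labels or [f"L{i+1}" for i in range(n)]
    parent = np.full(2 * n - 1, -1, dtype=int)
    child1 = np.full(2 * n - 1, -1, dtype=int)
    child2 = np.full(2 * n - 1, -1, dtype=int)
    ages = np.zeros(2 * n - 1)
    active = list(range(n))
    age = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        age += rng.exponential(1.0 / (k * birth_rate))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        child1[nxt], child2[nxt] = a, b
        ages[nxt] = age
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    tree = TimeTree(labels, parent, child1, child2, ages)
    tree.validate()
    return tree


def log_yule_density(tree: TimeTree, birth_rate: float) -> float:
    """Log density of (topology, node ages) under the conditioned Yule
    process, up to an additive constant independent of rate and ages:
    (n-1) log lambda - lambda * L with L the tree length."""
    if birth_rate <= 0:
        return -np.inf
    n = tree.n_tips
    return (n - 1) * np.log(birth_rate) - birth_rate * tree.length
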