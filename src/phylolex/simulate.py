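"""Generative model for the calibration studies.

A replicate draws, from the prior: a Yule birth rate and 10-30 tip time tree,
an uncorrelated-lognormal set of branch-rate multipliers (mean 1, log-sd
``sigma``), binary-covarion substitution parameters, and per-partition rate
multipliers from a (weighted) Dirichlet; it then evolves partitions of binary
cognate columns down the tree with a fixed clock rate.  The same
:class:`PriorConfig` object parameterises both simulation and inference — the
self-consistency that simulation-based calibration requires.

Defaults mirror the study conditions: clock rate fixed at 0.05, 3 partitions
of 10000 cognates on 30-tip trees.  Hyperparameters of the priors are
package choices (documented in the methods note) since only the prior
*families* are dictated by the model; they are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .cognates import CognateMatrix, apply_ascertainment_filter
from .covarion import CovarionParams, TransitionKernel, build_q_matrix, root_frequencies
from .trees import TimeTree, simulate_yule_tree


@dataclass
class PartitionRates:
    """Per-partition rate multipliers under a weighted mean-1 constraint.

    Constructed as ``m_i = x_i * sum(w) / w_i`` with ``x ~ Dirichlet(alpha)``,
    which guarantees ``sum_i w_i m_i / sum_i w_i = 1`` exactly; unweighted
    (``w = 1``) reduces to plain mean-1 rates.
    """

    m: np.ndarray
    weights: np.ndarray
    dirichlet_alpha: float = 1.0

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.m <= 0) or np.any(self.weights <= 0):
            raise ValueError("rates and weights must be positive")
        wm = float(np.sum(self.weights * self.m) / np.sum(self.weights))
        if not np.isclose(wm, 1.0, atol=1e-8):
            raise ValueError(f"weighted mean of rates is {wm}, not 1")

    @property
    def k(self) -> int:
        return len(self.m)


def sample_partition_rates(
    alpha: float, weights: np.ndarray, rng: np.random.Generator
) -> PartitionRates:
    weights = np.asarray(weights, dtype=float)
    x = rng.dirichlet(np.full(len(weights), alpha))
    # Dirichlet draws can hit exact 0 at low concentration; nudge into support
    x = np.clip(x, 1e-12, None)
    x /= x.sum()
    m = x * weights.sum() / weights
    return PartitionRates(m=m, weights=weights, dirichlet_alpha=alpha)


def log_partition_rates_prior(m: np.ndarray, weights: np.ndarray, alpha: float) -> float:
    """Log density of the weighted-Dirichlet prior, evaluated in the
    underlying simplex coordinates ``x_i = m_i w_i / sum(w)`` (the coordinates
    in which the delta-exchange proposal is uniform)."""
    m = np.asarray(m, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(m <= 0):
        return -np.inf
    x = m * weights / weights.sum()
    if not np.isclose(x.sum(), 1.0, atol=1e-6):
        return -np.inf
    x = x / x.sum()
    k = len(m)
    # symmetric Dirichlet(alpha) log density
    return float(gammaln(k * alpha) - k * gammaln(alpha) + (alpha - 1) * np.log(x).sum())


@dataclass
class ClockModel:
    """Relaxed clock: global rate ``mu`` (expected substitutions per cognate
    per time unit) and per-branch lognormal multipliers with mean 1."""

    mu: float
    sigma: float
    branch_rates: np.ndarray  # indexed by node id (rate of branch above node)

    def __post_init__(self) -> None:
        self.branch_rates = np.asarray(self.branch_rates, dtype=float)
        if self.mu <= 0 or self.sigma < 0:
            raise ValueError("mu must be positive and sigma non-negative")
        if np.any(self.branch_rates <= 0):
            raise ValueError("branch rates must be positive")


def sample_branch_rates(sigma: float, n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """iid LogNormal(-sigma^2/2, sigma) multipliers (mean exactly 1)."""
    if sigma == 0:
        return np.ones(n_nodes)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_nodes)


def log_branch_rates_prior(rates: np.ndarray, sigma: float) -> float:
    if sigma <= 0 or np.any(rates <= 0):
        return -np.inf
    lx = np.log(rates)
    z = (lx + 0.5 * sigma**2) / sigma
    return float(np.sum(-lx - np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * z * z))


@dataclass
class PriorConfig:
    """Hyperparameters of every prior, shared by simulation and inference."""

    # Yule birth rate ~ LogNormal(log(0.3), 0.5)
    birth_rate_meanlog: float = float(np.log(0.3))
    birth_rate_sdlog: float = 0.5
    # covarion slow-class rate ~ Uniform(0, 1)
    alpha_lo: float = 0.0
    alpha_hi: float = 1.0
    # hidden-class switch rate ~ Exponential(mean 1)
    switch_rate_mean: float = 1.0
    # present-state frequency ~ Beta(2, 2)  (Dirichlet(2,2) on pi_obs)
    pi_present_a: float = 2.0
    pi_present_b: float = 2.0
    # branch-rate log-sd ~ Exponential(mean 0.3)
    clock_sigma_mean: float = 0.3
    # partition-rate Dirichlet concentration (fixed, not inferred)
    dirichlet_alpha: float = 1.0
    # clock rate fixed so root age and tree length are identifiable
    clock_rate: float = 0.05

    def distributions(self) -> dict[str, stats.rv_continuous]:
        return {
            "birth_rate": stats.lognorm(
                s=self.birth_rate_sdlog, scale=np.exp(self.birth_rate_meanlog)
            ),
            "alpha": stats.uniform(self.alpha_lo, self.alpha_hi - self.alpha_lo),
            "switch_rate": stats.expon(scale=self.switch_rate_mean),
            "pi_present": stats.beta(self.pi_present_a, self.pi_present_b),
            "clock_sigma": stats.expon(scale=self.clock_sigma_mean),
        }

    # closed-form log densities for the MCMC hot path (equal to the scipy
    # frozen distributions above; asserted equal in the test-suite)
    def log_hyperprior(self, name: str, x: float) -> float:
        if name == "birth_rate":
            if x <= 0:
                return -np.inf
            z = (np.log(x) - self.birth_rate_meanlog) / self.birth_rate_sdlog
            return -np.log(x * self.birth_rate_sdlog) - 0.5 * np.log(2 * np.pi) - 0.5 * z * z
        if name == "alpha":
            if not (self.alpha_lo <= x <= self.alpha_hi):
                return -np.inf
            return -np.log(self.alpha_hi - self.alpha_lo)
        if name == "switch_rate":
            return -np.inf if x <= 0 else -x / self.switch_rate_mean - np.log(self.switch_rate_mean)
        if name == "pi_present":
            if not (0 < x < 1):
                return -np.inf
            a, b = self.pi_present_a, self.pi_present_b
            lbeta = gammaln(a) + gammaln(b) - gammaln(a + b)
            return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - lbeta
        if name == "clock_sigma":
            return -np.inf if x <= 0 else -x / self.clock_sigma_mean - np.log(self.clock_sigma_mean)
        raise KeyError(name)


@dataclass
class ParameterDraw:
    """One joint draw from the prior (the 'truth' of an SBC replicate)."""

    birth_rate: float
    tree: TimeTree
    clock: ClockModel
    covarion: CovarionParams
    rates: PartitionRates

    def scalar_summary(self) -> dict[str, float]:
        d = {
            "birth_rate": self.birth_rate,
            "alpha": self.covarion.alpha,
            "switch_rate": self.covarion.s,
            "pi_present": float(self.covarion.pi_obs[1]),
            "clock_sigma": self.clock.sigma,
            "tree_height": self.tree.height,
            "tree_length": self.tree.length,
            "mean_branch_rate": float(
                self.clock.branch_rates[
                    np.flatnonzero(self.tree.parent >= 0)
                ].mean()
            ),
        }
        for i, mi in enumerate(self.rates.m):
            d[f"m_{i+1}"] = float(mi)
        return d


def draw_from_priors(
    cfg: PriorConfig,
    n_tips: int,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> ParameterDraw:
    """Sample a full generative-model state (Fig-1-style graphical model)."""
    dists = cfg.distributions()
    lam = float(dists["birth_rate"].rvs(random_state=rng))
    tree = simulate_yule_tree(lam, n_tips, rng)
    sigma = float(dists["clock_sigma"].rvs(random_state=rng))
    branch_rates = sample_branch_rates(sigma, tree.n_nodes, rng)
    branch_rates[tree.root] = 1.0  # root has no branch
    clock = ClockModel(mu=cfg.clock_rate, sigma=sigma, branch_rates=branch_rates)
    alpha = float(dists["alpha"].rvs(random_state=rng))
    s = float(dists["switch_rate"].rvs(random_state=rng))
    p1 = float(dists["pi_present"].rvs(random_state=rng))
    p1 = min(max(p1, 1e-9), 1 - 1e-9)
    covarion = CovarionParams(alpha=alpha, s=max(s, 1e-9), pi_obs=np.array([1 - p1, p1]))
    rates = sample_partition_rates(cfg.dirichlet_alpha, weights, rng)
    return ParameterDraw(lam, tree, clock, covarion, rates)


def effective_branch_lengths(
    tree: TimeTree, clock: ClockModel, m_partition: float
) -> np.ndarray:
    """Expected substitutions per cognate on the branch above each node."""
    return tree.durations() * clock.mu * clock.branch_rates * m_partition


def simulate_matrix(
    tree: TimeTree,
    clock: ClockModel,
    params: CovarionParams,
    rates: PartitionRates,
    n_cognates: int,
    rng: np.random.Generator,
    partition_names: list[str] | None = None,
) -> CognateMatrix:
    """Simulate an *unfiltered* binary matrix: ``n_cognates`` columns per
    partition, all-absent columns retained, hidden states marginalised away
    in the output."""
    names = partition_names or [f"p{i+1}" for i in range(rates.k)]
    blocks = []
    columns: list[str] = []
    part_map: dict[str, str] = {}
    for i, mi in enumerate(rates.m):
        blocks.append(simulate_partition(tree, clock, params, float(mi), n_cognates, rng))
        for j in range(n_cognates):
            cid = f"{names[i]}_{j}"
            columns.append(cid)
            part_map[cid] = names[i]
    values = np.concatenate(blocks, axis=1)
    return CognateMatrix(list(tree.tip_labels), columns, values, part_map, ascertained=False)


def simulate_partition(
    tree: TimeTree,
    clock: ClockModel,
    params: CovarionParams,
    rate_multiplier: float,
    n_cols: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one partition: observed 0/1 values, shape (n_tips, n_cols)."""
    kernel = TransitionKernel(build_q_matrix(params, normalize=True).q)
    root_p = root_frequencies(params)
    states = _simulate_states(
        tree, kernel, root_p, effective_branch_lengths(tree, clock, rate_multiplier), n_cols, rng
    )
    return (states[: tree.n_tips] % 2).astype(np.int8)  # odd states are 'present'


def _simulate_states(
    tree: TimeTree,
    kernel: TransitionKernel,
    root_p: np.ndarray,
    eff_len: np.ndarray,
    n_cols: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n_nodes = tree.n_nodes
    p_mats = kernel(eff_len)  # (n_nodes, 4, 4); root entry unused
    states = np.empty((n_nodes, n_cols), dtype=np.int8)
    root = tree.root
    states[root] = rng.choice(4, size=n_cols, p=root_p / root_p.sum())
    # preorder: by decreasing age, ties broken by decreasing id (ids are
    # assigned children-before-parents, so this stays valid for tied ages)
    internals = np.flatnonzero(tree.child1 >= 0)
    order = internals[np.lexsort((-internals, -tree.ages[internals]))]
    for v in order:
        for c in (int(tree.child1[v]), int(tree.child2[v])):
            cum = np.cumsum(p_mats[c], axis=1)
            u = rng.random(n_cols)
            states[c] = np.minimum((u[:, None] > cum[states[v]]).sum(axis=1), 3)
    return states


# ---------------------------------------------------------------------------
# SBC replicate bundles


@dataclass
class SBCReplicateInputs:
    """Truth + data + inference settings for one calibration replicate."""

    index: int
    truth: ParameterDraw
    data: CognateMatrix
    observed_counts: np.ndarray  # per-partition column counts after any filtering
    inference_weights: np.ndarray
    ascertainment_correction: bool


def make_replicate(
    cfg: PriorConfig,
    study: int,
    n_tips: int,
    n_partitions: int,
    n_cognates: int,
    rng: np.random.Generator,
    index: int = 0,
) -> SBCReplicateInputs:
    """Draw truth, simulate data and package the study-specific inference
    configuration.

    Study 1: raw data (all-absent columns retained), no correction, unweighted
    rates.  Study 2: filtered data + correction, rates unweighted.  Study 3:
    filtered data + correction, Dirichlet prior and delta-exchange weights set
    to the observed per-partition cognate counts (the default behaviour of
    mainstream phylolinguistic pipelines).
    """
    if study not in (1, 2, 3):
        raise ValueError("study must be 1, 2 or 3")
    sim_weights = np.ones(n_partitions)
    while True:
        truth = draw_from_priors(cfg, n_tips, sim_weights, rng)
        raw = simulate_matrix(truth.tree, truth.clock, truth.covarion, truth.rates, n_cognates, rng)
        if study == 1:
            data = raw
            break
        try:
            data, _removed = apply_ascertainment_filter(raw)
            break
        except ValueError:
            continue  # a partition lost every column; redraw (degenerate replicate)
    names = [f"p{i+1}" for i in range(n_partitions)]
    counts = np.array([len(data.column_indices(nm)) for nm in names], dtype=float)
    if study == 3:
        inference_weights = counts.copy()
    else:
        inference_weights = np.ones(n_partitions)
    return SBCReplicateInputs(
        index=index,
        truth=truth,
        data=data,
        observed_counts=counts,
        inference_weights=inference_weights,
        ascertainment_correction=(study != 1),
    )


def generate_sbc_suite(
    cfg: PriorConfig,
    n_replicates: int,
    study: int,
    out_dir: str | Path,
    n_tips: int = 30,
    n_partitions: int = 3,
    n_cognates: int = 10000,
    seed: int = 0,
) -> list[Path]:
    """Persist replicate bundles (data, true tree, true parameters, inference
    config) as plain-text files; returns per-replicate directories."""
    from . import cognates  # local import to avoid cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    made = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(study, r)))
        rep = make_replicate(cfg, study, n_tips, n_partitions, n_cognates, rng, index=r)
        d = out / f"replicate_{r:03d}"
        d.mkdir(exist_ok=True)
        cognates.write_matrix(rep.data, d / "data.nex", format="nexus")
        (d / "true_tree.nwk").write_text(rep.truth.tree.to_newick() + "\n")
        truth = rep.truth.scalar_summary()
        lines = ["parameter\tvalue"] + [f"{k}\t{v:.10g}" for k, v in truth.items()]
        (d / "true_parameters.tsv").write_text("\n".join(lines) + "\n")
        cfg_lines = [
            f"study: {study}",
            f"ascertainment_correction: {str(rep.ascertainment_correction).lower()}",
            f"weights: [{', '.join(f'{w:g}' for w in rep.inference_weights)}]",
            f"clock_rate: {cfg.clock_rate}",
            f"dirichlet_alpha: {cfg.dirichlet_alpha}",
            f"seed: {seed}",
            f"replicate: {r}",
        ]
        (d / "inference_config.yaml").write_text("\n".join(cfg_lines) + "\n")
        made.append(d)
    return made
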