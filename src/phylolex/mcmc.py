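"""Metropolis-Hastings sampler over tree, clock, covarion and partition-rate
parameters.

A random-scan single-move sampler: at each iteration one operator is drawn by
weight, a proposal made, and accepted with the usual ratio (the likelihood can
be tempered by ``power`` for path sampling).  Proposals that only touch
hyperparameters with no likelihood term (birth rate, clock sigma) skip the
likelihood recomputation.

Operators: multiplicative scale moves (birth rate, switch rate, single branch
rate, all node ages), reflecting window moves (alpha, present-state frequency
— the binary simplex), three partition-rate moves (weighted delta exchange,
a constraint-preserving pair scale, a prior-independence redraw), a uniform
node-age move and narrow exchange on the topology, and two joint ridge moves
(ages x c with rates / c, which leaves the likelihood invariant, and a
non-centred sigma-rates rescaling for the clock-spread funnel).  Tunable
step sizes sit in :class:`MCMCConfig` and adapt toward ~30% acceptance
during burn-in only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import LikelihoodConfig, ModelState, PartitionedData, log_posterior
from .simulate import PriorConfig


@dataclass
class MCMCConfig:
    chain_length: int = 20000
    sample_every: int = 20
    burnin_frac: float = 0.1
    tree_mode: str = "sampled"  # or "fixed"
    power: float = 1.0  # likelihood tempering exponent
    # operator tunables
    scale_window: float = 0.5
    alpha_window: float = 0.15
    pi_window: float = 0.1
    delta_max: float = 0.15
    branch_rate_window: float = 0.6
    tree_scale_window: float = 0.08
    store_branch_rates: bool = False

    def __post_init__(self) -> None:
        if self.tree_mode not in ("sampled", "fixed"):
            raise ValueError("tree_mode must be 'sampled' or 'fixed'")


# ---------------------------------------------------------------------------
# proposals (each mutates a copied state; returns log Hastings ratio or None
# when the proposal is invalid)


def weighted_delta_exchange(
    m: np.ndarray, weights: np.ndarray, delta_max: float, rng: np.random.Generator
) -> tuple[np.ndarray, float] | None:
    """Transfer rate mass between two partitions preserving sum(w*m) exactly.

    delta ~ U(0, delta_max); m_i += delta/w_i, m_j -= delta/w_j.  Symmetric
    (log Hastings ratio 0); returns None if a rate would go non-positive.
    """
    if len(m) < 2:
        raise ValueError("delta exchange needs at least two partitions")
    i, j = rng.choice(len(m), size=2, replace=False)
    delta = rng.uniform(0.0, delta_max)
    out = m.copy()
    out[i] += delta / weights[i]
    out[j] -= delta / weights[j]
    if out[j] <= 0:
        return None
    return out, 0.0


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    y = (x - lo) % (2 * width)
    return lo + (y if y <= width else 2 * width - y)


@dataclass
class Operator:
    name: str
    weight: float
    affects_likelihood: bool
    proposed: int = 0
    accepted: int = 0
    step: float | None = None  # tunable step size; None = not tunable
    step_max: float = 10.0
    _batch_acc: int = 0
    _batch_n: int = 0

    def propose(self, state: ModelState, rng, cfg: MCMCConfig, weights: np.ndarray):
        raise NotImplementedError

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else float("nan")

    def adapt(self, accepted: bool, target: float = 0.3, batch: int = 25) -> None:
        """Burn-in step-size tuning toward the target acceptance rate."""
        if self.step is None:
            return
        self._batch_n += 1
        self._batch_acc += int(accepted)
        if self._batch_n >= batch:
            rate = self._batch_acc / self._batch_n
            self.step = float(np.clip(self.step * np.exp(rate - target), 1e-4, self.step_max))
            self._batch_n = 0
            self._batch_acc = 0


class _Scale(Operator):
    def __init__(self, name: str, attr: str, weight: float, affects_likelihood: bool, step: float):
        super().__init__(name, weight, affects_likelihood, step=step)
        self.attr = attr

    def propose(self, state, rng, cfg, weights):
        c = float(np.exp(rng.uniform(-self.step, self.step)))
        setattr(state, self.attr, getattr(state, self.attr) * c)
        return np.log(c)


class _WindowAlpha(Operator):
    def __init__(self, weight: float, step: float):
        super().__init__("alpha_window", weight, True, step=step)

    def propose(self, state, rng, cfg, weights):
        state.alpha = _reflect(state.alpha + rng.uniform(-self.step, self.step), 0.0, 1.0)
        return 0.0


class _WindowPi(Operator):
    def __init__(self, weight: float, step: float):
        super().__init__("pi_window", weight, True, step=step)

    def propose(self, state, rng, cfg, weights):
        eps = 1e-6
        state.pi_present = _reflect(
            state.pi_present + rng.uniform(-self.step, self.step), eps, 1 - eps
        )
        return 0.0


class _DeltaExchange(Operator):
    def __init__(self, weight: float, step: float):
        super().__init__("delta_exchange", weight, True, step=step)
        # the transferred mass is delta/w_i, so with large weights (cognate
        # counts) the tuned delta must be allowed to grow accordingly
        self.step_max = 1e5

    def propose(self, state, rng, cfg, weights):
        res = weighted_delta_exchange(state.m, weights, self.step, rng)
        if res is None:
            return None
        state.m, lhr = res
        return lhr


class _RatePairScale(Operator):
    """Multiply one partition rate by c and absorb the change in another so
    that sum(w*m) is preserved exactly.  Multiplicative moves suit rates that
    span orders of magnitude, where the additive delta exchange crawls.
    log Hastings ratio: log c (triangular Jacobian)."""

    def __init__(self, weight: float, step: float):
        super().__init__("rate_pair_scale", weight, True, step=step)

    def propose(self, state, rng, cfg, weights):
        i, j = rng.choice(len(state.m), size=2, replace=False)
        c = float(np.exp(rng.uniform(-self.step, self.step)))
        mi = state.m[i]
        state.m[i] = c * mi
        state.m[j] -= (c - 1.0) * mi * weights[i] / weights[j]
        if state.m[j] <= 0:
            return None
        return np.log(c)


class _RatesPriorDraw(Operator):
    """Independence proposal: draw the partition rates afresh from their
    weighted-Dirichlet prior.  The Hastings ratio cancels the prior term, so
    acceptance reduces to the (tempered) likelihood ratio — ideal for the
    near-prior power posteriors of path sampling, harmless elsewhere."""

    def __init__(self, weight: float, dirichlet_alpha: float):
        super().__init__("rates_prior_draw", weight, True)
        self.dirichlet_alpha = dirichlet_alpha

    def propose(self, state, rng, cfg, weights):
        from .simulate import log_partition_rates_prior, sample_partition_rates

        new = sample_partition_rates(self.dirichlet_alpha, weights, rng).m
        lhr = log_partition_rates_prior(
            state.m, weights, self.dirichlet_alpha
        ) - log_partition_rates_prior(new, weights, self.dirichlet_alpha)
        state.m = new
        return float(lhr)


class _BranchRateScale(Operator):
    def __init__(self, weight: float, step: float):
        super().__init__("branch_rate_scale", weight, True, step=step)

    def propose(self, state, rng, cfg, weights):
        non_root = np.flatnonzero(state.tree.parent >= 0)
        b = int(non_root[rng.integers(len(non_root))])
        c = float(np.exp(rng.uniform(-self.step, self.step)))
        state.branch_rates[b] *= c
        return np.log(c)


class _NodeAgeUniform(Operator):
    def __init__(self, weight: float):
        super().__init__("node_age_uniform", weight, True)

    def propose(self, state, rng, cfg, weights):
        t = state.tree
        internals = np.flatnonzero((t.child1 >= 0) & (t.parent >= 0))
        if len(internals) == 0:
            return None
        v = int(rng.choice(internals))
        lo = max(t.ages[int(t.child1[v])], t.ages[int(t.child2[v])])
        hi = t.ages[int(t.parent[v])]
        t.ages[v] = rng.uniform(lo, hi)
        return 0.0


class _TreeAgeScale(Operator):
    def __init__(self, weight: float, step: float):
        super().__init__("tree_age_scale", weight, True, step=step)

    def propose(self, state, rng, cfg, weights):
        t = state.tree
        c = float(np.exp(rng.uniform(-self.step, self.step)))
        internals = np.flatnonzero(t.child1 >= 0)
        t.ages[internals] *= c
        return len(internals) * np.log(c)


class _SigmaRatesJoint(Operator):
    """Scale sigma while holding every branch's standardised log-rate score
    fixed: z_b = (log r_b + sigma^2/2) / sigma is invariant, so the proposal
    moves along the funnel between the rate spread and its hyperparameter
    (the non-centred direction).  Hastings ratio includes the rate-transform
    Jacobian sum(log r' - log r) + (B+1) log c."""

    def __init__(self, weight: float, step: float):
        super().__init__("sigma_rates_joint", weight, True, step=step)

    def propose(self, state, rng, cfg, weights):
        c = float(np.exp(rng.uniform(-self.step, self.step)))
        sig = state.clock_sigma
        sig2 = sig * c
        non_root = np.flatnonzero(state.tree.parent >= 0)
        r = state.branch_rates[non_root]
        z = (np.log(r) + 0.5 * sig**2) / sig
        r2 = np.exp(sig2 * z - 0.5 * sig2**2)
        if not np.all(np.isfinite(r2)) or np.any(r2 <= 0):
            return None  # underflow at extreme sigma; reject
        state.clock_sigma = sig2
        state.branch_rates[non_root] = r2
        return float(np.sum(np.log(r2) - np.log(r)) + (len(r) + 1) * np.log(c))


class _RatesAgesTradeoff(Operator):
    """Scale all node ages by c and all branch rates by 1/c.

    Every effective branch length (duration x mu x rate x m) is exactly
    invariant, so the likelihood does not change: the move travels along the
    sharp posterior ridge between tree height and branch rates that single
    moves cross only slowly.  log Hastings ratio: (n_internal - n_branches)
    log c = -(n-1) log c.
    """

    def __init__(self, weight: float, step: float):
        super().__init__("rates_ages_tradeoff", weight, False, step=step)

    def propose(self, state, rng, cfg, weights):
        t = state.tree
        c = float(np.exp(rng.uniform(-self.step, self.step)))
        internals = np.flatnonzero(t.child1 >= 0)
        non_root = np.flatnonzero(t.parent >= 0)
        t.ages[internals] *= c
        state.branch_rates[non_root] /= c
        return (len(internals) - len(non_root)) * np.log(c)


class _NarrowExchange(Operator):
    def __init__(self, weight: float):
        super().__init__("narrow_exchange", weight, True)

    def propose(self, state, rng, cfg, weights):
        t = state.tree
        candidates = np.flatnonzero((t.child1 >= 0) & (t.parent >= 0))
        if len(candidates) == 0:
            return None
        c = int(rng.choice(candidates))
        p = int(t.parent[c])
        u = int(t.child1[p]) if int(t.child2[p]) == c else int(t.child2[p])
        if t.ages[c] <= t.ages[u]:
            return None  # uncle cannot be grafted below c
        g = int(t.child1[c]) if rng.random() < 0.5 else int(t.child2[c])
        # swap u (child of p) with g (child of c)
        if int(t.child1[p]) == u:
            t.child1[p] = g
        else:
            t.child2[p] = g
        if int(t.child1[c]) == g:
            t.child1[c] = u
        else:
            t.child2[c] = u
        t.parent[u] = c
        t.parent[g] = p
        return 0.0


def default_operators(
    tree_mode: str,
    n_partitions: int,
    cfg: MCMCConfig | None = None,
    dirichlet_alpha: float = 1.0,
) -> list[Operator]:
    cfg = cfg or MCMCConfig()
    ops: list[Operator] = [
        _Scale("birth_rate_scale", "birth_rate", 1.0, False, cfg.scale_window),
        _Scale("switch_rate_scale", "switch_rate", 1.5, True, cfg.scale_window),
        _WindowAlpha(1.5, cfg.alpha_window),
        _WindowPi(1.5, cfg.pi_window),
        _Scale("sigma_scale", "clock_sigma", 1.0, False, cfg.scale_window),
        _SigmaRatesJoint(2.0, 0.3),
        _BranchRateScale(6.0, cfg.branch_rate_window),
    ]
    if n_partitions >= 2:
        ops.append(_DeltaExchange(2.0, cfg.delta_max))
        ops.append(_RatePairScale(2.0, 0.4))
        ops.append(_RatesPriorDraw(1.0, dirichlet_alpha))
    if tree_mode == "sampled":
        ops += [
            _NodeAgeUniform(3.0),
            _NarrowExchange(3.0),
            _TreeAgeScale(2.0, cfg.tree_scale_window),
            _RatesAgesTradeoff(3.0, cfg.scale_window),
        ]
    return ops


# ---------------------------------------------------------------------------
# trace


@dataclass
class PosteriorTrace:
    """Sampled scalars (+ derived tree summaries) and, when the tree is
    sampled, per-sample clade bitmask sets."""

    samples: pd.DataFrame
    clade_samples: list[frozenset] | None
    branch_rate_samples: np.ndarray | None
    tip_labels: list[str]
    burnin_frac: float
    operators: list[Operator] = field(default_factory=list)

    def burned(self) -> pd.DataFrame:
        cut = int(len(self.samples) * self.burnin_frac)
        return self.samples.iloc[cut:].reset_index(drop=True)

    def burned_clades(self) -> list[frozenset]:
        if self.clade_samples is None:
            raise ValueError("no sampled trees in this trace (fixed-tree run)")
        cut = int(len(self.samples) * self.burnin_frac)
        return self.clade_samples[cut:]

    def clade_posterior(self) -> dict[int, float]:
        """Posterior probability per clade bitmask (post burn-in)."""
        clades = self.burned_clades()
        n = len(clades)
        freq: dict[int, int] = {}
        for s in clades:
            for c in s:
                freq[c] = freq.get(c, 0) + 1
        return {c: k / n for c, k in freq.items()}

    def write_tsv(self, path) -> None:
        df = self.samples.copy()
        df.insert(0, "Sample", df.pop("sample").astype(int))
        df.to_csv(path, sep="\t", index=False)


def run_mcmc(
    data: PartitionedData | None,
    priors: PriorConfig,
    lik_cfg: LikelihoodConfig,
    mcmc_cfg: MCMCConfig,
    init: ModelState,
    rng: np.random.Generator,
    operators: list[Operator] | None = None,
) -> PosteriorTrace:
    """Sample the posterior (or the prior when ``data=None``).

    ``mcmc_cfg.tree_mode='fixed'`` keeps the starting topology and node ages
    fixed (used by the posterior predictive workflow); branch rates are still
    sampled.  Non-mixing is not an error — diagnose with ESS downstream.
    """
    weights = (
        lik_cfg.weights if lik_cfg.weights is not None else np.ones(len(init.m))
    )
    ops = operators or default_operators(
        mcmc_cfg.tree_mode, len(init.m), mcmc_cfg, priors.dirichlet_alpha
    )
    op_w = np.array([o.weight for o in ops])
    op_w = op_w / op_w.sum()
    state = init.copy()
    lp, ll = log_posterior(state, data, priors, lik_cfg, power=mcmc_cfg.power)
    if not np.isfinite(lp):
        raise ValueError("initial state has zero prior density")

    records = []
    clade_samples: list[frozenset] | None = (
        [] if mcmc_cfg.tree_mode == "sampled" else None
    )
    br_samples: list[np.ndarray] | None = [] if mcmc_cfg.store_branch_rates else None
    non_root = np.flatnonzero(init.tree.parent >= 0)

    for it in range(mcmc_cfg.chain_length + 1):
        if it % mcmc_cfg.sample_every == 0:
            rec = {
                "sample": it,
                "birth_rate": state.birth_rate,
                "alpha": state.alpha,
                "switch_rate": state.switch_rate,
                "pi_present": state.pi_present,
                "clock_sigma": state.clock_sigma,
                "tree_height": state.tree.height,
                "tree_length": state.tree.length,
                "mean_branch_rate": float(state.branch_rates[non_root].mean()),
                "log_prior": lp,
                "log_likelihood": ll,
            }
            for i, mi in enumerate(state.m):
                rec[f"m_{i+1}"] = float(mi)
            records.append(rec)
            if clade_samples is not None:
                clade_samples.append(frozenset(state.tree.clades()))
            if br_samples is not None:
                br_samples.append(state.branch_rates.copy())
        if it == mcmc_cfg.chain_length:
            break
        op = ops[int(rng.choice(len(ops), p=op_w))]
        op.proposed += 1
        in_burnin = it < mcmc_cfg.burnin_frac * mcmc_cfg.chain_length
        prop = state.copy()
        lhr = op.propose(prop, rng, mcmc_cfg, weights)
        if lhr is None:
            if in_burnin:
                op.adapt(False)
            continue
        if op.affects_likelihood and data is not None and mcmc_cfg.power > 0:
            lp2, ll2 = log_posterior(prop, data, priors, lik_cfg, power=mcmc_cfg.power)
        else:
            lp2, ll2 = log_posterior(prop, None, priors, lik_cfg)[0], ll
        accepted = False
        if np.isfinite(lp2):
            log_accept = (lp2 - lp) + mcmc_cfg.power * (ll2 - ll) + lhr
            if log_accept >= 0 or rng.random() < np.exp(log_accept):
                state, lp, ll = prop, lp2, ll2
                accepted = True
                op.accepted += 1
        if in_burnin:
            op.adapt(accepted)

    return PosteriorTrace(
        samples=pd.DataFrame(records),
        clade_samples=clade_samples,
        branch_rate_samples=np.array(br_samples) if br_samples is not None else None,
        tip_labels=list(init.tree.tip_labels),
        burnin_frac=mcmc_cfg.burnin_frac,
        operators=ops,
    )
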