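"""Orchestration of the three calibration studies, the weighting-scheme
comparison and the posterior predictive workflow.

Everything is driven by a master seed: per-replicate generators are spawned
with ``np.random.SeedSequence(seed, spawn_key=...)`` so replicates are
independent, reproducible and individually re-runnable.

Scales: :meth:`SBCConfig.paper` carries the study conditions (30-tip Yule
trees, 3 partitions of 10000 cognates, 100 replicates, clock 0.05);
:meth:`SBCConfig.desk` is the reduced configuration used by the test-suite
and worked examples (10 tips, 2 partitions of 1000 cognates, 40 replicates,
short chains).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adequacy import adequacy_report, compute_metrics, simulate_predictive
from .cognates import CognateMatrix, Partition, PartitionSpec, build_partitions
from .diagnostics import (
    ECDFResult,
    SBCReplicate,
    coverage,
    ecdf_difference,
    ess,
    pit_ranks,
    pool_clade_tables,
)
from .evidence import PathSamplingResult, bayes_factors, path_sampling_log_ml, power_posterior_schedule
from .likelihood import LikelihoodConfig, ModelState, PartitionedData, compress_matrix
from .mcmc import MCMCConfig, PosteriorTrace, run_mcmc
from .simulate import (
    PriorConfig,
    SBCReplicateInputs,
    draw_from_priors,
    make_replicate,
)
from .trees import TimeTree


@dataclass
class SBCConfig:
    priors: PriorConfig = field(default_factory=PriorConfig)
    n_tips: int = 30
    n_partitions: int = 3
    n_cognates: int = 10000  # per partition, before ascertainment filtering
    n_replicates: int = 100
    chain_length: int = 60000
    sample_every: int = 60
    burnin_frac: float = 0.1
    rank_draws: int = 100  # L for rank statistics

    @classmethod
    def paper(cls) -> "SBCConfig":
        return cls()

    @classmethod
    def desk(cls) -> "SBCConfig":
        return cls(
            n_tips=10,
            n_partitions=2,
            n_cognates=1000,
            n_replicates=40,
            chain_length=36000,
            sample_every=36,
        )

    def parameter_names(self) -> list[str]:
        return (
            ["birth_rate", "alpha", "switch_rate", "pi_present", "clock_sigma"]
            + [f"m_{i+1}" for i in range(self.n_partitions)]
            + ["tree_height", "tree_length", "mean_branch_rate"]
        )


def _project_rates(m: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scale rates onto the inference constraint sum(w*m) = sum(w)."""
    return m * weights.sum() / np.sum(weights * m)


def _state_from_truth(inputs: SBCReplicateInputs) -> ModelState:
    t = inputs.truth
    m0 = _project_rates(t.rates.m, inputs.inference_weights)
    return ModelState(
        tree=t.tree.copy(),
        branch_rates=t.clock.branch_rates.copy(),
        birth_rate=t.birth_rate,
        alpha=t.covarion.alpha,
        switch_rate=t.covarion.s,
        pi_present=float(t.covarion.pi_obs[1]),
        clock_sigma=max(t.clock.sigma, 1e-6),
        m=m0,
    )


def run_sbc_replicate(
    study: int, cfg: SBCConfig, rep_index: int, seed: int
) -> SBCReplicate:
    """Simulate one replicate from the prior, re-infer it, and package the
    truth, posterior draws, per-parameter ESS and pooled clade table."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(study, rep_index)))
    inputs = make_replicate(
        cfg.priors, study, cfg.n_tips, cfg.n_partitions, cfg.n_cognates, rng, rep_index
    )
    names = [f"p{i+1}" for i in range(cfg.n_partitions)]
    pdata = compress_matrix(inputs.data, names)
    lik_cfg = LikelihoodConfig(
        ascertainment_correction=inputs.ascertainment_correction,
        weights=inputs.inference_weights,
    )
    mcmc_cfg = MCMCConfig(
        chain_length=cfg.chain_length,
        sample_every=cfg.sample_every,
        burnin_frac=cfg.burnin_frac,
        tree_mode="sampled",
    )
    trace = run_mcmc(pdata, cfg.priors, lik_cfg, mcmc_cfg, _state_from_truth(inputs), rng)
    draws = trace.burned()
    params = cfg.parameter_names()
    ess_map = {p: ess(draws[p].to_numpy()) if draws[p].nunique() > 1 else float(len(draws)) for p in params}
    return SBCReplicate(
        true_values=inputs.truth.scalar_summary(),
        draws=draws[params],
        ess=ess_map,
        clade_posterior=trace.clade_posterior(),
        true_clades=inputs.truth.tree.clades(),
    )


@dataclass
class SBCResult:
    study: int
    config: SBCConfig
    replicates: list[SBCReplicate]

    def coverage_table(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for p in self.config.parameter_names():
            frac, (lo, hi) = coverage(self.replicates, p, mass)
            rows.append(
                {
                    "parameter": p,
                    "coverage": frac,
                    "ci_low": lo,
                    "ci_high": hi,
                    "nominal_in_ci": lo <= mass <= hi,
                }
            )
        return pd.DataFrame(rows)

    def pooled_coverage(self, mass: float = 0.95) -> float:
        """Fraction of (replicate, parameter) pairs with the truth inside the
        HPD, pooled over all free parameters."""
        from .diagnostics import hpd_interval

        hits, n = 0, 0
        for p in self.config.parameter_names():
            for rep in self.replicates:
                lo, hi = hpd_interval(rep.draws[p].to_numpy(), mass)
                hits += int(lo <= rep.true_values[p] <= hi)
                n += 1
        return hits / n

    def rank_table(self, seed: int = 0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        rows = []
        for p in self.config.parameter_names():
            pit, ls = pit_ranks(self.replicates, p, self.config.rank_draws, rng)
            for r, (u, l) in enumerate(zip(pit, ls)):
                rows.append({"parameter": p, "replicate": r, "pit": u, "L": l})
        return pd.DataFrame(rows)

    def ecdf_results(self, level: float = 0.95, seed: int = 0) -> dict[str, ECDFResult]:
        rng = np.random.default_rng(seed)
        out = {}
        for p in self.config.parameter_names():
            pit, ls = pit_ranks(self.replicates, p, self.config.rank_draws, rng)
            out[p] = ecdf_difference(pit, ls, level=level, rng=rng)
        return out

    def clade_table(self) -> tuple[np.ndarray, np.ndarray]:
        return pool_clade_tables(self.replicates)

    def min_ess(self) -> float:
        return min(min(rep.ess.values()) for rep in self.replicates)


def run_sbc_study(study: int, cfg: SBCConfig, seed: int = 0) -> SBCResult:
    if cfg.n_replicates < 1:
        raise ValueError("need at least one replicate")
    reps = [run_sbc_replicate(study, cfg, r, seed) for r in range(cfg.n_replicates)]
    return SBCResult(study=study, config=cfg, replicates=reps)


# ---------------------------------------------------------------------------
# weighting-scheme comparison (path sampling)


@dataclass
class ComparisonConfig:
    priors: PriorConfig = field(default_factory=PriorConfig)
    n_steps: int = 30
    schedule_shape: float = 0.3
    chain_length: int = 8000
    sample_every: int = 5
    burnin_frac: float = 0.3
    ess_floor: float = 20.0
    delta_max: float = 0.4


def scheme_weights(parts: list[Partition], scheme: str) -> np.ndarray:
    """Partition weights under a named weighting scheme."""
    if scheme == "cognates":
        return np.array([len(p.column_idx) for p in parts], dtype=float)
    if scheme == "meanings":
        return np.array([p.n_meanings for p in parts], dtype=float)
    if scheme == "equal":
        return np.ones(len(parts))
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def path_sampling_for_weights(
    pdata: PartitionedData,
    tree: TimeTree,
    weights: np.ndarray,
    cmp_cfg: ComparisonConfig,
    seed: int,
    strict_clock: bool = False,
    fixed_covarion=None,
) -> PathSamplingResult:
    """Marginal likelihood of the fixed-tree model under one weighting scheme.

    Each power-posterior step runs an independently seeded chain started from
    its own prior draw (projected onto the weighting constraint), so steps are
    order-independent and mergeable.  ``strict_clock=True`` pins every branch
    rate at 1; ``fixed_covarion`` (a :class:`CovarionParams`) pins the
    substitution parameters.  Both are used by the weighting
    self-consistency experiment to make the candidate models differ in
    nothing but the partition-rate weighting.
    """
    from .mcmc import default_operators

    priors = cmp_cfg.priors
    lik_cfg = LikelihoodConfig(ascertainment_correction=True, weights=weights)
    schedule = power_posterior_schedule(cmp_cfg.n_steps, cmp_cfg.schedule_shape)

    def run_chain(beta: float, k: int) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        truth = draw_from_priors(priors, tree.n_tips, np.ones(pdata.k), rng)
        mcfg = MCMCConfig(
            chain_length=cmp_cfg.chain_length,
            sample_every=cmp_cfg.sample_every,
            burnin_frac=cmp_cfg.burnin_frac,
            tree_mode="fixed",
            power=beta,
            delta_max=cmp_cfg.delta_max,
        )
        operators = default_operators("fixed", pdata.k, mcfg, priors.dirichlet_alpha)
        if strict_clock:
            drop = ("sigma_scale", "sigma_rates_joint", "branch_rate_scale")
            operators = [o for o in operators if o.name not in drop]
        if fixed_covarion is not None:
            drop = ("alpha_window", "pi_window", "switch_rate_scale")
            operators = [o for o in operators if o.name not in drop]
        covarion = fixed_covarion if fixed_covarion is not None else truth.covarion
        init = ModelState(
            tree=tree.copy(),
            branch_rates=np.ones(tree.n_nodes),
            birth_rate=truth.birth_rate,
            alpha=covarion.alpha,
            switch_rate=covarion.s,
            pi_present=float(covarion.pi_obs[1]),
            clock_sigma=1e-9 if strict_clock else max(truth.clock.sigma, 1e-6),
            m=_project_rates(truth.rates.m, weights),
        )
        trace = run_mcmc(pdata, priors, lik_cfg, mcfg, init, rng, operators=operators)
        return trace.burned()["log_likelihood"].to_numpy()

    return path_sampling_log_ml(run_chain, schedule, ess_floor=cmp_cfg.ess_floor)


def compare_weightings(
    matrix: CognateMatrix,
    tree: TimeTree,
    spec: PartitionSpec,
    cmp_cfg: ComparisonConfig,
    seed: int = 0,
    schemes: tuple[str, ...] = ("cognates", "meanings", "equal"),
) -> pd.DataFrame:
    """Path-sampling evidence for each partition-rate weighting scheme,
    reported with Bayes factors against the best model."""
    parts = build_partitions(matrix, spec)
    pdata = compress_matrix(matrix, [p.name for p in parts])
    results: dict[str, PathSamplingResult] = {}
    for i, scheme in enumerate(schemes):
        w = scheme_weights(parts, scheme)
        results[scheme] = path_sampling_for_weights(
            pdata, tree, w, cmp_cfg, seed=seed * 1000 + i
        )
    table = bayes_factors({s: r.log_ml for s, r in results.items()})
    table["se"] = [results[s].se for s in table["model"]]
    return table


def weighting_selfconsistency_experiment(
    cmp_cfg: ComparisonConfig,
    seed: int = 0,
    n_tips: int = 8,
    meanings_per_bin: tuple[int, ...] = (8, 3, 1),
    cognates_per_meaning: int = 150,
) -> pd.DataFrame:
    """Generate data whose partition rates follow the *meaning-weighted*
    Dirichlet, then score all three weighting schemes by path sampling.

    Bins play the role of meaning-count partitions: bin i pools
    ``meanings_per_bin[i]`` meanings sharing one rate, so its simulated
    (pre-filter) length is meanings x cognates_per_meaning — the
    meaning-weighted model's own generative story (a fixed pool of potential
    cognate sets per meaning, of which the rate determines how many are
    observable).  A correctly behaving evidence machine should rank the
    meaning-weighted scheme first.

    Design notes (see the methods document): the schemes are identifiable
    only where the observable fraction is strongly rate-dependent (so
    observed cognate counts stop being proportional to meaning counts) and
    an overall rate rescaling is costly.  The experiment's regime is
    therefore ascertainment-heavy (present-state frequency ~ Beta(1.5, 10))
    with a near-strict clock (branch-rate log-sd prior mean 0.02) — applied
    identically to the generating model and to every candidate model, so the
    comparison stays self-consistent.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    k = len(meanings_per_bin)
    w_meanings = np.array(meanings_per_bin, dtype=float)
    cmp_cfg = replace(
        cmp_cfg,
        priors=replace(
            cmp_cfg.priors,
            dirichlet_alpha=1.0,
            pi_present_a=1.5,
            pi_present_b=10.0,
            clock_sigma_mean=0.02,
        ),
    )
    priors = cmp_cfg.priors
    truth = draw_from_priors(priors, n_tips, np.ones(k), rng)
    from .simulate import ClockModel, sample_partition_rates, simulate_partition
    from .cognates import CognateMatrix

    # strict clock: the weighting constraint is the only difference between
    # the candidate models, with no branch-rate channel to absorb it
    truth.clock = ClockModel(
        mu=priors.clock_rate, sigma=0.0, branch_rates=np.ones(truth.tree.n_nodes)
    )
    rates = sample_partition_rates(priors.dirichlet_alpha, w_meanings, rng)
    names = [f"bin{i+1}" for i in range(k)]
    blocks, columns, pmap = [], [], {}
    for i, nm in enumerate(names):
        n_cog = meanings_per_bin[i] * cognates_per_meaning
        vals = simulate_partition(truth.tree, truth.clock, truth.covarion, float(rates.m[i]), n_cog, rng)
        keep = (vals == 1).any(axis=0)
        vals = vals[:, keep]
        if vals.shape[1] == 0:
            raise RuntimeError("degenerate simulation: a bin lost every column")
        blocks.append(vals)
        for j in range(vals.shape[1]):
            cid = f"{nm}_{j}"
            columns.append(cid)
            pmap[cid] = nm
    matrix = CognateMatrix(
        list(truth.tree.tip_labels), columns, np.concatenate(blocks, axis=1), pmap, ascertained=True
    )
    pdata = compress_matrix(matrix, names)
    schemes = {
        "cognates": pdata.n_columns.astype(float),
        "meanings": w_meanings,
        "equal": np.ones(k),
    }
    results = {}
    for i, (scheme, w) in enumerate(schemes.items()):
        results[scheme] = path_sampling_for_weights(
            pdata,
            truth.tree,
            w,
            cmp_cfg,
            seed=seed * 100 + i,
            strict_clock=True,
            fixed_covarion=truth.covarion,
        )
    table = bayes_factors({s: r.log_ml for s, r in results.items()})
    table["se"] = [results[s].se for s in table["model"]]
    return table


# ---------------------------------------------------------------------------
# posterior predictive workflow


@dataclass
class PPSConfig:
    priors: PriorConfig = field(default_factory=PriorConfig)
    chain_length: int = 20000
    sample_every: int = 20
    burnin_frac: float = 0.1
    n_reps: int = 1001
    match_counts: bool = True


def run_pps(
    matrix: CognateMatrix,
    tree: TimeTree,
    cfg: PPSConfig,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PosteriorTrace]:
    """Fixed-tree inference, predictive simulation, eight metrics and p_B.

    Returns (report, per-replicate metric table, trace).
    """
    if matrix.has_missing():
        raise ValueError("posterior predictive workflow requires complete data")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    names = matrix.meanings
    pdata = compress_matrix(matrix, names)
    k = pdata.k
    w = weights if weights is not None else np.ones(k)
    lik_cfg = LikelihoodConfig(ascertainment_correction=True, weights=w)
    truth = draw_from_priors(cfg.priors, tree.n_tips, np.ones(k), rng)
    init = ModelState(
        tree=tree.copy(),
        branch_rates=np.ones(tree.n_nodes),
        birth_rate=truth.birth_rate,
        alpha=truth.covarion.alpha,
        switch_rate=truth.covarion.s,
        pi_present=float(truth.covarion.pi_obs[1]),
        clock_sigma=max(truth.clock.sigma, 1e-6),
        m=_project_rates(truth.rates.m, w),
    )
    mcfg = MCMCConfig(
        chain_length=cfg.chain_length,
        sample_every=cfg.sample_every,
        burnin_frac=cfg.burnin_frac,
        tree_mode="fixed",
        store_branch_rates=True,
    )
    trace = run_mcmc(pdata, cfg.priors, lik_cfg, mcfg, init, rng)
    observed_counts = {nm: int(n) for nm, n in zip(pdata.names, pdata.n_columns)}
    predictive = simulate_predictive(
        trace,
        tree,
        observed_counts,
        cfg.priors.clock_rate,
        rng,
        n_reps=cfg.n_reps,
        match_counts=cfg.match_counts,
    )
    report = adequacy_report(predictive, compute_metrics(matrix))
    return report, predictive, trace
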