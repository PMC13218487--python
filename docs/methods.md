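# Methods

## The model under test

`phylolex` implements, and then stress-tests, the analysis stack that has
become standard for Bayesian phylogenetics of cognate-coded lexical data:

- **Data.** Binary presence/absence characters (one per cognate set) grouped
  into partitions by meaning. Because data are collected per meaning, a
  cognate set absent in every language can never be observed (ascertainment
  bias); a set present in every language *can* be observed, so — unlike the
  usual invariant-site correction in morphology — only the all-absent pattern
  is conditioned away.
- **Substitution model.** The binary covarion: four states
  (absent-fast, present-fast, absent-slow, present-slow). Within a hidden
  class, the 0↔1 rate equals the equilibrium frequency of the destination
  observed state, down-weighted by α ∈ [0, 1] in the slow class; switches
  between classes never change the observed state. Three parameterisations
  are supported: `beast` (bare switch rate *s* both ways, hidden frequencies
  fixed at (½, ½) and excluded from the matrix — the default throughout this
  package, as in practice), `reversible` (switch rates s·π_hidden[dest];
  time-reversible with stationary distribution π_obs ⊗ π_hidden), and
  `tuffley_steel` (α = 0, separate s_fast/s_slow). The rate matrix is
  normalised so the equilibrium rate of *observable* events is 1, so branch
  lengths read as expected substitutions per cognate; hidden switches are
  excluded from that flux. Transition probabilities use the complex
  eigendecomposition of Q (the `beast` mode is non-reversible), validated
  per call against the stochastic-matrix invariants with a dense Padé
  `expm` fallback.
- **Tree and clock.** A Yule time tree conditioned on the tip count
  (constructed backwards: while k lineages exist the internode interval is
  Exponential(kλ) and a uniform pair merges), an uncorrelated lognormal
  relaxed clock with mean-1 branch-rate multipliers (log-sd σ), and a global
  clock rate fixed at μ = 0.05 so that root age and tree length are
  identifiable. The joint tree density used in inference is
  (n−1)·log λ − λ·L with L the tree length, which is the interval-product
  density up to a constant.
- **Partition rates.** Per-partition multipliers m with a weighted mean-1
  constraint, built constructively as m_i = x_i · Σw / w_i from
  x ~ Dirichlet(α·1). The weighted delta-exchange operator
  (m_i += δ/w_i, m_j −= δ/w_j) preserves Σ w·m exactly and is uniform in the
  x-coordinates, in which the prior density is evaluated.
- **Likelihood.** Felsenstein pruning over the four covarion states with
  two-state tip data (observed 0 is compatible with both absent states),
  site-pattern compression per partition, lazy rescaling against underflow,
  and the ascertainment correction
  Pr(x | observable) = Pr(x) / (1 − Pr(all-absent)), with the all-absent
  probability computed once per partition per evaluation under the current
  parameters.

## Priors

Only the prior *families* are fixed by the generative model; the
hyperparameter values are this package's choices (all configurable through
`PriorConfig`, and the identical object drives simulation and inference —
the self-consistency that simulation-based calibration requires):

| parameter | prior | default | why |
|---|---|---|---|
| birth rate λ | LogNormal | median 0.3, sdlog 0.5 (per time unit) | with μ = 0.05 this puts ~1–2 expected substitutions per cognate across a 10–30-tip tree: variable but not saturated characters, the regime where cognate data live |
| covarion α | Uniform(0, 1) | — | the slow class is by definition no faster than the fast class |
| switch rate s | Exponential | mean 1 (per expected substitution) | switching on the same time scale as substitution |
| π_present | Beta(2, 2) | — | mild shrinkage away from degenerate frequencies |
| clock σ | Exponential | mean 0.3 | moderate rate heterogeneity across branches |
| Dirichlet concentration | fixed 1.0 | — | diffuse partition-rate spread, which also makes partition length strongly rate-dependent after filtering |

## The calibration studies

Each replicate draws all parameters from the prior, simulates per-partition
cognate columns down the tree, and re-infers them by MCMC. Three
configurations:

1. **Raw data** — all-absent columns retained, no correction, unweighted
   rates (a pure implementation check).
2. **Matched model** — all-absent columns removed, ascertainment correction
   on, rates unweighted. Simulation and inference match exactly; this
   configuration should be (and is) calibrated.
3. **Cognate-count weighting** — filtered data and correction as in 2, but
   the Dirichlet prior and delta-exchange weights set to the *observed*
   per-partition cognate counts, the default behaviour of mainstream
   pipelines. The true rates satisfy the unweighted constraint Σm = K, which
   is off the weighted constraint manifold Σ w·m = Σ w that the sampler
   preserves — so partition rates and birth rate are underestimated and tree
   height/length overestimated, while the covarion parameters and the
   pooled branch-rate mean stay calibrated. This is the contrast the
   package exists to reproduce. One reduced-scale caveat: with only 18
   branches informing the branch-rate log-sd, a little of the
   partition-rate distortion leaks into apparent rate heterogeneity, so at
   desk scale σ drifts mildly (well short of the flagged parameters'
   violations) where the full-scale study keeps it calibrated.

Diagnostics: 95% HPD coverage with exact binomial intervals; PIT ranks of
the truth among posterior draws thinned to ≤100 values spaced at least
trace-length/ESS apart (ties broken uniformly), with ECDF-difference curves
against simultaneous bands calibrated by Monte Carlo (pointwise quantile
envelopes tuned by bisection to a 95% simultaneous level, honouring each
replicate's rank resolution); clade reliability as a CORP-style isotonic
(pool-adjacent-violators) regression of true-tree membership on pooled
posterior clade support, with bootstrap bands. ESS is the classic
initial-positive-sequence autocorrelation estimator N/(1 + 2Σρ).

### Scales

The study conditions are 30-tip trees, 3 partitions of 10000 cognates and
100 replicates (`SBCConfig.paper()`). The package's reduced configuration
(`SBCConfig.desk()`: 10 tips, 2 partitions of 1000 cognates, 40 replicates,
36000-iteration chains) keeps every structural feature — ascertainment-heavy
simulation, rate-dependent partition lengths, sampled topologies — while
fitting interactive runtimes; the test-suite uses it with 30 replicates and
the reproduction script with 48. The miscalibration study uses 3 partitions
(the full design's K) at the same total cognate budget, since the weighting
pathology grows with the number of partitions. Because replicate counts are
modest, calibration checks are assessed against exact binomial/band
uncertainty rather than point equality.

## MCMC

Random-scan Metropolis–Hastings. Scale moves (birth rate, switch rate,
single branch rates, all node ages), reflecting windows (α, π_present), the
weighted delta exchange, a uniform node-age move and narrow exchange on the
topology, plus two joint moves that follow the posterior's ridges:

- **ages × c, rates ÷ c** — leaves every effective branch length invariant
  (likelihood unchanged), decorrelating tree height from branch rates;
- **σ-rates joint** — scales σ holding each branch's standardised log-rate
  score fixed (the non-centred direction of the σ/rates funnel), without
  which σ mixes pathologically slowly.

Step sizes adapt toward ~30% acceptance during burn-in only (10% of the
chain, discarded). SBC chains start at the generating values — a draw from
the correct posterior — which removes burn-in transients; in study 3 the
starting rates are first projected onto the weighted constraint manifold.
Replicates are seeded by `SeedSequence(seed, spawn_key=(study, replicate))`,
so every run is reproducible and replicates are independently re-runnable.

Degenerate inputs: zero-length trees simulate constant columns from the root
marginal; a constant chain reports ESS = N with a warning; an all-absent
probability numerically at 1 raises rather than returning a corrected
likelihood.

## Model comparison

Path sampling: log Z = ∫ E_β[log L] dβ over 30 power posteriors on the
Beta(0.3, 1)-quantile schedule (β_k = (k/29)^{1/0.3}), trapezoid-integrated,
with a standard error from per-step variances divided by per-step ESS. Each
step runs an independently seeded chain (25% burn-in) from its own projected
prior draw, so steps are order-independent and mergeable. The machinery is
validated against the closed-form Beta-Binomial evidence and exercised on a
self-consistency experiment: data generated under meaning-count weighting
should, and do, favour the meaning-weighted scheme over cognate-count and
equal weighting. The tree is held fixed during these comparisons; the
schemes differ only in the partition-rate constraint.

The self-consistency experiment is a *controlled* comparison, and the
reasons are themselves findings worth recording: with every nuisance
parameter free, the three weighting schemes are close to unidentifiable at
small scale. Three effects hide them. First, a scheme's constraint
Σ wᵢmᵢ = Σ wᵢ only hurts if an overall rescaling is expensive — under a
loose relaxed clock the branch rates absorb any scale mismatch almost for
free, so the experiment uses a strict clock (all branch rates pinned at 1,
in generation and in every candidate model). Second, cognate-count weights
only *differ* from meaning-count weights when the observable fraction of
cognates varies strongly across partitions; the experiment therefore runs
ascertainment-heavy (present-state frequency ~ Beta(1.5, 10)) with a wide
rate spread (Dirichlet concentration 1). Third — and least obvious — the
covarion's own parameters carry a quasi-scale degree of freedom that can
re-absorb a wrong constraint: with α, s, π free, an independent Laplace
approximation of the evidence agrees with path sampling that the schemes
end up within ~1 log unit of each other (that agreement doubles as a
validation of the path-sampling estimator on this model class). The
experiment therefore fixes the substitution parameters at their generating
values in all three candidate models — the same logic by which the tree is
fixed — so the models differ in nothing but the weighting. In that design
the meaning-weighted scheme (the generating model) wins clearly; profile
likelihood probes across eight experiment seeds show it ahead of cognate
weighting by 0–15 log units (never behind) and ahead of equal weighting by
0.3–21.

## Posterior predictive adequacy

Fixed-tree inference, then one predictive dataset per (sub-sampled)
posterior draw. Eight metrics: max/min/mean pairwise Hamming distance
between languages, mean proportion of present cognates, variance of
per-language present counts, number of prevalent cognates (strictly >80% of
languages), number of singletons, and variance of cognate prevalence.
Discrepancy is the mid-point two-tailed p-value
p_B = 2·min(P(T<t) + ½P(T=t), P(T>t) + ½P(T=t)), capped at 1.

Predictive replicates are made comparable to ascertained data by simulating
cognates per partition with rejection of all-absent columns until the
observed column count is reached (`match_counts=True`). The conditioning
convention is a design choice — one could instead simulate a fixed raw
count and merely filter (`match_counts=False`, also implemented); matching
counts removes a nuisance dimension (column count) from every metric.
"Pairwise distance" defaults to the Hamming *fraction*; an absolute-count
variant is available.

## What the synthetic data do and do not emulate

The generator reproduces the structural features that drive the studied
pathologies: binary characters evolved under the covarion, all-absent
columns arising (frequently, at low rates) and being filtered, and the
induced correlation between a partition's rate and its observed length. It
does **not** emulate missing data (the likelihood refuses it rather than
mis-correcting), lexical borrowing/contact, semantic shift, or the
within-meaning dependence of real cognate sets (a single lexeme per meaning
per language). Passing calibration here therefore validates the *inference
machinery* under its own assumptions; it says nothing about whether the
covarion adequately describes real lexical evolution — that question is what
the posterior predictive module asks, and on real data several of its
metrics are expected to fail even when calibration succeeds.

## Known limitations

- Topology sampling uses narrow exchange plus node-age moves; for trees much
  larger than the desk scale, mixing over topologies would need richer moves
  (subtree-prune-regraft variants).
- The number of observed columns itself carries some information about the
  parameters (through Pr(all-absent)); like the standard correction, the
  likelihood conditions on it rather than modelling it. The matched-model
  calibration results show this is immaterial at the scales studied.
- ESS on the slowest parameters (σ, tree height) is tens-to-hundreds per
  desk-scale replicate; rank statistics guard against over-thinning by
  capping the rank resolution at the measured ESS.
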