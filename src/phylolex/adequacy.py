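"""Posterior predictive adequacy of the covarion model.

Replicate datasets are simulated from posterior draws on a fixed tree and
compared with the observed matrix through eight summary metrics chosen to
capture language divergence (pairwise distances), language composition
(present-cognate proportions) and the distribution of cognates across
languages (prevalence, singletons).  Discrepancy per metric is quantified by
the mid-point two-tailed predictive p-value ``p_B``: 1 means the observed
value sits at the centre of the predictive distribution, < 0.05 flags a
significant mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cognates import CognateMatrix
from .covarion import CovarionParams
from .mcmc import PosteriorTrace
from .simulate import ClockModel, simulate_partition
from .trees import TimeTree

METRIC_NAMES = (
    "max_pairwise_distance",
    "min_pairwise_distance",
    "mean_pairwise_distance",
    "mean_prop_present",
    "var_n_present",
    "n_prevalent",
    "n_singletons",
    "var_prevalence",
)


@dataclass
class PPSMetrics:
    """Eight adequacy metrics of a binary cognate matrix.

    Pairwise distance is the Hamming fraction over all columns; prevalence of
    a cognate is the fraction of languages in which it is present; 'prevalent'
    means strictly more than 80% of the language sample; a singleton
    (autapomorphy) is present in exactly one language.
    """

    max_pairwise_distance: float
    min_pairwise_distance: float
    mean_pairwise_distance: float
    mean_prop_present: float
    var_n_present: float
    n_prevalent: int
    n_singletons: int
    var_prevalence: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def compute_metrics(m: CognateMatrix, distance: str = "hamming") -> PPSMetrics:
    """Compute all eight metrics (no missing data allowed)."""
    if m.has_missing():
        raise ValueError("metrics require a matrix without missing data")
    x = m.values.astype(float)
    n_lang, n_col = x.shape
    diff = x[:, None, :] != x[None, :, :]
    d = diff.mean(axis=2) if distance == "hamming" else diff.sum(axis=2)
    iu = np.triu_indices(n_lang, k=1)
    pair = d[iu]
    n_present = x.sum(axis=1)
    prevalence = x.mean(axis=0)
    return PPSMetrics(
        max_pairwise_distance=float(pair.max()),
        min_pairwise_distance=float(pair.min()),
        mean_pairwise_distance=float(pair.mean()),
        mean_prop_present=float(x.mean()),
        var_n_present=float(np.var(n_present)),
        n_prevalent=int(np.sum(prevalence > 0.8)),
        n_singletons=int(np.sum(n_present_per_col(x) == 1)),
        var_prevalence=float(np.var(prevalence)),
    )


def n_present_per_col(x: np.ndarray) -> np.ndarray:
    return x.sum(axis=0)


def midpoint_p_value(simulated: np.ndarray, observed: float) -> float:
    """Mid-point two-tailed predictive p-value:
    ``2 * min(P(T<t) + P(T=t)/2, P(T>t) + P(T=t)/2)``, capped at 1."""
    sim = np.asarray(simulated, dtype=float)
    if len(sim) < 2:
        raise ValueError("need at least two simulated values")
    below = np.mean(sim < observed)
    ties = np.mean(sim == observed)
    above = np.mean(sim > observed)
    return float(min(1.0, 2.0 * min(below + ties / 2.0, above + ties / 2.0)))


def simulate_predictive(
    trace: PosteriorTrace,
    tree: TimeTree,
    observed_counts: dict[str, int],
    clock_rate: float,
    rng: np.random.Generator,
    n_reps: int = 1001,
    match_counts: bool = True,
    n_total: int | None = None,
) -> pd.DataFrame:
    """Simulate predictive datasets from posterior draws on the fixed tree and
    return one metrics row per replicate.

    ``match_counts=True`` (default) draws cognates per partition with
    rejection of all-absent columns until the observed column count is
    reached, so replicates are directly comparable to ascertained data;
    ``match_counts=False`` simulates ``n_total`` raw columns per partition and
    merely filters all-absent ones.
    """
    if trace.branch_rate_samples is None:
        raise ValueError("trace must store branch rates (fixed-tree run)")
    df = trace.burned()
    cut = len(trace.samples) - len(df)
    br = trace.branch_rate_samples[cut:]
    if len(df) < 1:
        raise ValueError("empty trace")
    pick = np.linspace(0, len(df) - 1, min(n_reps, len(df))).round().astype(int)
    names = list(observed_counts)
    rows = []
    for r, idx in enumerate(pick):
        row = df.iloc[idx]
        params = CovarionParams(
            alpha=float(row["alpha"]),
            s=float(row["switch_rate"]),
            pi_obs=np.array([1 - row["pi_present"], row["pi_present"]]),
        )
        clock = ClockModel(
            mu=clock_rate,
            sigma=max(float(row["clock_sigma"]), 1e-12),
            branch_rates=br[idx],
        )
        m = np.array([row[f"m_{i+1}"] for i in range(len(names))])
        blocks, columns, pmap = [], [], {}
        for i, nm in enumerate(names):
            target = observed_counts[nm]
            if match_counts:
                got = []
                n_have = 0
                guard = 0
                while n_have < target:
                    batch = simulate_partition(
                        tree, clock, params, float(m[i]), max(target - n_have, 32), rng
                    )
                    keep = (batch == 1).any(axis=0)
                    got.append(batch[:, keep])
                    n_have += int(keep.sum())
                    guard += 1
                    if guard > 1000:
                        raise RuntimeError("all-absent rejection not converging")
                vals = np.concatenate(got, axis=1)[:, :target]
            else:
                batch = simulate_partition(
                    tree, clock, params, float(m[i]), n_total or target, rng
                )
                keep = (batch == 1).any(axis=0)
                vals = batch[:, keep]
            blocks.append(vals)
            for j in range(vals.shape[1]):
                cid = f"{nm}_{r}_{j}"
                columns.append(cid)
                pmap[cid] = nm
        mat = CognateMatrix(
            list(tree.tip_labels),
            columns,
            np.concatenate(blocks, axis=1),
            pmap,
            ascertained=True,
        )
        rows.append({"replicate": r, **compute_metrics(mat).as_dict()})
    return pd.DataFrame(rows)


def adequacy_report(predictive: pd.DataFrame, observed: PPSMetrics) -> pd.DataFrame:
    """Per-metric observed value, predictive mean and mid-point p_B."""
    obs = observed.as_dict()
    rows = []
    for name in METRIC_NAMES:
        sims = predictive[name].to_numpy()
        rows.append(
            {
                "metric": name,
                "observed": obs[name],
                "predictive_mean": sims.mean(),
                "p_B": midpoint_p_value(sims, obs[name]),
            }
        )
    return pd.DataFrame(rows)
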