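"""Matched-model calibration study (ascertainment-filtered data, unweighted
partition rates).

Simulates replicates from the prior, re-infers them with the identical model,
and checks 95% HPD coverage, rank-ECDF uniformity and clade-support
reliability.  Finding: the analysis is well-calibrated — coverage is
consistent with 95% for every free parameter, the ECDF-difference curves are
consistent with rank uniformity (individual marginal band crossings occur at
the ~5%-per-parameter rate the simultaneous bands are calibrated to, without
any directional pattern), and clades with support p are in the true tree
about p of the time.

Reduced scale by default (10 tips, 2 partitions of 1000 cognates,
40 replicates); pass --paper-scale for the full study conditions.
"""

import argparse
from pathlib import Path

import numpy as np

from phylolex.diagnostics import clade_reliability
from phylolex.pipeline import SBCConfig, run_sbc_study
from phylolex.plots import plot_coverage, plot_ecdf_differences, plot_reliability

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-replicates", type=int, default=None)
parser.add_argument("--paper-scale", action="store_true")
args = parser.parse_args()

OUT = Path(__file__).resolve().parent.parent / "results" / "sbc_matched"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SBCConfig.paper() if args.paper_scale else SBCConfig.desk()
if args.n_replicates:
    cfg.n_replicates = args.n_replicates

result = run_sbc_study(2, cfg, seed=args.seed)

cov = result.coverage_table()
cov.to_csv(OUT / "coverage.tsv", sep="\t", index=False)
result.rank_table(args.seed).to_csv(OUT / "ranks.tsv", sep="\t", index=False)
ecdfs = result.ecdf_results(seed=args.seed)
plot_coverage(result, OUT / "coverage.png")
plot_ecdf_differences(ecdfs, OUT / "ecdf_difference.png")
support, in_true = result.clade_table()
rel = clade_reliability(support, in_true, rng=np.random.default_rng(args.seed))
plot_reliability(rel, OUT / "reliability.png")

print(cov.to_string(index=False))
print(f"pooled 95% HPD coverage: {100 * result.pooled_coverage():.1f}%")
print(f"rank uniformity: {sum(r.passed for r in ecdfs.values())}/{len(ecdfs)} parameters inside bands")
print(f"pooled clades: {len(support)}; CEP at 0.6 support: {rel.cep_at(0.6):.2f}")
print(f"minimum per-parameter ESS across replicates: {result.min_ess():.0f}")
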