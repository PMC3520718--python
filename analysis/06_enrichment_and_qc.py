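#!/usr/bin/env python
"""Quality summaries: PCA structure, platform concordance, term enrichment.

Reads the simulated study (run 01 first), decomposes sample variance by
PCA (the organ split should dominate an early component), measures
fold-change concordance between the gene-level matrix and a median-polished
probe-level re-measurement of the responsive loci, and runs a
hypergeometric enrichment on a synthetic annotation planted over the
responsive genes.  Outputs under results/qc/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from prr import diffexpr, downstream_qc as dq, io_core, simulate, tiling

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/simulated"))
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/qc"))
args = parser.parse_args()

expr = io_core.read_expression_matrix(args.data / "matrix.tsv")
design = io_core.read_design(args.data / "design.tsv")
truth = pd.read_csv(args.data / "truth.tsv", sep="\t")
args.out.mkdir(parents=True, exist_ok=True)

# PCA
fractions, scores = dq.pca_summary(expr, design)
io_core.write_results(scores, args.out / "pca_scores.tsv")
(args.out / "pca_fractions.json").write_text(json.dumps([float(f) for f in fractions]))
print("PCA variance fractions:", np.round(fractions[:4], 3).tolist())

# platform concordance over responsive loci (subset for probe re-measurement)
responsive = truth[(truth.organ == "root") & (truth.class_code != "BAR")]["gene_id"]
sub_truth = truth[truth.gene_id.isin(responsive)]
probe_expr, probe_map = simulate.simulate_probe_level(
    sub_truth, (3, 8), affinity_sd=0.3, seed=args.seed, probe_noise_sd=0.25
)
summary, _ = tiling.summarize_tiling_abundance(probe_expr, probe_map, design)
micro = diffexpr.compute_contrast(expr, design, "root", "response")
shared = [g for g in responsive if g in summary.index]
r2 = dq.platform_concordance(
    micro.loc[shared, "log2_fc"], summary.loc[shared, "root_response"]
)
print(f"micro/tiling fold-change concordance over {len(shared)} responsive loci: "
      f"R^2 = {r2:.3f}")

# enrichment: plant a term over responsive genes + background terms
universe = list(expr.index)
rng = np.random.default_rng(args.seed)
ann = [(g, "T:responsive", "planted responsive module") for g in responsive[:40]]
for j in range(5):
    for g in rng.choice(universe, size=60, replace=False):
        ann.append((g, f"T:bg{j}", f"background term {j}"))
annotations = pd.DataFrame(ann, columns=["gene_id", "term_id", "term_name"])
res = dq.hypergeometric_enrichment(set(responsive), annotations, universe)
io_core.write_results(res, args.out / "enrichment.tsv")
top = res.iloc[0]
print(f"top enriched term: {top.term_id} (k={top.k}/{top.K}, "
      f"Bonferroni p = {top.p_adj:.3g})")

results = {"pca_fractions": [float(f) for f in fractions[:4]],
           "concordance_r2": float(r2),
           "top_term": str(top.term_id), "top_term_p_adj": float(top.p_adj)}
(args.out / "qc_summary.json").write_text(json.dumps(results, indent=2))
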