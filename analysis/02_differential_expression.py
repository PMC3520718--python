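#!/usr/bin/env python
"""Two contrasts per organ with moderated t-tests and Bonferroni control.

Reads the simulated study from results/simulated/ (run 01 first), computes
the response (starved vs mock) and recovery (replete vs starved) contrasts
for each organ, and writes one table per (organ, contrast) under
results/contrasts/.
"""

import argparse
from pathlib import Path

from prr import diffexpr, io_core

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/simulated"))
parser.add_argument("--out", type=Path, default=Path("results/contrasts"))
args = parser.parse_args()

expr = io_core.read_expression_matrix(args.data / "matrix.tsv")
design = io_core.read_design(args.data / "design.tsv")
args.out.mkdir(parents=True, exist_ok=True)

for organ in io_core.ORGANS:
    for contrast in diffexpr.CONTRASTS:
        res = diffexpr.compute_contrast(expr, design, organ, contrast)
        io_core.write_results(res, args.out / f"{organ}_{contrast}.tsv")
        n_sig = int((res["p_adj"] <= 0.001).sum())
        print(
            f"{organ:5s} {contrast:8s}: {n_sig:4d} of {len(res)} genes significant "
            f"(Bonferroni p <= 0.001)"
        )
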