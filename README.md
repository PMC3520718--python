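# prr — response-and-recovery transcriptomics

`prr` re-implements, as a tested and reusable pipeline, the computational
analysis of a two-organ phosphate-starvation response-and-recovery
expression study: plants are profiled in roots and shoots under mock,
starved, and re-supplied (replete) conditions, and every gene is judged on
two contrasts —

- **response**: starved vs mock, log2 FC = mean(starved) − mean(mock)
- **recovery**: replete vs starved, log2 FC = mean(replete) − mean(starved)

Each contrast is tested per gene with a two-sided pooled-variance t-test
whose variances are moderated by empirical-Bayes shrinkage (a scaled
inverse-χ² prior fitted across genes by method of moments on the log
variances), with Bonferroni control over all genes per contrast.  The pair
of (significance, direction) outcomes assigns each gene one of **9
response-and-recovery classes**:

| code | response | recovery | reading |
|------|----------|----------|---------|
| BAR  | —        | —        | basal |
| CPR / CNR | +/− | same sign | continuous |
| IPR / INR | +/− | opposite sign | initial (fully recovers) |
| PPR / PNR | +/− | —       | persistent |
| LPR / LNR | —   | +/−     | latent (appears during recovery) |

Comparing root and shoot classes per gene yields a 9×9 joint matrix (up to
81 organ-specific patterns).  Genes absent from the expression micro-array
are assessed from tiling probes: genes with ≥ 3 probes are summarized by
Tukey median polish and a gene is called differential when its condition
difference G satisfies |G/σ| ≥ 3, with σ the genome-wide spread of G.
Finally, focal-stress genes are ranked for **specificity** against a panel
of other treatment contrasts by the minimum Bonferroni-adjusted p-value
they reach anywhere in the panel, and a bipartite gene–treatment
interaction network records which treatments co-regulate them.

A synthetic-data generator emulates the full 2-organ × 3-condition ×
3-replicate design with planted classes, probe-level affinities, and a
multi-treatment panel with planted overlaps, so every stage is testable
without any downloads.

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_study.py
python analysis/02_differential_expression.py
python analysis/03_classify_response_recovery.py
python analysis/04_tiling_pathway.py
python analysis/05_crosstalk_specificity.py
python analysis/06_enrichment_and_qc.py
```

With the default seed the run prints, among other lines:

```
root: responsive=99 (initial=44, persistent=7, latent=48); planted non-basal recovered: 100.0% of 99
joint matrix: union=198 (root 99 + shoot 101 - common 2); same-class systemic=1
root: sigma(response)=0.327, flagged 1.5% of genes in response; planted non-basal recovered: 100.0% of 24
specific fraction (degree 0): 70.7%; max interaction degree: 4
micro/tiling fold-change concordance over 99 responsive loci: R^2 = 0.994
```

i.e. the classifier recovers every planted non-basal class at the default
noise level, the σ-rule flags ~1.5% of genes (its intended sparse regime),
roughly 70% of focal-responsive genes interact with no other treatment in
the planted panel, and fold-changes measured at gene level and at
median-polished probe level agree with R² ≈ 0.99 over responsive loci.

The same steps are available as a CLI (`prr simulate`, `prr de`,
`prr classify`, `prr joint`, `prr tiling`, `prr table2-check`,
`prr specificity`, `prr enrich`, `prr qc`, `prr concordance`) operating on
the TSV artifacts the drivers write.

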