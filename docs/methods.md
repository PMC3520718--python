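# Methods

## The study design and its statistical model

The pipeline analyses a phosphate-starvation response-and-recovery design:
two organs (root, shoot) × three conditions (mock, starved, replete) ×
three biological replicates, measured as log2 intensities.  Two contrasts
are defined per organ:

- response:  log2 FC = mean(starved) − mean(mock)
- recovery:  log2 FC = mean(replete) − mean(starved)

The orientation is chosen so a gene that rises under starvation and falls
back during recovery has response "+" and recovery "−": the fully
recovering genes sit on the line response = −recovery (y = −x).

Per gene and contrast we use a two-sided pooled-variance t-test with
df = n₁ + n₂ − 2.  By default variances are moderated: per-gene pooled
variances s² are assumed to follow s²/s₀² ~ F(df, d₀) under a scaled
inverse-χ² prior, whose hyperparameters (d₀, s₀²) are fitted by method of
moments on log s² (digamma/trigamma identities of the log-F distribution;
the trigamma inverse is solved by Newton iteration).  The posterior
variance (df·s² + d₀·s₀²)/(df + d₀) is used with df + d₀ total degrees of
freedom.  With only 4 residual df per gene this moderation is what makes a
Bonferroni threshold of 0.001 attainable at realistic effect sizes — the
unmoderated t with df = 4 cannot reach genome-wide significance, which is
also why moderation defaults to on while the unmoderated path is retained
for oracle tests.  Degenerate cases: if the spread of log variances does
not exceed its pure-sampling value, d₀ = ∞ and all variances collapse to
s₀² (a normal reference test); exactly equal variances are returned
unchanged; a gene with zero pooled variance and zero difference gets
p = 1 by convention.

Multiplicity: Bonferroni with family = all genes in the tested matrix,
per contrast per organ.  A per-organ family is the most defensible reading
of a genome-wide corrected threshold when organs are analysed separately;
it is a parameter of `bonferroni_adjust`, not a constant.

## The 9-class scheme

Significance is p_adj ≤ α inclusive (α = 0.001 by default).  "No change"
means not significant — there is deliberately no secondary fold-change
floor.  The class is a pure function of the two (significant, sign) pairs;
a significant contrast with fold-change exactly 0 is impossible under the
t construction and is guarded by an error.  Counts aggregate as initial =
IPR+INR, persistent = PPR+PNR, latent = LPR+LNR, responsive = non-BAR, and
the root×shoot joint matrix (fixed row/column order BAR, CPR, IPR, PPR,
LPR, CNR, INR, PNR, LNR) reports union/common totals by
inclusion–exclusion, where "common" counts genes responsive in both
organs.

Linear fold magnitudes are 2^|log2 FC| rounded half-up, with direction
carried separately; half-up matches how folds are quoted in print.

## Tiling pathway

Genes with fewer than 3 mapped probes are excluded (ambiguous probes were
already dropped, not duplicated, at map load).  Each gene's probes ×
samples block (per organ) is decomposed by Tukey median polish
(convergence when the largest absolute removed median < 1e-4, max 10
sweeps — conventional for probe summarization; both configurable).  A
condition's abundance is the overall effect plus the mean column effect
over that condition's replicates; the mean (not median) keeps the
zero-noise case exact.  Per-probe affinity offsets are constant across
samples, land entirely in the row effects, and therefore cancel exactly
from all condition differences.

Detection standardizes the per-gene differences G by σ, the sample
standard deviation of G over all genes for that (organ, contrast),
centered at zero since a difference is expected null-centered (a
mean-centered option exists).  A gene is flagged when |G/σ| ≥ 3,
inclusive.  Two consequences worth keeping in mind:

- The rule is calibrated only in the sparse regime.  σ is computed over
  *all* genes, so if a large fraction of genes carries real effects, σ is
  inflated and power collapses.  The end-to-end recovery test plants ~3%
  non-basal genes, the regime in which the rule flags on the order of
  1–2% of genes — the regime it is meant for.
- The flags are invariant to any positive rescaling of G.

The packaged table `src/prr/data/tiling_worked_examples.tsv` (71 printed
rows of tiling-only loci: log2 response/recovery values and class labels
for both organs) supports a consistency scan: for each (organ, contrast)
the interval (max unflagged |value|, min flagged |value|] is computed; a
non-empty interval means one cut reproduces every printed label.  All four
intervals are non-empty: root-response (1.617, 1.625], root-recovery
(1.466, 1.684], shoot-response (1.289, 1.302], shoot-recovery
(1.297, 1.380].  The scan is an interval feasibility check rather than a
fixed-σ reproduction because the σ underlying the printed labels is not
recoverable from the table alone.

## Cross-talk

A treatment panel is a set of treatment-vs-control contrast tables over
one shared gene universe.  Specificity of a focal-responsive gene is the
minimum Bonferroni-adjusted p-value it reaches in any panel treatment:
rank 1 is the largest minimum p (the most relaxed threshold needed to
call the gene anywhere else).  Ties break by larger focal |log2 FC|, then
lexicographic gene id — a deterministic rule chosen because printed ranks
are unique.  A raw-p ranking is available behind a flag.  The interaction
network is strictly bipartite: edge (gene, treatment) iff the gene is
focal-responsive and treatment-significant at α; gene degree 0 is, by
construction, exactly the specific set at the same α (asserted by a
cross-operation test).  Treatment weights decompose by the focal gene's
phase (initial/persistent/latent).

## Synthetic data: what it emulates, what it does not

The generator plants, per gene and organ independently, a class drawn from
a configurable mix; condition means follow the additive log2 model
mock = μ, starved = μ + δ_resp, replete = μ + δ_resp + δ_rec, so a planted
δ equals the expected log2 FC and parameter-recovery tests are exact in
expectation.  Defaults, chosen once:

- baseline μ ~ Normal(8, 1.5²) log2 units and replicate noise
  sd = 0.25 — plausible array-scale values;
- effect size d = 2 log2 units;
- class mix mirroring the focal platform's observed root composition
  (≈5.5% responsive split 310:110:47:50:420:320 across
  IPR:INR:PPR:PNR:LPR:LNR, remainder basal, no continuous classes by
  default though they can be planted);
- probe layer: 3–8 probes per gene, affinity sd 0.3 constant across
  samples, probe-level measurement noise sd 0.25.

Reproducibility: one global seed drives a counter-based substream per gene
(`SeedSequence([seed, gene_index])`, draws in a fixed documented order),
recorded in the truth table; the probe-level generator replays these
substreams so probe values are exactly gene values plus probe terms, and
the zero-noise limit is reproduced at machine precision.

Deliberately not modelled: probe GC/affinity sequence models, spatial
array artifacts, normalization effects, organ-level RNA-abundance
asymmetry, and correlated (non-i.i.d.) replicate noise.  Passing tests
therefore demonstrate the correctness and calibration of the procedures
under the stated model, not robustness to real-array artifacts; headline
counts from the original deposited arrays are arithmetic-identity checks
over printed tallies, not re-derivations from raw data.

The treatment-panel generator plants a gene's effect in exactly the
listed treatments and nothing else, on a two-arm (control/treated,
3-replicate) design per treatment; panel contrasts reuse the same
moderated-t machinery.

## Quality summaries

PCA centers genes (no unit-variance scaling by default — array
convention) and eigen-decomposes the samples × samples covariance;
fractions are non-increasing and the organ split is expected to dominate
an early component.  Cross-platform concordance is the squared Pearson
correlation of matched fold-change vectors, evaluated over responsive
loci: at a realistic ~5% responsive fraction a genome-wide R² is dominated
by null-gene noise and says little about measurement agreement.  Term
enrichment is an upper-tail hypergeometric test per term with Bonferroni
over the terms that have at least one universe annotation; the universe
defaults to the genes tested on the platform (conservative), not the
genome.

## Problem sizes

The shipped analyses and tests use 250–2000 simulated genes, 1000-gene
probe-level runs, a 10-treatment panel, and a 100 000-draw Gaussian null
for σ-rule calibration; these sizes give stable Monte-Carlo behaviour for
every assertion (binomial SEs an order of magnitude below the tested
margins) while keeping any full run in the seconds-to-a-minute range.
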