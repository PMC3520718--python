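"""Synthetic response-and-recovery study generator.

Emulates a 2-organ (root, shoot) × 3-condition (mock, starved, replete) ×
n-replicate expression study with planted response-and-recovery classes, a
probe-level layer with per-probe affinities for the tiling pathway, and a
multi-treatment contrast panel with planted overlaps for the cross-talk
analysis.

The mean model is additive on the log2 scale: for a gene with baseline μ and
planted class effects (δ_resp, δ_rec),

    mock    = μ
    starved = μ + δ_resp
    replete = μ + δ_resp + δ_rec

so a planted δ equals the expected log2 fold-change of the corresponding
contrast, and an "initial" class (IPR/INR) returns exactly to baseline under
replete conditions (δ_rec = −δ_resp, the full-recovery line y = −x).

Determinism: one global seed governs everything through a counter-based
substream per gene (``SeedSequence([seed, gene_index])``), recorded in the
truth table, so any gene's draws can be replayed bit-identically — the
probe-level generator relies on this to reproduce gene-level sample values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CONDITIONS, ORGANS

#: Table-style listing order of the 9 response-and-recovery classes.
CLASS_CODES = ("BAR", "CPR", "IPR", "PPR", "LPR", "CNR", "INR", "PNR", "LNR")

#: Sign pattern (response, recovery) of each class; 0 = no change.
CLASS_SIGNS = {
    "BAR": (0, 0),
    "CPR": (+1, +1),
    "IPR": (+1, -1),
    "PPR": (+1, 0),
    "LPR": (0, +1),
    "CNR": (-1, -1),
    "INR": (-1, +1),
    "PNR": (-1, 0),
    "LNR": (0, -1),
}

# Default class mix mirrors the observed root composition of the study
# design this generator emulates: 1257 of 22810 measured loci responsive,
# split 310/110/47/50/420/320 across IPR/INR/PPR/PNR/LPR/LNR, and no
# continuous classes (none were observed; they can still be planted
# explicitly).
_N_UNIVERSE = 22810
DEFAULT_CLASS_PROPORTIONS = {
    "IPR": 310 / _N_UNIVERSE,
    "INR": 110 / _N_UNIVERSE,
    "PPR": 47 / _N_UNIVERSE,
    "PNR": 50 / _N_UNIVERSE,
    "LPR": 420 / _N_UNIVERSE,
    "LNR": 320 / _N_UNIVERSE,
}
DEFAULT_CLASS_PROPORTIONS["BAR"] = 1.0 - sum(DEFAULT_CLASS_PROPORTIONS.values())

BASELINE_MEAN = 8.0  # log2 units, array-scale intensity
BASELINE_SD = 1.5

__all__ = [
    "CLASS_CODES",
    "CLASS_SIGNS",
    "DEFAULT_CLASS_PROPORTIONS",
    "ClassEffect",
    "class_effect_template",
    "simulate_study",
    "simulate_probe_level",
    "simulate_treatment_panel",
]


@dataclass(frozen=True)
class ClassEffect:
    class_code: str
    delta_response: float
    delta_recovery: float


def class_effect_template(class_code: str, d: float) -> ClassEffect:
    """Planted (δ_response, δ_recovery) for a class at effect size ``d`` > 0."""
    if class_code not in CLASS_SIGNS:
        raise ValueError(f"unknown class code {class_code!r}; known: {CLASS_CODES}")
    if not d > 0:
        raise ValueError("effect size d must be positive")
    s_resp, s_rec = CLASS_SIGNS[class_code]
    return ClassEffect(class_code, s_resp * d, s_rec * d)


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(gene_index)]))


def _sample_ids(n_reps: int) -> list[str]:
    return [
        f"{organ}_{cond}_{rep}"
        for organ in ORGANS
        for cond in CONDITIONS
        for rep in range(1, n_reps + 1)
    ]


def _gene_draws(rng: np.random.Generator, n_reps: int, noise_sd: float):
    """Per-organ (class-uniform, baseline, noise) draws in a fixed order.

    The draw order is part of the reproducibility contract: replaying this
    function with the recorded per-gene substream regenerates the gene's
    sample values exactly.
    """
    out = {}
    for organ in ORGANS:
        u = rng.uniform()
        baseline = rng.normal(BASELINE_MEAN, BASELINE_SD)
        eps = rng.normal(0.0, noise_sd, size=(len(CONDITIONS), n_reps))
        out[organ] = (u, baseline, eps)
    return out


def _condition_means(baseline: float, delta_resp: float, delta_rec: float) -> np.ndarray:
    return baseline + np.array([0.0, delta_resp, delta_resp + delta_rec])


def simulate_study(
    n_genes: int,
    class_proportions: dict[str, float] | None = None,
    d: float = 2.0,
    noise_sd: float = 0.25,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the full two-organ study.

    Returns ``(expr, design, truth)``: a genes × (2·3·n_reps) log2 expression
    matrix, the matching design table, and the per-(gene, organ) ground
    truth (planted class, baseline, deltas, noise level, substream seed).
    Classes are planted independently per organ from ``class_proportions``.
    """
    if class_proportions is None:
        class_proportions = DEFAULT_CLASS_PROPORTIONS
    props = np.array([class_proportions.get(c, 0.0) for c in CLASS_CODES])
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions sum to {props.sum()}, expected 1")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    cum = np.cumsum(props)

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    samples = _sample_ids(n_reps)
    values = np.empty((n_genes, len(samples)))
    truth_rows = []
    for i, gid in enumerate(gene_ids):
        draws = _gene_draws(_gene_rng(seed, i), n_reps, noise_sd)
        row = []
        for organ in ORGANS:
            u, baseline, eps = draws[organ]
            cls = CLASS_CODES[int(np.searchsorted(cum, u, side="right"))]
            eff = class_effect_template(cls, d) if cls != "BAR" else ClassEffect("BAR", 0.0, 0.0)
            means = _condition_means(baseline, eff.delta_response, eff.delta_recovery)
            row.append((means[:, None] + eps).ravel())
            truth_rows.append(
                dict(
                    gene_id=gid,
                    organ=organ,
                    class_code=cls,
                    baseline=baseline,
                    delta_response=eff.delta_response,
                    delta_recovery=eff.delta_recovery,
                    d=d,
                    noise_sd=noise_sd,
                    n_reps=n_reps,
                    seed=seed,
                    gene_index=i,
                )
            )
        values[i] = np.concatenate(row)

    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="feature_id"), columns=samples)
    expr.attrs["log2"] = True
    design = pd.DataFrame(
        [
            dict(sample_id=s, organ=s.split("_")[0], condition=s.split("_")[1],
                 replicate=int(s.split("_")[2]))
            for s in samples
        ]
    ).set_index("sample_id", drop=False)
    truth = pd.DataFrame(truth_rows)
    return expr, design, truth


def regenerate_gene_values(truth: pd.DataFrame, gene_id: str) -> pd.Series:
    """Replay one gene's sample values bit-identically from its truth rows."""
    rows = truth[truth["gene_id"] == gene_id]
    if rows.empty:
        raise KeyError(gene_id)
    first = rows.iloc[0]
    n_reps = int(first["n_reps"])
    draws = _gene_draws(
        _gene_rng(int(first["seed"]), int(first["gene_index"])),
        n_reps,
        float(first["noise_sd"]),
    )
    out = {}
    for _, r in rows.iterrows():
        organ = r["organ"]
        _, baseline, eps = draws[organ]
        means = _condition_means(baseline, r["delta_response"], r["delta_recovery"])
        vals = (means[:, None] + eps).ravel()
        for j, cond in enumerate(CONDITIONS):
            for rep in range(1, n_reps + 1):
                out[f"{organ}_{cond}_{rep}"] = vals[j * n_reps + (rep - 1)]
    return pd.Series(out)


def simulate_probe_level(
    truth: pd.DataFrame,
    probes_per_gene: tuple[int, int] = (3, 8),
    affinity_sd: float = 0.3,
    seed: int = 0,
    probe_noise_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expand a gene-level truth table into probe-level data plus a probe map.

    probe value = replayed gene-level sample value
                + per-probe affinity offset ~ Normal(0, affinity_sd²),
                  constant across samples
                + i.i.d. probe-level measurement noise ~ Normal(0, probe_noise_sd²).

    With ``affinity_sd = probe_noise_sd = 0`` (and a zero-noise truth) every
    probe equals its gene's value exactly.
    """
    lo, hi = probes_per_gene
    if lo < 1 or hi < lo:
        raise ValueError("probes_per_gene must be a (min, max) range with min >= 1")
    gene_order = truth.drop_duplicates("gene_id")[["gene_id", "gene_index", "seed", "noise_sd", "n_reps"]]
    n_reps = int(gene_order["n_reps"].iloc[0])
    samples = _sample_ids(n_reps)

    probe_rows, probe_ids, map_rows = [], [], []
    for _, g in gene_order.iterrows():
        gene_vals = regenerate_gene_values(truth, g["gene_id"])[samples].to_numpy()
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(g["gene_index"]), 1]))
        n_probes = int(rng.integers(lo, hi + 1))
        affinities = rng.normal(0.0, affinity_sd, size=n_probes)
        noise = rng.normal(0.0, probe_noise_sd, size=(n_probes, len(samples)))
        block = gene_vals[None, :] + affinities[:, None] + noise
        for j in range(n_probes):
            pid = f"{g['gene_id']}_p{j + 1}"
            probe_ids.append(pid)
            map_rows.append((pid, g["gene_id"]))
        probe_rows.append(block)

    probe_expr = pd.DataFrame(
        np.vstack(probe_rows),
        index=pd.Index(probe_ids, name="feature_id"),
        columns=samples,
    )
    probe_expr.attrs["log2"] = True
    probe_map = pd.Series(
        {pid: gid for pid, gid in map_rows}, name="gene_id"
    ).rename_axis("probe_id")
    return probe_expr, probe_map


def simulate_treatment_panel(
    pi_gene_ids: list[str],
    n_treatments: int,
    overlap_spec: dict[str, set[int]] | None = None,
    d: float = 2.0,
    noise_sd: float = 0.25,
    n_reps: int = 3,
    seed: int = 0,
    universe: list[str] | None = None,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Simulate a panel of treatment-vs-control contrast datasets.

    Gene ``g`` receives effect ``d`` in exactly the treatments listed in
    ``overlap_spec[g]`` (0-based treatment indices); all other (gene,
    treatment) pairs are null.  Each treatment is returned as an
    (expression matrix, design) pair over the shared ``universe`` (defaults
    to ``pi_gene_ids``), with a two-arm mock/starved design on the root
    organ so the standard response contrast computes treated-vs-control.
    """
    overlap_spec = overlap_spec or {}
    if universe is None:
        universe = list(pi_gene_ids)
    universe_set = set(universe)
    unknown = set(overlap_spec) - universe_set
    if unknown:
        raise ValueError(f"overlap_spec genes outside universe: {sorted(unknown)}")
    for g, ts in overlap_spec.items():
        if any((t < 0) or (t >= n_treatments) for t in ts):
            raise ValueError(f"overlap_spec[{g!r}] names a treatment >= n_treatments")
    missing = set(pi_gene_ids) - universe_set
    if missing:
        raise ValueError(f"pi_gene_ids outside universe: {sorted(missing)}")

    treatments = [f"T{t + 1:02d}" for t in range(n_treatments)]
    samples = [f"root_{cond}_{rep}" for cond in ("mock", "starved") for rep in range(1, n_reps + 1)]
    design = pd.DataFrame(
        [
            dict(sample_id=s, organ="root", condition=s.split("_")[1],
                 replicate=int(s.split("_")[2]))
            for s in samples
        ]
    ).set_index("sample_id", drop=False)

    panel = {}
    for t, tid in enumerate(treatments):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7, t]))
        baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=len(universe))
        eps = rng.normal(0.0, noise_sd, size=(len(universe), len(samples)))
        effect = np.array(
            [d if t in overlap_spec.get(g, ()) else 0.0 for g in universe]
        )
        means = np.tile(baselines[:, None], (1, len(samples)))
        means[:, n_reps:] += effect[:, None]  # treated arm
        expr = pd.DataFrame(
            means + eps, index=pd.Index(universe, name="feature_id"), columns=samples
        )
        expr.attrs["log2"] = True
        panel[tid] = (expr, design.copy())
    return panel
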