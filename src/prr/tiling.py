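"""Tiling-array pathway: probe filtering, median polish, σ-rule detection.

Genes not represented on the expression micro-array are assessed from
tiling probes: genes with fewer than 3 mapped probes are excluded, each
remaining gene's probes × samples block is summarized by Tukey median
polish, per-condition abundances are read off the column effects, and the
per-gene condition differences G (response = starved − mock, recovery =
replete − starved) are standardized genome-wide: a gene is called
differentially expressed when |G/σ| ≥ k (default k = 3, inclusive), with σ
the spread of G over all genes for that (organ, contrast).  Flagged genes
are then classified into the same 9 response-and-recovery classes, with
"flagged" playing the role of "significant".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io_core import CONDITIONS, ORGANS
from .response_recovery import _CLASS_OF_FLAGS

#: classes whose definition implies the response / recovery contrast is flagged
RESPONSE_FLAGGED = frozenset({"IPR", "INR", "PPR", "PNR", "CPR", "CNR"})
RECOVERY_FLAGGED = frozenset({"IPR", "INR", "LPR", "LNR", "CPR", "CNR"})

__all__ = [
    "MedianPolishResult",
    "filter_genes_by_probe_count",
    "median_polish",
    "summarize_tiling_abundance",
    "z_score_detect",
    "classify_tiling_gene",
    "classify_tiling",
    "threshold_consistency_scan",
    "load_tiling_worked_examples",
]


def filter_genes_by_probe_count(
    probe_map: pd.Series, min_probes: int = 3
) -> tuple[set[str], dict[str, int]]:
    """Genes with ≥ ``min_probes`` mapped probes, plus an exclusion report."""
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    counts = probe_map.value_counts()
    retained = set(counts.index[counts >= min_probes])
    report = {
        "n_genes": int(counts.size),
        "n_retained": len(retained),
        "n_excluded": int(counts.size - len(retained)),
        "min_probes": int(min_probes),
    }
    return retained, report


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
            + self.residuals
        )


def median_polish(
    matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-4
) -> MedianPolishResult:
    """Tukey median polish: matrix = overall + row + column + residual.

    Alternates removing row and column medians until the largest absolute
    median removed in a sweep falls below ``tol`` or ``max_iter`` sweeps
    are reached.  The additive reconstruction identity holds exactly at
    every step by construction.
    """
    z = np.asarray(matrix, dtype=float).copy()
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish needs a non-empty 2-D matrix")
    if not np.all(np.isfinite(z)):
        raise ValueError("median_polish input must be finite")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        cmed = np.median(col)
        col -= cmed
        overall += cmed
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        rmed = np.median(row)
        row -= rmed
        overall += rmed
        moved = max(np.abs(rdelta).max(), np.abs(cdelta).max())
        if moved < tol:
            break
    return MedianPolishResult(overall, row, col, z)


def summarize_tiling_abundance(
    probe_expr: pd.DataFrame,
    probe_map: pd.Series,
    design: pd.DataFrame,
    min_probes: int = 3,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene condition abundances and contrast differences G.

    For each retained gene and organ, the probes × samples block is median
    polished; a condition's abundance is the overall effect plus the mean
    column effect over that condition's replicates (the probe affinities
    land in the row effects and cancel from all differences).  Columns of
    the result: ``{organ}_{condition}`` abundances and ``{organ}_response``
    / ``{organ}_recovery`` differences.
    """
    retained, report = filter_genes_by_probe_count(probe_map, min_probes)
    probes_by_gene = probe_map[probe_map.isin(retained)].groupby(probe_map).groups

    rows = {}
    for gene in sorted(retained):
        probes = [p for p in probes_by_gene[gene] if p in probe_expr.index]
        if not probes:
            continue
        rec: dict[str, float] = {}
        for organ in ORGANS:
            organ_samples = design.index[design["organ"] == organ]
            organ_samples = [s for s in organ_samples if s in probe_expr.columns]
            if not organ_samples:
                continue
            block = probe_expr.loc[probes, organ_samples].to_numpy()
            mp = median_polish(block, max_iter=max_iter, tol=tol)
            col_eff = pd.Series(mp.col_effects, index=organ_samples)
            for cond in CONDITIONS:
                cond_samples = design.index[
                    (design["organ"] == organ) & (design["condition"] == cond)
                ]
                cond_samples = [s for s in cond_samples if s in col_eff.index]
                if cond_samples:
                    rec[f"{organ}_{cond}"] = mp.overall + col_eff[cond_samples].mean()
            if f"{organ}_starved" in rec and f"{organ}_mock" in rec:
                rec[f"{organ}_response"] = rec[f"{organ}_starved"] - rec[f"{organ}_mock"]
            if f"{organ}_replete" in rec and f"{organ}_starved" in rec:
                rec[f"{organ}_recovery"] = rec[f"{organ}_replete"] - rec[f"{organ}_starved"]
        rows[gene] = rec
    summary = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
    return summary, report


def z_score_detect(
    G, k: float = 3.0, center: str = "zero"
) -> tuple[float, np.ndarray, np.ndarray]:
    """σ-rule detection over a vector of per-gene differences.

    Returns ``(sigma, flags, z)`` with ``z = G/σ`` and a gene flagged iff
    |z| ≥ k (inclusive).  By default σ is the sample standard deviation of
    G about zero (a difference is expected null-centered); ``center="mean"``
    uses the conventional mean-centered deviation instead.
    """
    g = np.asarray(G, dtype=float)
    if g.size < 10:
        raise ValueError("z_score_detect needs >= 10 genes")
    if center == "zero":
        sigma = float(np.sqrt(np.sum(g**2) / (g.size - 1)))
    elif center == "mean":
        sigma = float(np.std(g, ddof=1))
    else:
        raise ValueError("center must be 'zero' or 'mean'")
    if sigma == 0:
        raise ValueError("degenerate input: sigma is zero")
    z = g / sigma
    flags = np.abs(z) >= k
    return sigma, flags, z


def classify_tiling_gene(
    flag_resp: bool, sign_resp: int, flag_rec: bool, sign_rec: int
) -> str:
    """Same 9-class mapping as the micro-array scheme, on σ-rule flags."""
    states = []
    for flag, sign in ((flag_resp, sign_resp), (flag_rec, sign_rec)):
        if flag:
            if sign == 0:
                raise ValueError("flagged contrast with zero difference")
            states.append("+" if sign > 0 else "-")
        else:
            states.append("0")
    return _CLASS_OF_FLAGS[tuple(states)]


def classify_tiling(summary: pd.DataFrame, k: float = 3.0, center: str = "zero") -> pd.DataFrame:
    """σ-rule calls and class codes per organ from an abundance summary."""
    out = pd.DataFrame(index=summary.index)
    for organ in ORGANS:
        flags = {}
        for contrast in ("response", "recovery"):
            col = f"{organ}_{contrast}"
            sigma, fl, z = z_score_detect(summary[col].to_numpy(), k=k, center=center)
            out[f"{col}_z"] = z
            out[f"{col}_flag"] = fl
            out.attrs[f"sigma_{col}"] = sigma
            flags[contrast] = (fl, np.sign(summary[col].to_numpy()).astype(int))
        out[f"{organ}_class"] = [
            classify_tiling_gene(
                flags["response"][0][i], flags["response"][1][i],
                flags["recovery"][0][i], flags["recovery"][1][i],
            )
            for i in range(len(summary))
        ]
    return out


@dataclass
class ThresholdInterval:
    organ: str
    contrast: str
    lower: float          # max |value| among rows whose class implies "not flagged"
    upper: float          # min |value| among rows whose class implies "flagged"
    feasible: bool        # a single cut in (lower, upper] reproduces every label
    violating_rows: list[str]


def threshold_consistency_scan(rows: pd.DataFrame) -> dict[tuple[str, str], ThresholdInterval]:
    """Feasible |G| cut interval per (organ, contrast) from labelled rows.

    ``rows`` must carry ``{organ}_{response,recovery}`` values and
    ``{organ}_class`` labels (as in the packaged worked-example table).  For
    each (organ, contrast) the interval (max unflagged |value|,
    min flagged |value|] is returned; it is non-empty exactly when one
    threshold reproduces every printed label.  Infeasible pairs report the
    violating row identifiers.
    """
    out = {}
    for organ in ORGANS:
        for contrast, flag_classes in (
            ("response", RESPONSE_FLAGGED),
            ("recovery", RECOVERY_FLAGGED),
        ):
            values = rows[f"{organ}_{contrast}"].abs()
            flagged = rows[f"{organ}_class"].isin(flag_classes)
            lower = float(values[~flagged].max()) if (~flagged).any() else 0.0
            upper = float(values[flagged].min()) if flagged.any() else np.inf
            feasible = lower < upper
            violators: list[str] = []
            if not feasible:
                bad = (flagged & (values <= lower)) | (~flagged & (values >= upper))
                ids = rows["gene_id"] if "gene_id" in rows.columns else rows.index.to_series()
                violators = ids[bad.to_numpy()].astype(str).tolist()
            out[(organ, contrast)] = ThresholdInterval(
                organ, contrast, lower, upper, feasible, violators
            )
    return out


def load_tiling_worked_examples() -> pd.DataFrame:
    """Packaged table of tiling-only loci with printed log2 values and classes."""
    with resources.files("prr.data").joinpath("tiling_worked_examples.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
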