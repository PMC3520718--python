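"""Term enrichment, PCA quality summary, and cross-platform concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bonferroni_adjust

__all__ = ["hypergeometric_enrichment", "pca_summary", "platform_concordance"]


def hypergeometric_enrichment(
    gene_set, annotations: pd.DataFrame, universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a gene set.

    For each term with at least one annotated gene in the universe:
    p_raw = P(X ≥ k) with k genes of the set annotated, K of the universe
    annotated, set size n, universe size N.  Bonferroni is over the number
    of terms tested.  Results are sorted by p_raw.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    ann = annotations[annotations["gene_id"].isin(universe)]

    N, n = len(universe), len(gene_set)
    rows = []
    for (term_id, term_name), grp in ann.groupby(["term_id", "term_name"]):
        genes = set(grp["gene_id"])
        K = len(genes)
        k = len(genes & gene_set)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(term_id=term_id, term_name=term_name, k=k, K=K, n=n, N=N, p_raw=p_raw)
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p_raw", "p_adj"]
        )
    out["p_adj"] = bonferroni_adjust(out["p_raw"], len(out))
    return out.sort_values(["p_raw", "term_id"]).reset_index(drop=True)


def pca_summary(
    expr: pd.DataFrame,
    design: pd.DataFrame | None = None,
    n_components: int | None = None,
    scale: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Variance-explained fractions and per-sample scores.

    Genes (rows) are centered — and optionally unit-scaled — then the
    samples × samples covariance is eigen-decomposed.  Fractions are
    non-increasing and sum to ≤ 1 when truncated to ``n_components``.
    The score table is annotated with the design (organ, condition) when
    one is given.
    """
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    xc = x - x.mean(axis=1, keepdims=True)
    if scale:
        sd = xc.std(axis=1, ddof=1, keepdims=True)
        xc = np.divide(xc, sd, out=np.zeros_like(xc), where=sd > 0)
    if not np.any(xc):
        raise ValueError("constant matrix: no variance to decompose")

    cov = xc.T @ xc / max(x.shape[0] - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    eigvecs = eigvecs[:, order]

    k = n_components or min(x.shape) - 1 or 1
    k = min(k, len(eigvals))
    fractions = eigvals[:k] / eigvals.sum()
    scores = pd.DataFrame(
        eigvecs[:, :k] * np.sqrt(eigvals[:k] * max(x.shape[0] - 1, 1)),
        index=expr.columns.rename("sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    if design is not None:
        scores = scores.join(design[["organ", "condition"]], how="left")
    return fractions, scores


def platform_concordance(fc_a, fc_b) -> float:
    """Squared Pearson correlation of two matched per-gene fold-change vectors.

    R² is sign-blind; report direction separately from the correlation's
    sign if it matters.  Vectors must align gene-for-gene and have
    non-zero variance.
    """
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fold-change vectors must be 1-D and matched in length")
    if a.size < 3:
        raise ValueError("need >= 3 matched genes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a fold-change vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r
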