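"""Two-contrast differential expression with Bonferroni control.

The response contrast compares starved vs mock samples, the recovery
contrast replete vs starved, separately per organ.  Per gene, a two-sided
pooled-variance t-test is computed; by default per-gene variances are
moderated with an empirical-Bayes shrinkage toward a prior fitted across
genes by method of moments on the log variances (scaled inverse-chi-square
prior with d0 prior degrees of freedom and prior variance s0²), which adds
d0 to the residual degrees of freedom.  Multiplicity is controlled by
Bonferroni over all genes in the tested matrix, per contrast per organ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

#: (group1, group2) condition pairs; log2 fold-change is mean(g2) − mean(g1).
CONTRASTS = {
    "response": ("mock", "starved"),
    "recovery": ("starved", "replete"),
}

__all__ = ["CONTRASTS", "compute_contrast", "moderate_variances", "bonferroni_adjust"]


def bonferroni_adjust(p_values, m: int) -> np.ndarray:
    """min(1, m·p) for each p; ``m`` is the family size (≥ len(p_values))."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)


def _trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < tol * x:
            x = x_new
            break
        x = x_new
    return x


def moderate_variances(variances, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits a scaled inverse-chi-square prior (d0, s0²) by method of moments on
    the log variances (under the model s²/s0² ~ F(df, d0)) and returns
    ``(var_post, d0, s0_sq)`` where

        var_post = (df·s² + d0·s0²) / (df + d0).

    If the observed spread of log variances does not exceed what sampling
    alone produces, d0 = +inf and every posterior variance equals s0²; if
    all variances are exactly equal, that common value is returned.
    """
    s2 = np.asarray(variances, dtype=float)
    if s2.size < 10:
        raise ValueError("moderation needs >= 10 genes to fit a prior")
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    pos = s2[s2 > 0]
    if pos.size < 10:
        raise ValueError("too few positive variances to fit a prior")
    if np.allclose(s2, s2[0]):
        return s2.copy(), np.inf, float(s2[0])

    e = np.log(pos)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    bias = special.digamma(df / 2) - np.log(df / 2)
    excess = e_var - special.polygamma(1, df / 2)
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean - bias))
    else:
        x = _trigamma_inverse(float(excess))
        d0 = 2 * x
        s0_sq = float(np.exp(e_mean - bias + special.digamma(x) - np.log(x)))

    if np.isinf(d0):
        var_post = np.full_like(s2, s0_sq)
    else:
        var_post = (df * s2 + d0 * s0_sq) / (df + d0)
    return var_post, float(d0), s0_sq


def compute_contrast(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    organ: str,
    contrast_label: str,
    moderation: bool = True,
) -> pd.DataFrame:
    """Per-gene contrast for one organ.

    Returns a DataFrame indexed by gene with columns ``log2_fc``, ``t_stat``,
    ``df``, ``p_raw``, ``p_adj``, ``contrast_label``, ``organ``.  Bonferroni
    uses all genes in ``expr`` as the family.
    """
    if contrast_label not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast_label!r}; known: {list(CONTRASTS)}")
    cond1, cond2 = CONTRASTS[contrast_label]
    sub = design[design["organ"] == organ]
    g1 = sub.index[sub["condition"] == cond1]
    g2 = sub.index[sub["condition"] == cond2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"contrast {contrast_label!r} in organ {organ!r} needs >= 2 replicates "
            f"per condition (found {len(g1)} {cond1}, {len(g2)} {cond2})"
        )
    missing = (set(g1) | set(g2)) - set(expr.columns)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)}")

    a = expr[list(g1)].to_numpy()
    b = expr[list(g2)].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    fc = b.mean(axis=1) - a.mean(axis=1)
    df_resid = n1 + n2 - 2
    pooled = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df_resid

    if moderation:
        var_use, d0, _ = moderate_variances(pooled, df_resid)
        df_total = df_resid + d0
    else:
        var_use = pooled
        df_total = float(df_resid)

    se = np.sqrt(var_use * (1 / n1 + 1 / n2))
    t = np.divide(fc, se, out=np.zeros_like(fc), where=se > 0)
    degenerate = (se == 0) & (fc != 0)  # zero variance, non-zero difference
    t[degenerate] = np.sign(fc[degenerate]) * np.inf
    if np.isinf(df_total):
        p_raw = 2 * stats.norm.sf(np.abs(t))
    else:
        p_raw = 2 * stats.t.sf(np.abs(t), df_total)
    p_raw = np.where((se == 0) & (fc == 0), 1.0, p_raw)
    p_raw = np.where(np.isinf(t), 0.0, p_raw)

    m = expr.shape[0]
    out = pd.DataFrame(
        {
            "log2_fc": fc,
            "t_stat": t,
            "df": df_total,
            "p_raw": p_raw,
            "p_adj": bonferroni_adjust(p_raw, m),
            "contrast_label": contrast_label,
            "organ": organ,
        },
        index=expr.index.rename("gene_id"),
    )
    return out
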