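"""The 9-class response-and-recovery scheme and its count summaries.

Each gene is judged on two contrasts per organ — response (starved vs mock)
and recovery (replete vs starved) — each either significant (Bonferroni
p ≤ α, default 0.001, inclusive) with a direction, or "no change".  The
2×3 outcome grid yields 9 classes:

    ========  =========  =========
    code      response   recovery
    ========  =========  =========
    BAR       no change  no change
    CPR       sig +      sig +
    IPR       sig +      sig −
    PPR       sig +      no change
    LPR       no change  sig +
    CNR       sig −      sig −
    INR       sig −      sig +
    PNR       sig −      no change
    LNR       no change  sig −
    ========  =========  =========

Comparing a gene's root class against its shoot class gives a 9×9 joint
matrix (up to 81 organ patterns); "responsive" means any non-BAR class, and
"common" counts genes responsive in both organs.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .simulate import CLASS_CODES, CLASS_SIGNS

#: (response state, recovery state) → class; states are '+', '-', or '0'.
_SIGN_CHAR = {1: "+", -1: "-", 0: "0"}
_CLASS_OF_FLAGS = {
    (_SIGN_CHAR[r], _SIGN_CHAR[c]): code for code, (r, c) in CLASS_SIGNS.items()
}

PHASE_OF_CLASS = {
    "BAR": "basal",
    "CPR": "continuous",
    "CNR": "continuous",
    "IPR": "initial",
    "INR": "initial",
    "PPR": "persistent",
    "PNR": "persistent",
    "LPR": "latent",
    "LNR": "latent",
}

__all__ = [
    "PHASE_OF_CLASS",
    "classify_call",
    "classify_organ",
    "summarize_classes",
    "joint_class_matrix",
    "linear_fold_change",
]


def classify_call(
    p_adj_response: float,
    fc_response: float,
    p_adj_recovery: float,
    fc_recovery: float,
    alpha: float = 0.001,
) -> str:
    """Class code for one gene from its two adjusted p-values and fold-changes."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    states = []
    for p, fc in ((p_adj_response, fc_response), (p_adj_recovery, fc_recovery)):
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p <= alpha:
            if fc == 0:
                raise ValueError("significant contrast with fold-change exactly 0")
            states.append("+" if fc > 0 else "-")
        else:
            states.append("0")
    return _CLASS_OF_FLAGS[tuple(states)]


def classify_organ(
    response: pd.DataFrame, recovery: pd.DataFrame, alpha: float = 0.001
) -> pd.DataFrame:
    """Classify every gene of one organ from its two contrast tables.

    ``response`` and ``recovery`` are ``compute_contrast`` outputs over the
    same organ and identical gene sets.  The returned table records, per
    gene, the significance flag and fold-change sign of each contrast
    (sign is reported from the fold-change regardless of significance;
    significance alone drives the class) and the resulting class code.
    """
    if set(response.index) != set(recovery.index):
        diff = set(response.index) ^ set(recovery.index)
        raise ValueError(f"contrast gene sets differ ({len(diff)} genes in symmetric difference)")
    organs = set(response.get("organ", [])) | set(recovery.get("organ", []))
    if len(organs) > 1:
        raise ValueError(f"contrasts mix organs: {sorted(organs)}")
    rec = recovery.reindex(response.index)

    sig_resp = response["p_adj"].to_numpy() <= alpha
    sig_rec = rec["p_adj"].to_numpy() <= alpha
    fc_resp = response["log2_fc"].to_numpy()
    fc_rec = rec["log2_fc"].to_numpy()
    if np.any(sig_resp & (fc_resp == 0)) or np.any(sig_rec & (fc_rec == 0)):
        raise ValueError("significant contrast with fold-change exactly 0")

    resp_state = np.where(sig_resp, np.where(fc_resp > 0, "+", "-"), "0")
    rec_state = np.where(sig_rec, np.where(fc_rec > 0, "+", "-"), "0")
    codes = [_CLASS_OF_FLAGS[(r, c)] for r, c in zip(resp_state, rec_state)]

    return pd.DataFrame(
        {
            "organ": organs.pop() if organs else "",
            "response_significant": sig_resp,
            "response_sign": np.where(fc_resp > 0, "+", np.where(fc_resp < 0, "-", "0")),
            "response_log2_fc": fc_resp,
            "recovery_significant": sig_rec,
            "recovery_sign": np.where(fc_rec > 0, "+", np.where(fc_rec < 0, "-", "0")),
            "recovery_log2_fc": fc_rec,
            "class_code": codes,
            "alpha": alpha,
        },
        index=response.index.rename("gene_id"),
    )


def summarize_classes(calls: pd.DataFrame) -> dict[str, int]:
    """Per-class counts plus phase aggregates for one organ's calls.

    Aggregates: initial = IPR+INR, persistent = PPR+PNR, latent = LPR+LNR,
    continuous = CPR+CNR, responsive = everything except BAR.
    """
    if "organ" in calls.columns and calls["organ"].nunique() > 1:
        raise ValueError("summarize_classes expects calls from a single organ")
    counts = calls["class_code"].value_counts()
    out = {code: int(counts.get(code, 0)) for code in CLASS_CODES}
    out["initial"] = out["IPR"] + out["INR"]
    out["persistent"] = out["PPR"] + out["PNR"]
    out["latent"] = out["LPR"] + out["LNR"]
    out["continuous"] = out["CPR"] + out["CNR"]
    out["responsive"] = out["initial"] + out["persistent"] + out["latent"] + out["continuous"]
    out["total"] = int(len(calls))
    return out


def joint_class_matrix(
    root_calls: pd.DataFrame, shoot_calls: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """9×9 root (rows) × shoot (columns) class count matrix plus totals.

    Totals use inclusion–exclusion over responsiveness: ``common`` counts
    genes responsive (non-BAR) in both organs, ``union`` = root_responsive
    + shoot_responsive − common.  ``systemic_same_class`` counts diagonal
    cells excluding BAR/BAR.
    """
    if set(root_calls.index) != set(shoot_calls.index):
        raise ValueError("root and shoot calls must cover the same gene universe")
    shoot = shoot_calls.reindex(root_calls.index)
    matrix = pd.crosstab(
        root_calls["class_code"], shoot["class_code"],
        rownames=["root"], colnames=["shoot"],
    ).reindex(index=CLASS_CODES, columns=CLASS_CODES, fill_value=0)

    root_resp = root_calls["class_code"] != "BAR"
    shoot_resp = shoot["class_code"] != "BAR"
    common = int((root_resp & shoot_resp).sum())
    totals = {
        "n_genes": int(len(root_calls)),
        "root_responsive": int(root_resp.sum()),
        "shoot_responsive": int(shoot_resp.sum()),
        "common": common,
        "union": int(root_resp.sum() + shoot_resp.sum() - common),
        "root_only": int((root_resp & ~shoot_resp).sum()),
        "shoot_only": int((~root_resp & shoot_resp).sum()),
        "systemic_same_class": int(
            sum(matrix.loc[c, c] for c in CLASS_CODES if c != "BAR")
        ),
    }
    return matrix, totals


def linear_fold_change(log2_fc: float, decimals: int = 0) -> float:
    """Linear-scale fold magnitude 2^|log2_fc|, rounded half-up.

    Direction is not encoded — report it separately from the sign of the
    log2 value.  Half-up rounding matches how fold-changes are quoted in
    print (e.g. log2 5.971 → 63-fold at 0 decimals).
    """
    magnitude = 2.0 ** abs(float(log2_fc))
    quantum = Decimal(1).scaleb(-int(decimals))
    return float(Decimal(repr(magnitude)).quantize(quantum, rounding=ROUND_HALF_UP))
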