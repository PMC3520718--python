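import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_calls
from prr import diffexpr, simulate
from prr.response_recovery import (
    classify_call,
    classify_organ,
    joint_class_matrix,
    linear_fold_change,
    summarize_classes,
)

# independent statement of the scheme: (response state, recovery state) → class
TRUTH_TABLE = {
    ("0", "0"): "BAR",
    ("+", "+"): "CPR",
    ("+", "-"): "IPR",
    ("+", "0"): "PPR",
    ("0", "+"): "LPR",
    ("-", "-"): "CNR",
    ("-", "+"): "INR",
    ("-", "0"): "PNR",
    ("0", "-"): "LNR",
}


class TestClassifyCall:
    def test_exhaustive_truth_table(self):
        """Every (significance, sign) combination maps to exactly the class
        the scheme defines; all 9 classes are reachable and partition the
        flag space with no ambiguity."""
        seen = {}
        for p_r, fc_r, p_c, fc_c in itertools.product(
            [1e-4, 0.5], [+1.7, -1.7], repeat=2
        ):
            state = (
                ("+" if fc_r > 0 else "-") if p_r <= 0.001 else "0",
                ("+" if fc_c > 0 else "-") if p_c <= 0.001 else "0",
            )
            code = classify_call(p_r, fc_r, p_c, fc_c, alpha=0.001)
            assert code == TRUTH_TABLE[state]
            seen.setdefault(state, set()).add(code)
        assert set().union(*seen.values()) == set(TRUTH_TABLE.values())
        assert all(len(v) == 1 for v in seen.values())

    @pytest.mark.parametrize(
        "args,expected",
        [
            ((1e-4, +2.0, 1e-4, -2.0), "IPR"),
            ((0.5, +0.1, 0.7, -0.1), "BAR"),
            ((0.2, -0.3, 1e-5, -1.4), "LNR"),
        ],
    )
    def test_worked_examples(self, args, expected):
        assert classify_call(*args, alpha=0.001) == expected

    def test_alpha_boundary_inclusive(self):
        assert classify_call(0.001, 1.0, 0.5, 0.0) == "PPR"

    def test_bad_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            classify_call(0.5, 1, 0.5, 1, alpha=0)

    def test_significant_with_zero_fc(self):
        with pytest.raises(ValueError, match="exactly 0"):
            classify_call(1e-5, 0.0, 0.5, 1.0)


class TestClassifyOrgan:
    def test_all_null_is_all_basal(self):
        expr, design, _ = simulate.simulate_study(
            50, {"BAR": 1.0}, noise_sd=0.25, seed=21
        )
        resp = diffexpr.compute_contrast(expr, design, "root", "response")
        rec = diffexpr.compute_contrast(expr, design, "root", "recovery")
        calls = classify_organ(resp, rec)
        assert (calls["class_code"] == "BAR").all()

    def test_partition_property(self, small_root_calls):
        calls, _ = small_root_calls
        counts = summarize_classes(calls)
        assert counts["responsive"] + counts["BAR"] == counts["total"] == len(calls)

    def test_mismatched_gene_sets_reports_size(self, small_study):
        expr, design, _ = small_study
        resp = diffexpr.compute_contrast(expr, design, "root", "response")
        rec = diffexpr.compute_contrast(expr.iloc[:-3], design, "root", "recovery")
        with pytest.raises(ValueError, match="3 genes"):
            classify_organ(resp, rec)

    def test_alpha_monotonicity_never_moves_into_basal(self, small_study):
        expr, design, _ = small_study
        resp = diffexpr.compute_contrast(expr, design, "root", "response")
        rec = diffexpr.compute_contrast(expr, design, "root", "recovery")
        strict = classify_organ(resp, rec, alpha=0.001)
        relaxed = classify_organ(resp, rec, alpha=0.05)
        moved_to_bar = (strict["class_code"] != "BAR") & (relaxed["class_code"] == "BAR")
        assert not moved_to_bar.any()


class TestSummaries:
    def test_root_composition_totals(self):
        calls = make_calls(
            {"IPR": 310, "INR": 110, "PPR": 47, "PNR": 50, "LPR": 420, "LNR": 320},
            organ="root",
        )
        c = summarize_classes(calls)
        assert c["responsive"] == 1257
        assert c["latent"] == 740
        assert c["initial"] + c["persistent"] == 517

    def test_shoot_composition_totals(self):
        calls = make_calls(
            {"IPR": 69, "INR": 1, "PPR": 18, "PNR": 2, "LPR": 23, "LNR": 69},
            organ="shoot",
        )
        assert summarize_classes(calls)["responsive"] == 182

    def test_all_basal(self):
        calls = make_calls({"BAR": 40}, organ="root")
        assert summarize_classes(calls)["responsive"] == 0


class TestJointMatrix:
    def test_matrix_has_81_cells_and_conserves_genes(self, small_study):
        expr, design, _ = small_study
        calls = {}
        for organ in ("root", "shoot"):
            resp = diffexpr.compute_contrast(expr, design, organ, "response")
            rec = diffexpr.compute_contrast(expr, design, organ, "recovery")
            calls[organ] = classify_organ(resp, rec)
        matrix, totals = joint_class_matrix(calls["root"], calls["shoot"])
        assert matrix.shape == (9, 9)
        assert matrix.size == 81
        assert matrix.to_numpy().sum() == totals["n_genes"] == len(expr)
        assert totals["union"] == (
            totals["root_responsive"] + totals["shoot_responsive"] - totals["common"]
        )

    def test_identical_calls_put_all_mass_on_diagonal(self):
        calls = make_calls({"BAR": 10, "IPR": 5, "LNR": 3}, organ="root")
        shoot = calls.assign(organ="shoot")
        matrix, totals = joint_class_matrix(calls, shoot)
        assert np.trace(matrix.to_numpy()) == len(calls)
        assert totals["systemic_same_class"] == 8  # IPR + LNR, BAR/BAR excluded

    def test_universe_mismatch(self):
        a = make_calls({"BAR": 5}, organ="root")
        b = make_calls({"BAR": 6}, organ="shoot")
        with pytest.raises(ValueError, match="universe"):
            joint_class_matrix(a, b)


class TestLinearFoldChange:
    @pytest.mark.parametrize(
        "log2_fc,decimals,expected",
        [(5.971, 0, 63), (4.291, 1, 19.6), (0, 0, 1), (-5.971, 0, 63), (2.678, 0, 6.0)],
    )
    def test_values(self, log2_fc, decimals, expected):
        assert linear_fold_change(log2_fc, decimals) == expected


class TestFullRecoveryLine:
    def test_initial_responders_fall_on_y_equals_minus_x_at_zero_noise(self):
        """Genes that respond then fully recover satisfy response_fc = −recovery_fc."""
        expr, design, _ = simulate.simulate_study(
            30, {"IPR": 0.5, "INR": 0.5}, d=2.0, noise_sd=0.0, seed=13
        )
        resp = diffexpr.compute_contrast(expr, design, "root", "response", moderation=False)
        rec = diffexpr.compute_contrast(expr, design, "root", "recovery", moderation=False)
        assert np.allclose(resp["log2_fc"] + rec["log2_fc"], 0.0)
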