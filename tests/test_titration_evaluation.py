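import numpy as np
import pandas as pd
import pytest

from betam.core_metrics import MethylationMatrix, beta_to_m, compute_beta, compute_m
from betam.differential import differential_analysis, select_candidates
from betam.synthetic_titration import TitrationDesign, default_design, simulate_titration
from betam.titration_evaluation import (
    EvaluationCurve,
    TruePositiveSet,
    define_true_positives,
    dr,
    suggest_thresholds,
    threshold_sweep,
    titration_profile,
    top_n_curve,
    tpr,
)

from conftest import GROUP_A, GROUP_B


def _tp(ids):
    return TruePositiveSet(
        site_ids=list(ids), r_threshold=0.8,
        correlations=pd.DataFrame(
            {"r_beta": 1.0, "r_m": 1.0}, index=pd.Index(list(ids), name="TargetID")
        ),
    )


def _pair_matrices(beta_values, design):
    beta = MethylationMatrix(
        site_ids=[f"cg{i}" for i in range(beta_values.shape[0])],
        array_ids=design.array_ids,
        values=beta_values,
        scale="beta",
    )
    return beta, beta_to_m(beta)


class TestProfileAndTP:
    def test_default_profile(self):
        np.testing.assert_allclose(
            titration_profile(default_design()),
            [1.0, 1.0, 0.9, 0.9, 0.75, 0.5, 0.0, 0.0],
        )

    def test_profile_length_matches_arrays(self):
        d = default_design()
        assert len(titration_profile(d)) == d.n_arrays

    def test_affine_site_is_included_constant_site_excluded(self):
        d = default_design()
        f = titration_profile(d)
        vals = np.vstack([0.1 + 0.5 * f,           # perfectly affine: |r| = 1
                          np.full(8, 0.4)])        # constant: r undefined
        beta, m = _pair_matrices(vals, d)
        tp = define_true_positives(beta, m, d)
        assert tp.site_ids == ["cg0"]
        assert np.isnan(tp.correlations.loc["cg1", "r_beta"])

    def test_anticorrelated_site_is_included(self):
        d = default_design()
        f = titration_profile(d)
        beta, m = _pair_matrices(np.vstack([0.9 - 0.6 * f]), d)
        tp = define_true_positives(beta, m, d)
        assert tp.site_ids == ["cg0"]

    def test_requires_criterion_on_both_scales(self):
        d = default_design()
        f = titration_profile(d)
        rng = np.random.default_rng(0)
        # strong signal on the beta scale, wrecked on the m scale by replacing
        # m with noise via a hand-built mismatched matrix
        beta_vals = np.vstack([0.2 + 0.5 * f])
        beta = MethylationMatrix(site_ids=["cg0"], array_ids=d.array_ids,
                                 values=beta_vals, scale="beta")
        m_noise = MethylationMatrix(site_ids=["cg0"], array_ids=d.array_ids,
                                    values=rng.normal(size=(1, 8)), scale="m")
        tp = define_true_positives(beta, m_noise, d)
        assert tp.site_ids == []

    def test_constant_design_rejected(self):
        d = TitrationDesign(arrays=[("a1", 0.5, "Mix"), ("a2", 0.5, "Mix")])
        beta, m = _pair_matrices(np.array([[0.1, 0.9]]), d)
        with pytest.raises(ValueError):
            define_true_positives(beta, m, d)

    def test_recovery_on_simulated_truth(self):
        # low-noise simulation: nearly all strongly differential sites are
        # recovered, few null sites slip in
        x, truth = simulate_titration(
            n_sites=10_000, diff_fraction=0.3, gamma_shape=200.0,
            replicate_cv=0.02, seed=11,
        )
        tp = define_true_positives(compute_beta(x), compute_m(x), default_design())
        tp_set = tp.as_set
        strong = truth.is_differential & (np.abs(truth.p_A - truth.p_B) >= 0.3)
        recovered = np.mean([s in tp_set for s, keep in
                             zip(truth.site_ids, strong) if keep])
        null_rate = np.mean([s in tp_set for s, null in
                             zip(truth.site_ids, ~truth.is_differential) if null])
        assert recovered >= 0.95
        assert null_rate <= 0.07


class TestRates:
    def test_tpr_formula(self):
        tp = _tp("abcdefgh")
        assert tpr({"a", "b", "c", "d", "z"}, tp) == pytest.approx(0.8)
        assert tpr({"a", "b"}, tp) == 1.0
        assert tpr({"x", "y"}, tp) == 0.0

    def test_tpr_empty_detected_undefined(self):
        with pytest.raises(ValueError):
            tpr(set(), _tp("ab"))

    def test_dr_formula(self):
        tp = _tp("abcdefgh")
        assert dr({"a", "b", "c", "d", "z"}, tp) == pytest.approx(0.5)
        assert dr(set("abcdefgh") | {"z"}, tp) == 1.0
        assert dr(set(), tp) == 0.0

    def test_dr_empty_tp_rejected(self):
        with pytest.raises(ValueError):
            dr({"a"}, _tp([]))

    def test_invariant_to_site_relabeling(self):
        tp1, det1 = _tp(["s1", "s2"]), {"s1", "s3"}
        tp2, det2 = _tp(["x1", "x2"]), {"x1", "x3"}
        assert tpr(det1, tp1) == tpr(det2, tp2)
        assert dr(det1, tp1) == dr(det2, tp2)


class TestTopNCurve:
    def test_grid_includes_terminal_point(self):
        ranked = [f"s{i}" for i in range(120)]
        curve = top_n_curve(ranked, _tp(ranked[:10]), step=50)
        assert list(curve.table["x"]) == [50, 100, 120]

    def test_exact_multiple_has_no_duplicate_terminal(self):
        ranked = [f"s{i}" for i in range(100)]
        curve = top_n_curve(ranked, _tp(ranked[:10]), step=50)
        assert list(curve.table["x"]) == [50, 100]

    def test_dr_non_decreasing(self, eval_matrices):
        beta, m, _ = eval_matrices
        tp = define_true_positives(beta, m, default_design())
        res = differential_analysis(m, GROUP_A, GROUP_B)
        curve = top_n_curve(select_candidates(res), tp)
        assert np.all(np.diff(curve.table["dr"]) >= 0)

    def test_perfect_method_has_unit_tpr(self):
        ranked = [f"s{i}" for i in range(100)]
        tp = _tp(ranked)
        curve = top_n_curve(list(reversed(ranked)), tp, step=30)
        assert np.allclose(curve.table["tpr"], 1.0)

    def test_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(44)
        ranked = [f"s{i}" for i in range(200)]
        tp = _tp(rng.choice(ranked, size=60, replace=False))
        curve = top_n_curve(ranked, tp, step=50)
        for _, row in curve.table.iterrows():
            n = int(row["x"])
            detected = set(ranked[:n])
            assert row["tpr"] == pytest.approx(tpr(detected, tp))
            assert row["dr"] == pytest.approx(dr(detected, tp))

    def test_roc_points_are_one_minus_dr(self):
        ranked = [f"s{i}" for i in range(60)]
        curve = top_n_curve(ranked, _tp(ranked[:20]), step=20)
        np.testing.assert_allclose(curve.roc_points["one_minus_dr"],
                                   1.0 - curve.table["dr"])


class TestThresholdSweep:
    def _setup(self, eval_matrices):
        beta, m, _ = eval_matrices
        tp = define_true_positives(beta, m, default_design())
        res = differential_analysis(m, GROUP_A, GROUP_B)
        return res, tp

    def test_threshold_zero_equals_pure_p_gate(self, eval_matrices):
        res, tp = self._setup(eval_matrices)
        curve = threshold_sweep(res, tp, [0.0, 0.5, 1.0])
        detected = select_candidates(res, 0.05, 0.0)
        assert curve.table["tpr"].iloc[0] == pytest.approx(tpr(detected, tp))
        assert curve.table["n_detected"].iloc[0] == len(detected)

    def test_n_detected_non_increasing(self, eval_matrices):
        res, tp = self._setup(eval_matrices)
        curve = threshold_sweep(res, tp, np.linspace(0, 2.0, 11))
        assert np.all(np.diff(curve.table["n_detected"]) <= 0)

    def test_decreasing_thresholds_rejected(self, eval_matrices):
        res, tp = self._setup(eval_matrices)
        with pytest.raises(ValueError):
            threshold_sweep(res, tp, [0.5, 0.0])

    def test_empty_detection_gives_missing_tpr(self, eval_matrices):
        res, tp = self._setup(eval_matrices)
        curve = threshold_sweep(res, tp, [50.0, 60.0])  # beyond any m diff
        assert curve.table["n_detected"].iloc[-1] == 0
        assert np.isnan(curve.table["tpr"].iloc[-1])
        assert curve.table["dr"].iloc[-1] == 0.0


def _step_curve(thresholds, tpr_vals, dr_vals):
    return EvaluationCurve(
        table=pd.DataFrame({"x": thresholds,
                            "n_detected": np.arange(len(thresholds))[::-1] + 1,
                            "tpr": tpr_vals, "dr": dr_vals}),
        axis="threshold",
    )


class TestSuggestThresholds:
    def test_step_shaped_curve_recovers_printed_range(self):
        # DR flat to 0.4 then falling; TPR rising to a plateau from 1.4 on
        th = np.round(np.arange(0.0, 2.01, 0.2), 10)
        dr_vals = np.where(th <= 0.4, 0.9, 0.9 - 0.3 * (th - 0.4))
        tpr_vals = np.where(th >= 1.4, 0.95, 0.5 + (0.45 / 1.4) * th)
        sug = suggest_thresholds(_step_curve(th, tpr_vals, dr_vals))
        assert sug.lower == pytest.approx(0.4)
        assert sug.upper == pytest.approx(1.4)
        assert not sug.inconsistent

    def test_flat_curves_flagged_degenerate(self):
        th = [0.0, 0.5, 1.0]
        with pytest.warns(RuntimeWarning, match="inconsistent"):
            sug = suggest_thresholds(_step_curve(th, [0.7] * 3, [0.9] * 3))
        assert sug.lower == 1.0 and sug.upper == 0.0
        assert sug.inconsistent

    def test_zero_tolerance_on_exact_plateau(self):
        th = np.array([0.0, 0.4, 0.8, 1.2])
        dr_vals = np.array([0.9, 0.9, 0.5, 0.2])
        tpr_vals = np.array([0.5, 0.8, 0.95, 0.95])
        a = suggest_thresholds(_step_curve(th, tpr_vals, dr_vals),
                               plateau_tolerance=0.02)
        b = suggest_thresholds(_step_curve(th, tpr_vals, dr_vals),
                               plateau_tolerance=0.0)
        assert (a.lower, a.upper) == (b.lower, b.upper) == (0.4, 0.8)

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            suggest_thresholds(_step_curve([0.0, 0.1], [0.5, 0.6], [0.9, 0.8]))

    def test_top_n_curve_rejected(self):
        curve = top_n_curve([f"s{i}" for i in range(10)], _tp(["s0"]), step=5)
        with pytest.raises(ValueError):
            suggest_thresholds(curve)
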