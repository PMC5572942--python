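import numpy as np
import pandas as pd
import pytest

from richclubnet.errors import DegenerateMetricError, ValidationError
from richclubnet.group_stats import (
    DEFAULT_AVLT_NORMS,
    adjusted_permutation_test,
    ancova_lsd,
    classify_memory_status,
    cognitive_composites,
    partial_correlation,
    stepwise_regression,
)
from richclubnet.synthetic_cohort import generate_raw_scores


class TestComposites:
    def test_subject_at_sample_mean_scores_zero(self):
        raw = generate_raw_scores(["HC"] * 9, seed=1)
        means = raw.mean()
        raw.loc[len(raw)] = means  # append a perfectly average subject
        comp = cognitive_composites(raw)
        # z of derived components uses the same derived means, so the average
        # subject sits at 0 on every domain
        assert comp.executive[-1] == pytest.approx(0.0, abs=1e-10)
        assert comp.speed[-1] == pytest.approx(0.0, abs=1e-10)
        assert comp.memory[-1] == pytest.approx(0.0, abs=1e-10)

    def test_slower_tmt_b_strictly_lowers_executive(self):
        raw = generate_raw_scores(["HC"] * 8, seed=2)
        comp0 = cognitive_composites(raw, standardization_sample=[True] * 8)
        slowed = raw.copy()
        slowed.loc[0, "tmt_b"] += 30.0
        # standardize over the unchanged subjects to isolate the monotone effect
        mask = [False] + [True] * 7
        c_before = cognitive_composites(raw, standardization_sample=mask)
        c_after = cognitive_composites(slowed, standardization_sample=mask)
        assert c_after.executive[0] < c_before.executive[0]
        assert comp0.executive.shape == (8,)

    def test_matches_hand_computed_z_averages(self):
        raw = pd.DataFrame({
            "tmt_a": [30.0, 40, 50, 60, 45, 35],
            "tmt_b": [80.0, 120, 150, 200, 130, 100],
            "stroop_a": [20.0, 25, 30, 28, 22, 26],
            "stroop_c": [50.0, 70, 90, 95, 60, 75],
            "dst_forward": [8.0, 7, 6, 5, 8, 7],
            "dst_backward": [6.0, 4, 3, 2, 5, 4],
            "sdmt": [40.0, 35, 25, 20, 38, 30],
            "avlt_n1": [5.0, 4, 3, 2, 5, 4],
            "avlt_n2": [6.0, 5, 4, 3, 6, 5],
            "avlt_n3": [7.0, 6, 5, 3, 7, 5],
            "avlt_n4": [8.0, 6, 5, 4, 7, 6],
            "avlt_n5": [8.0, 7, 5, 3, 7, 6],
            "lmt": [12.0, 10, 8, 5, 11, 9],
        })

        def z(series):
            return (series - series.mean()) / series.std(ddof=1)

        exec_hand = np.mean([-z(raw.tmt_b - raw.tmt_a),
                             -z(raw.stroop_c - raw.stroop_a),
                             z(raw.dst_backward - raw.dst_forward)], axis=0)
        speed_hand = np.mean([-z(raw.stroop_a), -z(raw.tmt_a), z(raw.sdmt)], axis=0)
        mem_hand = np.mean([
            z(raw[["avlt_n1", "avlt_n2", "avlt_n3", "avlt_n4", "avlt_n5"]].mean(axis=1)),
            z(raw.lmt)], axis=0)
        comp = cognitive_composites(raw)
        assert np.allclose(comp.executive, exec_hand, atol=1e-12)
        assert np.allclose(comp.speed, speed_hand, atol=1e-12)
        assert np.allclose(comp.memory, mem_hand, atol=1e-12)

    def test_affine_rescaling_of_a_raw_test_is_absorbed(self):
        raw = generate_raw_scores(["HC"] * 10, seed=5)
        comp1 = cognitive_composites(raw)
        scaled = raw.copy()
        scaled["sdmt"] = scaled["sdmt"] * 3.0 + 7.0
        comp2 = cognitive_composites(scaled)
        assert np.allclose(comp1.speed, comp2.speed, atol=1e-10)

    def test_missing_scores_use_available_components(self):
        raw = generate_raw_scores(["HC"] * 6, seed=6)
        raw.loc[0, ["tmt_a", "tmt_b"]] = np.nan  # the TMT-missing subject
        comp = cognitive_composites(raw)
        assert np.isfinite(comp.executive[0])  # built from the other components

    def test_zero_variance_component_rejected(self):
        raw = generate_raw_scores(["HC"] * 5, seed=7)
        raw["sdmt"] = 30.0
        with pytest.raises(DegenerateMetricError):
            cognitive_composites(raw)


class TestMemoryStatus:
    def test_published_cutoff_at_four(self):
        assert classify_memory_status(55, 9, 4) == "memory_deficit"
        assert classify_memory_status(55, 9, 5) == "intact"

    def test_missing_stratum_is_an_error(self):
        with pytest.raises(ValidationError, match="stratum"):
            classify_memory_status(85, 9, 4, DEFAULT_AVLT_NORMS)

    def test_custom_norm_table(self):
        table = pd.DataFrame([{"age_min": 60, "age_max": 79, "cutoff": 3}])
        assert classify_memory_status(70, 12, 3, table) == "memory_deficit"
        assert classify_memory_status(70, 12, 4, table) == "intact"


class TestAdjustedPermutationTest:
    def test_reduces_to_unadjusted_when_covariates_are_noise(self, rng):
        n = 60
        groups = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        y = rng.normal(0, 1, n) + 0.8 * (groups == "A")
        cov = pd.DataFrame({"junk": rng.normal(0, 1, n)})
        p_adj = adjusted_permutation_test(y, groups, cov, n_perm=2000, seed=0,
                                          posthoc=False).p_value
        p_raw = adjusted_permutation_test(y, groups, None, n_perm=2000, seed=0,
                                          posthoc=False).p_value
        assert abs(p_adj - p_raw) < 0.05

    def test_power_for_one_sd_shift_at_study_sizes(self, rng):
        hits = 0
        reps = 40
        for rep in range(reps):
            groups = np.array(["LLD-MD"] * 15 + ["LLD-IM"] * 24 + ["HC"] * 30)
            y = rng.normal(0, 1, 69) + 1.0 * (groups == "HC")
            cov = pd.DataFrame({"age": rng.normal(65, 5, 69)})
            res = adjusted_permutation_test(y, groups, cov, n_perm=300, seed=rep,
                                            posthoc=False)
            hits += res.p_value < 0.05
        assert hits / reps > 0.8

    def test_seed_reproducible_and_subject_order_invariant(self, rng):
        n = 30
        groups = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        y = rng.normal(0, 1, n)
        cov = pd.DataFrame({"age": rng.normal(60, 4, n)})
        r1 = adjusted_permutation_test(y, groups, cov, n_perm=500, seed=3)
        r2 = adjusted_permutation_test(y, groups, cov, n_perm=500, seed=3)
        assert r1.p_value == r2.p_value
        # permuting subject order leaves the observed statistic unchanged
        perm = np.random.default_rng(5).permutation(n)
        r3 = adjusted_permutation_test(y[perm], groups[perm],
                                       cov.iloc[perm].reset_index(drop=True),
                                       n_perm=500, seed=3)
        assert r3.statistic == pytest.approx(r1.statistic)

    def test_posthoc_covers_all_pairs(self, rng):
        groups = np.array(["A"] * 8 + ["B"] * 8 + ["C"] * 8)
        y = rng.normal(0, 1, 24)
        res = adjusted_permutation_test(y, groups, None, n_perm=100, seed=1)
        assert set(res.posthoc) == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_group_with_single_subject_rejected(self, rng):
        groups = np.array(["A"] * 5 + ["B"])
        with pytest.raises(ValidationError):
            adjusted_permutation_test(rng.normal(size=6), groups, None, n_perm=10)


class TestAncovaLsd:
    def test_no_covariates_reduces_to_anova(self, rng):
        from scipy import stats as sps
        groups = np.array(["A"] * 10 + ["B"] * 12 + ["C"] * 9)
        y = rng.normal(0, 1, 31) + 0.5 * (groups == "B")
        res = ancova_lsd(y, groups, None)
        f_ref, p_ref = sps.f_oneway(y[groups == "A"], y[groups == "B"],
                                    y[groups == "C"])
        assert res.statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_two_groups_f_is_squared_lsd_t(self, rng):
        groups = np.array(["A"] * 10 + ["B"] * 10)
        y = rng.normal(0, 1, 20) + 0.4 * (groups == "B")
        cov = pd.DataFrame({"age": rng.normal(60, 5, 20)})
        res = ancova_lsd(y, groups, cov)
        # omnibus F equals the square of the pairwise t; identical p-values
        assert res.posthoc[("A", "B")] == pytest.approx(res.p_value)

    def test_adjusted_means_match_normal_equations(self):
        # tiny fully hand-solvable design
        y = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 5.0])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        res = ancova_lsd(y, groups, x)
        X = np.column_stack([np.ones(6), x, (groups == "B").astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        xbar = x.mean()
        assert res.adjusted_means["A"] == pytest.approx(beta[0] + beta[1] * xbar)
        assert res.adjusted_means["B"] == pytest.approx(
            beta[0] + beta[1] * xbar + beta[2])

    def test_agrees_with_permutation_test_on_gaussian_data(self, rng):
        agree = 0
        reps = 60
        for rep in range(reps):
            n = 45
            groups = np.array(["A"] * 15 + ["B"] * 15 + ["C"] * 15)
            effect = 0.8 if rep % 2 else 0.0
            y = rng.normal(0, 1, n) + effect * (groups == "A")
            cov = pd.DataFrame({"age": rng.normal(65, 5, n)})
            p1 = adjusted_permutation_test(y, groups, cov, n_perm=400, seed=rep,
                                           posthoc=False).p_value
            p2 = ancova_lsd(y, groups, cov).p_value
            agree += (p1 < 0.05) == (p2 < 0.05)
        assert agree / reps >= 0.9


class TestPartialCorrelation:
    def test_perfect_relation_is_one(self, rng):
        x = rng.normal(0, 1, 20)
        c = rng.normal(0, 1, 20)
        r, p = partial_correlation(x, x.copy(), c)
        assert r == pytest.approx(1.0)

    def test_matches_residual_correlation_oracle(self, rng):
        x = rng.normal(0, 1, 8)
        c = rng.normal(0, 1, 8)
        y = 0.6 * x + 0.5 * c + rng.normal(0, 0.5, 8)
        r, p = partial_correlation(x, y, c)
        Z = np.column_stack([np.ones(8), c])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_matches_pingouin(self, rng):
        import pingouin as pg
        x = rng.normal(0, 1, 25)
        c = rng.normal(0, 1, 25)
        y = 0.4 * x + 0.3 * c + rng.normal(0, 1, 25)
        r, p = partial_correlation(x, y, c)
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "c": c}),
                              x="x", y="y", covar="c")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_approaches_plain_pearson_for_independent_control(self, rng):
        n = 4000
        x = rng.normal(0, 1, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        c = rng.normal(0, 1, n)
        r_partial, _ = partial_correlation(x, y, c)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert abs(r_partial - r_plain) < 0.02


class TestStepwise:
    def test_pure_noise_candidate_rarely_enters(self, rng):
        entered = 0
        reps = 60
        for rep in range(reps):
            y = rng.normal(0, 1, 40)
            noise = rng.normal(0, 1, 40)
            hrsd = rng.normal(0, 1, 40)
            sw = stepwise_regression(y, {"noise": noise}, forced_covariate=hrsd)
            entered += bool(sw["selected"])
        assert entered / reps < 0.15  # nominal entry rate ~= p_enter

    def test_true_signal_candidate_selected_consistently(self, rng):
        hits = 0
        reps = 50
        for rep in range(reps):
            x1 = rng.normal(0, 1, 40)
            x2 = rng.normal(0, 1, 40)
            hrsd = rng.normal(0, 1, 40)
            y = x1 + 0.3 * rng.normal(0, 1, 40)
            sw = stepwise_regression(y, {"signal": x1, "noise": x2},
                                     forced_covariate=hrsd)
            hits += "signal" in sw["selected"]
        assert hits / reps >= 0.95

    def test_exact_relation_beta_one_forced_beta_zero(self, rng):
        x = rng.normal(0, 1, 30)
        hrsd = rng.normal(0, 1, 30)
        sw = stepwise_regression(x.copy(), {"x": x}, forced_covariate=hrsd)
        assert sw["selected"] == ["x"]
        assert sw["terms"]["x"]["beta"] == pytest.approx(1.0, abs=1e-8)
        assert abs(sw["forced"]["hrsd"]["beta"]) < 1e-8

    def test_collinear_candidate_dropped(self, rng):
        x = rng.normal(0, 1, 30)
        hrsd = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 0.2, 30)
        sw = stepwise_regression(y, {"a": x, "dup": 2.0 * hrsd},
                                 forced_covariate=hrsd)
        assert "dup" in sw["dropped_collinear"]
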