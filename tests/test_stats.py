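import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neurotracekit.stats_report import (
    GroupSample,
    adjust_p,
    anova_factorial,
    compare_two,
    normality_gate,
)

from _oracles import brute_force_bh, brute_force_bonferroni, brute_force_holm


def gs(label, values):
    return GroupSample(label, np.asarray(values, float))


class TestNormalityGate:
    def test_large_normal_samples_usually_pass(self):
        # two Shapiro screens at alpha=0.05 -> parametric rate ~0.90
        rng = np.random.default_rng(0)
        calls = [normality_gate([gs("a", rng.normal(size=60)),
                                 gs("b", rng.normal(size=60))])
                 for _ in range(300)]
        assert 0.85 <= np.mean([c == "parametric" for c in calls]) <= 0.96

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(30):
            bimodal = np.concatenate([rng.normal(-4, 0.3, 50),
                                      rng.normal(4, 0.3, 50)])
            rejections += normality_gate([gs("a", bimodal)]) == "nonparametric"
        assert rejections == 30

    def test_tiny_group_is_indeterminate(self):
        assert normality_gate([gs("a", [1.0, 2.0]),
                               gs("b", [0.0, 1.0, 2.0, 3.0])]) == "indeterminate"


class TestCompareTwo:
    def test_identical_samples_ks(self):
        x = np.arange(10.0)
        res = compare_two(gs("a", x), gs("b", x), mode="ks")
        assert res.statistic == 0.0 and res.p == 1.0
        assert res.summary_mode == "median_iqr"

    def test_power_on_separated_normals(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            compare_two(gs("a", rng.normal(0, 1, 50)),
                        gs("b", rng.normal(2, 1, 50)), mode="auto").p < 0.05
            for _ in range(50))
        assert rejections >= 49

    def test_ratio_paired_t_on_unit_ratios(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_two(gs("a", a), gs("b", a.copy()), mode="ratio_paired_t")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_ratio_paired_t_needs_equal_n_and_positive(self):
        with pytest.raises(ValueError, match="equal-length"):
            compare_two(gs("a", [1, 2, 3]), gs("b", [1, 2]),
                        mode="ratio_paired_t")
        with pytest.raises(ValueError, match="positive"):
            compare_two(gs("a", [1.0, -2.0, 3.0]), gs("b", [1.0, 2.0, 3.0]),
                        mode="ratio_paired_t")

    def test_t_statistic_matches_textbook_three_point_sample(self):
        # pooled-variance t for {1,2,3} vs {2,3,4}: t = -1/sqrt(2/3)
        res = compare_two(gs("a", [1, 2, 3]), gs("b", [2, 3, 4]), mode="t")
        assert res.statistic == pytest.approx(-1.0 / np.sqrt(2 / 3))
        assert res.df == (4.0,)

    def test_ks_statistic_matches_hand_computation(self):
        # {1,2,3} vs {4,5,6}: the empirical CDFs separate completely
        res = compare_two(gs("a", [1, 2, 3]), gs("b", [4, 5, 6]), mode="ks")
        assert res.statistic == 1.0


class TestAdjustP:
    def test_single_p_unchanged(self):
        for method in ("BH", "holm", "holm_sidak", "bonferroni"):
            assert adjust_p([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_hand_computed_example(self):
        np.testing.assert_allclose(adjust_p([0.01, 0.02, 0.03], "BH"),
                                   [0.03, 0.03, 0.03])

    def test_bonferroni_example(self):
        np.testing.assert_allclose(adjust_p([0.04, 0.5], "bonferroni"),
                                   [0.08, 1.0])

    @pytest.mark.parametrize("method,oracle", [
        ("BH", brute_force_bh),
        ("holm", lambda p: brute_force_holm(p, sidak=False)),
        ("holm_sidak", lambda p: brute_force_holm(p, sidak=True)),
        ("bonferroni", brute_force_bonferroni),
    ])
    def test_matches_brute_force_on_random_inputs(self, method, oracle):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            np.testing.assert_allclose(adjust_p(p, method), oracle(p),
                                       atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 50)
        for method in ("BH", "holm", "holm_sidak", "bonferroni"):
            assert np.all(adjust_p(p, method) >= p - 1e-12)

    def test_bh_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 20)
        np.testing.assert_allclose(adjust_p(p, "BH"),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_p([0.5, 1.2], "BH")


def _factorial_table(rng, effect_a=0.0, effect_b=0.0, n=10):
    rows = []
    for a in (0, 1):
        for b in (0, 1):
            for _ in range(n):
                rows.append((a, b, rng.normal(effect_a * a + effect_b * b, 1.0)))
    return pd.DataFrame(rows, columns=["fa", "fb", "value"])


class TestAnova:
    def test_zero_between_group_variance(self):
        table = _factorial_table(np.random.default_rng(0))
        table["value"] = np.tile([1.0, 2.0], len(table) // 2)  # no factor effect
        res = anova_factorial(table, "value", ("fa", "fb"))
        by_name = {r.test: r for r in res}
        assert by_name["anova:fa"].p > 0.5
        assert by_name["anova:fb"].p > 0.5

    def test_additive_effects_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            table = _factorial_table(rng, effect_a=1.5, effect_b=1.5)
            res = {r.test: r for r in anova_factorial(table, "value", ("fa", "fb"))}
            hits += (res["anova:fa"].p < 0.05) and (res["anova:fb"].p < 0.05)
        assert hits >= 19

    def test_single_observation_cells_rejected(self):
        table = _factorial_table(np.random.default_rng(0), n=1)
        with pytest.raises(ValueError, match="at least 2"):
            anova_factorial(table, "value", ("fa", "fb"))

    def test_repeated_measures_reports_fractional_corrected_df(self):
        rng = np.random.default_rng(4)
        rows = []
        for grp in ("ctrl", "treat"):
            for s in range(8):
                subj = f"{grp}{s}"
                walk = np.cumsum(rng.normal(0, 1.0, 6))  # strong autocorrelation
                for t in range(6):
                    rows.append((subj, grp, t,
                                 walk[t] + (0.8 * t if grp == "treat" else 0)))
        table = pd.DataFrame(rows, columns=["subject", "group", "time", "value"])
        res = anova_factorial(table, "value", ("time", "group"), repeated=True,
                              subject="subject")
        within = next(r for r in res if r.test == "rm_anova:time")
        assert within.extras["eps"] is not None and within.extras["eps"] < 0.9
        assert within.df[0] != round(within.df[0])  # fractional after correction

    def test_repeated_design_missing_cells_rejected(self):
        table = pd.DataFrame({
            "subject": ["s0", "s0", "s1"], "group": ["a", "a", "a"],
            "time": [0, 1, 0], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing cells"):
            anova_factorial(table, "value", ("time", "group"), repeated=True,
                            subject="subject")

    def test_per_level_posthoc_is_bh_adjusted(self):
        rng = np.random.default_rng(5)
        rows = []
        for t in range(4):
            for g in ("a", "b"):
                for _ in range(6):
                    rows.append((t, g, rng.normal(1.0 if g == "b" and t > 1 else 0.0)))
        table = pd.DataFrame(rows, columns=["time", "group", "value"])
        res = anova_factorial(table, "value", ("time", "group"),
                              posthoc="per_level_bh")
        ph = [r for r in res if r.test.startswith("per_level:")]
        assert len(ph) == 4
        assert all(r.adjusted_p >= r.p for r in ph)


class TestGatedPipelineCalibration:
    def test_type_one_error_on_normal_nulls(self):
        """Gated t/KS pipeline keeps ~5% size on normal null samples."""
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 800
        for _ in range(reps):
            res = compare_two(gs("a", rng.normal(size=15)),
                              gs("b", rng.normal(size=15)), mode="auto")
            rejections += res.p < 0.05
        assert 0.03 <= rejections / reps <= 0.07
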