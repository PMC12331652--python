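"""Improvement-rate statistics against closed forms, published table cells,
and independent reference implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gaitrefine as gr
from gaitrefine.stats import significance_stars, table_to_markdown


class TestRmse:
    def test_identity_is_zero(self):
        assert gr.rmse(np.arange(20.0), np.arange(20.0)) == 0.0

    def test_unit_offset_is_one(self):
        assert gr.rmse(np.ones(20), np.zeros(20)) == pytest.approx(1.0)

    def test_unit_impulse_over_20_samples(self):
        y = np.zeros(20)
        y[7] = 1.0
        assert gr.rmse(y, np.zeros(20)) == pytest.approx(np.sqrt(1 / 20))
        assert gr.rmse(y, np.zeros(20)) == pytest.approx(0.223607, abs=5e-7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            gr.rmse(np.zeros(5), np.zeros(6))


class TestImprovementRate:
    @pytest.mark.parametrize(
        "e_pro,e_base,expected", [(0.5, 0.5, 0.0), (0.25, 0.5, -0.5), (0.6, 0.5, 0.2)]
    )
    def test_closed_form(self, e_pro, e_base, expected):
        assert gr.improvement_rate(e_pro, e_base) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            gr.improvement_rate(0.1, 0.0)


def values_with(mean, sd, n, seed=0):
    """Exact-moment sample: mean and sample sd match the requested values."""
    v = np.random.default_rng(seed).normal(0, 1, n)
    v = (v - v.mean()) / v.std(ddof=1)
    return mean + sd * v


class TestEffectSizeAndCI:
    def test_symmetric_values_give_zero_d(self):
        assert gr.cohens_d([-1, 1, -2, 2]) == 0.0

    def test_translation_invariance(self):
        v = values_with(0.3, 0.1, 9, seed=1)
        assert gr.cohens_d(v, 0.0) == pytest.approx(gr.cohens_d(v + 5.0, 5.0))

    def test_walking_soleus_entire_cycle_effect_size(self):
        # mean -0.33 with sd from inverting d = mean/sd at the printed d
        v = values_with(-0.33, 0.179348, 8)
        assert gr.cohens_d(v) == pytest.approx(-1.84, abs=0.005)

    def test_walking_soleus_entire_cycle_ci(self):
        v = values_with(-0.33, 0.179348, 8)
        lo, hi = gr.confidence_interval(v)
        assert round(lo, 2) == -0.48
        assert round(hi, 2) == -0.18

    def test_running_semimembranosus_ci(self):
        v = values_with(-0.47, 0.124668, 10)
        lo, hi = gr.confidence_interval(v)
        assert round(lo, 2) == -0.56
        assert round(hi, 2) == -0.38

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            gr.cohens_d([1.0, 1.0, 1.0])


class TestTTest:
    def test_walking_soleus_entire_cycle_p_value(self):
        v = values_with(-0.33, 0.179348, 8)
        _, p = gr.t_test_vs_zero(v)
        assert p == pytest.approx(0.0012, abs=1e-4)

    def test_zero_mean_gives_t_zero_p_one(self):
        t, p = gr.t_test_vs_zero([-1.0, 1.0, -0.5, 0.5])
        assert t == 0.0
        assert p == 1.0

    def test_t_equals_d_times_sqrt_n(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            v = rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(3, 30))
            t, _ = gr.t_test_vs_zero(v)
            assert t == pytest.approx(gr.cohens_d(v) * np.sqrt(len(v)), rel=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            v = rng.normal(0.2, 1.0, rng.integers(3, 25))
            t, p = gr.t_test_vs_zero(v)
            ref = sps.ttest_1samp(v, 0.0)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ci_excludes_zero_iff_p_below_alpha(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            v = rng.normal(rng.normal(0, 0.3), 1.0, rng.integers(3, 20))
            lo, hi = gr.confidence_interval(v, alpha=0.05)
            _, p = gr.t_test_vs_zero(v)
            assert (lo > 0 or hi < 0) == (p < 0.05)


class TestTukey:
    def test_identical_groups_not_significant(self):
        g = {"A": [0.1, 0.2, 0.3, 0.15], "B": [0.1, 0.2, 0.3, 0.15], "C": [0.1, 0.2, 0.3, 0.15]}
        res = gr.tukey_conditions(g)
        assert not res["reject_05"].any()

    def test_separated_group_significant_vs_both(self):
        g = {
            "A": [0.0, 0.01, -0.01, 0.0],
            "B": [0.0, -0.01, 0.01, 0.0],
            "C": [10.0, 10.1, 9.9, 10.0],
        }
        res = gr.tukey_conditions(g).set_index(["group_a", "group_b"])
        assert res.loc[("A", "C"), "reject_05"]
        assert res.loc[("B", "C"), "reject_05"]
        assert not res.loc[("A", "B"), "reject_05"]

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            g = {k: rng.normal(rng.normal(), 1.0, n) for k in ("A", "B", "C")}
            ours = gr.tukey_conditions(g)
            data = np.concatenate(list(g.values()))
            labels = np.repeat(list(g), n)
            ref = pairwise_tukeyhsd(data, labels, alpha=0.05)
            np.testing.assert_allclose(ours["p_adj"], ref.pvalues, atol=1e-9)
            np.testing.assert_allclose(
                ours["mean_diff"], ref.meandiffs, atol=1e-12
            )

    def test_p_values_symmetric_under_relabeling(self):
        rng = np.random.default_rng(8)
        g = {k: rng.normal(0, 1, 5) for k in ("A", "B", "C")}
        swapped = {"A": g["B"], "B": g["A"], "C": g["C"]}
        p1 = gr.tukey_conditions(g).set_index(["group_a", "group_b"])["p_adj"]
        p2 = gr.tukey_conditions(swapped).set_index(["group_a", "group_b"])["p_adj"]
        assert p1[("A", "B")] == pytest.approx(p2[("A", "B")])
        assert p1[("A", "C")] == pytest.approx(p2[("B", "C")])

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            gr.tukey_conditions({"A": [1, 2, 3]})


class TestSubjectAggregation:
    def test_er_is_mean_over_speed_conditions(self):
        pairs = [(0.25, 0.5), (0.5, 0.5), (0.6, 0.5), (0.45, 0.5)]
        s = gr.subject_er(pairs, subject_id="S01", condition="One-Entire", muscle="m00")
        expect = np.mean([gr.improvement_rate(a, b) for a, b in pairs])
        assert s.er == pytest.approx(expect)

    def test_wrong_speed_count_rejected_unless_configured(self):
        with pytest.raises(ValueError, match="speed"):
            gr.subject_er([(0.1, 0.2)] * 3)
        s = gr.subject_er([(0.1, 0.2)] * 3, expected_speeds=None)
        assert s.er == pytest.approx(-0.5)


class TestEvalTable:
    def make_samples(self):
        rng = np.random.default_rng(9)
        out = []
        for cond in ("One-Quarter", "One-Entire", "All-Entire"):
            for i in range(8):
                out.append(
                    gr.ErSample(
                        subject_id=f"S{i:02d}", condition=cond, muscle="soleus",
                        er=float(rng.normal(-0.2, 0.15)),
                    )
                )
        return out

    def test_cells_match_direct_formula_evaluation(self):
        samples = self.make_samples()
        table = gr.build_eval_table(samples).set_index("condition")
        for cond in ("One-Quarter", "One-Entire", "All-Entire"):
            v = np.array([s.er for s in samples if s.condition == cond])
            row = table.loc[cond]
            assert row["n"] == 8
            assert row["er_mean"] == pytest.approx(v.mean())
            assert row["cohen_d"] == pytest.approx(gr.cohens_d(v))
            lo, hi = gr.confidence_interval(v)
            assert row["ci_low"] == pytest.approx(lo)
            assert row["ci_high"] == pytest.approx(hi)
            assert row["p"] == pytest.approx(gr.t_test_vs_zero(v)[1])
            assert row["ci_low"] <= row["er_mean"] <= row["ci_high"]

    def test_all_zero_er_marks_nothing_improved(self):
        samples = [
            gr.ErSample(subject_id=f"S{i}", condition="One-Entire", muscle="m", er=0.0)
            for i in range(8)
        ]
        table = gr.build_eval_table(samples)
        assert not table["improved"].any()
        assert table.loc[0, "p"] == 1.0

    def test_markdown_report_bolds_improved_cells(self):
        md = table_to_markdown(gr.build_eval_table(self.make_samples()))
        assert "| soleus |" in md
        assert "**" in md


def test_significance_star_thresholds():
    assert [significance_stars(p) for p in (0.5, 0.04, 0.009, 0.0009)] == [
        "", "*", "**", "***",
    ]
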