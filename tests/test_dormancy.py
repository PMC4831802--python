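import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import germcycle as gc


def _zone(n_cells, n_edu=0, n_ph3=0, **kw):
    cells = pd.DataFrame(
        {
            "dna_content": np.linspace(1, 2, n_cells),
            "edu": [True] * n_edu + [False] * (n_cells - n_edu),
            "ph3": [True] * n_ph3 + [False] * (n_cells - n_ph3),
        }
    )
    defaults = dict(
        worm_id="w0", arm="L", condition="x", assay="continuous", label_h=1.0
    )
    defaults.update(kw)
    return gc.GonadSample(cells=cells, **defaults)


class TestClassifyDormant:
    def test_no_edu_cell_means_dormant(self):
        assert gc.classify_dormant(_zone(260, n_edu=0))

    def test_single_edu_cell_means_active(self):
        assert not gc.classify_dormant(_zone(260, n_edu=1))

    def test_dormant_fraction_matches_switching_model(self):
        preset = gc.builtin_presets()["fog1_day1"]
        n = 200
        summary = gc.generate_continuous(preset, [1.0], n, seed=17)
        dormant_frac = 1.0 - summary["labeled"].mean()
        expected = preset.pi_d * math.exp(-preset.k_da * 1.0)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(dormant_frac - expected) < 3 * se


class TestExpectedMphase:
    @pytest.mark.parametrize(
        "n,f_m,expected", [(260, 0.10, 26.0), (100, 0.0, 0.0), (50, 0.2, 10.0)]
    )
    def test_expectation(self, n, f_m, expected):
        assert gc.expected_mphase_count(n, f_m) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gc.expected_mphase_count(260, 1.5)


class TestLabelingCurve:
    def test_unlabeled_fractions_and_cis(self):
        summary = pd.DataFrame(
            {
                "label_h": [1.0] * 20 + [4.0] * 40,
                "labeled": [0] * 11 + [1] * 9 + [1] * 40,
            }
        )
        curve = gc.labeling_curve(summary)
        assert curve.loc[0, "fraction_unlabeled"] == pytest.approx(0.55)
        assert curve.loc[1, "fraction_unlabeled"] == 0.0
        assert curve.loc[0, "ci_low"] < 0.55 < curve.loc[0, "ci_high"]

    def test_slow_switching_curve_decreases_but_stays_positive(self):
        preset = gc.ConditionPreset(
            "foglike", gc.wildtype_params(), 0.55, 0.25, 0.25 * 0.55 / 0.45
        )
        summary = gc.generate_continuous(preset, [1, 2, 4, 6], 400, seed=5)
        curve = gc.labeling_curve(summary)
        fracs = curve["fraction_unlabeled"].to_numpy()
        assert np.all(np.diff(fracs) < 0)
        assert fracs[-1] > 0  # still unlabeled zones at 6 h

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            gc.labeling_curve(pd.DataFrame({"label_h": [], "labeled": []}))


class TestFitSwitching:
    def test_parameter_recovery(self):
        preset = gc.ConditionPreset("rec", gc.wildtype_params(), 0.5, 0.3, 0.3)
        summary = gc.generate_continuous(preset, [1, 2, 4, 6, 8], 100, seed=0)
        obs = [
            gc.IntervalObs.from_assay(r.label_h, bool(r.labeled))
            for r in summary.itertuples()
        ]
        fit = gc.fit_switching(obs)
        assert fit.pi_d == pytest.approx(0.5, rel=0.15)
        assert fit.k_da == pytest.approx(0.3, rel=0.15)
        assert not fit.boundary

    def test_all_labeled_is_boundary_with_tiny_pi_d(self):
        obs = [gc.IntervalObs.from_assay(t, True) for t in (1, 1, 2, 2)]
        fit = gc.fit_switching(obs)
        assert fit.boundary and fit.pi_d <= 0.02

    def test_none_labeled_is_boundary(self):
        obs = [gc.IntervalObs.from_assay(t, False) for t in (1, 2, 4)]
        fit = gc.fit_switching(obs)
        assert fit.boundary and fit.pi_d == 1.0 and fit.k_da == 0.0

    def test_unlabeled_probability_curve_monotone(self):
        fit = gc.SwitchingFit(0.6, 0.4, 0.0, 10)
        t = np.linspace(0, 10, 50)
        u = fit.unlabeled_prob(t)
        assert np.all(np.diff(u) < 0) and np.all((u > 0) & (u < 1))


class TestMitoticIndex:
    def test_fraction(self):
        assert gc.mitotic_index(_zone(260, n_ph3=3)) == pytest.approx(3 / 260)
        assert gc.mitotic_index(_zone(100)) == 0.0

    def test_mixture_raises_cohort_cv(self):
        rng = np.random.default_rng(2)
        active = rng.binomial(260, 0.1, size=200) / 260
        for p_dormant, p_ref in [(0.3, 0.1), (0.6, 0.3)]:
            def cohort_cv(p):
                dormant = rng.random(200) < p
                idx = np.where(dormant, 0.0, active)
                return idx.std(ddof=1) / idx.mean()
            assert cohort_cv(p_dormant) > cohort_cv(p_ref)


class TestCVBootstrap:
    def test_known_cv(self):
        res = gc.cv_with_bootstrap([1.0, 2.0, 3.0], seed=1)
        assert res.cv == pytest.approx(0.5)
        assert res.ci_low <= res.cv <= res.ci_high

    def test_constant_values(self):
        res = gc.cv_with_bootstrap([2.0] * 10, seed=1)
        assert res.cv == 0.0 and res.ci_low == 0.0 and res.ci_high == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            gc.cv_with_bootstrap([-1.0, 1.0])

    def test_deterministic_given_seed(self):
        a = gc.cv_with_bootstrap([1, 2, 3, 4, 5.0], seed=9)
        b = gc.cv_with_bootstrap([1, 2, 3, 4, 5.0], seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestICRankTest:
    def test_identical_groups_give_null(self):
        grp = [gc.IntervalObs.from_assay(t, t < 3) for t in (1, 2, 4, 6)]
        u, p = gc.ic_rank_test(grp, list(grp), seed=0)
        assert u == 0.0 and p == 1.0

    def test_complete_separation_gives_extreme_u_and_min_p(self):
        a = [gc.IntervalObs(10.0, 12.0) for _ in range(8)]
        b = [gc.IntervalObs(1.0, 2.0) for _ in range(8)]
        u, p = gc.ic_rank_test(a, b, n_perm=999, seed=0)
        assert u == 64.0
        assert p <= 3 * 2 / 1000

    def test_matches_rank_test_decision_on_point_data(self):
        # degenerate intervals reduce to exact observations; compare the
        # decision with the ordinary two-sample rank test
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 15)
        y = rng.normal(1.2, 1, 15)
        eps = 1e-9
        a = [gc.IntervalObs(max(v, eps), max(v, eps) + eps) for v in x + 10]
        b = [gc.IntervalObs(max(v, eps), max(v, eps) + eps) for v in y + 10]
        _, p_ic = gc.ic_rank_test(a, b, n_perm=1999, seed=1)
        p_mw = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert (p_ic < 0.05) == (p_mw < 0.05)

    def test_too_few_permutations_rejected(self):
        a = [gc.IntervalObs(1.0, 2.0)]
        with pytest.raises(ValueError):
            gc.ic_rank_test(a, a, n_perm=10)


class TestBonferroni:
    def test_adjustment_and_cap(self):
        adj = gc.bonferroni([0.001, 0.5, 0.0], m=15)
        np.testing.assert_allclose(adj, [0.015, 1.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gc.bonferroni([1.5], m=2)


class TestSisterArms:
    def test_concordance_fraction(self):
        pairs = [(True, True)] * 33 + [(True, False)] * 3
        agree, _ = gc.sister_arm_agreement(pairs, n_perm=1999, seed=0)
        assert agree == pytest.approx(33 / 36)
        assert f"{agree:.0%}" == "92%"

    def test_all_concordant(self):
        agree, _ = gc.sister_arm_agreement([(True, True)] * 10, n_perm=1999, seed=0)
        assert agree == 1.0

    def test_independent_arms_not_significant(self):
        rng = np.random.default_rng(6)
        rejections = 0
        for rep in range(20):
            pairs = rng.random((40, 2)) < 0.5
            agree, p = gc.sister_arm_agreement(pairs, n_perm=999, seed=rep)
            rejections += p <= 0.05
        assert rejections <= 2  # null should rarely reject


class TestProportionTest:
    def test_no_association(self):
        assert gc.dormancy_proportion_test([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation_matches_hypergeometric(self):
        p = gc.dormancy_proportion_test([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_density_contrast_significant(self):
        # dormancy 23% vs 46% at n=100 per group
        p = gc.dormancy_proportion_test([[23, 77], [46, 54]])
        assert p < 0.05

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            gc.dormancy_proportion_test([[0, 0], [5, 5]])
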