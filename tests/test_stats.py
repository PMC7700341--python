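import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kidscreen.simulate import SimConfig, generate
from kidscreen.stats import (
    anova_crosscheck,
    attrition_tests,
    describe,
    kruskal_wallis,
    run_validation,
)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        # rank sums 6 and 15: H = 12/(6*7)*(36/3+225/3) - 3*7
        assert h == pytest.approx(3.857, abs=0.001)
        assert p == pytest.approx(0.0495, abs=0.001)

    def test_identical_groups_null(self):
        h, p = kruskal_wallis([2.0, 2.0, 2.0], [2.0, 2.0])
        assert h == 0.0 and p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], [])

    def test_no_tie_closed_form(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=12), rng.normal(size=9)
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        n = pooled.size
        r_a, r_b = ranks[:12].sum(), ranks[12:].sum()
        h_closed = 12.0 / (n * (n + 1)) * (r_a**2 / 12 + r_b**2 / 9) - 3 * (n + 1)
        h, _ = kruskal_wallis(a, b)
        assert h == pytest.approx(h_closed, abs=1e-10)

    def test_matches_rank_sum_normal_approximation(self):
        """With two groups the tie-corrected KW p equals the two-sided
        normal-approximation Wilcoxon rank-sum p (no continuity correction)."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n1, n2 = rng.integers(4, 30, 2)
            a = np.round(rng.normal(size=n1), 1)  # rounding makes ties
            b = np.round(rng.normal(0.3, 1.0, size=n2), 1)
            _, p_kw = kruskal_wallis(a, b)
            p_mw = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
            assert p_kw == pytest.approx(p_mw, abs=1e-9)

    def test_invariant_to_monotone_transform_and_group_order(self):
        rng = np.random.default_rng(6)
        a, b = rng.exponential(size=15), rng.exponential(2.0, size=10)
        h1, p1 = kruskal_wallis(a, b)
        h2, p2 = kruskal_wallis(np.log(b), np.log(a))
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestDescribe:
    def test_even_n_midpoint(self):
        assert describe([1, 2, 3, 4]).median == 2.5

    def test_linear_interpolation_convention(self):
        d = describe([1, 2, 3, 4, 5])
        assert d.median == 3.0
        assert d.q1 == 2.0 and d.q3 == 4.0 and d.iqr == 2.0

    def test_reversal_invariance(self):
        vals = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        assert describe(vals) == describe(vals[::-1])

    def test_constant_vector(self):
        d = describe([2.0, 2.0, 2.0])
        assert d.iqr == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestAttrition:
    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        flags = []
        for _ in range(150):
            retained = pd.DataFrame({"age": rng.normal(33, 6, 200)})
            dropped = pd.DataFrame({"age": rng.normal(33, 6, 60)})
            rep = attrition_tests(retained, dropped, {"age": "continuous"})
            flags.append(bool(rep.loc[0, "flagged"]))
        assert 0.01 <= np.mean(flags) <= 0.11

    def test_large_shift_flagged(self):
        rng = np.random.default_rng(1)
        retained = pd.DataFrame({"age": rng.normal(33, 6, 200)})
        dropped = pd.DataFrame({"age": rng.normal(33 + 12, 6, 60)})  # +2 SD
        rep = attrition_tests(retained, dropped, {"age": "continuous"})
        assert bool(rep.loc[0, "flagged"])

    def test_categorical_association_flagged(self):
        retained = pd.DataFrame({"job": ["unemployed"] * 150 + ["employed"] * 50})
        dropped = pd.DataFrame({"job": ["unemployed"] * 20 + ["employed"] * 40})
        rep = attrition_tests(retained, dropped, {"job": "categorical"})
        assert rep.loc[0, "test"] == "chi2" and bool(rep.loc[0, "flagged"])

    def test_single_level_categorical_skipped(self):
        retained = pd.DataFrame({"sex": ["female"] * 30})
        dropped = pd.DataFrame({"sex": ["female"] * 10})
        rep = attrition_tests(retained, dropped, {"sex": "categorical"})
        assert rep.loc[0, "note"] == "single observed level"
        assert not bool(rep.loc[0, "flagged"])

    def test_mar_generator_age_difference_detectable(self):
        """MAR attrition ties dropout to parent age; pooling several cohorts
        the retained parents are measurably older."""
        diffs = []
        for seed in range(10):
            b = generate(SimConfig(seed=seed, mar_attrition=True))
            d = b.demographics
            diffs.append(
                d.loc[d.completed, "parent_age"].mean()
                - d.loc[~d.completed, "parent_age"].mean()
            )
        assert np.mean(diffs) > 0.5


@pytest.fixture(scope="module")
def report(bundle):
    return run_validation(
        bundle.responses,
        bundle.anthro,
        bundle.replicates,
        bundle.controls,
        bundle.codebook,
        bundle.informative_items,
    )


class TestRunValidation:
    def test_reports_all_six_outcomes(self, report):
        outcomes = {r.outcome for r in report.results}
        assert outcomes == {
            "bmi_percentile",
            "bmi_z",
            "whtr",
            "metabolic",
            "lipid",
            "anti_inflammatory",
        }

    def test_built_in_inverse_associations_recovered(self, report):
        for outcome in ("bmi_percentile", "bmi_z", "whtr", "metabolic", "lipid"):
            r = report[outcome]
            assert r.high.median < r.low.median, outcome
        r = report["anti_inflammatory"]
        assert r.high.median > r.low.median

    def test_table_shape(self, report):
        frame = report.to_frame()
        assert {"outcome", "n_low", "median_low", "iqr_low", "q1_low", "q3_low",
                "n_high", "median_high", "H", "p"} <= set(frame.columns)
        assert len(frame) == 6

    def test_anova_crosscheck_agrees_in_direction(self, bundle, report):
        """The parametric parallel points the same way on a strong outcome."""
        f, p_anova = anova_crosscheck([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert f > 0 and p_anova < 0.05

    def test_empty_high_group_reported_untested(self, bundle):
        rep = run_validation(
            bundle.responses,
            bundle.anthro,
            bundle.replicates,
            bundle.controls,
            bundle.codebook,
            bundle.informative_items,
            threshold=1000.0,  # nobody reaches the high group
        )
        assert rep.n_high == 0
        assert all(not r.tested for r in rep.results)
        assert all(np.isnan(r.p) for r in rep.results)
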