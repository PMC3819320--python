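import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pibquant as pq
from pibquant.stats import icc_vc, threshold_search


class TestMCBP:
    def test_equal_members_give_that_value(self):
        bp = {m: 0.3 for m in pq.MCBP_COMPOSITES}
        assert pq.mcbp(bp) == pytest.approx(0.3)

    def test_unweighted_mean(self):
        bp = dict(zip(pq.MCBP_COMPOSITES, [0.1, 0.2, 0.3, 0.4]))
        assert pq.mcbp(bp) == pytest.approx(0.25)

    def test_missing_member_named_in_error(self):
        bp = {m: 0.3 for m in pq.MCBP_COMPOSITES if m != "TEMP_FS"}
        with pytest.raises(KeyError, match="TEMP_FS"):
            pq.mcbp(bp)


class TestClassifyPib:
    @pytest.mark.parametrize("value, status", [
        (0.19, "positive"),
        (0.18, "negative"),   # strict inequality at the cutoff
        (-0.05, "negative"),
        (0.1801, "positive"),
    ])
    def test_cutoff_is_strict(self, value, status):
        assert pq.classify_pib(value) == status

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pq.classify_pib(float("nan"))

    def test_classification_monotone_in_each_member(self):
        base = dict(zip(pq.MCBP_COMPOSITES, [0.15, 0.17, 0.18, 0.16]))
        assert pq.classify_pib(pq.mcbp(base)) == "negative"
        for m in pq.MCBP_COMPOSITES:
            bumped = dict(base, **{m: base[m] + 0.2})
            assert pq.classify_pib(pq.mcbp(bumped)) == "positive"


def exhaustive_min_nod(values, ref):
    """True minimum NOD over every achievable classification."""
    values = np.asarray(values, float)
    cands = np.unique(np.concatenate([values - 1e-9, values + 1e-9]))
    return min(int(((values > c) != ref).sum()) for c in cands)


class TestThresholdSearch:
    def test_separable_case(self):
        values = np.array([0.1, 0.2, 0.3, 0.4])
        ref = np.array([False, False, True, True])
        thr, nod, d = threshold_search(values, ref)
        assert thr == pytest.approx(0.25)
        assert nod == 0 and d == 0.0

    def test_self_consistent_reference(self):
        rng = np.random.default_rng(1)
        mcbp_values = rng.uniform(0.0, 0.6, 40)
        ref = mcbp_values > 0.18
        thr, nod, d = threshold_search(mcbp_values, ref)
        assert nod == 0

    def test_anticorrelated_labels_still_optimal(self):
        values = np.array([0.1, 0.2, 0.3, 0.4])
        ref = np.array([True, True, False, False])
        _, nod, _ = threshold_search(values, ref)
        assert nod == exhaustive_min_nod(values, ref)

    def test_all_positive_and_all_negative_reachable(self):
        values = np.array([0.2, 0.3, 0.5])
        thr_pos, nod_pos, _ = threshold_search(values, np.array([True, True, True]))
        thr_neg, nod_neg, _ = threshold_search(values, np.array([False, False, False]))
        assert nod_pos == 0 and nod_neg == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_search([], [])

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(1, 13))
            values = np.round(rng.normal(0.3, 0.2, n), 3)
            ref = rng.random(n) < 0.5
            _, nod, _ = threshold_search(values, ref)
            assert nod == exhaustive_min_nod(values, ref)


class TestDeltaPct:
    def test_identical_pairs_give_zero(self):
        assert pq.delta_pct([(0.3, 0.3), (0.5, 0.5)]) == 0.0

    def test_single_subject_hand_value(self):
        # 100 * |0.20 - 0.22| / 0.21
        assert pq.delta_pct([(0.20, 0.22)]) == pytest.approx(100 * 0.02 / 0.21, rel=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            pq.delta_pct(np.empty((0, 2)))

    def test_zero_pair_mean_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero pair mean"):
            v = pq.delta_pct([(0.2, 0.22), (0.1, -0.1)])
        assert v == pytest.approx(100 * 0.02 / 0.21, rel=1e-12)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_common_rescaling(self, scale):
        pairs = np.array([(0.2, 0.25), (0.4, 0.38), (0.6, 0.66)])
        assert pq.delta_pct(scale * pairs) == pytest.approx(pq.delta_pct(pairs), rel=1e-9)


class TestICC:
    def test_duplicated_measurements_give_perfect_agreement(self):
        df = pd.DataFrame({
            "subject": [1, 1, 2, 2, 3, 3],
            "value": [0.2, 0.2, 0.5, 0.5, 0.9, 0.9],
        })
        r = icc_vc(df)
        assert r.icc == pytest.approx(1.0)
        assert r.var_residual == pytest.approx(0.0)

    def test_recovers_simulated_variance_ratio(self):
        rng = np.random.default_rng(11)
        n = 500
        subj = rng.normal(0, 3.0, n)  # var 9
        rows = [
            {"subject": i, "replicate": rep, "value": subj[i] + rng.normal(0, 1.0)}
            for i in range(n) for rep in (1, 2)
        ]
        r = icc_vc(pd.DataFrame(rows))
        assert abs(r.icc - 0.9) <= 0.03
        assert r.ci_low < r.icc < r.ci_high

    def test_small_balanced_table_matches_anova_mean_squares(self):
        df = pd.DataFrame({
            "subject": [1, 1, 2, 2, 3, 3, 4, 4],
            "value": [5.1, 5.3, 7.0, 6.8, 4.2, 4.4, 6.1, 6.0],
        })
        v = df.pivot_table(index="subject", values="value", aggfunc=list)["value"]
        mat = np.array(v.tolist())
        k, n = 2, 4
        grand = mat.mean()
        msb = k * ((mat.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msw = ((mat - mat.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
        expected = ((msb - msw) / k) / ((msb - msw) / k + msw)
        assert icc_vc(df).icc == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 60
        subj = rng.normal(0, 2.0, n)
        rows = [
            {"subject": i, "replicate": rep, "value": subj[i] + rng.normal(0, 1.0)}
            for i in range(n) for rep in (1, 2)
        ]
        df = pd.DataFrame(rows)
        ours = icc_vc(df).icc
        theirs = pg.intraclass_corr(
            data=df, targets="subject", raters="replicate", ratings="value"
        ).set_index("Type").loc["ICC(1,1)", "ICC"]
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_rater_component_estimated_in_balanced_two_way(self):
        rng = np.random.default_rng(7)
        n = 200
        subj = rng.normal(0, 3.0, n)
        rater_effect = {1: 0.0, 2: 1.0}  # systematic offset between raters
        rows = [
            {"subject": i, "rater": rep, "value": subj[i] + rater_effect[rep] + rng.normal(0, 0.5)}
            for i in range(n) for rep in (1, 2)
        ]
        r = icc_vc(pd.DataFrame(rows), rater_col="rater")
        # realized components: subject = sample variance of subj, rater offset
        # +-0.5 (variance 0.5), residual 0.25
        assert r.var_rater > 0.05
        assert r.var_subject == pytest.approx(np.var(subj, ddof=1), rel=0.1)
        assert r.var_residual == pytest.approx(0.25, rel=0.4)

    def test_covariate_adjustment_removes_fixed_effects(self):
        rng = np.random.default_rng(9)
        n = 300
        age = rng.uniform(50, 90, n)
        subj = rng.normal(0, 1.0, n)
        rows = [
            {"subject": i, "value": subj[i] + 0.05 * age[i] + rng.normal(0, 0.5), "age": age[i]}
            for i in range(n) for _ in (1, 2)
        ]
        df = pd.DataFrame(rows)
        raw = icc_vc(df).icc
        adj = icc_vc(df, covariate_cols=["age"]).icc
        # the age effect masquerades as subject variance unless removed
        assert adj < raw

    def test_single_observation_subject_rejected(self):
        df = pd.DataFrame({"subject": [1, 1, 2], "value": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="single observation"):
            icc_vc(df)

    def test_collinear_covariates_rejected(self):
        df = pd.DataFrame({
            "subject": [1, 1, 2, 2],
            "value": [0.1, 0.2, 0.3, 0.4],
            "a": [1.0, 1.0, 2.0, 2.0],
            "b": [2.0, 2.0, 4.0, 4.0],
        })
        with pytest.raises(ValueError, match="collinear"):
            icc_vc(df, covariate_cols=["a", "b"])


class TestCorrelationReport:
    def test_identity_line(self):
        x = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        r = pq.correlation_report(x, x)
        assert r["pearson_r"] == pytest.approx(1.0)
        assert r["spearman_r"] == pytest.approx(1.0)
        assert r["slope"] == pytest.approx(1.0)
        assert r["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation(self):
        x = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        r = pq.correlation_report(x, 2 * x + 1)
        assert r["pearson_r"] == pytest.approx(1.0)
        assert r["slope"] == pytest.approx(2.0)
        assert r["intercept"] == pytest.approx(1.0)

    def test_spearman_matches_hand_ranking(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        # hand ranks: x -> 1..5, y -> (3,1,4,2,5); Pearson of ranks
        rx, ry = x, np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert pq.correlation_report(x, y)["spearman_r"] == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pq.correlation_report([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pq.correlation_report([1.0, 2.0], [1.0, 2.0])
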