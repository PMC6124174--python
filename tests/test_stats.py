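import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import brute_auc, brute_confusion, brute_youden

from caphos import LabRecord, Sex
from caphos.stats import (
    ConfusionCounts,
    auc_ci,
    bootstrap_auc_ci,
    classify,
    combined_rule,
    confusion,
    metrics,
    roc,
    youden_cutoff,
)


def _record(ca, p):
    return LabRecord(record_id="x", age=50, sex=Sex.FEMALE, ca=ca, p=p, pth=50, creatinine=70)


class TestClassify:
    @pytest.mark.parametrize(
        "score, cutoff, expected",
        [(3.56, 2.71, True), (2.09, 2.71, False), (2.71, 2.71, True)],
    )
    def test_ratio_convention_includes_the_cutoff(self, score, cutoff, expected):
        assert classify(score, cutoff, "gte") is expected

    def test_reference_limit_conventions_are_strict(self):
        assert not classify(2.65, 2.65, "gt")
        assert classify(2.66, 2.65, "gt")
        assert not classify(0.8072, 0.8072, "lt")
        assert classify(0.80, 0.8072, "lt")

    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=0.01, max_value=5),
    )
    def test_monotone_in_cutoff(self, score, cutoff, bump):
        # raising the cutoff can never turn a negative into a positive
        if not classify(score, cutoff, "gte"):
            assert not classify(score, cutoff + bump, "gte")

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            classify(1.0, 1.0, "ge")


class TestCombinedRule:
    def test_both_branches_negative(self):
        assert combined_rule(_record(2.50, 1.20)) is False  # ratio 2.08, Ca in range

    def test_calcium_branch_alone(self):
        assert combined_rule(_record(2.80, 1.20)) is True  # ratio 2.33 but Ca > 2.65

    def test_ratio_branch_alone(self):
        assert combined_rule(_record(2.50, 0.80)) is True  # ratio 3.125


class TestConfusion:
    def test_all_correct(self):
        counts = confusion([True] * 5 + [False] * 5, ["case"] * 5 + ["control"] * 5)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (5, 5, 0, 0)

    def test_published_case_control_counts(self):
        # 84 of 97 cases called, 12 of 96 controls false-alarmed
        truth = [True] * 97 + [False] * 96
        preds = [True] * 84 + [False] * 13 + [True] * 12 + [False] * 84
        counts = confusion(preds, truth)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (84, 13, 12, 84)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == brute_confusion(preds, truth)

    def test_length_mismatch_and_unknown_label(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])
        with pytest.raises(ValueError):
            confusion([True], ["patient"])


class TestMetrics:
    def test_case_control_accuracy(self):
        m = metrics(ConfusionCounts(tp=84, fn=13, fp=12, tn=84))
        assert m.accuracy == pytest.approx(100 * 168 / 193)
        assert m.rounded()["accuracy"] == 87
        assert m.truncated()["accuracy"] == 87  # convention-invariant cell

    def test_database_sensitivity_at_one_decimal(self):
        m = metrics(ConfusionCounts(tp=441, fn=149, fp=1762, tn=18095))
        assert m.rounded(1)["sensitivity"] == 74.7
        assert m.specificity == pytest.approx(100 * 18095 / 19857)

    def test_zero_sensitivity_with_undefined_ppv(self):
        m = metrics(ConfusionCounts(tp=0, fn=35, fp=0, tn=88))
        assert m.sensitivity == 0.0
        assert m.ppv is None  # undefined, never coerced to 0
        assert m.specificity == 100.0

    def test_normocalcemic_subgroup_row_against_all_controls(self):
        # 35 normocalcemic cases, none hypercalcemic by definition, 96 controls
        m = metrics(ConfusionCounts(tp=0, fn=35, fp=0, tn=96))
        assert m.rounded()["npv"] == 73
        assert m.rounded()["accuracy"] == 73

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=100)
    def test_complement_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if tp + fn > 0:
            assert m.sensitivity + 100 * fn / (tp + fn) == pytest.approx(100.0)
        if fp + tn > 0:
            assert m.specificity + 100 * fp / (fp + tn) == pytest.approx(100.0)


class TestRoc:
    def test_small_example_matches_pairwise_concordance(self):
        scores = [3, 4, 5, 1, 2, 3]
        truth = [True] * 3 + [False] * 3
        result = roc(scores, truth)
        assert result.auc == pytest.approx(8.5 / 9)
        assert result.auc == pytest.approx(brute_auc([3, 4, 5], [1, 2, 3]))

    def test_small_example_youden_tie_breaks_low(self):
        # J = 2/3 at both 3 and 4; the lower threshold (max sensitivity) wins
        result = roc([3, 4, 5, 1, 2, 3], [True] * 3 + [False] * 3)
        assert youden_cutoff(result) == 3
        assert result.youden_cutoff == 3

    def test_perfect_separation(self):
        result = roc([10, 11, 12, 1, 2, 3], [True] * 3 + [False] * 3)
        assert result.auc == 1.0
        assert result.youden_cutoff == 10  # smallest positive-class score
        assert result.auc_se == 0.0
        assert result.auc_ci95 == (1.0, 1.0)

    def test_uninformative_scores_give_half_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        truth = rng.uniform(size=4000) < 0.5
        assert roc(scores, truth).auc == pytest.approx(0.5, abs=0.05)

    def test_sensitivity_non_increasing_and_curve_endpoints(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.normal(size=200), 1)
        truth = rng.uniform(size=200) < 0.4
        result = roc(scores, truth)
        assert np.all(np.diff(result.sensitivity) <= 1e-12)
        assert result.sensitivity[0] == 1.0  # lowest threshold calls everything positive
        assert result.sensitivity[-1] == 0.0 and result.specificity[-1] == 1.0

    def test_shift_invariance_of_cutoff(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n1, n0 = rng.integers(3, 20, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)
            truth = [True] * n1 + [False] * n0
            shift = float(rng.uniform(5, 10))
            base = roc(scores, truth).youden_cutoff
            shifted = roc(scores + shift, truth).youden_cutoff
            assert shifted == pytest.approx(base + shift, abs=1e-9)

    def test_agrees_with_scikit_learn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = np.round(rng.normal(size=300), 1)
        truth = rng.uniform(size=300) < 0.3
        assert roc(scores, truth).auc == pytest.approx(
            roc_auc_score(truth, scores), rel=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [True, True, True])
        with pytest.raises(ValueError):
            roc([1.0, 1.0], [True, False])


class TestAucCi:
    def test_symmetric_about_half(self):
        se, (lo, hi) = auc_ci(0.5, 500, 500)
        assert lo + hi == pytest.approx(1.0)
        assert se > 0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            auc_ci(0.8, 0, 10)
        with pytest.raises(ValueError):
            auc_ci(1.2, 10, 10)

    def test_monte_carlo_coverage(self):
        # two-normal cohorts with known AUC; the 95% CI should cover it in
        # roughly 95% of replicates
        from scipy.stats import norm

        true_auc = norm.cdf(1.0 / np.sqrt(2.0))  # unit-variance classes, shift 1
        rng = np.random.default_rng(11)
        covered = 0
        reps = 200
        for _ in range(reps):
            pos = rng.normal(1.0, 1.0, size=50)
            neg = rng.normal(0.0, 1.0, size=50)
            result = roc(
                np.concatenate([pos, neg]), [True] * 50 + [False] * 50
            )
            lo, hi = result.auc_ci95
            covered += lo <= true_auc <= hi
        assert 0.90 * reps <= covered <= 0.99 * reps

    def test_bootstrap_interval_brackets_the_point_estimate(self):
        rng = np.random.default_rng(4)
        pos = rng.normal(1.2, 1.0, size=40)
        neg = rng.normal(0.0, 1.0, size=60)
        scores = np.concatenate([pos, neg])
        truth = [True] * 40 + [False] * 60
        point = roc(scores, truth).auc
        _, (lo, hi) = bootstrap_auc_ci(scores, truth, n_boot=300, seed=5)
        assert lo <= point <= hi


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_roc_and_youden_match_brute_force(data):
    n1 = data.draw(st.integers(min_value=2, max_value=12))
    n0 = data.draw(st.integers(min_value=2, max_value=12))
    # integer scores force ties both within and across classes
    scores = data.draw(
        st.lists(st.integers(min_value=1, max_value=8), min_size=n1 + n0, max_size=n1 + n0)
    )
    truth = [True] * n1 + [False] * n0
    if len(set(scores)) < 2:
        return
    result = roc(scores, truth)
    assert result.auc == pytest.approx(brute_auc(scores[:n1], scores[n1:]), abs=1e-12)
    assert youden_cutoff(result) == brute_youden(scores, truth)
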