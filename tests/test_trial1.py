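import pytest

from caphos import LabRecord, Sex
from caphos.config import Config
from caphos.stats import confusion, metrics
from caphos.trial1 import (
    CohortLabel,
    apply_eligibility,
    assign_labels,
    derive_cutoff,
    evaluate_indices,
)


def rec(rid="r", age=50.0, ca=2.4, p=1.1, pth=50.0, creat=70.0, sex=Sex.MALE,
        flags=(), truth=None, albumin=None):
    return LabRecord(
        record_id=rid, age=age, sex=sex, ca=ca, p=p, pth=pth, creatinine=creat,
        exclusion_flags=frozenset(flags), truth_phpt=truth, albumin=albumin,
    )


class TestEligibility:
    def test_minor_excluded_for_age(self):
        result = apply_eligibility([rec(age=17.0)])
        assert result.eligible == []
        assert result.excluded[0][1] == "age_out_of_range"

    def test_renal_failure_excluded(self):
        # creatinine 260 umol/L at age 50 gives MDRD GFR ~ 24
        result = apply_eligibility([rec(age=50.0, creat=260.0)])
        assert result.excluded[0][1] == "gfr_le_30"

    def test_clean_record_eligible(self):
        result = apply_eligibility([rec(age=63.0, creat=70.0)])
        assert len(result.eligible) == 1 and not result.excluded

    def test_first_matching_reason_wins(self):
        # a minor with a chart flag is counted under the age stage only
        result = apply_eligibility([rec(age=17.0, flags=("cancer",))])
        assert result.excluded[0][1] == "age_out_of_range"
        assert result.flow.stages[0].n_excluded == 1
        assert result.flow.stages[2].n_excluded == 0

    def test_flow_conservation(self):
        records = [
            rec("a", age=17.0), rec("b", creat=600.0), rec("c", flags=("lithium",)),
            rec("d"), rec("e", age=95.0),
        ]
        result = apply_eligibility(records)
        assert result.flow.n_in == 5
        assert len(result.eligible) + len(result.excluded) == 5
        assert result.flow.n_out == len(result.eligible) == 1
        assert sum(s.n_excluded for s in result.flow.stages) == 4

    def test_empty_input(self):
        result = apply_eligibility([])
        assert result.eligible == [] and result.flow.n_in == 0


class TestAssignLabels:
    def test_hypercalcemic_case(self):
        (lr,) = assign_labels([rec(ca=2.75, truth=True)])
        assert lr.label is CohortLabel.PHPT_HYPERCALCEMIC

    def test_normocalcemic_case(self):
        (lr,) = assign_labels([rec(ca=2.55, truth=True)])
        assert lr.label is CohortLabel.PHPT_NORMOCALCEMIC

    def test_control_definition_enforced(self):
        (lr,) = assign_labels([rec(pth=95.0, truth=False)])
        assert lr.label is CohortLabel.EXCLUDED and lr.reason == "control_criteria"
        (ok,) = assign_labels([rec(pth=60.0, truth=False)])
        assert ok.label is CohortLabel.CONTROL

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError):
            assign_labels([rec(truth=None)])

    def test_every_eligible_record_gets_exactly_one_label(self, labeled_cohort):
        assert all(lr.label in CohortLabel for lr in labeled_cohort)
        n_cases = sum(lr.is_case for lr in labeled_cohort)
        n_controls = sum(lr.label is CohortLabel.CONTROL for lr in labeled_cohort)
        n_excluded = sum(lr.label is CohortLabel.EXCLUDED for lr in labeled_cohort)
        assert n_cases + n_controls + n_excluded == len(labeled_cohort)
        assert n_cases > 0 and n_controls > 0


class TestEvaluateIndices:
    def test_hand_built_fixture(self, fixtures):
        cohort = assign_labels(fixtures["evaluation_cohort"])
        full, _ = evaluate_indices(cohort)
        row = full.set_index("index").loc["ca_p"]
        expected = fixtures["evaluation_expected"]
        assert row["sensitivity_raw"] == pytest.approx(expected["sensitivity"])
        assert row["specificity_raw"] == pytest.approx(expected["specificity"])
        assert (row["tp"], row["fn"], row["fp"], row["tn"]) == (5, 1, 1, 5)

    def test_serum_ca_has_zero_sensitivity_in_ncphpt_subgroup(self, labeled_cohort):
        _, subgroup = evaluate_indices(labeled_cohort)
        assert subgroup.set_index("index").loc["ca", "sensitivity_raw"] == 0.0

    def test_combined_rule_dominates_serum_ca(self, labeled_cohort):
        full, _ = evaluate_indices(labeled_cohort)
        table = full.set_index("index")
        assert table.loc["combined", "sensitivity_raw"] >= table.loc["ca", "sensitivity_raw"]

    def test_perfectly_separated_cohort_scores_all_metrics_100(self):
        cases = [rec(f"c{i}", ca=3.0, p=0.8, pth=200.0, truth=True) for i in range(5)]
        controls = [rec(f"k{i}", ca=2.3, p=1.2, pth=40.0, truth=False) for i in range(5)]
        full, _ = evaluate_indices(assign_labels(cases + controls))
        row = full.set_index("index").loc["ca_p"]
        assert row["sensitivity_raw"] == 100.0 and row["specificity_raw"] == 100.0

    def test_corrected_indices_restricted_to_albumin_subset(self):
        cases = [rec(f"c{i}", ca=3.0, p=0.8, truth=True, albumin=42.0 if i < 3 else None)
                 for i in range(5)]
        controls = [rec(f"k{i}", ca=2.3, p=1.2, truth=False, albumin=40.0) for i in range(5)]
        full, _ = evaluate_indices(assign_labels(cases + controls))
        table = full.set_index("index")
        assert table.loc["corrected_ca_p", "tp"] + table.loc["corrected_ca_p", "fn"] == 3
        assert table.loc["ca_p", "tp"] + table.loc["ca_p", "fn"] == 5

    def test_single_class_cohort_rejected(self):
        cases = [rec(ca=3.0, truth=True)]
        with pytest.raises(ValueError):
            evaluate_indices(assign_labels(cases))

    def test_table_row_order_and_counts_reconcile(self, labeled_cohort):
        full, _ = evaluate_indices(labeled_cohort)
        assert list(full["index"][:3]) == ["ca_p", "corrected_ca_p", "pth"]
        n_cases = sum(lr.is_case for lr in labeled_cohort)
        n_controls = sum(lr.label is CohortLabel.CONTROL for lr in labeled_cohort)
        row = full.set_index("index").loc["ca_p"]
        assert row["tp"] + row["fn"] == n_cases
        assert row["fp"] + row["tn"] == n_controls


class TestDeriveCutoff:
    def test_label_like_scores_separate_exactly(self):
        cases = [rec(f"c{i}", ca=3.0, p=1.0, truth=True) for i in range(4)]
        controls = [rec(f"k{i}", ca=2.4, p=1.0, truth=False) for i in range(4)]
        cutoff, result = derive_cutoff(assign_labels(cases + controls))
        assert result.auc == 1.0
        assert cutoff == pytest.approx(3.0)  # smallest case score

    def test_cutoff_near_published_on_calibrated_cohort(self, labeled_cohort):
        cutoff, result = derive_cutoff(labeled_cohort)
        assert 2.3 < cutoff < 3.1
        assert result.auc > 0.85

    def test_metrics_at_derived_cutoff_match_roc_row(self, labeled_cohort):
        cutoff, result = derive_cutoff(labeled_cohort)
        scores, truth = [], []
        for lr in labeled_cohort:
            if lr.label is not CohortLabel.EXCLUDED:
                scores.append(lr.record.ca_p)
                truth.append(lr.is_case)
        counts = confusion([s >= cutoff for s in scores], truth)
        m = metrics(counts)
        idx = list(result.thresholds).index(cutoff)
        assert m.sensitivity / 100 == pytest.approx(result.sensitivity[idx])
        assert m.specificity / 100 == pytest.approx(result.specificity[idx])
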