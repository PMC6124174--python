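"""Case-control evaluation of the Ca/P ratio and competing indices.

Given curated records with a chart-level ground-truth diagnosis, this pipeline
(1) applies the eligibility criteria (age 18–90, MDRD GFR > 30, no coded
exclusion condition), (2) partitions the cohort into hypercalcemic PHPT,
normocalcemic PHPT (NCPHPT: Ca within the reference interval but PTH raised)
and controls (non-PHPT with both Ca and PTH in range), and (3) evaluates each
diagnostic index at its published cutoff — Ca/P and corrected Ca/P at 2.71,
PTH above 88 ng/L, total and corrected Ca above 2.65 mmol/L, phosphorous below
2.5 mg/dL, and the combined Ca/P-or-Ca rule — for the whole cohort and for the
NCPHPT subgroup against all controls. A Youden-optimal Ca/P cutoff can also be
re-derived from the cohort itself.

Note the control definition makes PTH's apparent performance optimistic:
controls are selected to have normal PTH, so the PTH index is circular by
construction. The pipeline reproduces (and documents) that circularity rather
than hiding it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .biochem import (
    CorrectionUnavailableError,
    LabRecord,
    ReferenceRanges,
    ca_p_ratio,
    convert_ratio_cutoff,
    corrected_calcium,
    mdrd_gfr,
    round_half_away,
)
from .config import Config
from .flow import FlowReport
from .stats import RocResult, classify, combined_rule, confusion, metrics, roc

__all__ = [
    "CohortLabel",
    "LabeledRecord",
    "EligibilityResult",
    "apply_eligibility",
    "assign_labels",
    "evaluate_indices",
    "derive_cutoff",
    "INDEX_ORDER",
]


class CohortLabel(str, enum.Enum):
    PHPT_HYPERCALCEMIC = "phpt_hypercalcemic"
    PHPT_NORMOCALCEMIC = "phpt_normocalcemic"
    CONTROL = "control"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class LabeledRecord:
    record: LabRecord
    label: CohortLabel
    reason: str | None = None

    @property
    def is_case(self) -> bool:
        return self.label in (CohortLabel.PHPT_HYPERCALCEMIC, CohortLabel.PHPT_NORMOCALCEMIC)


@dataclass(frozen=True)
class EligibilityResult:
    eligible: list[LabRecord]
    excluded: list[tuple[LabRecord, str]]
    flow: FlowReport


def apply_eligibility(records: list[LabRecord]) -> EligibilityResult:
    """Apply the shared eligibility criteria, logging each stage.

    Exclusion reasons are assigned in a fixed order — age (<18 or >90), renal
    (MDRD GFR ≤ 30), then any coded chart exclusion flag — so a record failing
    several criteria is counted once, under the first.
    """
    flow = FlowReport()
    excluded: list[tuple[LabRecord, str]] = []
    current = list(records)

    def stage(name: str, reason: str, fails) -> None:
        nonlocal current
        kept = []
        n_in = len(current)
        for rec in current:
            if fails(rec):
                excluded.append((rec, reason))
            else:
                kept.append(rec)
        flow.add(name, n_in, n_in - len(kept), reason)
        current = kept

    stage("age", "age_out_of_range", lambda r: r.age < 18 or r.age > 90)
    stage("renal", "gfr_le_30", lambda r: mdrd_gfr(r.creatinine, r.age, r.sex, r.black) <= 30)
    stage("flags", "exclusion_flag", lambda r: len(r.exclusion_flags) > 0)
    return EligibilityResult(eligible=current, excluded=excluded, flow=flow)


def assign_labels(
    records: list[LabRecord],
    ranges: ReferenceRanges | None = None,
    ncphpt_on_corrected: bool = False,
) -> list[LabeledRecord]:
    """Partition eligible records into cohort groups using ground truth.

    PHPT records (truth) split on the calcium upper reference limit into
    hypercalcemic (Ca above it) and normocalcemic (Ca at or below it); by
    default the split uses total Ca, optionally albumin-corrected Ca. Non-PHPT
    records become controls only when both Ca and PTH lie within the reference
    ranges; otherwise they are excluded as failing the control definition.
    """
    ranges = ranges or ReferenceRanges()
    ca_upper = ranges.ca[1]
    labeled = []
    for rec in records:
        if rec.truth_phpt is None:
            raise ValueError(f"record {rec.record_id}: ground-truth diagnosis missing")
        if rec.truth_phpt:
            ca = rec.ca
            if ncphpt_on_corrected and rec.albumin is not None:
                ca = corrected_calcium(rec.ca, rec.albumin)
            label = (
                CohortLabel.PHPT_HYPERCALCEMIC if ca > ca_upper else CohortLabel.PHPT_NORMOCALCEMIC
            )
            labeled.append(LabeledRecord(rec, label))
        elif ranges.contains("ca", rec.ca) and ranges.contains("pth", rec.pth):
            labeled.append(LabeledRecord(rec, CohortLabel.CONTROL))
        else:
            labeled.append(LabeledRecord(rec, CohortLabel.EXCLUDED, "control_criteria"))
    return labeled


# Row order of the published evaluation tables.
INDEX_ORDER = ("ca_p", "corrected_ca_p", "pth", "ca", "corrected_ca", "p", "combined")


def _index_definitions(config: Config):
    """(name, score function, SI cutoff, positivity, needs-albumin) per index."""
    return [
        ("ca_p", lambda r: ca_p_ratio(r.ca, r.p), config.ratio_cutoff_si, config.boundary, False),
        (
            "corrected_ca_p",
            lambda r: ca_p_ratio(corrected_calcium(r.ca, r.albumin), r.p),
            config.ratio_cutoff_si,
            config.boundary,
            True,
        ),
        ("pth", lambda r: r.pth, config.pth_cutoff, "gt", False),
        ("ca", lambda r: r.ca, config.ca_cutoff, "gt", False),
        (
            "corrected_ca",
            lambda r: corrected_calcium(r.ca, r.albumin),
            config.ca_cutoff,
            "gt",
            True,
        ),
        ("p", lambda r: r.p, config.p_cutoff_si, "lt", False),
    ]


def _evaluate_one_table(
    cases: list[LabRecord], controls: list[LabRecord], config: Config, include_combined: bool
) -> pd.DataFrame:
    rows = []
    for name, score_fn, cutoff, orientation, needs_albumin in _index_definitions(config):
        case_sub = [r for r in cases if not needs_albumin or r.albumin is not None]
        ctrl_sub = [r for r in controls if not needs_albumin or r.albumin is not None]
        if not case_sub or not ctrl_sub:
            continue
        preds = [classify(score_fn(r), cutoff, orientation) for r in case_sub + ctrl_sub]
        truth = [True] * len(case_sub) + [False] * len(ctrl_sub)
        rows.append(_table_row(name, cutoff, preds, truth, config))
    if include_combined:
        preds = [
            combined_rule(r, config.ratio_cutoff_si, config.ca_cutoff) for r in cases + controls
        ]
        truth = [True] * len(cases) + [False] * len(controls)
        rows.append(
            _table_row("combined", config.ratio_cutoff_si, preds, truth, config)
        )
    return pd.DataFrame(rows)


def _table_row(name, cutoff, preds, truth, config) -> dict:
    counts = confusion(preds, truth)
    m = metrics(counts)
    integers = m.truncated() if config.rounding == "truncate" else m.rounded()
    row = {
        "index": name,
        "cutoff_si": cutoff,
        "cutoff_cu": round_half_away(convert_ratio_cutoff(cutoff), 1)
        if name in ("ca_p", "corrected_ca_p", "combined")
        else None,
        "tp": counts.tp,
        "fn": counts.fn,
        "fp": counts.fp,
        "tn": counts.tn,
    }
    for key, value in m.raw().items():
        row[f"{key}_raw"] = value
    for key, value in integers.items():
        row[key] = value
    return row


def evaluate_indices(
    cohort: list[LabeledRecord], config: Config | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every index on the full cohort and on the NCPHPT subgroup.

    Returns (full-cohort table, NCPHPT-subgroup table). The subgroup table
    pits normocalcemic cases against all controls — the setting where serum Ca
    has, by definition, zero sensitivity — and omits the combined rule, which
    the published subgroup analysis does not report. Corrected indices are
    evaluated on the albumin-available subset only.
    """
    config = config or Config()
    cases = [lr.record for lr in cohort if lr.is_case]
    normo = [lr.record for lr in cohort if lr.label is CohortLabel.PHPT_NORMOCALCEMIC]
    controls = [lr.record for lr in cohort if lr.label is CohortLabel.CONTROL]
    if not cases or not controls:
        raise ValueError("cohort must contain both cases and controls")
    full = _evaluate_one_table(cases, controls, config, include_combined=True)
    subgroup = (
        _evaluate_one_table(normo, controls, config, include_combined=False)
        if normo
        else pd.DataFrame()
    )
    return full, subgroup


def derive_cutoff(cohort: list[LabeledRecord]) -> tuple[float, RocResult]:
    """Re-derive the Youden-optimal Ca/P cutoff from a labeled cohort.

    PHPT of either subtype is the positive class; scores are Ca/P ratios.
    """
    scores, truth = [], []
    for lr in cohort:
        if lr.label is CohortLabel.EXCLUDED:
            continue
        scores.append(ca_p_ratio(lr.record.ca, lr.record.p))
        truth.append(lr.is_case)
    result = roc(scores, truth)
    return result.youden_cutoff, result
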