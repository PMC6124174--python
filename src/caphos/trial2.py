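"""Laboratory-database mining cascade for PHPT-like records.

An anonymous laboratory extract has no diagnoses, so case and control status
are defined distributionally: after refining the raw rows (complete Ca/P/PTH/
creatinine panel, MDRD GFR > 30, age 18–90), each analyte's distribution is
assessed, right-skewed analytes (typically PTH) are log-transformed, and
empirical 5th/95th centile bounds are computed. Rows with PTH or Ca below the
5th centile are excluded as possible hypoparathyroidism; of the remainder,
rows with both PTH and Ca above the 95th centile are labeled PHPT and all
others controls. The Ca/P ratio is then evaluated at the fixed case-control
cutoff (2.71) and a database-specific Youden cutoff is derived from the same
labels.

Centile bounds are computed on the refined set before the hypoparathyroid
exclusion (the exclusion itself consumes those bounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biochem import mdrd_gfr, round_half_away
from .config import Config
from .flow import FlowReport
from .stats import ConfusionCounts, DiagnosticMetrics, RocResult, classify, confusion, metrics, roc

__all__ = [
    "CentileBounds",
    "REQUIRED_ANALYTES",
    "refine",
    "assess_distributions",
    "label_records",
    "evaluate_trial2",
    "Trial2Evaluation",
    "run_trial2",
]

REQUIRED_ANALYTES = ("ca", "p", "pth", "creatinine")

#: Analytes whose distribution is assessed and bounded.
_BOUNDED = ("ca", "p", "pth")


@dataclass(frozen=True)
class CentileBounds:
    """Empirical 5th/95th centiles per analyte, on the measurement scale.

    ``transformed`` records which analytes were log-transformed before the
    centiles were taken (the bounds are back-transformed to the raw scale);
    ``skewness`` holds the raw-scale sample skewness that drove the decision.
    """

    bounds: dict[str, tuple[float, float]]
    transformed: dict[str, bool]
    skewness: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        for analyte, (low, high) in self.bounds.items():
            if not low < high:
                raise ValueError(f"{analyte}: centile bounds must satisfy low < high")

    def low(self, analyte: str) -> float:
        return self.bounds[analyte][0]

    def high(self, analyte: str) -> float:
        return self.bounds[analyte][1]


def _gfr_column(df: pd.DataFrame) -> pd.Series:
    return df.apply(
        lambda r: mdrd_gfr(r["creatinine"], r["age"], r["sex"], bool(r.get("black", False))),
        axis=1,
    )


def refine(records: pd.DataFrame) -> tuple[pd.DataFrame, FlowReport]:
    """Sequential refinement of a raw extract, in the fixed published order.

    (1) drop rows missing any of Ca, P, PTH or creatinine; (2) drop rows with
    MDRD GFR ≤ 30 (renal failure); (3) drop rows aged under 18 or over 90.
    Idempotent: refining an already-refined frame changes nothing.
    """
    flow = FlowReport()
    df = records

    complete = df[list(REQUIRED_ANALYTES)].notna().all(axis=1)
    flow.add("completeness", len(df), int((~complete).sum()), "incomplete_panel")
    df = df[complete]

    if len(df):
        renal_ok = _gfr_column(df) > 30
    else:
        renal_ok = pd.Series(dtype=bool)
    flow.add("renal", len(df), int((~renal_ok).sum()), "gfr_le_30")
    df = df[renal_ok] if len(df) else df

    age_ok = (df["age"] >= 18) & (df["age"] <= 90)
    flow.add("age", len(df), int((~age_ok).sum()), "age_out_of_range")
    df = df[age_ok]

    return df.reset_index(drop=True), flow


def assess_distributions(
    refined: pd.DataFrame, config: Config | None = None, min_n: int = 50
) -> CentileBounds:
    """Decide per-analyte transformations and compute 5th/95th centile bounds.

    An analyte is log-transformed before the centiles are taken when its
    sample skewness exceeds the configured threshold in absolute value
    (default 1; a Shapiro–Wilk trigger at p < 0.05 is available instead).
    Bounds are linearly interpolated empirical quantiles, back-transformed to
    the measurement scale where a log-transform applied.
    """
    config = config or Config()
    n = len(refined)
    if n < min_n:
        raise ValueError(f"need at least {min_n} refined rows to assess distributions, got {n}")
    bounds: dict[str, tuple[float, float]] = {}
    transformed: dict[str, bool] = {}
    skewness: dict[str, float] = {}
    for analyte in _BOUNDED:
        values = refined[analyte].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            raise ValueError(f"{analyte}: constant column, distribution shape undefined")
        skew = float(sps.skew(values))
        skewness[analyte] = skew
        if config.transform_trigger == "shapiro":
            sample = values if n <= 5000 else np.sort(values)[:: max(1, n // 5000)][:5000]
            transform = sps.shapiro(sample).pvalue < 0.05 and (values > 0).all()
        else:
            transform = abs(skew) > config.skew_threshold and (values > 0).all()
        transformed[analyte] = bool(transform)
        work = np.log(values) if transform else values
        lo, hi = np.quantile(work, [0.05, 0.95])
        if transform:
            lo, hi = np.exp(lo), np.exp(hi)
        bounds[analyte] = (float(lo), float(hi))
    return CentileBounds(bounds=bounds, transformed=transformed, skewness=skewness, n=n)


def label_records(
    refined: pd.DataFrame, bounds: CentileBounds
) -> tuple[pd.DataFrame, FlowReport]:
    """Attach distribution-based labels, excluding hypoparathyroid-like rows first.

    A row with PTH or Ca below the 5th centile is ``excluded_hypopara``; of the
    remainder, a row with both PTH and Ca above the 95th centile is ``phpt``,
    anything else ``control`` (a single extreme analyte is not enough).
    """
    if bounds.n != len(refined):
        raise ValueError(
            f"bounds were computed on {bounds.n} rows but {len(refined)} were supplied"
        )
    pth, ca = refined["pth"], refined["ca"]
    hypopara = (pth < bounds.low("pth")) | (ca < bounds.low("ca"))
    phpt = (pth > bounds.high("pth")) & (ca > bounds.high("ca")) & ~hypopara
    labels = np.where(hypopara, "excluded_hypopara", np.where(phpt, "phpt", "control"))
    labeled = refined.assign(label=labels)
    flow = FlowReport()
    flow.add("hypopara", len(labeled), int(hypopara.sum()), "pth_or_ca_below_5th_centile")
    return labeled, flow


@dataclass(frozen=True)
class Trial2Evaluation:
    counts: ConfusionCounts
    metrics: DiagnosticMetrics
    fixed_cutoff: float
    fixed_cutoff_cu: float
    roc: RocResult
    derived_cutoff: float
    n_phpt: int
    n_control: int

    @property
    def prevalence_pct(self) -> float:
        """PHPT-labeled share of the final analysis set, percent."""
        return 100.0 * self.n_phpt / (self.n_phpt + self.n_control)


def evaluate_trial2(labeled: pd.DataFrame, config: Config | None = None) -> Trial2Evaluation:
    """Evaluate Ca/P on the labeled database and re-derive its own cutoff.

    The fixed evaluation uses the case-control cutoff (default 2.71); the
    derived cutoff is the database's own Youden optimum over the same scores,
    mirroring the two published operating points.
    """
    config = config or Config()
    final = labeled[labeled["label"] != "excluded_hypopara"]
    truth = (final["label"] == "phpt").to_numpy()
    if truth.all() or not truth.any():
        raise ValueError("both phpt and control labels are required")
    scores = (final["ca"] / final["p"]).to_numpy()
    preds = [classify(s, config.ratio_cutoff_si, config.boundary) for s in scores]
    counts = confusion(preds, truth)
    roc_result = roc(scores, truth)
    from .biochem import convert_ratio_cutoff

    return Trial2Evaluation(
        counts=counts,
        metrics=metrics(counts),
        fixed_cutoff=config.ratio_cutoff_si,
        fixed_cutoff_cu=round_half_away(convert_ratio_cutoff(config.ratio_cutoff_si), 1),
        roc=roc_result,
        derived_cutoff=roc_result.youden_cutoff,
        n_phpt=int(truth.sum()),
        n_control=int((~truth).sum()),
    )


def run_trial2(
    records: pd.DataFrame, config: Config | None = None
) -> tuple[Trial2Evaluation, CentileBounds, FlowReport]:
    """Full cascade: refine → assess distributions → label → evaluate."""
    config = config or Config()
    refined, flow = refine(records)
    bounds = assess_distributions(refined, config)
    labeled, hypo_flow = label_records(refined, bounds)
    for stage in hypo_flow.stages:
        flow.add(stage.name, stage.n_in, stage.n_excluded, stage.reason)
    evaluation = evaluate_trial2(labeled, config)
    return evaluation, bounds, flow
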