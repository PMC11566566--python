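"""Sample-level quality control.

Samples pass when every signal metric sits strictly inside its bound
(``LRR_SD < 0.3``, ``BAF_drift < 0.01``, ``|WF| < 0.05``) and the call count
does not exceed the NumCNV limit (fails only when strictly greater, i.e. a
sample at exactly the limit is kept).  The two boundary rules intentionally
differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigurationError
from .models import CnvCall, SampleQcRecord


@dataclass(frozen=True)
class QcThresholds:
    """Upper bounds for the per-sample quality metrics.

    ``extra_bounds`` maps a metric attribute name (e.g. ``lrr_mean``) to an
    ``(lower, upper)`` pair, either end optional; the metric must satisfy
    ``lower < value < upper`` where given.  No extra bounds are active by
    default.
    """

    lrr_sd_max: float = 0.3
    baf_drift_max: float = 0.01
    wf_abs_max: float = 0.05
    num_cnv_max: int = 50
    extra_bounds: dict[str, tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name, bound in (
            ("lrr_sd_max", self.lrr_sd_max),
            ("baf_drift_max", self.baf_drift_max),
            ("wf_abs_max", self.wf_abs_max),
            ("num_cnv_max", self.num_cnv_max),
        ):
            if bound <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class QcDecision:
    sample_id: str
    passed: bool
    failed_criteria: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed flag inconsistent with failed_criteria")


def _require(record: SampleQcRecord, attr: str, criterion: str):
    value = getattr(record, attr)
    if value is None:
        raise ConfigurationError(
            f"sample {record.sample_id}: metric {attr!r} required by active "
            f"threshold {criterion!r} is absent"
        )
    return value


def apply_sample_qc(
    records: Sequence[SampleQcRecord], thresholds: Optional[QcThresholds] = None
) -> list[QcDecision]:
    """Evaluate every sample against the thresholds.

    Returns one decision per record, in input order, listing every violated
    criterion.  A metric required by an active threshold but absent from a
    record raises :class:`ConfigurationError`.
    """
    if not records:
        raise ConfigurationError("apply_sample_qc: no QC records supplied")
    thresholds = thresholds or QcThresholds()
    decisions: list[QcDecision] = []
    for rec in records:
        failed: list[str] = []
        if _require(rec, "lrr_sd", "LRR_SD") >= thresholds.lrr_sd_max:
            failed.append("LRR_SD")
        if _require(rec, "baf_drift", "BAF_drift") >= thresholds.baf_drift_max:
            failed.append("BAF_drift")
        if abs(_require(rec, "wf", "WF")) >= thresholds.wf_abs_max:
            failed.append("WF")
        if _require(rec, "num_cnv", "NumCNV") > thresholds.num_cnv_max:
            failed.append("NumCNV")
        for attr, (lo, hi) in thresholds.extra_bounds.items():
            value = _require(rec, attr, attr)
            if (lo is not None and value <= lo) or (hi is not None and value >= hi):
                failed.append(attr)
        decisions.append(
            QcDecision(sample_id=rec.sample_id, passed=not failed, failed_criteria=tuple(failed))
        )
    return decisions


def drop_failed_samples(
    calls: Sequence[CnvCall], decisions: Sequence[QcDecision]
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Split calls into (kept, removed) according to their sample's decision.

    Calls of samples absent from the decisions are removed (no QC record
    means no evidence of quality).
    """
    passed = {d.sample_id for d in decisions if d.passed}
    kept = [c for c in calls if c.sample_id in passed]
    removed = [c for c in calls if c.sample_id not in passed]
    return kept, removed


_METRICS = (
    "lrr_mean", "lrr_median", "lrr_sd",
    "baf_mean", "baf_median", "baf_sd",
    "baf_drift", "wf", "num_cnv",
)


def qc_summary_table(
    records: Sequence[SampleQcRecord],
    decisions: Sequence[QcDecision],
    calls: Optional[Sequence[CnvCall]] = None,
) -> dict:
    """Plot-ready QC summary: per-metric five-number summaries split by
    pass/fail, sample counts, and the number of calls lost with failing
    samples (when ``calls`` is given)."""
    status = {d.sample_id: d.passed for d in decisions}
    rows = []
    for rec in records:
        row = {"sample_id": rec.sample_id, "passed": status[rec.sample_id]}
        for m in _METRICS:
            row[m] = getattr(rec, m)
        rows.append(row)
    df = pd.DataFrame(rows)

    summaries = []
    for m in _METRICS:
        if df[m].isna().all():
            continue
        for passed in (True, False):
            sub = df.loc[df["passed"] == passed, m].dropna()
            if sub.empty:
                continue
            summaries.append(
                {
                    "metric": m,
                    "group": "pass" if passed else "fail",
                    "n": len(sub),
                    "min": sub.min(),
                    "q1": sub.quantile(0.25),
                    "median": sub.median(),
                    "q3": sub.quantile(0.75),
                    "max": sub.max(),
                }
            )
    n_fail = sum(1 for d in decisions if not d.passed)
    counts = {
        "initial_samples": len(records),
        "final_samples": len(records) - n_fail,
        "lost_samples": n_fail,
    }
    if calls is not None:
        kept, removed = drop_failed_samples(calls, decisions)
        counts.update(
            initial_calls=len(calls), final_calls=len(kept), lost_calls=len(removed)
        )
    return {"metric_summaries": pd.DataFrame(summaries), "counts": counts}
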