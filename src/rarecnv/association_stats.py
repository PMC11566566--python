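"""Size-binned and overall case-control frequency comparison.

Each 2x2 table (CNV counts vs cohort sizes) gets four statistics:

* ``p_two_prop`` — two-sided two-proportion chi-square test WITH Yates
  continuity correction (the R ``prop.test`` dialect);
* ``or_estimate`` with a Woolf (log-normal) confidence interval;
* ``p_or`` — Pearson chi-square on the same table WITHOUT continuity
  correction (the dialect of the odds-ratio-associated P column).

The two p-value flavours coexist deliberately; collapsing them onto one
test would not reproduce published summary files.  No multiple-testing
adjustment is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .models import CnvCall, CnvType, CohortTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SizeBins:
    """Half-open size bins in kb; the last bin is unbounded above but labeled
    with a 1,000,000 kb cap (``1000KB_1000000KB`` style)."""

    edges_kb: tuple[float, ...] = (50.0, 100.0, 200.0, 500.0, 1000.0)
    cap_kb: float = 1_000_000.0

    def __post_init__(self) -> None:
        if len(self.edges_kb) < 1 or any(
            a >= b for a, b in zip(self.edges_kb, self.edges_kb[1:])
        ):
            raise ConfigurationError("bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        def fmt(x: float) -> str:
            return f"{int(x)}KB" if float(x).is_integer() else f"{x}KB"

        uppers = list(self.edges_kb[1:]) + [self.cap_kb]
        return [f"{fmt(lo)}_{fmt(hi)}" for lo, hi in zip(self.edges_kb, uppers)]

    def label_for(self, length_kb: float) -> str:
        if length_kb < self.edges_kb[0]:
            raise ConfigurationError(
                f"call of {length_kb} kb is below the lowest bin edge "
                f"{self.edges_kb[0]} kb — size filter contract violated"
            )
        idx = 0
        for i, edge in enumerate(self.edges_kb):
            if length_kb >= edge:
                idx = i
        return self.labels[idx]


def bin_by_size(calls: Sequence[CnvCall], bins: SizeBins | None = None) -> dict[str, list[CnvCall]]:
    """Assign every call to exactly one size bin (lower edge inclusive)."""
    bins = bins or SizeBins()
    out: dict[str, list[CnvCall]] = {label: [] for label in bins.labels}
    for c in calls:
        out[bins.label_for(c.length_kb)].append(c)
    return out


def two_proportion_test(a: int, n1: int, b: int, n2: int, correction: bool = True) -> float:
    """Two-sided chi-square two-proportion test on [[a, n1-a], [b, n2-b]].

    With ``correction`` the Yates adjustment ``max(0, |ad-bc| - N/2)`` is
    applied (R ``prop.test`` semantics — the statistic clamps at zero, so
    identical proportions give p = 1).
    """
    if n1 <= 0 or n2 <= 0:
        raise ConfigurationError("two_proportion_test: empty cohort")
    N = n1 + n2
    m1 = a + b           # successes margin
    m2 = (n1 - a) + (n2 - b)
    if m1 == 0 or m2 == 0:
        return 1.0  # no variation in outcome
    det = abs(a * (n2 - b) - b * (n1 - a))
    if correction:
        det = max(0.0, det - N / 2.0)
    chi2 = N * det * det / (n1 * n2 * m1 * m2)
    return float(stats.chi2.sf(chi2, df=1))


def odds_ratio_woolf(
    a: int, n1: int, b: int, n2: int, conf_level: float = 0.95
) -> tuple[float, float, float, float]:
    """Odds ratio with Woolf confidence interval and uncorrected Pearson p.

    Returns ``(or, ci_low, ci_high, p_or)`` for the table
    ``[[a, n1-a], [b, n2-b]]``.  Any zero cell triggers the
    Haldane-Anscombe policy: 0.5 is added to all four cells for the OR and
    CI only (logged); counts and p-values are untouched.
    """
    cells = [a, n1 - a, b, n2 - b]
    if any(c < 0 for c in cells):
        raise ConfigurationError("negative cell in 2x2 table")
    if a == n1 and b == n2:
        raise ConfigurationError("degenerate margins: every sample is a carrier")
    work = [float(c) for c in cells]
    if any(c == 0 for c in work):
        logger.info("zero cell in 2x2 (%s): Haldane-Anscombe 0.5 applied to OR/CI", cells)
        work = [c + 0.5 for c in work]
    c11, c12, c21, c22 = work
    or_est = (c11 * c22) / (c12 * c21)
    se = math.sqrt(sum(1.0 / c for c in work))
    z = stats.norm.ppf(1 - (1 - conf_level) / 2)
    ci_low = math.exp(math.log(or_est) - z * se)
    ci_high = math.exp(math.log(or_est) + z * se)
    p_or = two_proportion_test(a, n1, b, n2, correction=False)
    return or_est, ci_low, ci_high, p_or


@dataclass(frozen=True)
class AssociationResult:
    cnv_type: CnvType
    bin_label: str                 # "ALL" or a size-bin label
    a: int                         # case CNV count
    b: int                         # control CNV count
    n1: int                        # case cohort size
    n2: int                        # control cohort size
    case_freq: float
    control_freq: float
    p_two_prop: Optional[float]
    or_estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_or: Optional[float]


def _result(cnv_type: CnvType, label: str, a: int, b: int, n1: int, n2: int,
            conf_level: float) -> AssociationResult:
    if a == 0 and b == 0:
        return AssociationResult(cnv_type, label, a, b, n1, n2, a / n1, b / n2,
                                 None, None, None, None, None)
    or_est, lo, hi, p_or = odds_ratio_woolf(a, n1, b, n2, conf_level)
    return AssociationResult(
        cnv_type=cnv_type, bin_label=label, a=a, b=b, n1=n1, n2=n2,
        case_freq=a / n1, control_freq=b / n2,
        p_two_prop=two_proportion_test(a, n1, b, n2),
        or_estimate=or_est, ci_low=lo, ci_high=hi, p_or=p_or,
    )


def association_summary(
    rare_calls: Sequence[CnvCall],
    cohort: CohortTable,
    bins: SizeBins | None = None,
    conf_level: float = 0.95,
) -> list[AssociationResult]:
    """Overall (per-type ALL row) and per-size-bin association results.

    ``a``/``b`` count rare CNVs of the type/bin carried by case/control
    samples; frequencies divide by the cohort sizes.  Empty bins get a row
    with undefined statistics (``None``).
    """
    bins = bins or SizeBins()
    n1, n2 = cohort.n_cases, cohort.n_controls
    if n1 == 0 or n2 == 0:
        raise ConfigurationError("association requires both cases and controls")
    case_ids = set(cohort.case_ids)
    results: list[AssociationResult] = []
    for cnv_type in (CnvType.DEL, CnvType.DUP):
        typed = [c for c in rare_calls if c.cnv_type is cnv_type]
        a_all = sum(1 for c in typed if c.sample_id in case_ids)
        b_all = len(typed) - a_all
        results.append(_result(cnv_type, "ALL", a_all, b_all, n1, n2, conf_level))
        for label, group in bin_by_size(typed, bins).items():
            a = sum(1 for c in group if c.sample_id in case_ids)
            b = len(group) - a
            results.append(_result(cnv_type, label, a, b, n1, n2, conf_level))
    return results


def summary_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Summary table in the published column order (plus type/bin keys);
    doubles as forest-plot data (OR with CI per bin)."""
    rows = []
    for r in results:
        rows.append(
            {
                "CNV": r.cnv_type.value,
                "Length": r.bin_label,
                "Cases": r.a,
                "Controls": r.b,
                "Cases_freq": round(r.case_freq, 4),
                "Controls_freq": round(r.control_freq, 4),
                "P.value": None if r.p_two_prop is None else round(r.p_two_prop, 4),
                "OR": None if r.or_estimate is None else round(r.or_estimate, 4),
                "X95.CI": ""
                if r.ci_low is None
                else f"{r.ci_low:.4f},{r.ci_high:.4f}",
                "P": None if r.p_or is None else round(r.p_or, 4),
            }
        )
    return pd.DataFrame(rows)
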