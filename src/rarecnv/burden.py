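"""Global case-control CNV burden test.

Four per-sample metrics are compared between cases and controls:

* RATE  - number of segments
* PROP  - indicator of carrying at least one segment
* TOTKB - total kb spanned
* AVGKB - mean segment size in kb (defined only for carriers)

The test statistic is the case mean minus the control mean; significance
comes from phenotype-label permutation with an add-one empirical p-value,
``(1 + exceedances) / (n_perm + 1)``.  AVGKB means are taken over
CNV-carrying samples only, both observed and in every permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .models import CnvCall, CohortTable, Phenotype

METRICS = ("RATE", "PROP", "TOTKB", "AVGKB")


@dataclass(frozen=True)
class BurdenMetrics:
    sample_id: str
    rate: int
    prop: int
    totkb: float
    avgkb: Optional[float]  # None when rate == 0


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 10_000
    seed: int = 0
    alternative: str = "case_greater"  # or "two_sided"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.alternative not in ("case_greater", "two_sided"):
            raise ConfigurationError(f"unknown alternative {self.alternative!r}")


def per_sample_metrics(
    calls: Sequence[CnvCall], cohort: CohortTable
) -> list[BurdenMetrics]:
    """One metrics record per cohort sample, zero-CNV samples included."""
    totbp: dict[str, int] = {s: 0 for s in cohort.sample_ids}
    nseg: dict[str, int] = {s: 0 for s in cohort.sample_ids}
    for c in calls:
        if c.sample_id in nseg:
            nseg[c.sample_id] += 1
            totbp[c.sample_id] += c.length
    out = []
    for s in cohort.sample_ids:
        rate = nseg[s]
        totkb = totbp[s] / 1000.0
        out.append(
            BurdenMetrics(
                sample_id=s,
                rate=rate,
                prop=1 if rate > 0 else 0,
                totkb=totkb,
                avgkb=totkb / rate if rate > 0 else None,
            )
        )
    return out


def _group_means(values: np.ndarray, is_case: np.ndarray) -> tuple[float, float]:
    """Case and control means ignoring NaN; NaN when a group has no finite value."""
    with np.errstate(invalid="ignore"):
        case = np.nanmean(values[is_case]) if np.any(~np.isnan(values[is_case])) else np.nan
        ctrl = np.nanmean(values[~is_case]) if np.any(~np.isnan(values[~is_case])) else np.nan
    return float(case), float(ctrl)


def burden_test(
    metrics: Sequence[BurdenMetrics],
    cohort: CohortTable,
    config: PermutationConfig | None = None,
) -> pd.DataFrame:
    """Permutation burden test over the four metrics.

    Returns a table with columns metric, case_mean, control_mean, statistic,
    empirical_p, n_perm, testable.  Labels are permuted jointly across the
    four metrics; results are deterministic given ``config.seed``.
    """
    config = config or PermutationConfig()
    order = {m.sample_id: i for i, m in enumerate(metrics)}
    missing = [s for s in cohort.sample_ids if s not in order]
    if missing:
        raise ConfigurationError(f"metrics missing for samples: {', '.join(missing)}")
    is_case = np.array(
        [cohort[m.sample_id].phenotype is Phenotype.CASE for m in metrics], dtype=bool
    )
    if is_case.all() or not is_case.any():
        raise ConfigurationError("burden test needs both cases and controls")

    cols = {
        "RATE": np.array([m.rate for m in metrics], dtype=float),
        "PROP": np.array([m.prop for m in metrics], dtype=float),
        "TOTKB": np.array([m.totkb for m in metrics], dtype=float),
        "AVGKB": np.array(
            [np.nan if m.avgkb is None else m.avgkb for m in metrics], dtype=float
        ),
    }

    observed = {}
    testable = {}
    for name, vals in cols.items():
        cmean, kmean = _group_means(vals, is_case)
        observed[name] = (cmean, kmean, cmean - kmean)
        testable[name] = math.isfinite(cmean) and math.isfinite(kmean)

    rng = np.random.default_rng(config.seed)
    exceed = {name: 0 for name in cols}
    n = len(metrics)
    for _ in range(config.n_perm):
        perm_case = np.zeros(n, dtype=bool)
        perm_case[rng.permutation(n)[: int(is_case.sum())]] = True
        for name, vals in cols.items():
            if not testable[name]:
                continue
            cmean, kmean = _group_means(vals, perm_case)
            stat = cmean - kmean
            if not math.isfinite(stat):
                continue  # a permutation with no AVGKB-eligible sample in a group
            obs = observed[name][2]
            if config.alternative == "case_greater":
                if stat >= obs:
                    exceed[name] += 1
            else:
                if abs(stat) >= abs(obs):
                    exceed[name] += 1

    rows = []
    for name in METRICS:
        cmean, kmean, stat = observed[name]
        rows.append(
            {
                "metric": name,
                "case_mean": cmean,
                "control_mean": kmean,
                "statistic": stat,
                "empirical_p": (1 + exceed[name]) / (config.n_perm + 1)
                if testable[name]
                else np.nan,
                "n_perm": config.n_perm,
                "testable": testable[name],
            }
        )
    return pd.DataFrame(rows)
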