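"""Common-CNV identification in a reference control subset and rare filtering.

Two different overlap measures are used on purpose, mirroring the tools the
analysis is modelled on:

* discovery of common CNVs counts, for each reference CNV, the reference
  CNVs of the same type whose **union-intersection** overlap (|A∩B|/|A∪B|)
  reaches the threshold — a symmetric criterion;
* removal of common variants from cases and remaining controls uses
  **query-fraction** overlap: a call is dropped when a common CNV of the
  same type covers at least the threshold fraction of the call's own
  length (asymmetric, per-pair).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .models import CnvCall, CnvType, CohortTable, Phenotype

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RareConfig:
    overlap_threshold: float = 0.5        # union-intersection, discovery
    common_min_count: int = 4
    reference_size: int = 200
    reference_ids: Optional[frozenset[str]] = None
    query_overlap_threshold: float = 0.5  # query-fraction, removal

    def __post_init__(self) -> None:
        for name, t in (
            ("overlap_threshold", self.overlap_threshold),
            ("query_overlap_threshold", self.query_overlap_threshold),
        ):
            if not 0 < t <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if self.common_min_count < 1:
            raise ConfigurationError("common_min_count must be >= 1")


@dataclass(frozen=True)
class CommonCnv:
    """A reference CNV classified as common, with its overlap count."""

    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def union_overlap_fraction(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for two 1-based inclusive intervals.

    Accepts any objects with ``chrom``/``start``/``end``; returns 0 for
    different chromosomes or disjoint intervals.  Symmetric by construction.
    """
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    len_a = a.end - a.start + 1
    len_b = b.end - b.start + 1
    return inter / (len_a + len_b - inter)


def query_fraction(query, other) -> float:
    """Fraction of ``query``'s own length covered by ``other`` (asymmetric)."""
    if query.chrom != other.chrom:
        return 0.0
    inter = min(query.end, other.end) - max(query.start, other.start) + 1
    if inter <= 0:
        return 0.0
    return inter / (query.end - query.start + 1)


def overlap_counts(calls: Sequence[CnvCall], threshold: float = 0.5) -> list[int]:
    """Per-call count of calls (self included) with union-intersection
    overlap >= threshold.

    ``calls`` must all be of one cnv_type (counting never crosses DEL/DUP).
    Returns counts aligned with the input order; every count is >= 1.
    """
    types = {c.cnv_type for c in calls}
    if len(types) > 1:
        raise ConfigurationError("overlap_counts requires calls of a single cnv_type")
    n = len(calls)
    counts = [1] * n  # self-overlap
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(calls):
        by_chrom.setdefault(c.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: (calls[i].start, calls[i].end))
        for pos, i in enumerate(idxs):
            a = calls[i]
            for j in idxs[pos + 1:]:
                b = calls[j]
                if b.start > a.end:  # sorted by start: no later call intersects a
                    break
                if union_overlap_fraction(a, b) >= threshold:
                    counts[i] += 1
                    counts[j] += 1
    return counts


def select_reference_controls(
    cohort: CohortTable, config: RareConfig, seed: int = 0
) -> set[str]:
    """Reference control subset: the explicit id list when given, otherwise a
    seeded uniform sample of ``reference_size`` controls."""
    controls = cohort.control_ids
    if config.reference_ids is not None:
        unknown = sorted(set(config.reference_ids) - set(controls))
        if unknown:
            raise ConfigurationError(
                f"reference ids not found among controls: {', '.join(unknown)}"
            )
        return set(config.reference_ids)
    if config.reference_size > len(controls):
        raise ConfigurationError(
            f"reference_size {config.reference_size} exceeds the control pool "
            f"({len(controls)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(controls), size=config.reference_size, replace=False)
    ids = {controls[i] for i in chosen}
    logger.info("sampled %d reference controls (seed=%d)", len(ids), seed)
    return ids


def identify_common(
    reference_calls: Sequence[CnvCall], config: RareConfig | None = None
) -> list[CommonCnv]:
    """Classify reference CNVs as common when their within-type overlap count
    reaches ``common_min_count``."""
    config = config or RareConfig()
    common: list[CommonCnv] = []
    for cnv_type in (CnvType.DEL, CnvType.DUP):
        typed = [c for c in reference_calls if c.cnv_type is cnv_type]
        counts = overlap_counts(typed, config.overlap_threshold)
        for c, k in zip(typed, counts):
            if k >= config.common_min_count:
                common.append(
                    CommonCnv(chrom=c.chrom, start=c.start, end=c.end,
                              cnv_type=cnv_type, count=k)
                )
    return common


def filter_rare(
    calls: Sequence[CnvCall],
    common_set: Sequence[CommonCnv],
    cohort: CohortTable,
    config: RareConfig | None = None,
) -> tuple[list[CnvCall], list[CnvCall], CohortTable]:
    """Remove common variants and the reference controls themselves.

    Returns ``(rare_calls, removed_calls, cohort')`` where ``cohort'`` is the
    cohort minus reference controls and both call lists are restricted to
    ``cohort'``.  A call is removed when some common CNV of the same type
    covers at least ``query_overlap_threshold`` of the call's length
    (per-pair coverage, not merged-union).
    """
    config = config or RareConfig()
    cohort2 = cohort.drop_reference_controls()
    keep_samples = set(cohort2.sample_ids)
    by_type_chrom: dict[tuple[CnvType, str], list[CommonCnv]] = {}
    for cc in common_set:
        by_type_chrom.setdefault((cc.cnv_type, cc.chrom), []).append(cc)
    rare: list[CnvCall] = []
    removed: list[CnvCall] = []
    for c in calls:
        if c.sample_id not in keep_samples:
            continue
        commons = by_type_chrom.get((c.cnv_type, c.chrom), ())
        if any(query_fraction(c, cc) >= config.query_overlap_threshold for cc in commons):
            removed.append(c)
        else:
            rare.append(c)
    return rare, removed, cohort2


def carrier_frequency_table(
    rare_calls: Sequence[CnvCall],
    cohort: CohortTable,
    overlap_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-CNV overlap count and carrier frequency within the post-filter
    cohort; feeds the frequency-histogram quality check."""
    if len(cohort) == 0:
        raise ConfigurationError("empty cohort")
    rows = []
    for cnv_type in (CnvType.DEL, CnvType.DUP):
        typed = [c for c in rare_calls if c.cnv_type is cnv_type]
        counts = overlap_counts(typed, overlap_threshold)
        for c, k in zip(typed, counts):
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "cnv_type": cnv_type.value,
                    "count": k,
                    "frequency": k / len(cohort),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "cnv_type", "count", "frequency"],
    )
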