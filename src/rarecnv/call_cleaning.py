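"""Removal of calls in spurious genomic regions and merging of adjacent calls.

Region exclusion drops whole calls that touch HLA / immunoglobulin /
centromere / telomere intervals (or, in ``query_fraction`` mode, calls whose
own length is covered beyond a threshold by the union of regions).

Adjacent-call merging counteracts the tendency of callers to split large
CNVs: two consecutive same-sample, same-chromosome (and by default same
copy-number) calls are combined when the gap between them is small relative
to the span of the would-be merged call, ``gap / span <= fraction``.  Each
configured fraction is applied as its own pass, iterated to a fixpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError
from .models import CnvCall, GenomicRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeConfig:
    fractions: tuple[float, ...] = (0.5, 0.4)
    require_same_state: bool = True

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ConfigurationError("MergeConfig.fractions must be non-empty")
        for f in self.fractions:
            if not 0 < f < 1:
                raise ConfigurationError(f"merge fraction {f} outside (0,1)")


def _covered_bp(call: CnvCall, regions: Sequence[GenomicRegion]) -> int:
    """Base pairs of `call` covered by the union of `regions` (same chrom)."""
    ivals = sorted(
        (max(call.start, r.start), min(call.end, r.end))
        for r in regions
        if r.chrom == call.chrom and r.start <= call.end and r.end >= call.start
    )
    covered = 0
    cur_start = cur_end = None
    for s, e in ivals:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered


def exclude_regions(
    calls: Sequence[CnvCall],
    regions: Sequence[GenomicRegion],
    min_overlap_fraction: float = 0.5,
    mode: str = "any_overlap",
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Partition calls into (kept, removed) by overlap with spurious regions.

    ``any_overlap``: a single shared base pair removes the call.
    ``query_fraction``: the call is removed when the union of regions covers
    at least ``min_overlap_fraction`` of its own length.
    """
    if mode not in ("any_overlap", "query_fraction"):
        raise ConfigurationError(f"unknown exclusion mode {mode!r}")
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    kept: list[CnvCall] = []
    removed: list[CnvCall] = []
    for c in calls:
        chrom_regions = by_chrom.get(c.chrom, ())
        covered = _covered_bp(c, chrom_regions)
        if mode == "any_overlap":
            drop = covered >= 1
        else:
            drop = covered / c.length >= min_overlap_fraction
        (removed if drop else kept).append(c)
    return kept, removed


def _merge_pass(group: list[CnvCall], fraction: float) -> list[CnvCall]:
    """One left-to-right merging sweep over a sorted same-group call list."""
    out: list[CnvCall] = []
    cur = group[0]
    for nxt in group[1:]:
        gap = nxt.start - cur.end - 1
        span = max(cur.end, nxt.end) - cur.start + 1
        if gap / span <= fraction:
            cur = CnvCall(
                sample_id=cur.sample_id,
                chrom=cur.chrom,
                start=cur.start,
                end=max(cur.end, nxt.end),
                cn=cur.cn,
                num_snps=cur.num_snps + nxt.num_snps,
                conf=(
                    None
                    if cur.conf is None and nxt.conf is None
                    else max(v for v in (cur.conf, nxt.conf) if v is not None)
                ),
            )
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


def merge_adjacent(
    calls: Sequence[CnvCall], config: MergeConfig | None = None
) -> list[CnvCall]:
    """Merge artificially split adjacent calls.

    Calls are grouped by (sample, chrom) plus copy number when
    ``require_same_state``; within each group, consecutive pairs with
    ``gap/span <= fraction`` are combined (coordinates unioned, probe counts
    summed, confidence = max) and each fraction's pass iterates to a
    fixpoint.  The output is sorted; the call count never increases and no
    covered base is lost.
    """
    config = config or MergeConfig()
    groups: dict[tuple, list[CnvCall]] = {}
    for c in calls:
        key = (c.sample_id, c.chrom, c.cn) if config.require_same_state else (
            c.sample_id, c.chrom)
        groups.setdefault(key, []).append(c)
    merged: list[CnvCall] = []
    for key, group in groups.items():
        ordered = sorted(group, key=lambda c: (c.start, c.end))
        if ordered != group:
            logger.info("merge_adjacent: group %s was unsorted; sorted internally", key)
        for fraction in config.fractions:
            while True:
                new = _merge_pass(ordered, fraction)
                if len(new) == len(ordered):
                    break
                ordered = new
        merged.extend(ordered)
    merged.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return merged
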