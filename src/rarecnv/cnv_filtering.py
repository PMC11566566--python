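"""Core-sample retention and size/probe-count filtering.

"Larger than 50 kb" and "more than 5 probes" are strict inequalities: a
50,000 bp call or a 5-probe call is removed.  Boundary-case removals are
logged so counts can be reconciled against non-strict implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .models import CnvCall, CohortTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CnvFilterConfig:
    min_length_bp: int = 50_000   # exclusive
    min_probes: int = 5           # exclusive
    core_sample_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0:
            raise ConfigurationError("min_length_bp must be > 0")
        if self.min_probes < 0:
            raise ConfigurationError("min_probes must be >= 0")


def retain_core_samples(
    calls: Sequence[CnvCall], cohort: CohortTable, core_ids: Iterable[str]
) -> tuple[list[CnvCall], CohortTable]:
    """Restrict cohort and calls to the core (unrelated, unstratified) samples.

    Zero-CNV core samples stay in the cohort — they are needed as
    denominators downstream.  Core ids absent from the cohort are warned
    about; an empty intersection is an error.
    """
    core = set(core_ids)
    unknown = sorted(core - set(cohort.sample_ids))
    if unknown:
        logger.warning(
            "%d core ids absent from the cohort: %s", len(unknown), ", ".join(unknown)
        )
    keep = core & set(cohort.sample_ids)
    if not keep:
        raise ConfigurationError("no core sample id matches the cohort")
    cohort_core = cohort.subset(keep)
    calls_core = [c for c in calls if c.sample_id in keep]
    return calls_core, cohort_core


def filter_by_size_probes(
    calls: Sequence[CnvCall], config: CnvFilterConfig | None = None
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Keep calls with length > min_length_bp AND num_snps > min_probes."""
    config = config or CnvFilterConfig()
    kept: list[CnvCall] = []
    removed: list[CnvCall] = []
    for c in calls:
        if c.length > config.min_length_bp and c.num_snps > config.min_probes:
            kept.append(c)
        else:
            if c.length == config.min_length_bp or c.num_snps == config.min_probes:
                logger.info(
                    "boundary removal: %s:%d-%d length=%d num_snps=%d",
                    c.chrom, c.start, c.end, c.length, c.num_snps,
                )
            removed.append(c)
    return kept, removed
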