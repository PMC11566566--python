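"""Core domain types shared by all pipeline stages.

Coordinates are 1-based and inclusive throughout the package (the PennCNV /
Plink convention); BED input is converted at the I/O boundary.  Chromosome
names are stored without a ``chr`` prefix, with X/Y/MT uppercased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional


class CnvType(str, Enum):
    """Deletion (copy number below 2) or duplication (above 2)."""

    DEL = "DEL"
    DUP = "DUP"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and uppercase X/Y/MT names."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y", "mt", "m"):
        c = c.upper()
    return c


def cnv_type_from_cn(cn: int) -> CnvType:
    if cn == 2:
        raise ValueError("copy number 2 is diploid, not a CNV")
    return CnvType.DEL if cn < 2 else CnvType.DUP


@dataclass(frozen=True)
class CnvCall:
    """One called copy-number segment in one sample.

    ``start``/``end`` are 1-based inclusive base-pair positions; ``length``
    is always derived from the coordinates, never taken from a file field.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    num_snps: int
    conf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start > end)"
            )
        if self.cn == 2:
            raise ValueError(f"call {self.chrom}:{self.start}-{self.end} has cn=2")
        if self.num_snps <= 0:
            raise ValueError("num_snps must be positive")

    @property
    def cnv_type(self) -> CnvType:
        return cnv_type_from_cn(self.cn)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return self.length / 1000.0


@dataclass(frozen=True)
class SampleQcRecord:
    """Per-sample signal-quality metrics and call count.

    Optional metrics are ``None`` when absent from the input table; they are
    never silently filled with zero.
    """

    sample_id: str
    lrr_mean: Optional[float] = None
    lrr_median: Optional[float] = None
    lrr_sd: Optional[float] = None
    baf_mean: Optional[float] = None
    baf_median: Optional[float] = None
    baf_sd: Optional[float] = None
    baf_drift: Optional[float] = None
    wf: Optional[float] = None
    num_cnv: Optional[int] = None


@dataclass(frozen=True)
class GenomicRegion:
    """A labeled genomic interval (1-based inclusive after normalization)."""

    chrom: str
    start: int
    end: int
    label: str = "region"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} (start > end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRecord:
    """A gene with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"invalid gene interval for {self.gene_id}")


class Phenotype(str, Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class CohortRecord:
    sample_id: str
    phenotype: Phenotype
    is_core: bool = False
    is_reference_control: bool = False

    def __post_init__(self) -> None:
        if self.is_reference_control and self.phenotype is not Phenotype.CONTROL:
            raise ValueError(
                f"sample {self.sample_id}: reference-control flag on a non-control"
            )


class CohortTable:
    """Sample -> phenotype mapping with core / reference-control subsets.

    Sample ids are unique; iteration order is insertion order.
    """

    def __init__(self, records: Iterable[CohortRecord]):
        self._records: dict[str, CohortRecord] = {}
        for rec in records:
            if rec.sample_id in self._records:
                raise ValueError(f"duplicate sample_id {rec.sample_id!r} in cohort")
            self._records[rec.sample_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CohortRecord]:
        return iter(self._records.values())

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._records

    def __getitem__(self, sample_id: str) -> CohortRecord:
        return self._records[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self._records)

    @property
    def case_ids(self) -> list[str]:
        return [r.sample_id for r in self if r.phenotype is Phenotype.CASE]

    @property
    def control_ids(self) -> list[str]:
        return [r.sample_id for r in self if r.phenotype is Phenotype.CONTROL]

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)

    def subset(self, sample_ids: Iterable[str]) -> "CohortTable":
        wanted = set(sample_ids)
        return CohortTable(r for r in self if r.sample_id in wanted)

    def with_flags(
        self,
        core_ids: Optional[Iterable[str]] = None,
        reference_ids: Optional[Iterable[str]] = None,
    ) -> "CohortTable":
        """Return a copy with core / reference-control flags set from id lists."""
        core = set(core_ids) if core_ids is not None else None
        ref = set(reference_ids) if reference_ids is not None else None
        out = []
        for r in self:
            out.append(
                CohortRecord(
                    sample_id=r.sample_id,
                    phenotype=r.phenotype,
                    is_core=(r.sample_id in core) if core is not None else r.is_core,
                    is_reference_control=(r.sample_id in ref)
                    if ref is not None
                    else r.is_reference_control,
                )
            )
        return CohortTable(out)

    def drop_reference_controls(self) -> "CohortTable":
        return CohortTable(r for r in self if not r.is_reference_control)
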