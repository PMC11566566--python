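"""Synthetic cohort generator.

Produces every input the pipeline consumes — per-call rawcnv file, QC
summary table, FAM phenotypes, exclusion-region and gene BED files, core-id
list — together with a truth table recording each planted variant and QC
failure, all reproducibly from a single seed.

Statistical structure:

* background CNVs per sample ~ Poisson(background_rate), placed uniformly
  on the genome with log-uniform lengths;
* common loci and planted case/control effects are Bernoulli carrier draws
  per sample; carrier intervals get positional jitter bounded to 10% of the
  locus length, so any two carriers keep union-intersection overlap
  >= 0.9/1.1 > 0.5 and planted common loci always satisfy the discovery
  criterion;
* QC metrics are drawn from comfortably passing distributions; a configured
  fraction of samples is pushed past exactly one threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .models import (
    CnvCall,
    CnvType,
    CohortRecord,
    CohortTable,
    GeneRecord,
    GenomicRegion,
    Phenotype,
    SampleQcRecord,
)
from . import io_formats

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PlantedLocus:
    """A locus whose carriers are drawn per sample.

    For common loci set ``case_carrier_freq == control_carrier_freq``; for
    planted effects make them differ.
    """

    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    case_carrier_freq: float
    control_carrier_freq: float
    name: str = "locus"

    def __post_init__(self) -> None:
        for f in (self.case_carrier_freq, self.control_carrier_freq):
            if not 0 <= f <= 1:
                raise ConfigurationError("carrier frequencies must be in [0,1]")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_cases: int = 100
    n_controls: int = 300
    seed: int = 0
    background_rate: float = 2.0          # mean CNVs per sample (Poisson)
    length_dist_kb: tuple[float, float] = (20.0, 2000.0)  # log-uniform bounds
    del_fraction: float = 0.5
    common_loci: tuple[PlantedLocus, ...] = ()
    planted_effects: tuple[PlantedLocus, ...] = ()
    qc_fail_fraction: float = 0.0
    genome: tuple[tuple[str, int], ...] = (("1", 50_000_000), ("2", 40_000_000))
    probe_spacing_bp: int = 2_000
    non_core_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.genome:
            raise ConfigurationError("genome must be non-empty")
        chrom_len = dict(self.genome)
        for locus in self.common_loci + self.planted_effects:
            if locus.chrom not in chrom_len or locus.end > chrom_len[locus.chrom]:
                raise ConfigurationError(
                    f"planted locus {locus.name} outside the genome"
                )


@dataclass
class SyntheticCohort:
    """In-memory generated data plus the planted truth."""

    calls: list[CnvCall]
    qc_records: list[SampleQcRecord]
    cohort: CohortTable
    regions: list[GenomicRegion]
    genes: list[GeneRecord]
    core_ids: set[str]
    truth: pd.DataFrame


_QC_FAIL_MODES = ("LRR_SD", "BAF_drift", "WF")


def _jitter_locus(locus: PlantedLocus, chrom_len: int, rng: np.random.Generator):
    # shift bounded to +-5% of the locus length: carriers keep >=0.5 overlap
    length = locus.end - locus.start + 1
    shift = int(rng.integers(-length // 20, length // 20 + 1))
    start = max(1, locus.start + shift)
    end = min(chrom_len, start + length - 1)
    return start, end


def _default_regions(genome: Sequence[tuple[str, int]]) -> list[GenomicRegion]:
    regions: list[GenomicRegion] = []
    for i, (chrom, length) in enumerate(genome):
        telo = min(50_000, length // 100)
        regions.append(GenomicRegion(chrom, 1, telo, "telomere"))
        regions.append(GenomicRegion(chrom, length - telo + 1, length, "telomere"))
        mid = length // 2
        regions.append(GenomicRegion(chrom, mid - 500_000, mid + 500_000, "centromere"))
        if i == 0:
            regions.append(
                GenomicRegion(chrom, length // 4, length // 4 + 3_000_000, "HLA")
            )
    return regions


def _default_genes(
    genome: Sequence[tuple[str, int]], rng: np.random.Generator, n_genes: int = 200
) -> list[GeneRecord]:
    lengths = np.array([l for _, l in genome], dtype=float)
    probs = lengths / lengths.sum()
    genes = []
    for i in range(n_genes):
        k = int(rng.choice(len(genome), p=probs))
        chrom, clen = genome[k]
        glen = int(rng.integers(10_000, 200_000))
        start = int(rng.integers(1, max(2, clen - glen)))
        genes.append(GeneRecord(f"G{i + 1:04d}", chrom, start, start + glen - 1))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def generate_cohort(
    spec: SyntheticCohortSpec, out_dir: Optional[PathLike] = None
) -> SyntheticCohort:
    """Generate a complete synthetic cohort; optionally write all input files.

    When ``out_dir`` is given the following files are written there:
    ``cohort.rawcnv``, ``cohort.qcsum``, ``cohort.fam``, ``regions.bed``,
    ``genes.bed``, ``core_ids.txt``, ``truth.tsv``.  Output is byte-identical
    for a given spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    chrom_len = dict(spec.genome)
    chroms = [c for c, _ in spec.genome]
    lengths = np.array([l for _, l in spec.genome], dtype=float)
    chrom_probs = lengths / lengths.sum()

    sample_ids = [f"CASE{i + 1:05d}" for i in range(spec.n_cases)] + [
        f"CTRL{i + 1:05d}" for i in range(spec.n_controls)
    ]
    phenotypes = [Phenotype.CASE] * spec.n_cases + [Phenotype.CONTROL] * spec.n_controls

    calls: list[CnvCall] = []
    truth_rows: list[dict] = []
    lo_kb, hi_kb = spec.length_dist_kb

    for sid, pheno in zip(sample_ids, phenotypes):
        n_bg = int(rng.poisson(spec.background_rate))
        for _ in range(n_bg):
            k = int(rng.choice(len(chroms), p=chrom_probs))
            chrom = chroms[k]
            length = int(
                round(1000 * math.exp(rng.uniform(math.log(lo_kb), math.log(hi_kb))))
            )
            length = min(length, chrom_len[chrom] - 1)
            start = int(rng.integers(1, chrom_len[chrom] - length + 1))
            cn = 1 if rng.random() < spec.del_fraction else 3
            num_snps = max(1, math.ceil(length / spec.probe_spacing_bp))
            calls.append(
                CnvCall(sid, chrom, start, start + length - 1, cn, num_snps,
                        conf=round(float(rng.uniform(10, 100)), 3))
            )
        for kind, loci in (("common", spec.common_loci), ("effect", spec.planted_effects)):
            for locus in loci:
                freq = (
                    locus.case_carrier_freq
                    if pheno is Phenotype.CASE
                    else locus.control_carrier_freq
                )
                if rng.random() >= freq:
                    continue
                start, end = _jitter_locus(locus, chrom_len[locus.chrom], rng)
                cn = 1 if locus.cnv_type is CnvType.DEL else 3
                num_snps = max(1, math.ceil((end - start + 1) / spec.probe_spacing_bp))
                calls.append(
                    CnvCall(sid, locus.chrom, start, end, cn, num_snps,
                            conf=round(float(rng.uniform(10, 100)), 3))
                )
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "kind": kind,
                        "locus": locus.name,
                        "chrom": locus.chrom,
                        "start": start,
                        "end": end,
                        "cnv_type": locus.cnv_type.value,
                    }
                )

    # QC metrics: pass-region draws, then push the chosen failers past
    # exactly one threshold each
    n = len(sample_ids)
    n_fail = int(rng.binomial(n, spec.qc_fail_fraction)) if spec.qc_fail_fraction else 0
    fail_idx = set(rng.choice(n, size=n_fail, replace=False).tolist()) if n_fail else set()
    call_counts: dict[str, int] = {}
    for c in calls:
        call_counts[c.sample_id] = call_counts.get(c.sample_id, 0) + 1

    qc_records: list[SampleQcRecord] = []
    for i, sid in enumerate(sample_ids):
        lrr_sd = float(rng.uniform(0.08, 0.25))
        baf_drift = float(rng.uniform(0.0, 0.008))
        wf = float(rng.uniform(-0.04, 0.04))
        fail_mode = None
        if i in fail_idx:
            fail_mode = _QC_FAIL_MODES[int(rng.integers(len(_QC_FAIL_MODES)))]
            if fail_mode == "LRR_SD":
                lrr_sd = float(rng.uniform(0.31, 0.5))
            elif fail_mode == "BAF_drift":
                baf_drift = float(rng.uniform(0.011, 0.03))
            else:
                wf = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.051, 0.1))
            truth_rows.append(
                {"sample_id": sid, "kind": "qc_fail", "locus": fail_mode,
                 "chrom": "", "start": 0, "end": 0, "cnv_type": ""}
            )
        qc_records.append(
            SampleQcRecord(
                sample_id=sid,
                lrr_mean=round(float(rng.normal(0.0, 0.02)), 6),
                lrr_median=round(float(rng.normal(0.0, 0.02)), 6),
                lrr_sd=round(lrr_sd, 6),
                baf_mean=round(float(rng.normal(0.5, 0.01)), 6),
                baf_median=round(float(rng.normal(0.5, 0.01)), 6),
                baf_sd=round(float(rng.uniform(0.02, 0.05)), 6),
                baf_drift=round(baf_drift, 6),
                wf=round(wf, 6),
                num_cnv=call_counts.get(sid, 0),
            )
        )

    n_non_core = int(round(spec.non_core_fraction * n))
    non_core = (
        set(rng.choice(n, size=n_non_core, replace=False).tolist())
        if n_non_core
        else set()
    )
    core_ids = {sid for i, sid in enumerate(sample_ids) if i not in non_core}

    cohort = CohortTable(
        CohortRecord(sample_id=sid, phenotype=pheno, is_core=sid in core_ids)
        for sid, pheno in zip(sample_ids, phenotypes)
    )
    regions = _default_regions(spec.genome)
    genes = _default_genes(spec.genome, rng)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "kind", "locus", "chrom", "start", "end", "cnv_type"],
    )

    data = SyntheticCohort(
        calls=calls, qc_records=qc_records, cohort=cohort,
        regions=regions, genes=genes, core_ids=core_ids, truth=truth,
    )
    if out_dir is not None:
        write_cohort_files(data, out_dir)
    return data


def write_cohort_files(data: SyntheticCohort, out_dir: PathLike) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "rawcnv": out / "cohort.rawcnv",
        "qcsum": out / "cohort.qcsum",
        "fam": out / "cohort.fam",
        "regions": out / "regions.bed",
        "genes": out / "genes.bed",
        "core_ids": out / "core_ids.txt",
        "truth": out / "truth.tsv",
    }
    io_formats.write_rawcnv(data.calls, paths["rawcnv"])
    io_formats.write_qc_summary(data.qc_records, paths["qcsum"])
    with paths["fam"].open("w") as fh:
        for r in data.cohort:
            pheno = 2 if r.phenotype is Phenotype.CASE else 1
            fh.write(f"{r.sample_id} {r.sample_id} 0 0 0 {pheno}\n")
    io_formats.write_bed_regions(data.regions, paths["regions"])
    with paths["genes"].open("w") as fh:
        for g in data.genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
    with paths["core_ids"].open("w") as fh:
        for sid in sorted(data.core_ids):
            fh.write(sid + "\n")
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
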