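"""Readers and writers for every external format the pipeline touches.

Supported formats
-----------------
* PennCNV ``.rawcnv`` per-call text files (read/write)
* PennCNV-style QC summary tables, TSV with a header (read)
* Plink CNV-list ``.cnv`` / ``.fam`` pairs (read/write)
* BED3/BED4 region and gene files (read)
* plain-text id / gene-set lists (read)

All coordinates are normalized to the internal 1-based inclusive convention
on read; BED's 0-based half-open coordinates are shifted at this boundary.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import ConfigurationError, ParseError
from .models import (
    CnvCall,
    CohortRecord,
    CohortTable,
    GeneRecord,
    GenomicRegion,
    Phenotype,
    SampleQcRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_RAWCNV_REGION = re.compile(r"^(?P<chrom>[^:]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def _int_field(text: str) -> int:
    # PennCNV writes large numbers with thousands separators (length=1,023,456)
    return int(text.replace(",", ""))


def read_rawcnv(path: PathLike, dialect: str = "penncnv") -> list[CnvCall]:
    """Parse a PennCNV ``.rawcnv`` file into a list of :class:`CnvCall`.

    Lines look like::

        chr1:100001-200000 numsnp=55 length=100,000 state2,cn=1 S001 startsnp=rs1 endsnp=rs2 conf=15.1

    The declared ``length=`` field is cross-checked against the coordinates;
    on mismatch the coordinates win and a warning is logged.  Records with
    cn=2 are rejected.
    """
    if dialect != "penncnv":
        raise ConfigurationError(f"unknown rawcnv dialect {dialect!r}")
    path = Path(path)
    calls: list[CnvCall] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 fields, got {len(fields)}")
            m = _RAWCNV_REGION.match(fields[0])
            if m is None:
                raise ParseError(f"{path}:{lineno}: malformed region {fields[0]!r}")
            chrom = normalize_chrom(m.group("chrom"))
            start = _int_field(m.group("start"))
            end = _int_field(m.group("end"))
            kv = {}
            sample_id: Optional[str] = None
            cn: Optional[int] = None
            for tok in fields[1:]:
                if "cn=" in tok:  # "state2,cn=1"
                    try:
                        cn = int(tok.split("cn=")[1])
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: bad state/cn token {tok!r}") from exc
                elif "=" in tok:
                    key, _, val = tok.partition("=")
                    kv[key] = val
                elif sample_id is None:
                    sample_id = tok
            if sample_id is None or cn is None or "numsnp" not in kv:
                raise ParseError(f"{path}:{lineno}: missing sample, cn or numsnp field")
            if cn == 2:
                raise ParseError(f"{path}:{lineno}: record with cn=2 is not a CNV call")
            try:
                num_snps = _int_field(kv["numsnp"])
                conf = float(kv["conf"]) if "conf" in kv else None
                declared_length = _int_field(kv["length"]) if "length" in kv else None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            if start > end:
                raise ParseError(f"{path}:{lineno}: start > end in {fields[0]!r}")
            if declared_length is not None and declared_length != end - start + 1:
                logger.warning(
                    "%s:%d: declared length=%d != end-start+1=%d; coordinates win",
                    path, lineno, declared_length, end - start + 1,
                )
            calls.append(
                CnvCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cn=cn,
                    num_snps=num_snps,
                    conf=conf,
                )
            )
    return calls


def write_rawcnv(calls: Iterable[CnvCall], path: PathLike) -> None:
    """Write calls back out in the rawcnv dialect (no thousands separators)."""
    path = Path(path)
    with path.open("w") as fh:
        for c in calls:
            state = {0: 1, 1: 2, 3: 5, 4: 6}.get(c.cn, 0)
            line = (
                f"chr{c.chrom}:{c.start}-{c.end} numsnp={c.num_snps} "
                f"length={c.length} state{state},cn={c.cn} {c.sample_id} "
                f"startsnp=. endsnp=."
            )
            if c.conf is not None:
                line += f" conf={c.conf:g}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# QC summary tables

_QC_MANDATORY = ("LRR_mean", "LRR_SD", "BAF_mean", "BAF_SD", "BAF_drift", "WF")
_QC_FIELD_MAP = {
    "LRR_mean": "lrr_mean",
    "LRR_median": "lrr_median",
    "LRR_SD": "lrr_sd",
    "BAF_mean": "baf_mean",
    "BAF_median": "baf_median",
    "BAF_SD": "baf_sd",
    "BAF_drift": "baf_drift",
    "WF": "wf",
}
_SAMPLE_COL_CANDIDATES = ("sample_id", "Sample", "sample", "File", "ID", "IID")


def read_qc_summary(
    path: PathLike,
    calls: Optional[Sequence[CnvCall]] = None,
    aliases: Optional[dict[str, str]] = None,
) -> list[SampleQcRecord]:
    """Read a PennCNV-style per-sample QC summary table (TSV with header).

    ``aliases`` maps canonical column names (``LRR_SD`` etc.) to the names
    used in the file.  ``NumCNV`` may be absent if ``calls`` is given, in
    which case per-sample call counts are recomputed from the call list.
    Optional ``LRR_median``/``BAF_median`` columns are accepted but not
    required; absent optional metrics stay ``None``.
    """
    path = Path(path)
    aliases = aliases or {}
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: empty QC summary file")
        header = header_line.rstrip("\n").split("\t")
        colidx = {name: i for i, name in enumerate(header)}

        def col(canonical: str) -> Optional[int]:
            return colidx.get(aliases.get(canonical, canonical))

        missing = [name for name in _QC_MANDATORY if col(name) is None]
        if missing:
            raise ConfigurationError(
                f"{path}: missing mandatory QC columns: {', '.join(missing)}"
            )
        sample_col = None
        for cand in _SAMPLE_COL_CANDIDATES:
            if aliases.get("sample_id", cand) in colidx or cand in colidx:
                sample_col = colidx.get(aliases.get("sample_id", cand), colidx.get(cand))
                break
        if sample_col is None:
            raise ConfigurationError(f"{path}: no sample id column found")
        numcnv_col = col("NumCNV")
        if numcnv_col is None and calls is None:
            raise ConfigurationError(
                f"{path}: NumCNV column absent and no call list provided to recompute it"
            )
        counts: dict[str, int] = {}
        if calls is not None:
            for c in calls:
                counts[c.sample_id] = counts.get(c.sample_id, 0) + 1

        records: list[SampleQcRecord] = []
        seen: set[str] = set()
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            sample_id = fields[sample_col]
            if sample_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicated sample_id {sample_id!r}")
            seen.add(sample_id)

            def fval(canonical: str) -> Optional[float]:
                i = col(canonical)
                if i is None or i >= len(fields) or fields[i] in ("", "NA"):
                    return None
                return float(fields[i])

            if numcnv_col is not None:
                num_cnv = int(float(fields[numcnv_col]))
            else:
                num_cnv = counts.get(sample_id, 0)
            records.append(
                SampleQcRecord(
                    sample_id=sample_id,
                    num_cnv=num_cnv,
                    **{attr: fval(name) for name, attr in _QC_FIELD_MAP.items()},
                )
            )
    if calls is not None and numcnv_col is not None:
        for rec in records:
            observed = counts.get(rec.sample_id, 0)
            if rec.num_cnv != observed:
                logger.warning(
                    "sample %s: NumCNV=%d in summary but %d calls in call file",
                    rec.sample_id, rec.num_cnv, observed,
                )
    return records


def write_qc_summary(records: Iterable[SampleQcRecord], path: PathLike) -> None:
    path = Path(path)
    cols = list(_QC_FIELD_MAP) + ["NumCNV"]
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(cols) + "\n")
        for r in records:
            vals = []
            for name in _QC_FIELD_MAP:
                v = getattr(r, _QC_FIELD_MAP[name])
                vals.append("NA" if v is None else f"{v:.6g}")
            vals.append("NA" if r.num_cnv is None else str(r.num_cnv))
            fh.write(r.sample_id + "\t" + "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# BED regions and gene maps

def read_bed_regions(path: PathLike, default_label: str = "region") -> list[GenomicRegion]:
    """Read BED3+ (0-based half-open) into 1-based inclusive regions."""
    path = Path(path)
    regions: list[GenomicRegion] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line with < 3 columns")
            try:
                bed_start, bed_end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if bed_start >= bed_end:
                raise ParseError(f"{path}:{lineno}: BED start >= end")
            label = fields[3] if len(fields) >= 4 else default_label
            regions.append(
                GenomicRegion(
                    chrom=normalize_chrom(fields[0]),
                    start=bed_start + 1,
                    end=bed_end,
                    label=label,
                )
            )
    return regions


def write_bed_regions(regions: Iterable[GenomicRegion], path: PathLike) -> None:
    """Write regions as BED4 (inverse of :func:`read_bed_regions`)."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def read_gene_map(path: PathLike, dialect: str = "bed") -> list[GeneRecord]:
    """Read a gene coordinate map.

    ``dialect='bed'``: BED4, 0-based half-open with gene id in column 4.
    ``dialect='table'``: 4 columns ``gene_id chrom start end``, 1-based inclusive.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: gene map line with < 4 columns")
            if dialect == "bed":
                gene_id = fields[3]
                chrom = normalize_chrom(fields[0])
                start, end = int(fields[1]) + 1, int(fields[2])
            elif dialect == "table":
                gene_id = fields[0]
                chrom = normalize_chrom(fields[1])
                start, end = int(fields[2]), int(fields[3])
            else:
                raise ConfigurationError(f"unknown gene map dialect {dialect!r}")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end))
    return genes


def read_gene_set(path: PathLike, gene_map: Optional[Sequence[GeneRecord]] = None) -> set[str]:
    """Read a one-id-per-line gene set; warn about ids absent from the map."""
    path = Path(path)
    ids: set[str] = set()
    with path.open() as fh:
        for raw in fh:
            gid = raw.strip()
            if gid and not gid.startswith("#"):
                ids.add(gid)
    if not ids:
        raise ConfigurationError(f"{path}: empty gene set (enrichment undefined)")
    if gene_map is not None:
        known = {g.gene_id for g in gene_map}
        missing = sorted(ids - known)
        if missing:
            logger.warning(
                "%s: %d gene-set members absent from the gene map: %s",
                path, len(missing), ", ".join(missing),
            )
    return ids


def read_id_list(path: PathLike) -> set[str]:
    """Plain-text sample-id list, one id per line."""
    with Path(path).open() as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# Plink CNV-list format

_CNV_HEADER = "FID IID CHR BP1 BP2 TYPE SCORE SITES"


def write_plink_cnv(
    calls: Sequence[CnvCall], cohort: CohortTable, path_prefix: PathLike
) -> tuple[Path, Path]:
    """Write a Plink ``.cnv``/``.fam`` pair.

    ``TYPE`` carries the copy number, ``SCORE`` the confidence (0 when
    absent), ``SITES`` the probe count.  FAM phenotype is 1 = control,
    2 = case, with FID = IID.
    """
    orphans = sorted({c.sample_id for c in calls} - set(cohort.sample_ids))
    if orphans:
        raise ConfigurationError(
            f"calls reference samples absent from the cohort: {', '.join(orphans)}"
        )
    prefix = Path(path_prefix)
    cnv_path = prefix.with_suffix(".cnv")
    fam_path = prefix.with_suffix(".fam")
    with cnv_path.open("w") as fh:
        fh.write(_CNV_HEADER + "\n")
        for c in calls:
            score = 0 if c.conf is None else c.conf
            fh.write(
                f"{c.sample_id} {c.sample_id} {c.chrom} {c.start} {c.end} "
                f"{c.cn} {score:g} {c.num_snps}\n"
            )
    with fam_path.open("w") as fh:
        for r in cohort:
            pheno = 2 if r.phenotype is Phenotype.CASE else 1
            fh.write(f"{r.sample_id} {r.sample_id} 0 0 0 {pheno}\n")
    return cnv_path, fam_path


def read_plink_cnv(path: PathLike) -> list[CnvCall]:
    """Read a Plink CNV-list ``.cnv`` file written by :func:`write_plink_cnv`."""
    path = Path(path)
    calls: list[CnvCall] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if fields[0] == "FID":  # header
                continue
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected 8 columns")
            calls.append(
                CnvCall(
                    sample_id=fields[1],
                    chrom=normalize_chrom(fields[2]),
                    start=int(fields[3]),
                    end=int(fields[4]),
                    cn=int(fields[5]),
                    num_snps=int(fields[7]),
                    conf=float(fields[6]) if float(fields[6]) != 0 else None,
                )
            )
    return calls


def read_fam(path: PathLike) -> CohortTable:
    """Read a Plink ``.fam`` file; phenotype 1 = control, 2 = case."""
    path = Path(path)
    records: list[CohortRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 FAM columns")
            code = fields[5]
            if code == "2":
                pheno = Phenotype.CASE
            elif code == "1":
                pheno = Phenotype.CONTROL
            else:
                raise ParseError(
                    f"{path}:{lineno}: unsupported phenotype code {code!r} (need 1/2)"
                )
            records.append(CohortRecord(sample_id=fields[1], phenotype=pheno))
    return CohortTable(records)
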