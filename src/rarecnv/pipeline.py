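"""End-to-end pipeline runner and cascade reporting.

The runner chains the stages qc -> clean -> merge -> filter -> burden ->
rare -> assoc -> enrich, writing one TSV per stage plus a Table-1-style
cascade report of samples/calls entering and leaving each stage.  Merging
can reduce the call count without losing calls; such rows carry a
"combined" note instead of counting the difference as lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import io_formats
from .association_stats import SizeBins, association_summary, summary_to_frame
from .burden import PermutationConfig, burden_test, per_sample_metrics
from .call_cleaning import MergeConfig, exclude_regions, merge_adjacent
from .cnv_filtering import CnvFilterConfig, filter_by_size_probes, retain_core_samples
from .enrichment import compute_covariates, enrichment_test
from .errors import ConfigurationError
from .models import CnvCall, CohortTable
from .rare_extraction import (
    RareConfig,
    carrier_frequency_table,
    filter_rare,
    identify_common,
    select_reference_controls,
)
from .sample_qc import QcThresholds, apply_sample_qc, drop_failed_samples, qc_summary_table

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

STAGES = ("qc", "clean", "filter", "burden", "rare", "assoc", "enrich")


@dataclass(frozen=True)
class CascadeRow:
    stage: str
    initial_samples: int
    final_samples: int
    lost_samples: int
    initial_calls: int
    final_calls: int
    lost_calls: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.final_samples != self.initial_samples - self.lost_samples:
            raise ValueError(f"{self.stage}: sample counts inconsistent")
        if not self.note and self.final_calls != self.initial_calls - self.lost_calls:
            raise ValueError(f"{self.stage}: call counts inconsistent")


@dataclass
class CascadeReport:
    rows: list[CascadeRow] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        row = CascadeRow(**kwargs)
        if self.rows:
            prev = self.rows[-1]
            if (
                row.initial_samples != prev.final_samples
                or row.initial_calls != prev.final_calls
            ):
                raise ValueError(
                    f"cascade broken at {row.stage}: initial counts do not match "
                    f"previous final counts"
                )
        self.rows.append(row)

    def validate(self) -> None:
        for prev, cur in zip(self.rows, self.rows[1:]):
            assert cur.initial_samples == prev.final_samples
            assert cur.initial_calls == prev.final_calls

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def write_tsv(self, path: PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def render(self) -> str:
        lines = [
            f"{'stage':<24}{'samples in':>11}{'out':>8}{'lost':>6}"
            f"{'calls in':>10}{'out':>8}{'lost':>6}  note"
        ]
        for r in self.rows:
            lines.append(
                f"{r.stage:<24}{r.initial_samples:>11}{r.final_samples:>8}"
                f"{r.lost_samples:>6}{r.initial_calls:>10}{r.final_calls:>8}"
                f"{r.lost_calls:>6}  {r.note}"
            )
        return "\n".join(lines)


@dataclass
class PipelineResult:
    report: CascadeReport
    outputs: dict[str, Path]


_INPUT_KEYS = ("rawcnv", "qcsum", "fam")
_OPTIONAL_FILES = ("regions", "genes", "gene_set", "core_ids", "reference_ids")


def run_pipeline(config: dict, out_dir: PathLike) -> PipelineResult:
    """Run the configured stages in order and write stage outputs + report.

    ``config`` keys (paths): rawcnv, qcsum, fam required; regions (list of
    BED paths), genes, gene_set, core_ids, reference_ids optional.
    Parameter keys: qc_thresholds, merge, filter, rare, bins, n_perm, seed,
    stages (prefix of the stage list to run).  Every input file is checked
    before any stage runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", STAGES))
    if tuple(STAGES[: len(stages)]) != stages:
        raise ConfigurationError(f"stages must be a prefix of {STAGES}")

    # fail fast: verify every referenced input exists before running anything
    missing = []
    for key in _INPUT_KEYS:
        if key not in config:
            missing.append(key)
        elif not Path(config[key]).exists():
            missing.append(str(config[key]))
    for key in _OPTIONAL_FILES:
        if key in config and config[key]:
            paths = config[key] if isinstance(config[key], (list, tuple)) else [config[key]]
            for p in paths:
                if not Path(p).exists():
                    missing.append(str(p))
    if missing:
        raise ConfigurationError(f"missing inputs: {', '.join(missing)}")

    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_perm", 10_000))
    thresholds = QcThresholds(**config.get("qc_thresholds", {}))
    merge_cfg = MergeConfig(**{
        k: tuple(v) if k == "fractions" else v
        for k, v in config.get("merge", {}).items()
    })
    filter_cfg = CnvFilterConfig(**config.get("filter", {}))
    rare_kwargs = dict(config.get("rare", {}))
    bins = SizeBins(tuple(config["bins"])) if "bins" in config else SizeBins()
    logger.info(
        "thresholds: qc=%s merge=%s filter=%s rare=%s n_perm=%d seed=%d",
        thresholds, merge_cfg, filter_cfg, rare_kwargs, n_perm, seed,
    )

    calls = io_formats.read_rawcnv(config["rawcnv"])
    cohort = io_formats.read_fam(config["fam"])
    qc_records = io_formats.read_qc_summary(config["qcsum"], calls=calls)

    report = CascadeReport()
    outputs: dict[str, Path] = {}
    n_samples = len(cohort)

    # --- qc -----------------------------------------------------------------
    decisions = apply_sample_qc(qc_records, thresholds)
    kept_calls, removed = drop_failed_samples(calls, decisions)
    passed_ids = {d.sample_id for d in decisions if d.passed}
    cohort = cohort.subset(set(cohort.sample_ids) & passed_ids)
    report.add(
        stage="sample_qc",
        initial_samples=n_samples, final_samples=len(cohort),
        lost_samples=n_samples - len(cohort),
        initial_calls=len(calls), final_calls=len(kept_calls),
        lost_calls=len(calls) - len(kept_calls),
    )
    pd.DataFrame(
        [{"sample_id": d.sample_id, "passed": d.passed,
          "failed_criteria": ",".join(d.failed_criteria)} for d in decisions]
    ).to_csv(out / "qc_decisions.tsv", sep="\t", index=False)
    outputs["qc_decisions"] = out / "qc_decisions.tsv"
    summary = qc_summary_table(qc_records, decisions, calls)
    summary["metric_summaries"].to_csv(out / "qc_metric_summaries.tsv", sep="\t", index=False)
    outputs["qc_metric_summaries"] = out / "qc_metric_summaries.tsv"
    calls = kept_calls

    if "clean" in stages:
        region_paths = config.get("regions", [])
        if isinstance(region_paths, (str, Path)):
            region_paths = [region_paths]
        removal_rows = []
        for rp in region_paths:
            regions = io_formats.read_bed_regions(Path(rp))
            kept_calls, removed = exclude_regions(calls, regions, mode=config.get(
                "region_mode", "any_overlap"))
            for c in removed:
                removal_rows.append(
                    {"sample_id": c.sample_id, "chrom": c.chrom, "start": c.start,
                     "end": c.end, "region_file": str(rp)}
                )
            report.add(
                stage=f"clean:{Path(rp).name}",
                initial_samples=len(cohort), final_samples=len(cohort), lost_samples=0,
                initial_calls=len(calls), final_calls=len(kept_calls),
                lost_calls=len(calls) - len(kept_calls),
            )
            calls = kept_calls
        pd.DataFrame(
            removal_rows,
            columns=["sample_id", "chrom", "start", "end", "region_file"],
        ).to_csv(out / "region_removals.tsv", sep="\t", index=False)
        outputs["region_removals"] = out / "region_removals.tsv"
        merged = merge_adjacent(calls, merge_cfg)
        report.add(
            stage="merge_adjacent",
            initial_samples=len(cohort), final_samples=len(cohort), lost_samples=0,
            initial_calls=len(calls), final_calls=len(merged), lost_calls=0,
            note=f"{len(calls) - len(merged)} calls combined, none lost",
        )
        calls = merged
        io_formats.write_rawcnv(calls, out / "clean.rawcnv")
        outputs["clean_rawcnv"] = out / "clean.rawcnv"

    if "filter" in stages:
        if config.get("core_ids"):
            core = io_formats.read_id_list(config["core_ids"])
            n0, c0 = len(cohort), len(calls)
            calls, cohort = retain_core_samples(calls, cohort, core)
            report.add(
                stage="retain_core",
                initial_samples=n0, final_samples=len(cohort),
                lost_samples=n0 - len(cohort),
                initial_calls=c0, final_calls=len(calls), lost_calls=c0 - len(calls),
            )
        kept_calls, removed = filter_by_size_probes(calls, filter_cfg)
        report.add(
            stage="size_probe_filter",
            initial_samples=len(cohort), final_samples=len(cohort), lost_samples=0,
            initial_calls=len(calls), final_calls=len(kept_calls),
            lost_calls=len(removed),
        )
        calls = kept_calls
        io_formats.write_plink_cnv(calls, cohort, out / "filtered")
        outputs["filtered_cnv"] = out / "filtered.cnv"

    if "burden" in stages:
        metrics = per_sample_metrics(calls, cohort)
        bt = burden_test(metrics, cohort, PermutationConfig(n_perm=n_perm, seed=seed))
        bt.to_csv(out / "burden.tsv", sep="\t", index=False)
        outputs["burden"] = out / "burden.tsv"
        report.add(
            stage="burden",
            initial_samples=len(cohort), final_samples=len(cohort), lost_samples=0,
            initial_calls=len(calls), final_calls=len(calls), lost_calls=0,
        )

    rare_calls = calls
    if "rare" in stages:
        if config.get("reference_ids"):
            rare_kwargs["reference_ids"] = frozenset(
                io_formats.read_id_list(config["reference_ids"])
            )
        rare_cfg = RareConfig(**rare_kwargs)
        ref_ids = select_reference_controls(cohort, rare_cfg, seed=seed)
        cohort = cohort.with_flags(reference_ids=ref_ids)
        ref_calls = [c for c in calls if c.sample_id in ref_ids]
        common = identify_common(ref_calls, rare_cfg)
        pd.DataFrame(
            [{"chrom": cc.chrom, "start": cc.start, "end": cc.end,
              "cnv_type": cc.cnv_type.value, "count": cc.count} for cc in common],
            columns=["chrom", "start", "end", "cnv_type", "count"],
        ).to_csv(out / "common_cnvs.tsv", sep="\t", index=False)
        outputs["common_cnvs"] = out / "common_cnvs.tsv"
        n0, c0 = len(cohort), len(calls)
        rare_calls, removed, cohort = filter_rare(calls, common, cohort, rare_cfg)
        report.add(
            stage="rare_extraction",
            initial_samples=n0, final_samples=len(cohort),
            lost_samples=n0 - len(cohort),
            initial_calls=c0, final_calls=len(rare_calls),
            lost_calls=c0 - len(rare_calls),
            note="reference controls and common CNVs removed",
        )
        freq = carrier_frequency_table(rare_calls, cohort, rare_cfg.overlap_threshold)
        freq.to_csv(out / "carrier_frequencies.tsv", sep="\t", index=False)
        outputs["carrier_frequencies"] = out / "carrier_frequencies.tsv"
        io_formats.write_plink_cnv(rare_calls, cohort, out / "rare")
        outputs["rare_cnv"] = out / "rare.cnv"
        calls = rare_calls

    if "assoc" in stages:
        results = association_summary(calls, cohort, bins)
        summary_to_frame(results).to_csv(out / "association_summary.tsv", sep="\t",
                                         index=False)
        outputs["association_summary"] = out / "association_summary.tsv"
        report.add(
            stage="association",
            initial_samples=len(cohort), final_samples=len(cohort), lost_samples=0,
            initial_calls=len(calls), final_calls=len(calls), lost_calls=0,
            note="no multiple-testing adjustment applied",
        )

    if "enrich" in stages:
        if not config.get("genes"):
            raise ConfigurationError("enrich stage requires a 'genes' gene map")
        gene_map = io_formats.read_gene_map(config["genes"])
        gene_set = (
            io_formats.read_gene_set(config["gene_set"], gene_map)
            if config.get("gene_set")
            else None
        )
        covs = compute_covariates(calls, cohort, gene_map, gene_set)
        perm = PermutationConfig(n_perm=n_perm, seed=seed, alternative="two_sided")
        rows = [enrichment_test(covs, cohort, "genic", perm)]
        if gene_set:
            rows.append(enrichment_test(covs, cohort, "gene_set", perm))
        pd.DataFrame([vars(r) for r in rows]).to_csv(
            out / "enrichment_summary.tsv", sep="\t", index=False
        )
        outputs["enrichment_summary"] = out / "enrichment_summary.tsv"
        report.add(
            stage="enrichment",
            initial_samples=len(cohort), final_samples=len(cohort), lost_samples=0,
            initial_calls=len(calls), final_calls=len(calls), lost_calls=0,
        )

    report.validate()
    report.write_tsv(out / "cascade_report.tsv")
    (out / "cascade_report.txt").write_text(report.render() + "\n")
    outputs["cascade_report"] = out / "cascade_report.tsv"
    return PipelineResult(report=report, outputs=outputs)
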