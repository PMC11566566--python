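# rarecnv

Rare copy-number-variant (CNV) case–control analysis from SNP-array call
data: sample quality control, spurious-region cleaning and adjacent-call
merging, core-sample/size filtering, global burden testing, rare/common
partitioning by overlap-based frequency, size-binned association statistics
(two-proportion tests and Woolf odds-ratio confidence intervals), and
permutation-based gene-set enrichment. A synthetic cohort generator produces
every input format the pipeline consumes, so the whole stack is testable
without external data.

## Layout

| module | role |
|---|---|
| `rarecnv.io_formats` | PennCNV `.rawcnv`, QC summary TSV, Plink `.cnv`/`.fam`, BED3/BED4, id lists; coordinate normalization (internal 1-based inclusive) |
| `rarecnv.sample_qc` | pass/fail decisions on LRR_SD / BAF_drift / \|WF\| / NumCNV thresholds, plot-ready summaries |
| `rarecnv.call_cleaning` | exclusion of calls in HLA/immunoglobulin/centromere/telomere regions; gap-fraction merging of split calls |
| `rarecnv.cnv_filtering` | core-sample retention, strict >50 kb / >5 probes filter |
| `rarecnv.burden` | RATE / PROP / TOTKB / AVGKB metrics and permutation burden test |
| `rarecnv.rare_extraction` | union-intersection overlap counting, common-CNV discovery in a reference control subset, query-fraction removal, carrier-frequency tables |
| `rarecnv.association_stats` | size bins, Yates two-proportion p, Woolf OR/CI, uncorrected Pearson p, Table-style summary frames |
| `rarecnv.enrichment` | GCNT/NSEG/AVGKB covariates and logistic-regression permutation enrichment (genic + gene-set tests) |
| `rarecnv.synthetic_cohort` | seeded generator for calls, QC tables, phenotypes, regions, genes and a planted-truth table |
| `rarecnv.pipeline` / `rarecnv.cli` | stage runner, cascade report, `rarecnv` command-line interface |

## CLI

```bash
# generate a synthetic cohort
rarecnv simulate --seed 3 --out sim/

# full pipeline from a YAML config
rarecnv run-all --config config.yaml --seed 1 --out results/

# individual stages
rarecnv qc      --rawcnv sim/cohort.rawcnv --qcsum sim/cohort.qcsum --out qc/
rarecnv clean   --rawcnv qc/qc_pass.rawcnv --regions sim/regions.bed --out clean/
rarecnv filter  --rawcnv clean/clean.rawcnv --fam sim/cohort.fam --out filt/
rarecnv burden  --cnv filt/filtered.cnv --fam filt/filtered.fam --out burden.tsv
rarecnv rare    --cnv filt/filtered.cnv --fam filt/filtered.fam --reference-size 200 --out rare/
rarecnv assoc   --cnv rare/rare.cnv --fam rare/rare.fam --out assoc.tsv
rarecnv enrich  --cnv rare/rare.cnv --fam rare/rare.fam --genes sim/genes.bed \
                --gene-set panel.txt --out enrich.tsv
```

A `run-all` config is a YAML mapping with input paths (`rawcnv`, `qcsum`,
`fam` required; `regions`, `genes`, `gene_set`, `core_ids`, `reference_ids`
optional) and parameters (`qc_thresholds`, `merge`, `filter`, `rare`,
`bins`, `n_perm`, `seed`, `stages`). Defaults: LRR_SD < 0.3,
BAF_drift < 0.01, |WF| < 0.05, NumCNV ≤ 50; merge fractions 0.5 then 0.4;
length > 50 kb and > 5 probes; reference of 200 controls with common count
≥ 4 at 0.5 overlap; size bins 50/100/200/500/1000 kb; 10,000 permutations.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked 2x2
examples, brute-force and distribution-function oracle equivalence,
permutation-calibration and parameter-recovery simulations, pipeline
determinism). The calibration/recovery tests take a couple of minutes.

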