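import pytest

from rarecnv.models import (
    CnvCall,
    CnvType,
    CohortRecord,
    CohortTable,
    Phenotype,
    SampleQcRecord,
)


def make_call(sample="S1", chrom="1", start=100_001, end=200_000, cn=1,
              num_snps=55, conf=None):
    return CnvCall(sample_id=sample, chrom=chrom, start=start, end=end, cn=cn,
                   num_snps=num_snps, conf=conf)


@pytest.fixture
def small_cohort():
    return CohortTable(
        [
            CohortRecord("S1", Phenotype.CASE),
            CohortRecord("S2", Phenotype.CASE),
            CohortRecord("S3", Phenotype.CONTROL),
            CohortRecord("S4", Phenotype.CONTROL),
            CohortRecord("S5", Phenotype.CONTROL),
        ]
    )


@pytest.fixture
def qc_record():
    def _make(sample_id="S1", lrr_sd=0.12, baf_drift=0.0003, wf=-0.01, num_cnv=7,
              **kwargs):
        defaults = dict(lrr_mean=0.0, lrr_median=0.0, baf_mean=0.5,
                        baf_median=0.5, baf_sd=0.03)
        defaults.update(kwargs)
        return SampleQcRecord(sample_id=sample_id, lrr_sd=lrr_sd,
                              baf_drift=baf_drift, wf=wf, num_cnv=num_cnv,
                              **defaults)
    return _make
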