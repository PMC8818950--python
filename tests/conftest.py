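import numpy as np
import pytest

from tsmr.gwas_io import SummaryStatRecord
from tsmr.harmonization import HarmonizedInstrument


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-9,
    n=10000,
) -> SummaryStatRecord:
    return SummaryStatRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_instruments(bx, by, sy, sx=None, eaf=0.3) -> list[HarmonizedInstrument]:
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sx = np.full(len(bx), 1e-4) if sx is None else np.asarray(sx)
    return [
        HarmonizedInstrument(
            snp_id=f"rs{i}",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
            eaf_exp=eaf,
            eaf_out=eaf,
            status="aligned",
            kept=True,
        )
        for i in range(len(bx))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
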