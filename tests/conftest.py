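import numpy as np
import pytest

from locusfine import LocusTable, VariantRecord


def make_record(rsid="rs1", pos=100, beta=0.05, se=0.01, p=None, **kw):
    if p is None and beta is not None and se is not None:
        from locusfine import p_from_z

        p = max(p_from_z(beta / se), 5e-324)
    return VariantRecord(
        rsid=rsid, chrom="2", pos=pos, beta=beta, se=se, p=p,
        maf=kw.pop("maf", 0.3), n=kw.pop("n", 100_000.0), **kw,
    )


@pytest.fixture
def toy_table():
    """Three-variant locus with a clearly dominant middle variant."""
    return LocusTable(
        (
            make_record("rsA", 100, beta=0.010, se=0.005),
            make_record("rsB", 200, beta=0.080, se=0.005),
            make_record("rsC", 300, beta=0.002, se=0.005),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
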