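import numpy as np
import pytest

from mrmediate.harmonize import HarmonizedInstrument
from mrmediate.sumstats import SumStatRecord, SumStatSet


def make_instruments(beta_exp, beta_out, se_out, se_exp=None, prefix="rs"):
    """Build a HarmonizedInstrument list from parallel arrays."""
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    se_out = np.asarray(se_out, float)
    se_exp = np.full_like(beta_exp, 0.01) if se_exp is None else np.asarray(se_exp, float)
    return [
        HarmonizedInstrument(
            snp_id=f"{prefix}{i}",
            beta_exp=float(beta_exp[i]),
            se_exp=float(se_exp[i]),
            beta_out=float(beta_out[i]),
            se_out=float(se_out[i]),
        )
        for i in range(len(beta_exp))
    ]


def random_instruments(rng, j=10, causal=0.1):
    """Random small instance: strong instruments, true slope ``causal``."""
    beta_exp = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    se_exp = rng.uniform(0.005, 0.02, j)
    se_out = rng.uniform(0.005, 0.03, j)
    beta_out = causal * beta_exp + rng.normal(0, se_out)
    return make_instruments(beta_exp, beta_out, se_out, se_exp)


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=None,
                eaf=0.3, n=10000.0):
    if pval is None:
        from scipy import stats
        pval = float(2 * stats.norm.sf(abs(beta / se)))
    return SumStatRecord(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                         beta=beta, se=se, pval=pval, eaf=eaf, n=n)


def make_set(records, label="trait", trait_type="quantitative"):
    return SumStatSet(trait_label=label, trait_type=trait_type, records=list(records))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_set():
    return make_set(
        [
            make_record("rs1", "A", "G", beta=0.10, se=0.012, eaf=0.30),
            make_record("rs2", "C", "T", beta=-0.08, se=0.011, eaf=0.45),
            make_record("rs3", "G", "A", beta=0.12, se=0.015, eaf=0.12),
        ]
    )
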