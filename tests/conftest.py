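import numpy as np
import pytest

from tiermr.sumstats import HarmonizedPair, HarmonizationAction, InstrumentSet


def make_pair(variant_id="rs1", beta_exp=0.1, se_exp=0.01, beta_out=0.02,
              se_out=0.01, pval_exp=1e-10, pval_out=0.05, eaf_exp=0.3,
              eaf_out=0.3, pos=None):
    return HarmonizedPair(
        variant_id=variant_id, beta_exp=beta_exp, se_exp=se_exp, pval_exp=pval_exp,
        beta_out=beta_out, se_out=se_out, pval_out=pval_out,
        eaf_exp=eaf_exp, eaf_out=eaf_out, action=HarmonizationAction.KEPT, pos=pos,
    )


def make_instruments(bx, sx, by, sy, exposure_id="X", outcome_id="Y"):
    pairs = [
        make_pair(variant_id=f"rs{i + 1}", beta_exp=float(b), se_exp=float(s),
                  beta_out=float(bo), se_out=float(so))
        for i, (b, s, bo, so) in enumerate(zip(bx, sx, by, sy))
    ]
    return InstrumentSet(exposure_id, outcome_id, pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_instruments(rng):
    """10 instruments from a homogeneous causal model (true beta 0.3)."""
    m = 10
    lam = rng.uniform(0.05, 0.15, m)
    sx = np.full(m, 0.005)
    sy = rng.uniform(0.008, 0.02, m)
    bx = rng.normal(lam, sx)
    by = rng.normal(0.3 * lam, sy)
    return make_instruments(bx, sx, by, sy)
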