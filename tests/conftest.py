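import numpy as np
import pytest
from hypothesis import settings

from tsmr.harmonize import HarmonizedInstrument
from tsmr.summary_io import SummaryStatRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_instruments(gamma, se_gamma, alpha, se_alpha, **kwargs) -> list[HarmonizedInstrument]:
    """Build harmonized instruments from parallel effect/SE arrays."""
    out = []
    for j, (g, sg, a, sa) in enumerate(zip(gamma, se_gamma, alpha, se_alpha)):
        out.append(HarmonizedInstrument(
            rsid=f"rs{j + 1}", effect_allele="A", other_allele="G",
            gamma=float(g), se_gamma=float(sg), alpha=float(a), se_alpha=float(sa),
            **kwargs,
        ))
    return out


def make_record(rsid, beta=0.1, se=0.01, pval=1e-9, ea="A", oa="G", eaf=0.3, n=100_000):
    return SummaryStatRecord(rsid=rsid, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, pval=pval, eaf=eaf, n=n)


@pytest.fixture
def random_instruments():
    """J=10 noisy instruments around slope -0.28, heterogeneous SEs, fixed seed."""
    rng = np.random.default_rng(42)
    J = 10
    gamma = rng.normal(0.1, 0.04, J)
    se_gamma = rng.uniform(0.002, 0.008, J)
    se_alpha = rng.uniform(0.004, 0.012, J)
    alpha = -0.28 * gamma + rng.normal(0, se_alpha)
    return make_instruments(gamma, se_gamma, alpha, se_alpha)


@pytest.fixture
def collinear_instruments():
    """J=7 noise-free instruments lying exactly on alpha = -0.28 * gamma."""
    gamma = np.linspace(0.05, 0.2, 7)
    return make_instruments(gamma, [0.003] * 7, -0.28 * gamma, [0.005] * 7)
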