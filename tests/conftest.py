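import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from multipgs import SimConfig, simulate_panels

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_populations=2,
        n_variants=200,
        block_sizes=[10] * 20,
        rho=0.6,
        fst=0.1,
        base_freq_range=(0.1, 0.9),
        h2=0.3,
        pi0=0.5,
        rg=0.7,
        n_gwas=[1500, 1500],
        n_target=[400, 400],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panels(small_config):
    return simulate_panels(small_config, {"POP1": 600, "POP2": 600}, stream="ref")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_sumstats(
    n: int = 20,
    seed: int = 0,
    beta_scale: float = 0.05,
    n_samples: int = 5000,
) -> pd.DataFrame:
    """Small synthetic, internally consistent summary-statistic table."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    freq = rng.uniform(0.1, 0.9, n)
    beta = rng.normal(0, beta_scale, n)
    se = np.sqrt(1 / (2 * freq * (1 - freq) * n_samples))
    p = 2 * stats.norm.sf(np.abs(beta / se))
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n)],
            "CHR": 1,
            "BP": (np.arange(n) + 1) * 1000,
            "A1": [pairs[i % 4][0] for i in range(n)],
            "A2": [pairs[i % 4][1] for i in range(n)],
            "FREQ": freq,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n_samples,
            "INFO": 1.0,
        }
    )
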