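import numpy as np
import pandas as pd
import pytest


def make_instruments(beta_exp, beta_out, se_out, se_exp=None, snps=None) -> pd.DataFrame:
    """Build a minimal harmonized-instrument table from effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    se_exp = np.broadcast_to(
        np.asarray(0.01 if se_exp is None else se_exp, dtype=float), beta_exp.shape
    )
    n = len(beta_exp)
    return pd.DataFrame({
        "snp": snps if snps is not None else [f"rs{i + 1:03d}" for i in range(n)],
        "effect_allele": "A",
        "other_allele": "G",
        "beta_exp": beta_exp,
        "se_exp": se_exp,
        "p_exp": 1e-10,
        "eaf_exp": 0.3,
        "beta_out": beta_out,
        "se_out": se_out,
        "p_out": 0.5,
        "eaf_out": 0.3,
        "action": "as_is",
    })


def random_instruments(rng, n=8):
    """A random but well-conditioned instrument set for oracle comparisons."""
    beta_exp = rng.uniform(0.05, 0.2, n) * rng.choice([-1, 1], n)
    se_out = rng.uniform(0.005, 0.03, n)
    beta_out = 0.3 * beta_exp + rng.normal(0, se_out)
    return make_instruments(beta_exp, beta_out, se_out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_stats(tmp_path):
    """A 3-row well-formed summary-statistics TSV."""
    path = tmp_path / "stats.tsv"
    path.write_text(
        "snp\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
        "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.01\t1e-20\t1000\n"
        "rs2\t1\t200\tC\tT\t0.5\t-0.05\t0.02\t0.02\t1000\n"
        "rs3\t2\t300\tG\tA\t0.1\t0.02\t0.01\t0.4\t1000\n"
    )
    return path
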