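import numpy as np
import pandas as pd
import pytest

from prsbilevel.datatypes import AnnotationMap, LDBlock, SummaryStats


def build_sumstats(beta_hat, n_gwas=1000, prefix="rs"):
    beta_hat = np.asarray(beta_hat, dtype=float)
    m = beta_hat.size
    table = pd.DataFrame({
        "variant_id": [f"{prefix}{i + 1}" for i in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1),
        "a1": "A",
        "a2": "G",
        "beta_hat": beta_hat,
    })
    return SummaryStats(table, n_gwas)


def identity_blocks(ss, block_size=None):
    """Unit-diagonal LD blocks covering the summary statistics."""
    ids = ss.variant_ids
    block_size = block_size or len(ids)
    out = []
    for lo in range(0, len(ids), block_size):
        chunk = ids[lo:lo + block_size]
        out.append(LDBlock(chunk, np.eye(len(chunk))))
    return out


def single_group_map(ss, label="g1"):
    return AnnotationMap(groups=[label],
                         assignment={v: (label,) for v in ss.variant_ids})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sumstats():
    return build_sumstats([0.1, -0.2, 0.0, 0.05], n_gwas=500)
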