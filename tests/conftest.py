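import numpy as np
import pandas as pd
import pytest

from sweepscan.allele_data import LocusTable, het_columns


def make_table(fst, het=None, chrom="chr1", n_pops=2, start_pos=100, step=100):
    """Build a small LocusTable from explicit fst (and optional het) values."""
    fst = np.asarray(fst, dtype=float)
    n = len(fst)
    if het is None:
        het = np.full((n, n_pops), 0.3)
    het = np.asarray(het, dtype=float)
    df = pd.DataFrame(
        {
            "name": [f"rs{i + 1}" for i in range(n)],
            "chrom": chrom,
            "pos": start_pos + step * np.arange(n),
            **{c: het[:, j] for j, c in enumerate(het_columns(n_pops))},
            "fst": fst,
        }
    )
    return LocusTable(df, n_pops=n_pops)


def random_table(rng, n=200, chrom="chr1", n_pops=2):
    """A random but valid LocusTable (uniform het/fst), for oracle tests."""
    het = rng.uniform(0.0, 0.5, size=(n, n_pops))
    fst = rng.uniform(0.0, 1.0, size=n)
    return make_table(fst, het=het, chrom=chrom, n_pops=n_pops)


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)
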