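import numpy as np
import pytest

import foniokit as fk
from foniokit.genotypes import GenotypeMatrix


def make_genotypes(codes, pops=None, chrom=None, pos=None, ids=None,
                   depths=None):
    """Build a GenotypeMatrix from a nested list of codes (rows=individuals)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    return GenotypeMatrix(
        genotypes=codes,
        chrom=np.array(chrom if chrom is not None else ["1"] * L, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, L + 1) * 10),
        individual_ids=ids or [f"i{k}" for k in range(n)],
        pop_labels=pops,
        depths=None if depths is None else np.asarray(depths),
    )


@pytest.fixture(scope="session")
def four_pop_dataset():
    """Deep two-pair divergence simulation shared across test modules."""
    model = fk.four_population_model()
    return fk.simulate_windows(
        model,
        {"exilis": 5, "longiflora": 3, "iburua": 5, "ternata": 3},
        25, 50_000, seed=11,
    )


@pytest.fixture(scope="session")
def two_pop_split_dataset():
    """Two populations with an old clean split (no bottleneck)."""
    model = fk.two_population_model(t_div=100_000.0, bottleneck_size=None)
    return fk.simulate_unlinked_snps(
        model, {"cultivated": 8, "wild": 8}, 400, 1000, seed=5
    )
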