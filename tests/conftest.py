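import numpy as np
import pandas as pd
import pytest

from equiroh.genotype_io import GenotypeMatrix, SNPMap


@pytest.fixture
def tiny_map() -> SNPMap:
    """One chromosome, 10 evenly spaced markers at 100 kb."""
    return SNPMap.from_arrays(
        ["1"] * 10, [f"m{i}" for i in range(10)], list(range(100_000, 1_100_000, 100_000))
    )


@pytest.fixture
def two_chrom_map() -> SNPMap:
    pos1 = list(range(1_000_000, 3_100_000, 100_000))  # 21 markers, span 2 Mb
    pos2 = list(range(500_000, 2_600_000, 100_000))
    return SNPMap.from_arrays(
        ["1"] * len(pos1) + ["2"] * len(pos2),
        [f"a{i}" for i in range(len(pos1))] + [f"b{i}" for i in range(len(pos2))],
        pos1 + pos2,
    )


@pytest.fixture
def small_genotypes(tiny_map) -> GenotypeMatrix:
    rng = np.random.default_rng(7)
    codes = rng.integers(0, 3, size=(4, len(tiny_map))).astype(np.int8)
    return GenotypeMatrix([f"ind{i}" for i in range(4)], codes)


def random_map(rng, n_chrom, n_markers, spacing=10_000) -> SNPMap:
    chroms, mids, poss = [], [], []
    for c in range(1, n_chrom + 1):
        gaps = rng.integers(1, 2 * spacing, size=n_markers)
        pos = np.cumsum(gaps)
        chroms += [str(c)] * n_markers
        mids += [f"c{c}m{j}" for j in range(n_markers)]
        poss += pos.tolist()
    return SNPMap.from_arrays(chroms, mids, poss)
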