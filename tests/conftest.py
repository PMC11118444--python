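import numpy as np
import pytest

from wrightgst import GenotypeTable, Pedigree


@pytest.fixture
def worked_table() -> GenotypeTable:
    """Deme A = {a/a, a/b}, deme B = {b/b, b/b}: the hand-enumerable fixture.

    Full enumeration of gene pairs gives f = 3/4, g_w = (1/2 + 1)/2 = 3/4
    (equal deme weights), g_b = 1/4.
    """
    codes = np.array([
        [[0, 0]], [[0, 1]],   # deme A
        [[1, 1]], [[1, 1]],   # deme B
    ])
    return GenotypeTable.from_codes(
        ids=["A1", "A2", "B1", "B2"],
        demes=["A", "A", "B", "B"],
        loci=["L0"],
        codes=codes,
    )


@pytest.fixture
def parent_offspring_pedigree() -> Pedigree:
    """X is the offspring of founder A mated to A's own offspring C."""
    return Pedigree({"A": None, "B": None, "C": ("A", "B"), "X": ("A", "C")})


@pytest.fixture
def full_sib_pedigree() -> Pedigree:
    return Pedigree({"A": None, "B": None, "C": ("A", "B"), "D": ("A", "B"),
                     "X": ("C", "D")})
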