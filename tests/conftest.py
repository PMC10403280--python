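import warnings

import pytest

from coevoscreen.library_design import DegenerateCodon, LibraryDesign


def make_design(
    name: str,
    codons_a: list[str],
    codons_b: list[str],
    scaffold_len: int = 20,
) -> LibraryDesign:
    """Small synthetic design with evenly spaced randomized positions."""
    scaffold = ("ACDEFGHIKLMNPQRSTVWY" * 3)[:scaffold_len]
    pos_a = list(range(2, 2 + 2 * len(codons_a), 2))
    pos_b = list(range(3, 3 + 2 * len(codons_b), 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LibraryDesign(
            name=name,
            scaffold_A=scaffold,
            scaffold_B=scaffold,
            positions_A=pos_a,
            positions_B=pos_b,
            codons_A=[DegenerateCodon(c) for c in codons_a],
            codons_B=[DegenerateCodon(c) for c in codons_b],
        )


@pytest.fixture
def tiny_design() -> LibraryDesign:
    """2 A-positions over {F,L}, 1 B-position over {F,I,L,V}."""
    return make_design("tiny", ["TTM", "TTM"], ["NTT"])


@pytest.fixture
def small_design() -> LibraryDesign:
    """3 A-positions over {F,I,L,V}, 2 B-positions over {F,I,L,M,V}."""
    return make_design("small", ["NTT"] * 3, ["DTK"] * 2)
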