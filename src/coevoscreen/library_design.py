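"""Display-library designs: scaffolds, randomized positions, degenerate codons.

A library is defined by two scaffold chains (here Z-domain / affibody style
three-helix bundles), a set of randomized interface positions on each chain,
and one degenerate codon per randomized position. The degenerate codon fixes
both the nucleotide-level diversity (number of distinct triplets) and the
functional amino-acid alphabet available at that position.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import yaml

# IUPAC nucleotide degeneracy codes.
IUPAC_NT: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# Standard genetic code, DNA triplets; "*" marks stop codons.
GENETIC_CODE: dict[str, str] = {}
_BASES = "TCAG"
_AA_TABLE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AA_TABLE[_i]

#: 58-residue Z domain of staphylococcal protein A (chain A scaffold).
Z_DOMAIN = "VDNKFNKEQQNAFYEILHLPNLNEEQRNAFIQSLKDDPSQSANLLAEAKKLNDAQAPK"

#: Synthetic placeholder for the affibody partner chain: the Z backbone with
#: the interface residues L9/V17/I31/F32 of the weak-affinity binder
#: substituted. The true partner sequence is not bundled; any 58-residue
#: chain with matching residue numbering can be supplied instead.
AFFIBODY_PLACEHOLDER = (
    Z_DOMAIN[:8] + "L" + Z_DOMAIN[9:16] + "V" + Z_DOMAIN[17:30] + "IF" + Z_DOMAIN[32:]
)


class CodonError(ValueError):
    """Raised for invalid IUPAC characters or malformed codons."""


@dataclass(frozen=True)
class DegenerateCodon:
    """A 3-character degenerate codon over IUPAC nucleotide codes."""

    iupac: str

    def __post_init__(self) -> None:
        if len(self.iupac) != 3:
            raise CodonError(f"degenerate codon must have 3 characters, got {self.iupac!r}")
        for pos, ch in enumerate(self.iupac.upper()):
            if ch not in IUPAC_NT:
                raise CodonError(
                    f"invalid IUPAC nucleotide code {ch!r} at codon position {pos + 1}"
                )
        object.__setattr__(self, "iupac", self.iupac.upper())


def expand_degenerate_codon(
    codon: DegenerateCodon | str,
) -> tuple[set[str], dict[str, int], set[str]]:
    """Expand a degenerate codon into triplets and encoded amino acids.

    Returns ``(triplets, amino_acid_multiset, stop_triplets)`` where
    ``amino_acid_multiset`` maps each encoded amino acid to the number of
    triplets encoding it (stop codons excluded and reported separately).
    """
    if not isinstance(codon, DegenerateCodon):
        codon = DegenerateCodon(codon)
    triplets = {
        "".join(bases)
        for bases in itertools.product(*(IUPAC_NT[ch] for ch in codon.iupac))
    }
    aa_counts: dict[str, int] = {}
    stops: set[str] = set()
    for t in sorted(triplets):
        aa = GENETIC_CODE[t]
        if aa == "*":
            stops.add(t)
        else:
            aa_counts[aa] = aa_counts.get(aa, 0) + 1
    return triplets, aa_counts, stops


@dataclass
class LibraryDesign:
    """A two-chain display library design.

    Positions are 1-based residue numbers on each scaffold, matching the
    structural residue labels used for the Z-domain/affibody interface
    (e.g. 9, 13, 17, 31, 35). Alphabets are derived from codon expansions;
    stop codons are excluded from the functional alphabet with a warning.
    """

    name: str
    scaffold_A: str
    scaffold_B: str
    positions_A: list[int]
    positions_B: list[int]
    codons_A: list[DegenerateCodon]
    codons_B: list[DegenerateCodon]
    alphabets_A: list[str] = field(default_factory=list)
    alphabets_B: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chain in ("A", "B"):
            scaffold = getattr(self, f"scaffold_{chain}")
            positions = getattr(self, f"positions_{chain}")
            codons = getattr(self, f"codons_{chain}")
            if any(p2 <= p1 for p1, p2 in zip(positions, positions[1:])):
                raise ValueError(f"positions_{chain} must be strictly increasing")
            if positions and (positions[0] < 1 or positions[-1] > len(scaffold)):
                raise ValueError(
                    f"positions_{chain} out of range 1..{len(scaffold)}: {positions}"
                )
            if len(codons) != len(positions):
                raise ValueError(
                    f"chain {chain}: {len(codons)} codons for {len(positions)} positions"
                )
            derived = []
            for codon in codons:
                _, aa_counts, stops = expand_degenerate_codon(codon)
                if stops:
                    warnings.warn(
                        f"{self.name} chain {chain} codon {codon.iupac}: stop codon(s) "
                        f"{sorted(stops)} excluded from the functional alphabet",
                        stacklevel=2,
                    )
                if not aa_counts:
                    raise ValueError(f"codon {codon.iupac} encodes only stops")
                derived.append("".join(sorted(aa_counts)))
            setattr(self, f"alphabets_{chain}", derived)

    def variable_length(self, chain: Literal["A", "B"]) -> int:
        return len(getattr(self, f"positions_{chain}"))

    def alphabets(self, chain: Literal["A", "B"]) -> list[str]:
        return getattr(self, f"alphabets_{chain}")

    def apply_variant(self, chain: Literal["A", "B"], variant: str) -> str:
        """Substitute a variable-region string into the scaffold -> full chain."""
        positions = getattr(self, f"positions_{chain}")
        scaffold = getattr(self, f"scaffold_{chain}")
        if len(variant) != len(positions):
            raise ValueError(
                f"variant length {len(variant)} != {len(positions)} randomized positions"
            )
        chars = list(scaffold)
        for pos, aa in zip(positions, variant):
            chars[pos - 1] = aa
        return "".join(chars)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scaffold_A": self.scaffold_A,
            "scaffold_B": self.scaffold_B,
            "positions_A": list(self.positions_A),
            "positions_B": list(self.positions_B),
            "codons_A": [c.iupac for c in self.codons_A],
            "codons_B": [c.iupac for c in self.codons_B],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryDesign":
        return cls(
            name=d["name"],
            scaffold_A=d["scaffold_A"],
            scaffold_B=d["scaffold_B"],
            positions_A=list(d["positions_A"]),
            positions_B=list(d["positions_B"]),
            codons_A=[DegenerateCodon(c) for c in d["codons_A"]],
            codons_B=[DegenerateCodon(c) for c in d["codons_B"]],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "LibraryDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def diversity(design: LibraryDesign) -> tuple[int, int]:
    """(nucleotide_diversity, functional_diversity) of the paired library.

    Nucleotide diversity is the product of codon-expansion sizes over all
    randomized positions on both chains; functional diversity the product of
    amino-acid alphabet sizes.
    """
    nt, fn = 1, 1
    for codons, alphabets in (
        (design.codons_A, design.alphabets_A),
        (design.codons_B, design.alphabets_B),
    ):
        for codon, alphabet in zip(codons, alphabets):
            triplets, _, _ = expand_degenerate_codon(codon)
            nt *= len(triplets)
            fn *= len(alphabet)
    return nt, fn


def chain_functional_diversity(design: LibraryDesign, chain: Literal["A", "B"]) -> int:
    out = 1
    for alphabet in design.alphabets(chain):
        out *= len(alphabet)
    return out


def enumerate_variants(
    design: LibraryDesign, chain: Literal["A", "B"], limit: int = 1_000_000
) -> Iterator[str]:
    """Yield every distinct variable-region string once, lexicographically.

    Refuses (with the exact count) when the chain's functional diversity
    exceeds ``limit``; callers should sample instead.
    """
    n = chain_functional_diversity(design, chain)
    if n > limit:
        raise ValueError(
            f"chain {chain} functional diversity {n} exceeds enumeration limit {limit}"
        )
    for combo in itertools.product(*design.alphabets(chain)):
        yield "".join(combo)


def write_variants_fasta(
    design: LibraryDesign, chain: Literal["A", "B"], path: str | Path,
    limit: int = 1_000_000,
) -> int:
    """Export enumerated variable regions as FASTA (id = variable region)."""
    n = 0
    with open(path, "w") as fh:
        for variant in enumerate_variants(design, chain, limit=limit):
            fh.write(f">{variant}\n{design.apply_variant(chain, variant)}\n")
            n += 1
    return n


# ---- shipped designs ----------------------------------------------------
#
# Degenerate codons chosen to reproduce the published amino-acid alphabets:
#   DTK -> 6 triplets  -> {F,I,L,M,V}                       (no stops)
#   HWW -> 12 triplets -> {F,H,I,K,L,N,Q,Y} + 1 stop (TAA)
#   NWW -> 16 triplets -> {D,E,F,H,I,K,L,N,Q,V,Y} + 1 stop (TAA)
# NWW at 8 positions gives the theoretical nucleotide diversity
# 16^8 = 4,294,967,296.


def ll1_design() -> LibraryDesign:
    """First low-affinity coselection library: Z-A 5 positions over 8 polar +
    hydrophobic amino acids, Z-B 4 positions over 5 hydrophobic amino acids."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LibraryDesign(
            name="LL1",
            scaffold_A=Z_DOMAIN,
            scaffold_B=AFFIBODY_PLACEHOLDER,
            positions_A=[9, 13, 17, 31, 35],
            positions_B=[9, 17, 31, 32],
            codons_A=[DegenerateCodon("HWW")] * 5,
            codons_B=[DegenerateCodon("DTK")] * 4,
        )


def ll2_design() -> LibraryDesign:
    """Second low-affinity coselection library: 4 positions per chain, both
    over the expanded 11-amino-acid alphabet {D,E,F,H,I,K,L,N,Q,V,Y}."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LibraryDesign(
            name="LL2",
            scaffold_A=Z_DOMAIN,
            scaffold_B=AFFIBODY_PLACEHOLDER,
            positions_A=[9, 13, 17, 31],
            positions_B=[9, 17, 31, 32],
            codons_A=[DegenerateCodon("NWW")] * 4,
            codons_B=[DegenerateCodon("NWW")] * 4,
        )
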