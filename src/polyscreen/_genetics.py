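"""Genetic-code helpers shared across the package.

Built on Biopython's standard codon table (NCBI table 1). Stop codons are
pooled under the single-letter class ``X`` throughout, matching the
convention used for nonsense edits in saturation-mutagenesis logos.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = "ACGT"

#: All 64 codons in lexicographic order.
CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: Nonsense codons of the standard code (TAA, TAG, TGA).
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

#: Class label for the pooled stop/nonsense codons.
STOP_AA = "X"

#: codon -> single-letter amino acid, stops mapped to ``X``.
CODON_TO_AA: dict[str, str] = {
    c: (STOP_AA if c in _STANDARD.stop_codons else _STANDARD.forward_table[c])
    for c in CODONS
}

#: amino acid -> sorted tuple of synonymous codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
for _aa in AA_TO_CODONS:
    AA_TO_CODONS[_aa] = tuple(sorted(c for c, a in CODON_TO_AA.items() if a == _aa))

#: The 20 amino acids plus the stop class, alphabetical with X last.
AMINO_ACIDS: tuple[str, ...] = tuple(
    sorted(a for a in AA_TO_CODONS if a != STOP_AA)
) + (STOP_AA,)


def translate(seq: str) -> str:
    """Translate an in-frame coding sequence; stops appear as ``X``."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return str(Seq(seq).translate()).replace("*", STOP_AA)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def synonymous_codons(codon: str, gc_third: bool = False) -> tuple[str, ...]:
    """Synonymous alternatives for ``codon`` (including itself).

    With ``gc_third`` only codons whose third base is G or C are returned;
    every amino acid (and the stop class) has at least one such codon in
    the standard code.
    """
    options = AA_TO_CODONS[CODON_TO_AA[codon]]
    if gc_third:
        options = tuple(c for c in options if c[2] in "GC")
    return options
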