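"""Exact-match codon counting over paired amplicon reads.

A read pair is assigned to codon ``c`` when either mate, in either
orientation, contains ``flank_left + c + flank_right`` as an exact
substring; anchors are fixed-length sequences immediately flanking the
randomized codon in the edited amplicon. Pairs with no such match are
tallied as unclassified. Edited molecules are recognized by diagnostic
tag k-mers that exist only in the edited allele.

Exact matching with no quality filtering keeps the counter provably
equivalent to a brute-force scan, which the tests exploit.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from ._genetics import CODONS, revcomp

MIN_FLANK = 8
DEFAULT_FLANK = 12

_COLUMNS = list(CODONS) + ["unclassified"]


class CountingError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconDesign:
    """Geometry of one edited amplicon target.

    ``amplicon_sequence`` is the edited reference (tag bases applied; the
    randomized codon may be written as ``NNN``), ``codon_offset`` the 0-based
    offset of the randomized codon, ``tag_kmers`` edited-only diagnostic
    k-mers, and the flanks the exact anchors either side of the codon.
    ``unedited_sequence``, when given, is the tag-free allele (used by the
    read simulator for the unedited fraction).
    """

    amplicon_sequence: str
    codon_offset: int
    tag_kmers: tuple[str, ...]
    flank_left: str
    flank_right: str
    expected_length: int | None = None
    unedited_sequence: str | None = None

    def __post_init__(self) -> None:
        amp = self.amplicon_sequence.upper()
        object.__setattr__(self, "amplicon_sequence", amp)
        object.__setattr__(self, "flank_left", self.flank_left.upper())
        object.__setattr__(self, "flank_right", self.flank_right.upper())
        object.__setattr__(
            self, "tag_kmers", tuple(k.upper() for k in self.tag_kmers)
        )
        if min(len(self.flank_left), len(self.flank_right)) < MIN_FLANK:
            raise CountingError(f"flank shorter than minimum k = {MIN_FLANK}")
        if self.codon_offset + 3 > len(amp):
            raise CountingError("codon_offset+3 exceeds amplicon length")
        o = self.codon_offset
        if amp[o - len(self.flank_left) : o] != self.flank_left:
            raise CountingError("flank_left is not the sequence left of the codon")
        if amp[o + 3 : o + 3 + len(self.flank_right)] != self.flank_right:
            raise CountingError("flank_right is not the sequence right of the codon")

    @classmethod
    def from_amplicon(
        cls,
        amplicon_sequence: str,
        codon_offset: int,
        tag_offsets: Sequence[int] = (),
        k: int = DEFAULT_FLANK,
        tag_kmer_len: int = 20,
        unedited_sequence: str | None = None,
    ) -> "AmpliconDesign":
        """Derive flanks and tag k-mers from the edited amplicon.

        ``tag_offsets`` are offsets of tag bases within the amplicon; one
        diagnostic k-mer covering each is extracted (deduplicated). Windows
        are shifted off the randomized codon so the k-mer is invariant to
        the codon a molecule carries.
        """
        amp = amplicon_sequence.upper()
        c0, c1 = codon_offset, codon_offset + 3
        kmers = []
        for p in tag_offsets:
            lo, hi = 0, len(amp) - tag_kmer_len  # valid window starts
            if p >= c1:  # tag right of codon: window must start after the codon
                lo = max(lo, c1)
            elif p < c0:  # tag left of codon: window must end before the codon
                hi = min(hi, c0 - tag_kmer_len)
            else:
                raise CountingError("tag offset inside the randomized codon")
            if lo > hi:
                raise CountingError("no codon-free window covers the tag base")
            s = min(max(lo, p - tag_kmer_len // 2), hi)
            km = amp[s : s + tag_kmer_len]
            if "N" not in km and km not in kmers:
                kmers.append(km)
        return cls(
            amplicon_sequence=amp,
            codon_offset=codon_offset,
            tag_kmers=tuple(kmers),
            flank_left=amp[codon_offset - k : codon_offset],
            flank_right=amp[codon_offset + 3 : codon_offset + 3 + k],
            expected_length=len(amp),
            unedited_sequence=unedited_sequence,
        )


@dataclass
class CodonCountTable:
    """Per-sample counts of the 64 codons plus an unclassified bin.

    ``counts`` is a samples x (64 codons + ``unclassified``) DataFrame;
    ``total_pairs`` the number of read pairs seen per sample.
    """

    counts: pd.DataFrame
    total_pairs: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=_COLUMNS, fill_value=0)
        if (self.counts.to_numpy() < 0).any():
            raise CountingError("negative counts")
        classified = self.counts.sum(axis=1)
        tp = self.total_pairs.reindex(self.counts.index)
        if (classified > tp).any():
            raise CountingError("counts exceed total read pairs")

    @property
    def codon_counts(self) -> pd.DataFrame:
        """The samples x 64 codon block, without the unclassified bin."""
        return self.counts[list(CODONS)]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        counts = self.counts.add(other.counts, fill_value=0).astype(self.counts.dtypes.iloc[0])
        totals = self.total_pairs.add(other.total_pairs, fill_value=0)
        return CodonCountTable(counts, totals)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (sample_id, codon, count) table, unclassified included."""
        tidy = (
            self.counts.rename_axis("sample_id")
            .reset_index()
            .melt(id_vars="sample_id", var_name="codon", value_name="count")
        )
        return tidy.sort_values(["sample_id", "codon"], ignore_index=True)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, total_pairs: pd.Series | None = None) -> "CodonCountTable":
        wide = tidy.pivot_table(
            index="sample_id", columns="codon", values="count", fill_value=0
        )
        if total_pairs is None:
            total_pairs = wide.sum(axis=1)
        return cls(wide, total_pairs)


ReadPair = tuple[str, str]


def _find_codon(read: str, fl: str, fr: str) -> str | None:
    """First flank-anchored codon in ``read`` (one orientation)."""
    start = 0
    n_fl = len(fl)
    while True:
        i = read.find(fl, start)
        if i < 0:
            return None
        j = i + n_fl
        if read[j + 3 : j + 3 + len(fr)] == fr and len(read) >= j + 3 + len(fr):
            return read[j : j + 3]
        start = i + 1


def classify_pair(pair: ReadPair, design: AmpliconDesign) -> str | None:
    """Codon carried by a read pair, or None if unclassified.

    Mate 1 takes precedence over mate 2; each mate is scanned forward then
    reverse-complemented. Codons containing N are unclassified.
    """
    fl, fr = design.flank_left, design.flank_right
    for mate in pair:
        for read in (mate, revcomp(mate)):
            codon = _find_codon(read.upper(), fl, fr)
            if codon is not None:
                return codon if codon in CODONS else None
    return None


def count_codons(
    read_pairs: Iterable[ReadPair], design: AmpliconDesign
) -> tuple[dict[str, int], int, int]:
    """Count codon occurrences over one sample's read pairs.

    Returns ``(codon counts incl. 'unclassified', total pairs, conflicts)``
    where conflicts tallies pairs whose two mates carry different codons
    (mate 1 wins). Totals are order-independent.
    """
    counts = dict.fromkeys(_COLUMNS, 0)
    total = 0
    conflicts = 0
    fl, fr = design.flank_left, design.flank_right
    for r1, r2 in read_pairs:
        total += 1
        c1 = _find_codon(r1.upper(), fl, fr) or _find_codon(revcomp(r1.upper()), fl, fr)
        c2 = _find_codon(r2.upper(), fl, fr) or _find_codon(revcomp(r2.upper()), fl, fr)
        codon = c1 if c1 is not None else c2
        if c1 is not None and c2 is not None and c1 != c2:
            conflicts += 1
        if codon is None or codon not in CODONS:
            counts["unclassified"] += 1
        else:
            counts[codon] += 1
    return counts, total, conflicts


def detect_edited_fraction(
    read_pairs: Iterable[ReadPair], design: AmpliconDesign
) -> float:
    """Fraction of pairs carrying any diagnostic tag k-mer (either strand).

    Pairs with a tag but an unreadable codon still count as edited; an
    empty stream yields 0.0.
    """
    kmers = design.tag_kmers + tuple(revcomp(k) for k in design.tag_kmers)
    total = 0
    edited = 0
    for r1, r2 in read_pairs:
        total += 1
        if any(k in r1.upper() or k in r2.upper() for k in kmers):
            edited += 1
    return edited / total if total else 0.0


def count_samples(
    samples: dict[str, Iterable[ReadPair]], design: AmpliconDesign
) -> tuple[CodonCountTable, pd.DataFrame]:
    """Count every sample; returns the table and a QC frame.

    QC columns: total_pairs, classified, unclassified, conflicts,
    edited_fraction.
    """
    rows = {}
    qc = []
    for sample_id, pairs in samples.items():
        pairs = list(pairs)
        counts, total, conflicts = count_codons(pairs, design)
        rows[sample_id] = counts
        qc.append(
            {
                "sample_id": sample_id,
                "total_pairs": total,
                "classified": total - counts["unclassified"],
                "unclassified": counts["unclassified"],
                "conflicts": conflicts,
                "edited_fraction": detect_edited_fraction(pairs, design),
            }
        )
    frame = pd.DataFrame.from_dict(rows, orient="index")
    totals = pd.Series({q["sample_id"]: q["total_pairs"] for q in qc})
    return CodonCountTable(frame, totals), pd.DataFrame(qc).set_index("sample_id")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream co-ordered mate pairs from two (optionally gzipped) FASTQ files."""
    from Bio import SeqIO

    def _open(p):
        p = Path(p)
        return gzip.open(p, "rt") if p.suffix == ".gz" else open(p)

    with _open(path1) as h1, _open(path2) as h2:
        it1 = SeqIO.parse(h1, "fastq")
        it2 = SeqIO.parse(h2, "fastq")
        for r1 in it1:
            try:
                r2 = next(it2)
            except StopIteration:
                raise CountingError("mate-count mismatch between FASTQ files")
            yield str(r1.seq), str(r2.seq)
        if next(it2, None) is not None:
            raise CountingError("mate-count mismatch between FASTQ files")
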