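"""Synonymous gene recoding and single-stranded editing-template design.

Two design tasks for marker-free CRISPR saturation mutagenesis of a
multicopy gene family complemented by a single ectopic copy:

* :func:`recode_cds` — recode a coding sequence so that every codon's third
  base is G or C (favouring expression) while eliminating each supplied
  Cas9 guide site (PAM destroyed, protospacer mismatched), with the minimal
  number of base changes.
* :func:`design_ssodn` — build a single-stranded oligodeoxynucleotide (ssODN)
  repair template carrying a randomized (``NNN``), specific, or deleted codon
  at a target residue, flanked by homology arms, with synonymous "tag" bases
  that protect the edited allele from re-cutting and create a novel
  primer-binding site for selective amplification of edited molecules.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product

from ._genetics import (
    CODON_TO_AA,
    STOP_CODONS,
    hamming,
    revcomp,
    synonymous_codons,
    translate,
)

_PAM_RE = re.compile(r"[ACGT]GG")


class DesignError(ValueError):
    """A template-design constraint cannot be satisfied."""


class GuideNotFoundError(DesignError):
    """The guide's protospacer+PAM does not occur in the reference."""


@dataclass(frozen=True)
class GuideSite:
    """A Cas9 target: 20-nt protospacer followed by an NGG PAM.

    ``cut_offset`` optionally records the blunt-cut position relative to the
    start codon (Cas9 cuts between protospacer positions 17 and 18).
    """

    protospacer: str
    pam: str
    strand: str = "+"
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if not _PAM_RE.fullmatch(self.pam.upper()):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam", self.pam.upper())

    @property
    def site(self) -> str:
        """protospacer+PAM in guide orientation (23 nt)."""
        return self.protospacer + self.pam


@dataclass(frozen=True)
class EditTemplate:
    """A designed ssODN: homology arms around a tagged, codon-edited core.

    ``tag_positions`` lists synonymous changes as (reference offset,
    reference base, new base). ``codon_spec`` is ``"NNN"``, a literal codon,
    or ``"del"`` for a codon deletion.
    """

    sequence: str
    left_arm: str
    right_arm: str
    codon_spec: str
    tag_positions: tuple[tuple[int, str, str], ...] = field(default_factory=tuple)


def find_guide(seq: str, guide: GuideSite) -> tuple[int, str]:
    """Locate the guide's 23-nt site in ``seq``; return (start, strand).

    Searches both orientations regardless of the guide's nominal strand;
    raises :class:`GuideNotFoundError` if absent.
    """
    site = guide.site
    i = seq.find(site)
    if i >= 0:
        return i, "+"
    i = seq.find(revcomp(site))
    if i >= 0:
        return i, "-"
    raise GuideNotFoundError(f"guide {guide.protospacer}+{guide.pam} not found")


def cas9_site_intact(seq: str, guide: GuideSite) -> bool:
    """Exact Cas9 re-search: does protospacer+PAM occur on either strand?"""
    site = guide.site
    return site in seq or revcomp(site) in seq


def _guide_disrupted(
    region: str, orig_region: str, strand: str, *, require_both: bool
) -> bool:
    """Check PAM loss / protospacer mismatches for a 23-nt site region.

    ``region`` is the edited sequence over the original site span in genomic
    orientation; for ``-`` sites it is reverse-complemented before scoring.
    """
    if strand == "-":
        region = revcomp(region)
        orig_region = revcomp(orig_region)
    proto_mm = hamming(region[:20], orig_region[:20])
    pam_lost = not (region[21] == "G" and region[22] == "G")
    if require_both:
        return pam_lost and proto_mm >= 2
    return pam_lost or proto_mm >= 2


def _codon_span(lo: int, hi: int, n: int) -> tuple[int, int]:
    """Smallest codon-aligned window covering [lo, hi), clipped to [0, n)."""
    return max(0, lo - lo % 3), min(n, hi + (-hi) % 3)


def recode_cds(
    cds: str, guides: tuple[GuideSite, ...] | list[GuideSite] = ()
) -> tuple[str, int]:
    """Recode a CDS so every third codon position is G or C.

    The translation is unchanged. For each guide located in the CDS, the
    recoded sequence destroys the PAM and mismatches >=2 protospacer bases
    (both when jointly achievable with synonymous G/C-third codons, at least
    one otherwise). Among valid assignments the one changing the fewest
    bases is chosen; ties break toward the alphabetically smallest codon
    string. Returns ``(recoded_sequence, number_of_changed_bases)``.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    protein = translate(cds)
    if "X" in protein[:-1]:
        raise ValueError("internal stop codon in CDS")

    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    # per-codon minimal G/C-third choice, deterministic
    best = [
        min(synonymous_codons(c, gc_third=True), key=lambda s: (hamming(c, s), s))
        for c in codons
    ]

    sites = [find_guide(cds, g) for g in guides]
    # merge overlapping guide windows so joint constraints are solved jointly
    windows: list[tuple[int, int, list[int]]] = []  # (start, end, site indices)
    for k, (start, _) in enumerate(sites):
        lo, hi = _codon_span(start, start + 23, len(cds))
        for w in windows:
            if lo < w[1] and hi > w[0]:
                w_lo, w_hi = min(lo, w[0]), max(hi, w[1])
                windows.remove(w)
                lo, hi, k_list = w_lo, w_hi, w[2] + [k]
                break
        else:
            k_list = [k]
        windows.append((lo, hi, k_list))

    for lo, hi, k_list in windows:
        idx = range(lo // 3, hi // 3)
        option_sets = [synonymous_codons(codons[i], gc_third=True) for i in idx]

        def satisfied(assign: tuple[str, ...], both: bool) -> bool:
            edited = dict(zip(idx, assign))
            seq_w = "".join(edited[i] for i in idx)
            for k in k_list:
                start, strand = sites[k]
                region = _build_region(seq_w, lo, start, start + 23, cds)
                if not _guide_disrupted(
                    region, cds[start : start + 23], strand, require_both=both
                ):
                    return False
            return True

        def _build_region(seq_w: str, w_lo: int, a: int, b: int, ref: str) -> str:
            # site span may poke outside the codon-aligned window at sequence ends
            left = ref[a:w_lo] if a < w_lo else ""
            right = ref[w_lo + len(seq_w) : b] if b > w_lo + len(seq_w) else ""
            core = seq_w[max(0, a - w_lo) : b - w_lo]
            return left + core + right

        solution = None
        for both in (True, False):
            candidates = (
                (sum(hamming(codons[i], a) for i, a in zip(idx, assign)),
                 "".join(assign), assign)
                for assign in product(*option_sets)
                if satisfied(assign, both)
            )
            solution = min(candidates, default=None)
            if solution is not None:
                break
        if solution is None:
            raise DesignError(
                "guide site cannot be disrupted with synonymous G/C-third codons"
            )
        for i, a in zip(idx, solution[2]):
            best[i] = a

    recoded = "".join(best)
    assert translate(recoded) == protein
    return recoded, hamming(cds, recoded)


def _max_change_tags(
    ref: str,
    core_lo: int,
    core_hi: int,
    target_span: tuple[int, int],
    site_start: int,
    site_strand: str,
) -> dict[int, str]:
    """Choose synonymous tag codons within the guide site.

    For each whole codon of [core_lo, core_hi) overlapping the 23-nt guide
    site and not the randomized target codon, pick the synonymous codon with
    the most base changes (ties: alphabetically smallest). Returns
    {codon start offset: new codon}.
    """
    tags: dict[int, str] = {}
    for pos in range(core_lo, core_hi, 3):
        if pos >= target_span[0] and pos < target_span[1]:
            continue
        if pos + 3 <= site_start or pos >= site_start + 23:
            continue
        orig = ref[pos : pos + 3]
        alt = max(synonymous_codons(orig), key=lambda s: (hamming(orig, s), [-ord(c) for c in s]))
        if alt != orig:
            tags[pos] = alt
    return tags


def design_ssodn(
    reference: str,
    target_codon_index: int,
    guide: GuideSite,
    codon_spec: str,
    arm_len: int = 25,
    primer_len: int = 20,
) -> EditTemplate:
    """Design an ssODN repair template for one codon of ``reference``.

    The template is ``left_arm + edited_core + right_arm`` where the core
    covers the target codon and the guide site. Synonymous tag codons inside
    the guide site (i) destroy the PAM, (ii) mismatch the protospacer, and
    (iii) create a tagged ``primer_len``-mer absent from the unedited
    reference (checked by exact search of both strands). ``codon_spec`` is
    ``"NNN"`` (randomized, IUPAC semantics), a specific codon, or ``"del"``.
    """
    reference = reference.upper()
    if len(reference) % 3:
        raise ValueError("reference length must be divisible by 3")
    t0, t1 = target_codon_index * 3, target_codon_index * 3 + 3
    if t1 > len(reference):
        raise DesignError("target codon outside reference")
    spec = codon_spec.upper()
    if spec not in ("NNN", "DEL") and (len(spec) != 3 or any(b not in "ACGT" for b in spec)):
        raise ValueError(f"codon_spec {codon_spec!r} must be 'NNN', 'del' or a codon")

    site_start, site_strand = find_guide(reference, guide)
    lo, hi = _codon_span(min(site_start, t0), max(site_start + 23, t1), len(reference))

    tags = _max_change_tags(reference, lo, hi, (t0, t1), site_start, site_strand)
    tagged = list(reference)
    tag_positions = []
    for pos, alt in sorted(tags.items()):
        for j, b in enumerate(alt):
            if reference[pos + j] != b:
                tag_positions.append((pos + j, reference[pos + j], b))
            tagged[pos + j] = b
    tagged_seq = "".join(tagged)

    # PAM must be gone from tag changes alone (the randomized codon cannot be
    # relied on to disrupt it: it may regenerate any base).
    region = tagged_seq[site_start : site_start + 23]
    if not _guide_disrupted(
        region, reference[site_start : site_start + 23], site_strand, require_both=False
    ) or not _pam_destroyed(region, reference[site_start : site_start + 23], site_strand):
        raise DesignError(
            "cannot destroy PAM with synonymous tag changes: PAM lies in codons "
            "without distinguishing synonyms (or in the randomized codon)"
        )

    # novel primer-binding site: a tagged primer_len-mer containing the most
    # tag changes, avoiding the randomized codon, absent from the reference.
    # The window may run into the homology arms — those bases match the
    # reference, so novelty must come from the tag changes it covers.
    tag_offsets = [p for p, _, _ in tag_positions]
    best_kmer = None
    w_lo = max(0, lo - arm_len)
    w_hi = min(len(tagged_seq) - primer_len, hi + arm_len - primer_len)
    for start in range(w_lo, w_hi + 1):
        if start < t1 and start + primer_len > t0:
            continue  # overlaps the randomized codon
        kmer = tagged_seq[start : start + primer_len]
        n_tags = sum(start <= p < start + primer_len for p in tag_offsets)
        novel = kmer not in reference and revcomp(kmer) not in reference
        cand = (novel, n_tags, -start)
        if best_kmer is None or cand > best_kmer[0]:
            best_kmer = (cand, kmer)
    if best_kmer is None or not best_kmer[0][0]:
        raise DesignError("no tagged k-mer is novel with respect to the reference")

    # apply the codon edit
    core = tagged_seq[lo:t0] + ("" if spec == "DEL" else spec) + tagged_seq[t1:hi]
    if spec == "DEL":
        edited_full = tagged_seq[:t0] + tagged_seq[t1:]
        if cas9_site_intact(edited_full, guide):
            raise DesignError("codon deletion recreates the guide site")

    if arm_len > lo or hi + arm_len > len(reference):
        raise DesignError("homology arms extend beyond the reference")
    left_arm = reference[lo - arm_len : lo]
    right_arm = reference[hi : hi + arm_len]
    return EditTemplate(
        sequence=left_arm + core + right_arm,
        left_arm=left_arm,
        right_arm=right_arm,
        codon_spec="del" if spec == "DEL" else spec,
        tag_positions=tuple(tag_positions),
    )


def _pam_destroyed(region: str, orig: str, strand: str) -> bool:
    if strand == "-":
        region, orig = revcomp(region), revcomp(orig)
    return not (region[21] == "G" and region[22] == "G")


def saturation_combinatorics(n_positions: int) -> dict[str, int]:
    """Edit-space arithmetic for an NNN saturation screen.

    Counts are recomputed from the genetic-code model: 4^3 codons per
    randomized position, the standard code's nonsense codons, and
    ``n_positions * 64`` total programmed edits.
    """
    codons = 4 ** 3
    return {
        "codons_per_position": codons,
        "nonsense_per_position": len(STOP_CODONS),
        "missense_and_sense_per_position": codons - len(STOP_CODONS),
        "total_edits": codons * n_positions,
    }


def sample_design(
    n_libraries: int = 6,
    post_delivery_timepoints: int = 4,
    predelivery_samples_per_library: int = 1,
) -> dict[str, int]:
    """Sampling arithmetic for a multi-library time-course screen.

    Each library yields one pre-delivery sample plus one sample per
    post-delivery timepoint; edited amplicons exist only post-delivery.
    """
    post = n_libraries * post_delivery_timepoints
    return {
        "post_delivery_samples": post,
        "total_samples": post + n_libraries * predelivery_samples_per_library,
    }
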