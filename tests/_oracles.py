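"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately naive re-derivations (regex scans, exhaustive
enumeration, textbook formulas) kept separate from the package code paths
they check.
"""

from __future__ import annotations

import math
import re
from itertools import product

from Bio.Data import CodonTable
from Bio.Seq import Seq

_STD = CodonTable.unambiguous_dna_by_id[1]
_ALL_CODONS = ["".join(p) for p in product("ACGT", repeat=3)]
_SYN: dict[str, list[str]] = {}
for c in _ALL_CODONS:
    aa = "*" if c in _STD.stop_codons else _STD.forward_table[c]
    _SYN.setdefault(aa, []).append(c)


def regex_count_codons(pairs, flank_left, flank_right):
    """Regex scan over all mates and orientations; mate 1 wins conflicts."""
    pat = re.compile(re.escape(flank_left) + "(...)" + re.escape(flank_right))
    counts: dict[str, int] = {}
    unclassified = 0
    for r1, r2 in pairs:
        hit = None
        for read in (r1, str(Seq(r1).reverse_complement()),
                     r2, str(Seq(r2).reverse_complement())):
            m = pat.search(read.upper())
            if m:
                hit = m.group(1)
                break
        if hit is None or any(b not in "ACGT" for b in hit):
            unclassified += 1
        else:
            counts[hit] = counts.get(hit, 0) + 1
    return counts, unclassified


def _codon_aa(c: str) -> str:
    return "*" if c in _STD.stop_codons else _STD.forward_table[c]


def brute_force_recode_changes(cds: str, guide_site: str | None = None) -> int:
    """Minimum base changes for G/C-third recoding with guide disruption.

    Codons outside the guide window take their independent minimum-change
    G/C-third synonym. Codons overlapping the 23-nt guide site (protospacer
    + NGG PAM, located on either strand) are enumerated exhaustively over
    all synonymous G/C-third options; an assignment is valid if the PAM is
    destroyed and >=2 protospacer bases differ (falling back to either
    condition alone if no assignment satisfies both).
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]

    def options(c):
        return [s for s in _SYN[_codon_aa(c)] if s[2] in "GC"]

    def mindist(c):
        return min(sum(a != b for a, b in zip(c, s)) for s in options(c))

    if guide_site is None:
        return sum(mindist(c) for c in codons)

    rc = str(Seq(guide_site).reverse_complement())
    if guide_site in cds:
        start, strand = cds.index(guide_site), "+"
    elif rc in cds:
        start, strand = cds.index(rc), "-"
    else:
        raise ValueError("guide site not present")
    lo = (start // 3) * 3
    hi = math.ceil((start + 23) / 3) * 3
    hi = min(hi, len(cds))
    window_idx = list(range(lo // 3, hi // 3))
    base = sum(mindist(codons[i]) for i in range(len(codons)) if i not in window_idx)

    orig_region = cds[start : start + 23]

    def disrupted(region, require_both):
        r, o = (region, orig_region) if strand == "+" else (
            str(Seq(region).reverse_complement()),
            str(Seq(orig_region).reverse_complement()),
        )
        mm = sum(a != b for a, b in zip(r[:20], o[:20]))
        pam_gone = not (r[21] == "G" and r[22] == "G")
        return (pam_gone and mm >= 2) if require_both else (pam_gone or mm >= 2)

    for require_both in (True, False):
        best = None
        for assign in product(*(options(codons[i]) for i in window_idx)):
            seq_w = "".join(assign)
            full = cds[:lo] + seq_w + cds[hi:]
            if not disrupted(full[start : start + 23], require_both):
                continue
            cost = sum(
                a != b for a, b in zip(cds[lo:hi], seq_w)
            )
            if best is None or cost < best:
                best = cost
        if best is not None:
            return base + best
    raise ValueError("no valid assignment")


def welch_t_p(a, b):
    """Textbook Welch statistic, Satterthwaite df, two-sided p."""
    import numpy as np
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * tdist.sf(abs(t), df)


#: Junction class by (left unit strand, right unit strand) — full enumeration.
JUNCTION_BY_STRANDS = {
    ("+", "+"): "tandem_tts_tss",
    ("-", "-"): "tandem_tts_tss",
    ("-", "+"): "divergent_start",
    ("+", "-"): "convergent_tts",
}
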