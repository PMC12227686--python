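"""Recoding and ssODN template design."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyscreen as ps
from polyscreen.design import (
    DesignError,
    GuideNotFoundError,
    cas9_site_intact,
    find_guide,
)
from polyscreen._genetics import hamming, revcomp, synonymous_codons

from _oracles import brute_force_recode_changes
from conftest import random_cds


class TestRecode:
    def test_forced_single_synonym(self):
        recoded, n = ps.recode_cds("ATGAAAAAA")
        assert recoded == "ATGAAGAAG"
        assert n == 2

    def test_every_third_base_gc(self, rng):
        cds = random_cds(rng, 80)
        recoded, _ = ps.recode_cds(cds)
        assert all(recoded[i] in "GC" for i in range(2, len(recoded), 3))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_translation_preserved(self, seed):
        cds = random_cds(np.random.default_rng(seed), 30)
        recoded, _ = ps.recode_cds(cds)
        assert ps.translate(recoded) == ps.translate(cds)

    def test_idempotent(self, rng):
        cds = random_cds(rng, 60)
        once, _ = ps.recode_cds(cds)
        twice, n = ps.recode_cds(once)
        assert twice == once
        assert n == 0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ps.recode_cds("ATGA")  # not a codon multiple
        with pytest.raises(ValueError):
            ps.recode_cds("ATGTAAAAA")  # internal stop

    def test_guide_not_found_rejected(self, rng):
        cds = random_cds(rng, 40)
        guide = ps.GuideSite("A" * 20, "TGG")
        with pytest.raises(GuideNotFoundError):
            ps.recode_cds(cds, (guide,))


def _plant_guide(rng, n_codons=100):
    """Random CDS with a located NGG site usable as a guide."""
    while True:
        cds = random_cds(rng, n_codons)
        for start in range(10, len(cds) - 23):
            if cds[start + 21] == "G" and cds[start + 22] == "G":
                guide = ps.GuideSite(cds[start : start + 20], cds[start + 20 : start + 23])
                return cds, guide, start


class TestGuideDisruption:
    def test_site_eliminated_and_mismatched(self, rng):
        cds, guide, start = _plant_guide(rng)
        recoded, _ = ps.recode_cds(cds, (guide,))
        assert not cas9_site_intact(recoded, guide)
        region = recoded[start : start + 23]
        assert not (region[21] == "G" and region[22] == "G")  # PAM gone
        assert hamming(region[:20], guide.protospacer) >= 2

    @pytest.mark.parametrize("seed", range(8))
    def test_change_count_matches_bruteforce(self, seed):
        """Exhaustive per-codon constrained search gives the same minimum."""
        rng = np.random.default_rng(1000 + seed)
        cds, guide, _ = _plant_guide(rng, n_codons=100)
        _, n = ps.recode_cds(cds, (guide,))
        assert n == brute_force_recode_changes(cds, guide.site)

    @pytest.mark.parametrize("seed", range(4))
    def test_change_count_matches_bruteforce_no_guide(self, seed):
        rng = np.random.default_rng(2000 + seed)
        cds = random_cds(rng, 100)
        _, n = ps.recode_cds(cds)
        assert n == brute_force_recode_changes(cds)


@pytest.fixture
def reference_and_guide(rng):
    return _plant_guide(rng, n_codons=80)


class TestSsodn:
    def test_construction_arithmetic(self, reference_and_guide):
        ref, guide, start = reference_and_guide
        idx = start // 3 + 1  # codon inside the guide window
        tpl = ps.design_ssodn(ref, idx, guide, "NNN", arm_len=25)
        assert tpl.left_arm in ref and tpl.right_arm in ref
        assert len(tpl.left_arm) == len(tpl.right_arm) == 25
        core_len = len(tpl.sequence) - 50
        assert tpl.sequence == tpl.left_arm + tpl.sequence[25:25 + core_len] + tpl.right_arm
        assert "NNN" in tpl.sequence

    def test_arms_flank_core_exactly(self, reference_and_guide):
        ref, guide, start = reference_and_guide
        idx = start // 3 + 1
        tpl = ps.design_ssodn(ref, idx, guide, "NNN")
        i = ref.index(tpl.left_arm)
        j = ref.index(tpl.right_arm)
        assert i + 25 <= j  # arms in order, separated by the replaced core

    def test_synonymous_codon_keeps_translation(self, reference_and_guide):
        ref, guide, start = reference_and_guide
        idx = start // 3 + 1
        orig = ref[idx * 3 : idx * 3 + 3]
        syn = next(c for c in synonymous_codons(orig) if c != orig) \
            if len(synonymous_codons(orig)) > 1 else orig
        tpl = ps.design_ssodn(ref, idx, guide, syn)
        edited = _apply_template(ref, tpl)
        assert ps.translate(edited) == ps.translate(ref)

    def test_deletion_drops_one_residue(self, reference_and_guide):
        ref, guide, start = reference_and_guide
        idx = start // 3 + 1
        try:
            tpl = ps.design_ssodn(ref, idx, guide, "del")
        except DesignError:
            pytest.skip("deletion recreates guide in this layout")
        edited = _apply_template(ref, tpl)
        prot_ref, prot_ed = ps.translate(ref), ps.translate(edited)
        assert len(prot_ed) == len(prot_ref) - 1
        assert prot_ed == prot_ref[:idx] + prot_ref[idx + 1 :]

    def test_edited_sequence_escapes_cas9(self, reference_and_guide):
        """Re-simulated Cas9 search finds no protospacer+PAM hit."""
        ref, guide, start = reference_and_guide
        idx = start // 3 + 1
        tpl = ps.design_ssodn(ref, idx, guide, "AAG")
        edited = _apply_template(ref, tpl)
        assert not cas9_site_intact(edited, guide)

    def test_tagged_kmer_novel(self, reference_and_guide):
        ref, guide, start = reference_and_guide
        idx = start // 3 + 1
        tpl = ps.design_ssodn(ref, idx, guide, "AAG")
        edited = _apply_template(ref, tpl)
        # some 20-mer of the edited core is absent from the unedited locus
        core = tpl.sequence[25:-25]
        novel = [
            core[i : i + 20]
            for i in range(len(core) - 19)
            if core[i : i + 20] not in ref and revcomp(core[i : i + 20]) not in ref
        ]
        assert novel

    def test_tags_are_synonymous(self, reference_and_guide):
        ref, guide, start = reference_and_guide
        idx = start // 3 + 1
        tpl = ps.design_ssodn(ref, idx, guide, "AAG")
        tagged = list(ref)
        for off, refb, newb in tpl.tag_positions:
            assert tagged[off] == refb
            tagged[off] = newb
        assert ps.translate("".join(tagged)) == ps.translate(ref)


def _apply_template(ref: str, tpl: ps.EditTemplate) -> str:
    """Simulate perfect homology-directed repair of the template into ref."""
    i = ref.index(tpl.left_arm)
    j = ref.index(tpl.right_arm, i)
    return ref[: i + len(tpl.left_arm)] + tpl.sequence[len(tpl.left_arm):-len(tpl.right_arm)] + ref[j:]


class TestCombinatorics:
    def test_edit_space(self):
        three = ps.saturation_combinatorics(3)
        six = ps.saturation_combinatorics(6)
        assert three["codons_per_position"] == 64
        assert three["nonsense_per_position"] == 3
        assert three["total_edits"] == 192
        assert six["total_edits"] == 384

    def test_sample_arithmetic(self):
        d = ps.sample_design(n_libraries=6, post_delivery_timepoints=4)
        assert d["post_delivery_samples"] == 24
        assert d["total_samples"] == 30


class TestGuideSite:
    def test_validation(self):
        with pytest.raises(ValueError):
            ps.GuideSite("ACGT", "AGG")
        with pytest.raises(ValueError):
            ps.GuideSite("A" * 20, "ATT")

    def test_find_guide_reverse_strand(self, rng):
        cds, guide, start = _plant_guide(rng, 50)
        rc = revcomp(cds)
        pos, strand = find_guide(rc, guide)
        assert strand == "-"
        assert rc[pos : pos + 23] == revcomp(guide.site)
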