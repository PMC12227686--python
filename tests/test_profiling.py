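"""Depth normalization, baseline ratios, amino-acid aggregation, tolerance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyscreen as ps
from polyscreen.counting import CodonCountTable
from polyscreen.profiling import ProfilingError


def _table(counts_by_sample: dict[str, dict[str, int]]) -> CodonCountTable:
    frame = pd.DataFrame.from_dict(counts_by_sample, orient="index").fillna(0)
    return CodonCountTable(frame, frame.sum(axis=1))


class TestDepthNormalize:
    def test_factor_arithmetic(self):
        # totals {100, 300} -> factors {0.5, 1.5}; a count of 10 in s1 -> 20
        t = _table({"s1": {"AAA": 10, "AAC": 90}, "s2": {"AAA": 100, "AAC": 200}})
        norm = ps.depth_normalize(t)
        assert norm.loc["s1", "AAA"] == pytest.approx(20.0)
        assert norm.loc["s2", "AAA"] == pytest.approx(100 / 1.5)

    def test_single_sample_unchanged(self):
        t = _table({"s1": {"AAA": 7, "TTT": 3}})
        norm = ps.depth_normalize(t)
        assert norm.loc["s1", "AAA"] == pytest.approx(7.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_mean_total_conserved(self, seed):
        rng = np.random.default_rng(seed)
        counts = {
            f"s{i}": {c: int(n) for c, n in zip(ps.CODONS, rng.integers(1, 500, 64))}
            for i in range(6)
        }
        t = _table(counts)
        norm = ps.depth_normalize(t)
        raw_totals = t.codon_counts.sum(axis=1)
        assert np.allclose(norm.sum(axis=1), raw_totals.mean())
        assert norm.sum(axis=1).mean() == pytest.approx(raw_totals.mean())

    def test_zero_total_rejected(self):
        t = _table({"s1": {"AAA": 0}, "s2": {"AAA": 5}})
        with pytest.raises(ProfilingError, match="zero-total"):
            ps.depth_normalize(t)


class TestAverageReplicates:
    def test_identical_replicates_unchanged(self):
        t = _table({"a": {"AAA": 10, "CCC": 4}, "b": {"AAA": 10, "CCC": 4}})
        man = pd.DataFrame({"sample_id": ["a", "b"], "day": [2.0, 2.0]})
        out = ps.average_replicates(t.codon_counts.astype(float), man)
        assert out.loc[2.0, "AAA"] == 10

    def test_mean_of_pair(self):
        t = _table({"a": {"AAA": 0}, "b": {"AAA": 10}})
        man = pd.DataFrame({"sample_id": ["a", "b"], "day": [4.0, 4.0]})
        out = ps.average_replicates(t.codon_counts.astype(float), man)
        assert out.loc[4.0, "AAA"] == 5

    def test_random_pair_equals_explicit_mean(self, rng):
        vals = rng.integers(0, 100, size=(4, 64)).astype(float)
        frame = pd.DataFrame(vals, index=list("abcd"), columns=list(ps.CODONS))
        man = pd.DataFrame(
            {"sample_id": list("abcd"), "day": [1.0, 1.0, 3.0, 3.0]}
        )
        out = ps.average_replicates(frame, man)
        assert np.allclose(out.loc[1.0], vals[:2].mean(axis=0))
        assert np.allclose(out.loc[3.0], vals[2:].mean(axis=0))

    def test_missing_replicate_warns(self):
        t = _table({"a": {"AAA": 4}, "b": {"AAA": 6}, "c": {"AAA": 8}})
        man = pd.DataFrame(
            {"sample_id": list("abc"), "day": [0.5, 0.5, 2.0]}
        )
        with pytest.warns(UserWarning, match="unequal replicate"):
            out = ps.average_replicates(t.codon_counts.astype(float), man)
        assert out.loc[2.0, "AAA"] == 8


class TestRelativeToBaseline:
    def test_constant_counts_score_one(self):
        frame = pd.DataFrame(
            {c: [40.0, 40.0, 40.0] for c in ps.CODONS}, index=[0.5, 2.0, 4.0]
        )
        scores = ps.relative_to_baseline(frame)
        assert np.allclose(scores.to_numpy(), 1.0)

    def test_halving_series(self):
        frame = pd.DataFrame({c: [8.0, 4.0, 2.0, 1.0] for c in ps.CODONS},
                             index=[0.5, 2.0, 4.0, 6.0])
        scores = ps.relative_to_baseline(frame, eps=0.0)
        assert np.allclose(scores.loc["AAA"], [1.0, 0.5, 0.25, 0.125])

    def test_baseline_column_is_one(self, rng):
        frame = pd.DataFrame(
            rng.integers(1, 200, size=(3, 64)).astype(float),
            index=[0.5, 2.0, 6.0], columns=list(ps.CODONS),
        )
        scores = ps.relative_to_baseline(frame)
        assert np.allclose(scores[0.5], 1.0)

    def test_missing_baseline_rejected(self):
        frame = pd.DataFrame({c: [1.0] for c in ps.CODONS}, index=[2.0])
        with pytest.raises(ProfilingError):
            ps.relative_to_baseline(frame, baseline_day=0.5)


class TestAminoAcidAggregation:
    def test_uniform_synonyms(self):
        frame = pd.DataFrame({2.0: 0.2}, index=list(ps.CODONS))
        aa = ps.aggregate_amino_acids(frame)
        assert aa.loc["L", 2.0] == pytest.approx(0.2)  # six leucine codons
        assert aa.loc["X", 2.0] == pytest.approx(0.2)  # pooled stops

    def test_matches_bruteforce_mean(self, rng):
        frame = pd.DataFrame(
            rng.random(size=(64, 3)), index=list(ps.CODONS), columns=[0.5, 2.0, 4.0]
        )
        aa = ps.aggregate_amino_acids(frame)
        for residue in ps.AMINO_ACIDS:
            syn = [c for c in ps.CODONS if ps.CODON_TO_AA[c] == residue]
            assert np.allclose(aa.loc[residue], frame.loc[syn].mean(axis=0))

    def test_stop_class_pools_three_codons(self):
        assert len([c for c in ps.CODONS if ps.CODON_TO_AA[c] == "X"]) == 3


class TestTolerance:
    def test_reference_weight_zero(self, rng):
        aa = pd.DataFrame(rng.uniform(0.1, 1, size=(21, 2)),
                          index=list(ps.AMINO_ACIDS), columns=[0.5, 6.0])
        calls, weights = ps.call_tolerance(aa, 6.0)
        assert weights["K"] == pytest.approx(0.0)
        assert calls["K"] == "tolerated"

    def test_threshold_classes(self):
        aa = pd.DataFrame(
            {6.0: [1.0, 0.6, 0.01]}, index=["K", "R", "X"]
        )
        calls, w = ps.call_tolerance(aa, 6.0, theta_hi=-1, theta_lo=-3)
        assert calls == {"K": "tolerated", "R": "tolerated", "X": "not_tolerated"}

    def test_missing_reference_rejected(self):
        aa = pd.DataFrame({6.0: [1.0]}, index=["R"])
        with pytest.raises(ProfilingError):
            ps.call_tolerance(aa, 6.0)


class TestPoolLibraries:
    def test_identical_libraries(self, small_screen_counts):
        table, _ = small_screen_counts
        pooled, conc = ps.pool_libraries({"A": table, "B": table})
        assert (pooled.counts == 2 * table.counts).all().all()
        assert conc.log_count_r.iloc[0] == pytest.approx(1.0)

    def test_single_library_identity(self, small_screen_counts):
        table, _ = small_screen_counts
        pooled, conc = ps.pool_libraries({"A": table})
        assert (pooled.counts == table.counts).all().all()
        assert conc.empty

    def test_pool_equals_recompute_from_summed_counts(self, small_screen_counts, rng):
        table, _ = small_screen_counts
        other = CodonCountTable(
            (table.counts * 3).astype(float), table.total_pairs * 3
        )
        pooled, _ = ps.pool_libraries({"A": table, "B": other})
        assert np.allclose(pooled.counts, table.counts * 4)


class TestScaleInvariance:
    def test_profiles_unchanged_by_global_scaling(self, small_screen_counts, small_screen):
        table, _ = small_screen_counts
        scaled = CodonCountTable(table.counts * 10, table.total_pairs * 10)
        p1 = ps.profile_screen(table, small_screen.manifest)
        p2 = ps.profile_screen(scaled, small_screen.manifest)
        # the pseudo-count breaks exact equality where counts hit zero
        # (lethal codons at late days); compare the well-populated entries
        mask = p1.codon_scores > 0.05
        ratio = (p2.codon_scores / p1.codon_scores)[mask]
        assert np.nanmax(np.abs(np.log(ratio.to_numpy(dtype=float)))) < 0.05
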