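"""Codon counts -> normalized, baseline-relative fitness profiles.

The scoring chain mirrors the standard depth-correction / replicate-average
/ baseline-ratio treatment of time-course saturation-mutagenesis counts:

1. :func:`depth_normalize` — divide each sample's counts by the correction
   factor ``sample total / mean total across samples``.
2. :func:`average_replicates` — arithmetic mean of biological replicates at
   each timepoint.
3. :func:`relative_to_baseline` — ratio to the earliest (12 h = day 0.5)
   timepoint, with a pseudo-count guarding finite-depth zeros.
4. :func:`aggregate_amino_acids` — mean over synonymous codons; the three
   nonsense codons pool into class ``X``.
5. :func:`call_tolerance` — log2 enrichment versus the wild-type residue at
   the final day, thresholded into tolerated / intermediate / not_tolerated.

Scores are dimensionless, baseline = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._genetics import AMINO_ACIDS, CODON_TO_AA, CODONS
from .counting import CodonCountTable

DEFAULT_EPS = 0.5
DEFAULT_THETA_HI = -1.0
DEFAULT_THETA_LO = -3.0


class ProfilingError(ValueError):
    pass


@dataclass
class FitnessProfile:
    """Baseline-relative scores for one randomized position.

    ``codon_scores``: 64 codons x timepoints (days); ``aa_scores``: 21
    classes (20 amino acids + stop ``X``) x timepoints; ``logo_weights``:
    signed log2 enrichment vs the wild-type residue at the final day;
    ``tolerance``: per-class call at the final day.
    """

    codon_scores: pd.DataFrame
    aa_scores: pd.DataFrame
    logo_weights: pd.Series
    tolerance: dict[str, str]
    baseline_day: float
    final_day: float


def depth_normalize(table: CodonCountTable) -> pd.DataFrame:
    """Correction-factor normalization of a codon count table.

    ``factor_s = total_s / mean(totals)``; every codon count of sample *s*
    is divided by ``factor_s``. Totals are the classified codon counts. The
    mean of normalized totals equals the mean of raw totals. Returns a
    samples x 64 float frame.
    """
    counts = table.codon_counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ProfilingError(f"zero-total sample(s): {bad}")
    factors = totals / totals.mean()
    return counts.div(factors, axis=0)


def average_replicates(
    normalized: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Mean over biological replicates at each timepoint.

    ``manifest`` maps ``sample_id`` to ``day`` (and optionally ``replicate``,
    ``library``). Returns a days x 64 frame indexed by day. Timepoints with
    fewer replicates than others are averaged over what is present (with a
    warning).
    """
    import warnings

    man = manifest.set_index("sample_id") if "sample_id" in manifest.columns else manifest
    missing = normalized.index.difference(man.index)
    if len(missing):
        raise ProfilingError(f"samples absent from manifest: {list(missing)}")
    days = man.loc[normalized.index, "day"]
    n_per_day = days.value_counts()
    if n_per_day.nunique() > 1:
        warnings.warn(
            "unequal replicate counts across timepoints; averaging available",
            stacklevel=2,
        )
    return normalized.groupby(days).mean().sort_index()


def relative_to_baseline(
    per_timepoint: pd.DataFrame,
    baseline_day: float = 0.5,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Ratio of each codon's trajectory to the baseline timepoint.

    ``score[c, t] = (n[c, t] + eps) / (n[c, baseline] + eps)``; the baseline
    column is identically 1. Returns a 64 codons x days frame.
    """
    if baseline_day not in per_timepoint.index:
        raise ProfilingError(f"baseline day {baseline_day} not in table")
    base = per_timepoint.loc[baseline_day]
    scores = (per_timepoint + eps).div(base + eps, axis=1)
    return scores.T  # codons x days


def aggregate_amino_acids(codon_scores: pd.DataFrame) -> pd.DataFrame:
    """Mean score over synonymous codons, per amino-acid class and day.

    The stop class ``X`` pools TAA, TAG and TGA. Returns 21 x days.
    """
    aa = pd.Series({c: CODON_TO_AA[c] for c in codon_scores.index})
    out = codon_scores.groupby(aa).mean()
    return out.reindex(list(AMINO_ACIDS))


def call_tolerance(
    aa_scores: pd.DataFrame,
    final_day: float | None = None,
    reference_aa: str = "K",
    theta_hi: float = DEFAULT_THETA_HI,
    theta_lo: float = DEFAULT_THETA_LO,
) -> tuple[dict[str, str], pd.Series]:
    """Classify residues by final-day log2 enrichment versus the wild type.

    ``logo_weight = log2(score_aa / score_ref)`` at the final day; tolerated
    when >= ``theta_hi``, not_tolerated when <= ``theta_lo``, intermediate
    between. The reference residue itself scores 0 (tolerated by
    construction).
    """
    if final_day is None:
        final_day = aa_scores.columns.max()
    if final_day not in aa_scores.columns:
        raise ProfilingError(f"final day {final_day} not in table")
    col = aa_scores[final_day]
    if reference_aa not in col.index or not np.isfinite(col[reference_aa]) or col[reference_aa] <= 0:
        raise ProfilingError(f"reference amino acid {reference_aa!r} absent")
    weights = np.log2(col / col[reference_aa])
    calls = {}
    for aa_, w in weights.items():
        if w >= theta_hi:
            calls[aa_] = "tolerated"
        elif w <= theta_lo:
            calls[aa_] = "not_tolerated"
        else:
            calls[aa_] = "intermediate"
    return calls, weights.rename("logo_weight")


def pool_libraries(
    tables: dict[str, CodonCountTable], mode: str = "sum"
) -> tuple[CodonCountTable, pd.DataFrame]:
    """Pool duplicate-library count tables.

    ``mode='sum'`` (default) adds raw counts sample-by-sample before any
    normalization — samples are matched on index; ``mode='mean'`` averages.
    Also returns a pairwise concordance frame (Pearson r of log1p counts
    over matching samples), the tabular analogue of a replica
    principal-component concordance check.
    """
    if not tables:
        raise ProfilingError("no libraries to pool")
    names = list(tables)
    frames = [tables[n].counts for n in names]
    idx = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(idx):
            raise ProfilingError("libraries have mismatched sample indexes")
    stacked = np.stack([f.to_numpy(dtype=float) for f in frames])
    agg = stacked.sum(axis=0) if mode == "sum" else stacked.mean(axis=0)
    pooled = CodonCountTable(
        pd.DataFrame(agg, index=idx, columns=frames[0].columns),
        sum((tables[n].total_pairs for n in names[1:]), tables[names[0]].total_pairs)
        if mode == "sum"
        else sum((tables[n].total_pairs for n in names[1:]), tables[names[0]].total_pairs) / len(names),
    )
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x = np.log1p(tables[a].codon_counts.to_numpy(dtype=float)).ravel()
            y = np.log1p(tables[b].codon_counts.to_numpy(dtype=float)).ravel()
            r = float(np.corrcoef(x, y)[0, 1]) if x.std() > 0 and y.std() > 0 else np.nan
            rows.append({"library_a": a, "library_b": b, "log_count_r": r})
    return pooled, pd.DataFrame(rows)


def profile_screen(
    table: CodonCountTable,
    manifest: pd.DataFrame,
    baseline_day: float = 0.5,
    eps: float = DEFAULT_EPS,
    reference_aa: str = "K",
    theta_hi: float = DEFAULT_THETA_HI,
    theta_lo: float = DEFAULT_THETA_LO,
) -> FitnessProfile:
    """Full scoring chain for one randomized position."""
    normalized = depth_normalize(table)
    per_day = average_replicates(normalized, manifest)
    codon_scores = relative_to_baseline(per_day, baseline_day=baseline_day, eps=eps)
    aa_scores = aggregate_amino_acids(codon_scores)
    final_day = float(aa_scores.columns.max())
    tolerance, weights = call_tolerance(
        aa_scores, final_day, reference_aa, theta_hi, theta_lo
    )
    return FitnessProfile(
        codon_scores=codon_scores,
        aa_scores=aa_scores,
        logo_weights=weights,
        tolerance=tolerance,
        baseline_day=baseline_day,
        final_day=final_day,
    )
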