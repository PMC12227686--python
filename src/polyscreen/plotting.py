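"""Optional figure output: radial codon plots, logo bars, distance profiles.

Tables are the pipeline contract; these helpers render them with plain
matplotlib when figures are requested.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from ._genetics import CODONS  # noqa: E402


def radial_codon_plot(codon_scores, ax=None, log: bool = True):
    """Polar plot of per-codon scores, one ring per timepoint."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    theta = np.linspace(0, 2 * np.pi, len(CODONS), endpoint=False)
    for day in codon_scores.columns:
        vals = codon_scores[day].reindex(list(CODONS)).to_numpy(dtype=float)
        r = np.log2(vals + 1e-6) if log else vals
        ax.plot(np.append(theta, theta[0]), np.append(r, r[0]), label=f"day {day:g}")
    ax.set_xticks(theta[::4])
    ax.set_xticklabels(list(CODONS)[::4], fontsize=6)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    return ax


def logo_bar_plot(logo_weights, ax=None):
    """Signed log2 enrichment per amino-acid class as a ranked bar chart."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    w = logo_weights.sort_values(ascending=False)
    colors = ["tab:blue" if v >= 0 else "tab:red" for v in w]
    ax.bar(w.index, w.to_numpy(), color=colors)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("log2 enrichment vs WT")
    return ax


def distance_profile_plot(profile, ax=None):
    """Mean log2FC against distance-bin midpoint with SEM error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    mid = (profile.bin_start + profile.bin_end) / 2
    ax.errorbar(mid, profile["mean"], yerr=profile["sem"], fmt="o-", ms=3)
    ax.axhline(0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel("mean log2 fold-change")
    return ax
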