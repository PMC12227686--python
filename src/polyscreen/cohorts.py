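"""Cohort-level statistics over differential tables joined to gene context.

Given a differential expression/abundance table (feature_id, log2fc, fdr)
and per-gene polycistron context, these routines test whether a cohort —
e.g. genes within 10 kbp of a transcription start-site — behaves
differently from the rest of the genome:

* :func:`cohort_ttest` — Welch two-sided t on log2 fold-changes, cohort vs
  complement, with the boxplot summary (quartiles, 1.5 x IQR whiskers,
  median notch +/- 1.58 IQR / sqrt(n)).
* :func:`updown_chi2` — chi-square goodness of fit of the cohort's
  significantly up vs down counts against 50:50 (1 df, no continuity
  correction): stat = (n_up - n_down)^2 / (n_up + n_down).
* :func:`distance_profile` — binned mean log2fc versus distance to the
  flanking site.
* :func:`compare_comparisons` — total-changed ratio and decreased fraction
  between two comparisons' significant counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FDR = 0.01
DEFAULT_WINDOW = 10_000

#: Named cohort predicates over a context row set.
COHORTS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "near_tss": lambda c: c.near_tss,
    "near_tts": lambda c: c.near_tts,
    "divergent_tss": lambda c: c.near_tss & (c.tss_class == "divergent_start"),
    "convergent_tts": lambda c: c.near_tts & (c.tts_class == "convergent_tts"),
    "tandem_tss": lambda c: c.near_tss & (c.tss_class == "tandem_tts_tss"),
    "tandem_tts": lambda c: c.near_tts & (c.tts_class == "tandem_tts_tss"),
    "distal": lambda c: ~c.near_tss & ~c.near_tts,
}


class CohortError(ValueError):
    pass


@dataclass
class CohortResult:
    """Statistics for one cohort against its complement."""

    label: str
    n: int
    mean_log2fc: float
    median_log2fc: float
    t_stat: float = np.nan
    t_p: float = np.nan
    n_up: int = 0
    n_down: int = 0
    chi2_stat: float = np.nan
    chi2_p: float = np.nan
    boxplot: dict = field(default_factory=dict)


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    req = {"feature_id", "log2fc", "fdr"}
    if not req <= set(table.columns):
        raise CohortError(f"differential table needs columns {sorted(req)}")
    if not np.isfinite(table["log2fc"]).all():
        raise CohortError("non-finite log2fc")
    if ((table["fdr"] < 0) | (table["fdr"] > 1)).any():
        raise CohortError("fdr outside [0, 1]")
    return table


def _join(table: pd.DataFrame, contexts: pd.DataFrame) -> pd.DataFrame:
    joined = validate_table(table).merge(
        contexts, left_on="feature_id", right_on="gene_id", how="inner"
    )
    return joined[joined.in_unit] if "in_unit" in joined.columns else joined


def _cohort_mask(
    joined: pd.DataFrame, cohort_def: str | Callable | pd.Series
) -> pd.Series:
    if isinstance(cohort_def, str):
        try:
            fn = COHORTS[cohort_def]
        except KeyError:
            raise CohortError(
                f"unknown cohort {cohort_def!r}; known: {sorted(COHORTS)}"
            ) from None
        return fn(joined).astype(bool)
    if callable(cohort_def):
        return cohort_def(joined).astype(bool)
    return joined.feature_id.isin(cohort_def).astype(bool) if not isinstance(
        cohort_def, pd.Series
    ) else cohort_def.reindex(joined.index).fillna(False).astype(bool)


def boxplot_summary(values: np.ndarray) -> dict:
    """Quartiles, 1.5 x IQR whisker range and median notch, as in the figures."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    notch = 1.58 * iqr / np.sqrt(len(values))
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_lo": float(inside.min()) if inside.size else float("nan"),
        "whisker_hi": float(inside.max()) if inside.size else float("nan"),
        "notch_lo": float(med - notch),
        "notch_hi": float(med + notch),
        "n": int(len(values)),
    }


def cohort_ttest(
    table: pd.DataFrame,
    contexts: pd.DataFrame,
    cohort_def: str | Callable | pd.Series | Sequence[str],
    label: str | None = None,
) -> CohortResult:
    """Welch two-sided t-test of a cohort's log2fc against its complement."""
    joined = _join(table, contexts)
    mask = _cohort_mask(joined, cohort_def)
    a = joined.loc[mask, "log2fc"].to_numpy(dtype=float)
    b = joined.loc[~mask, "log2fc"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CohortError("each group needs at least 2 features")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return CohortResult(
        label=label or (cohort_def if isinstance(cohort_def, str) else "cohort"),
        n=len(a),
        mean_log2fc=float(a.mean()),
        median_log2fc=float(np.median(a)),
        t_stat=float(t),
        t_p=float(p),
        boxplot=boxplot_summary(a),
    )


def chi2_updown(n_up: int, n_down: int) -> tuple[float, float]:
    """Goodness-of-fit of (n_up, n_down) against 50:50, 1 df.

    ``stat = (n_up - n_down)^2 / (n_up + n_down)``; returns (stat, p), or
    (nan, nan) when there are no significant features.
    """
    if n_up < 0 or n_down < 0:
        raise CohortError("counts must be non-negative")
    total = n_up + n_down
    if total == 0:
        return float("nan"), float("nan")
    stat = (n_up - n_down) ** 2 / total
    return float(stat), float(stats.chi2.sf(stat, df=1))


def updown_chi2(
    table: pd.DataFrame,
    contexts: pd.DataFrame,
    cohort_def: str | Callable | pd.Series | Sequence[str],
    fdr_threshold: float = DEFAULT_FDR,
    label: str | None = None,
    versus_background: bool = False,
) -> CohortResult:
    """Chi-square test of significant up/down counts within a cohort.

    Features with ``fdr < fdr_threshold`` are signed by log2fc. By default
    the (n_up, n_down) pair is tested against a 50:50 split; with
    ``versus_background`` a 2x2 cohort-vs-complement contingency test is
    used instead.
    """
    joined = _join(table, contexts)
    mask = _cohort_mask(joined, cohort_def)
    sig = joined.fdr < fdr_threshold
    up = sig & (joined.log2fc > 0)
    down = sig & (joined.log2fc < 0)
    n_up, n_down = int((mask & up).sum()), int((mask & down).sum())
    if versus_background:
        tab = np.array(
            [[n_up, n_down], [int((~mask & up).sum()), int((~mask & down).sum())]]
        )
        if tab.sum(axis=1).min() == 0 or tab.sum(axis=0).min() == 0:
            stat, p = float("nan"), float("nan")
        else:
            stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
    else:
        stat, p = chi2_updown(n_up, n_down)
    vals = joined.loc[mask, "log2fc"]
    return CohortResult(
        label=label or (cohort_def if isinstance(cohort_def, str) else "cohort"),
        n=int(mask.sum()),
        mean_log2fc=float(vals.mean()) if len(vals) else float("nan"),
        median_log2fc=float(vals.median()) if len(vals) else float("nan"),
        n_up=n_up,
        n_down=n_down,
        chi2_stat=float(stat),
        chi2_p=float(p),
    )


def distance_profile(
    table: pd.DataFrame,
    contexts: pd.DataFrame,
    max_d: int = 50_000,
    bin_bp: int = 2_000,
    side: str = "tss",
    by_class: bool = False,
) -> pd.DataFrame:
    """Binned mean log2fc versus distance from the TSS or TTS.

    Bins cover [0, max_d); empty bins are retained with NaN mean/SEM. With
    ``by_class`` a separate series is produced per flanking-junction class.
    """
    if side not in ("tss", "tts"):
        raise CohortError("side must be 'tss' or 'tts'")
    joined = _join(table, contexts)
    d = joined[f"d_{side}"]
    edges = np.arange(0, max_d + bin_bp, bin_bp)
    joined = joined.assign(_bin=pd.cut(d, edges, right=False))
    keys = ["_bin"] + ([f"{side}_class"] if by_class else [])
    grouped = joined.groupby(keys, observed=False)["log2fc"]
    out = grouped.agg(n="count", mean="mean", sem="sem").reset_index()
    out = out.rename(columns={"_bin": "distance_bin"})
    out["bin_start"] = out.distance_bin.map(lambda b: int(b.left))
    out["bin_end"] = out.distance_bin.map(lambda b: int(b.right))
    return out.drop(columns="distance_bin")


def compare_comparisons(
    result_a: tuple[int, int], result_b: tuple[int, int]
) -> dict[str, float]:
    """Arithmetic comparison of two (n_up, n_down) significant-count pairs.

    Returns the ratio of total changed features (A over B, 1-decimal
    rounding) and the percentage of A's changed features that decreased
    (integer rounding), matching standard reporting precision.
    """
    a_up, a_down = result_a
    b_up, b_down = result_b
    if min(a_up, a_down, b_up, b_down) < 0:
        raise CohortError("counts must be non-negative")
    total_a, total_b = a_up + a_down, b_up + b_down
    if total_b == 0 or total_a == 0:
        raise CohortError("zero total significant count")
    return {
        "ratio_total_changed": round(total_a / total_b, 1),
        "percent_decreased": int(round(100 * a_down / total_a)),
    }
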