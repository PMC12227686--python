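"""Polycistronic transcription-unit maps and strand-aware gene context.

Trypanosomatid protein-coding genes are transcribed in long polycistronic
units; each unit runs from a transcription start-site (TSS) to a
termination-site (TTS) along its strand. Junctions between adjacent units
fall into three classes: divergent (two TSSs back-to-back), convergent
(two TTSs head-to-head) and tandem (one unit's TTS beside the next unit's
TSS). Gene-level context — distance from the unit's TSS and TTS measured
along the direction of transcription — drives the promoter-proximity
cohort analyses downstream.

Coordinates are 0-based half-open; distances are measured to the gene's
transcription-direction 5' end (for the TSS) and 3' end (for the TTS), so
``d_tss + gene span + d_tts == unit length``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DIVERGENT = "divergent_start"
CONVERGENT = "convergent_tts"
TANDEM = "tandem_tts_tss"
EDGE = "edge"

DEFAULT_WINDOW = 10_000


class MapError(ValueError):
    pass


@dataclass
class PolycistronMap:
    """Ordered transcription units and classified junctions.

    ``units`` columns: unit_id, chrom, strand, tss, tts, start, end (start/
    end are the genomic interval; tss/tts the oriented site coordinates).
    ``junctions`` columns: chrom, coordinate, upstream_unit, downstream_unit,
    junction_class.
    """

    units: pd.DataFrame
    junctions: pd.DataFrame


def _site_frame(sites: pd.DataFrame, role: str) -> pd.DataFrame:
    req = {"chrom", "start", "strand"}
    if not req <= set(sites.columns):
        raise MapError(f"{role} table needs columns {sorted(req)}")
    out = sites[["chrom", "start", "strand"]].copy()
    out["role"] = role
    return out


def build_map(tss_sites: pd.DataFrame, tts_sites: pd.DataFrame) -> PolycistronMap:
    """Pair TSSs with TTSs into units and classify the junctions between.

    Each TSS is paired with the next TTS in its direction of transcription
    on the same chromosome and strand; an unpaired or interleaved site is
    rejected with its coordinates. Adjacent units on a chromosome define a
    junction, classified from the roles of the two facing unit ends.
    """
    sites = pd.concat(
        [_site_frame(tss_sites, "TSS"), _site_frame(tts_sites, "TTS")],
        ignore_index=True,
    )
    units = []
    for (chrom, strand), grp in sites.groupby(["chrom", "strand"]):
        ordered = grp.sort_values("start", ascending=(strand == "+"))
        roles = ordered["role"].tolist()
        coords = ordered["start"].tolist()
        if len(roles) % 2:
            raise MapError(f"odd site count on {chrom}{strand}: {coords}")
        for i in range(0, len(roles), 2):
            if roles[i] != "TSS" or roles[i + 1] != "TTS":
                raise MapError(
                    f"unpaired TSS/TTS on {chrom}{strand} near coordinate {coords[i]}"
                )
            tss, tts = coords[i], coords[i + 1]
            start, end = (tss, tts) if strand == "+" else (tts, tss)
            units.append(
                {"chrom": chrom, "strand": strand, "tss": tss, "tts": tts,
                 "start": start, "end": end}
            )
    if not units:
        raise MapError("no units could be formed")
    udf = pd.DataFrame(units).sort_values(["chrom", "start"], ignore_index=True)
    udf.insert(0, "unit_id", [f"PTU{i + 1:03d}" for i in range(len(udf))])

    juncs = []
    for chrom, grp in udf.groupby("chrom"):
        grp = grp.sort_values("start")
        rows = grp.to_dict("records")
        for a, b in zip(rows, rows[1:]):
            if b["start"] < a["end"]:
                raise MapError(
                    f"overlapping units {a['unit_id']}/{b['unit_id']} on {chrom}"
                )
            juncs.append(
                {
                    "chrom": chrom,
                    "coordinate": (a["end"] + b["start"]) // 2,
                    "upstream_unit": a["unit_id"],
                    "downstream_unit": b["unit_id"],
                    "junction_class": classify_junction(a["strand"], b["strand"]),
                }
            )
    jdf = pd.DataFrame(
        juncs,
        columns=["chrom", "coordinate", "upstream_unit", "downstream_unit", "junction_class"],
    )
    return PolycistronMap(units=udf, junctions=jdf)


def classify_junction(left_strand: str, right_strand: str) -> str:
    """Junction class from the strands of the left and right units.

    The left unit's right-hand end is its TTS on ``+`` and its TSS on ``-``;
    mirrored for the right unit's left-hand end. Two facing TSSs are
    divergent, two facing TTSs convergent, a TTS beside a TSS tandem.
    """
    left_end = "TTS" if left_strand == "+" else "TSS"
    right_end = "TSS" if right_strand == "+" else "TTS"
    if left_end == "TSS" and right_end == "TSS":
        return DIVERGENT
    if left_end == "TTS" and right_end == "TTS":
        return CONVERGENT
    return TANDEM


def _flanking_classes(pmap: PolycistronMap) -> pd.DataFrame:
    """Per unit: junction class at its TSS end and its TTS end (or 'edge')."""
    tss_cls = {}
    tts_cls = {}
    for _, j in pmap.junctions.iterrows():
        up = pmap.units.loc[pmap.units.unit_id == j.upstream_unit].iloc[0]
        down = pmap.units.loc[pmap.units.unit_id == j.downstream_unit].iloc[0]
        # the upstream unit's right-hand end
        (tts_cls if up.strand == "+" else tss_cls)[up.unit_id] = j.junction_class
        (tss_cls if down.strand == "+" else tts_cls)[down.unit_id] = j.junction_class
    out = pmap.units[["unit_id"]].copy()
    out["tss_class"] = out.unit_id.map(tss_cls).fillna(EDGE)
    out["tts_class"] = out.unit_id.map(tts_cls).fillna(EDGE)
    return out.set_index("unit_id")


def gene_context(
    pmap: PolycistronMap, genes: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Strand-aware distances of each gene to its unit's TSS and TTS.

    ``genes`` needs gene_id, chrom, start, end. A gene is assigned to the
    unit containing its midpoint (genes spanning a junction draw a warning);
    genes outside every unit are retained with ``in_unit=False`` and NaN
    distances so cohorts can exclude them. ``near_*`` flags use strict
    ``distance < window``.

    Returns one row per gene: unit_id, strand, d_tss, d_tts, tss_class,
    tts_class, near_tss, near_tts, in_unit.
    """
    if window <= 0:
        raise MapError("window must be positive")
    flank = _flanking_classes(pmap)

    n = len(genes)
    unit_idx = np.full(n, -1)
    g_start = genes.start.to_numpy()
    g_end = genes.end.to_numpy()
    mid = (g_start + g_end) // 2
    for chrom, ugrp in pmap.units.groupby("chrom"):
        sel = (genes.chrom == chrom).to_numpy()
        if not sel.any():
            continue
        ugrp = ugrp.sort_values("start")
        starts = ugrp.start.to_numpy()
        ends = ugrp.end.to_numpy()
        pos = np.searchsorted(starts, mid[sel], side="right") - 1
        ok = (pos >= 0) & (mid[sel] < ends[np.clip(pos, 0, None)])
        idx = np.where(sel)[0]
        unit_idx[idx[ok]] = ugrp.index.to_numpy()[pos[ok]]

    in_unit = unit_idx >= 0
    safe = np.where(in_unit, unit_idx, 0)
    u = pmap.units.loc[safe].reset_index(drop=True)
    fwd = (u.strand == "+").to_numpy()
    d_tss = np.where(fwd, g_start - u.tss.to_numpy(), u.tss.to_numpy() - g_end)
    d_tts = np.where(fwd, u.tts.to_numpy() - g_end, g_start - u.tts.to_numpy())
    d_tss = np.maximum(0, d_tss).astype(float)
    d_tts = np.maximum(0, d_tts).astype(float)

    spanners = int(
        (in_unit & ((g_start < u.start.to_numpy()) | (g_end > u.end.to_numpy()))).sum()
    )
    if spanners:
        warnings.warn(
            f"{spanners} gene(s) span a unit boundary; assigned by midpoint",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "gene_id": genes.gene_id.to_numpy(),
            "unit_id": np.where(in_unit, u.unit_id.to_numpy(), None),
            "strand": np.where(in_unit, u.strand.to_numpy(), None),
            "d_tss": np.where(in_unit, d_tss, np.nan),
            "d_tts": np.where(in_unit, d_tts, np.nan),
            "tss_class": np.where(
                in_unit, flank.tss_class.reindex(u.unit_id).to_numpy(), None
            ),
            "tts_class": np.where(
                in_unit, flank.tts_class.reindex(u.unit_id).to_numpy(), None
            ),
            "near_tss": in_unit & (d_tss < window),
            "near_tts": in_unit & (d_tts < window),
            "in_unit": in_unit,
        }
    )
    return out
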