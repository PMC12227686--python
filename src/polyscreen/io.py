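"""Flat-file interchange: GFF3 genes, BED6 sites, TSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]
_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_gff3_genes(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table (gene_id, chrom, start, end, strand) as GFF3.

    Internal coordinates are 0-based half-open; GFF3 is 1-based inclusive.
    """
    with open(path, "w") as h:
        h.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            h.write(
                "\t".join(
                    [
                        str(g.chrom), "polyscreen", "gene", str(g.start + 1),
                        str(g.end), ".", str(g.strand), ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from a flat GFF3 into the internal gene table."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS, dtype={"seqid": str}
    )
    df = df[df["type"] == "gene"].copy()
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    return pd.DataFrame(
        {
            "gene_id": ids.to_numpy(),
            "chrom": df["seqid"].to_numpy(),
            "start": df["start"].to_numpy(dtype=int) - 1,
            "end": df["end"].to_numpy(dtype=int),
            "strand": df["strand"].to_numpy(),
        }
    )


def write_bed6(sites: pd.DataFrame, path: str | Path) -> None:
    sites[_BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=_BED6_COLS, dtype={"chrom": str})


def read_manifest(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t")
    if "sample_id" not in man.columns or "day" not in man.columns:
        raise ValueError("manifest needs sample_id and day columns")
    return man


def read_differential_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
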