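"""Readers and writers for the package's plain-text table dialects.

All tables are tab-separated. The hit table follows BLAST ``outfmt 6``
column order (no header) with a trailing ``qcovhsp`` column, and the depth
table follows the headerless three-column ``samtools depth`` dialect;
everything else carries a header row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .lineage import TaxLineage

#: BLAST tabular (outfmt 6) columns plus query coverage per HSP.
HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qcovhsp",
]

METADATA_COLUMNS = [
    "sample_id",
    "date",
    "site",
    "aw_fraction",
    "ice_cover_pct",
    "past_ice_cover_pct",
    "daylight_h",
    "temperature_C",
    "chlorophyll_au",
]


# -- ASV counts ------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write an ASV × sample integer count table (first column ``asv_id``)."""
    out = counts.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="asv_id")
    return df.astype(int)


# -- sample metadata -------------------------------------------------------

def write_metadata(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index=False, date_format="%Y-%m-%d")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", parse_dates=["date"])
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table is missing columns: {sorted(missing)}")
    return df


# -- lineage maps ----------------------------------------------------------

def write_lineage_map(
    lineages: Mapping[str, TaxLineage], path: str | Path, id_column: str = "asv_id"
) -> None:
    df = pd.DataFrame(
        {
            id_column: list(lineages.keys()),
            "lineage": [lin.to_string() for lin in lineages.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_lineage_map(path: str | Path) -> dict[str, TaxLineage]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    id_column = df.columns[0]
    return {
        row[id_column]: TaxLineage.from_string(row["lineage"])
        for _, row in df.iterrows()
    }


# -- alignment hit tables --------------------------------------------------

def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a headerless BLAST-outfmt-6 + ``qcovhsp`` hit table."""
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    return df


# -- depth tables ----------------------------------------------------------

def write_depth_table(depth: pd.DataFrame, path: str | Path) -> None:
    """Write a ``samtools depth``-style table (contig, 1-based pos, depth)."""
    depth[["contig", "pos", "depth"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_depth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["contig", "pos", "depth"]
    )


# -- BED (marker gene coordinates) ----------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a minimal BED table: contig, 0-based start, end, name."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name"],
        usecols=[0, 1, 2, 3],
    )
    return df
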