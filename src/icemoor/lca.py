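"""Two-stage LCA taxonomic classification of long reads from protein hits.

Open reading frames predicted on long (HiFi) reads are aligned against a
reference protein database whose subjects carry GTDB lineages. Hits are
filtered in two stages — the aligner-level thresholds (identity >= 50%,
query cover >= 60%, bitscore within 5% of the ORF's best) and a stricter
post-hoc cut (identity > 65%, e-value < 1e-10) — then each ORF receives
the lowest common ancestor of its surviving hits' lineages, and each read
the LCA of its ORFs' lineages. Functional gene counts are normalised per
sample by the average depth of 16 universal single-copy ribosomal protein
genes, turning raw counts into copies per genome equivalent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .lineage import RANKS, TaxLineage, lca

logger = logging.getLogger(__name__)

# stage-1 aligner thresholds and stage-2 post-hoc cuts
DEFAULT_ID_MIN = 50.0
DEFAULT_QCOV_MIN = 60.0
DEFAULT_TOP_PCT = 5.0
DEFAULT_PIDENT_MIN2 = 65.0
DEFAULT_EVALUE_MAX2 = 1e-10

#: default ORF-id convention: <read_id>_orf<N>
DEFAULT_ORF_PATTERN = r"^(?P<read>.+)_orf\d+$"

N_MARKER_GENES = 16


@dataclass
class ReadClassification:
    read_id: str
    lineage: TaxLineage
    deepest_rank: str
    n_orfs_used: int


def filter_hits(
    hits: pd.DataFrame,
    id_min: float = DEFAULT_ID_MIN,
    qcov_min: float = DEFAULT_QCOV_MIN,
    top_pct: float = DEFAULT_TOP_PCT,
    pident_min2: float = DEFAULT_PIDENT_MIN2,
    evalue_max2: float = DEFAULT_EVALUE_MAX2,
) -> pd.DataFrame:
    """Two-stage per-ORF hit filter.

    Stage 1 (aligner semantics): ``pident >= id_min``, ``qcovhsp >=
    qcov_min``, and bitscore within ``top_pct`` percent of the ORF's best
    surviving bitscore. Stage 2 (post-hoc): ``pident > pident_min2``
    (strict) and ``evalue < evalue_max2`` (strict). ORFs losing all their
    hits simply vanish from the result.
    """
    stage1 = hits[(hits["pident"] >= id_min) & (hits["qcovhsp"] >= qcov_min)]
    if len(stage1) == 0:
        return stage1
    best = stage1.groupby("qseqid")["bitscore"].transform("max")
    stage1 = stage1[stage1["bitscore"] >= (1 - top_pct / 100) * best]
    stage2 = stage1[
        (stage1["pident"] > pident_min2) & (stage1["evalue"] < evalue_max2)
    ]
    return stage2


def classify_orf(lineages: list[TaxLineage]) -> TaxLineage:
    """LCA over an ORF's retained hit lineages; no hits → unclassified."""
    if not lineages:
        return TaxLineage.unclassified()
    return lca(lineages)


def classify_read(
    read_id: str,
    orf_lineages: list[TaxLineage],
    include_unclassified: bool = False,
) -> ReadClassification:
    """Secondary LCA over a read's ORF lineages.

    Fully unclassified ORFs are excluded by default (an ORF with no
    reference homolog should not erase the evidence of its neighbours);
    a read with no classified ORFs is unclassified.
    """
    used = (
        orf_lineages
        if include_unclassified
        else [l for l in orf_lineages if not l.is_unclassified]
    )
    if not used:
        lineage = TaxLineage.unclassified()
    else:
        lineage = lca(used)
    return ReadClassification(
        read_id=read_id,
        lineage=lineage,
        deepest_rank=lineage.deepest_rank,
        n_orfs_used=len(used),
    )


def read_of_orf(orf_id: str, pattern: str = DEFAULT_ORF_PATTERN) -> str:
    m = re.match(pattern, orf_id)
    if not m:
        raise ValueError(f"ORF id {orf_id!r} does not match pattern {pattern!r}")
    return m.group("read")


def classify_reads(
    hits: pd.DataFrame,
    subject_lineages: Mapping[str, TaxLineage],
    orf_to_read: Mapping[str, str] | None = None,
    orf_pattern: str = DEFAULT_ORF_PATTERN,
    include_unclassified: bool = False,
    **filter_kwargs,
) -> list[ReadClassification]:
    """Full pipeline: filter hits, ORF-level LCA, then read-level LCA.

    ``orf_to_read`` maps ORF ids to read ids; when absent, read ids are
    parsed from ORF ids with ``orf_pattern``. Reads whose every ORF lost
    all hits are still reported (as unclassified).
    """
    retained = filter_hits(hits, **filter_kwargs)

    all_orfs = hits["qseqid"].unique()
    orf_lineage: dict[str, TaxLineage] = {}
    grouped = retained.groupby("qseqid")["sseqid"]
    for orf_id in all_orfs:
        if orf_id in grouped.groups:
            subjects = grouped.get_group(orf_id)
            lineages = []
            for sid in subjects:
                if sid not in subject_lineages:
                    logger.warning("subject %s has no lineage; skipped", sid)
                    continue
                lineages.append(subject_lineages[sid])
            orf_lineage[orf_id] = classify_orf(lineages)
        else:
            orf_lineage[orf_id] = TaxLineage.unclassified()

    by_read: dict[str, list[TaxLineage]] = {}
    for orf_id, lineage in orf_lineage.items():
        read_id = (
            orf_to_read[orf_id] if orf_to_read is not None else read_of_orf(orf_id, orf_pattern)
        )
        by_read.setdefault(read_id, []).append(lineage)

    return [
        classify_read(read_id, lineages, include_unclassified)
        for read_id, lineages in sorted(by_read.items())
    ]


def rank_assignment_summary(
    classifications: list[ReadClassification],
) -> pd.Series:
    """Fraction of reads assigned a name at each rank; non-increasing from
    domain to species by the prefix-truncated lineage structure."""
    n = len(classifications)
    if n == 0:
        return pd.Series(0.0, index=list(RANKS))
    counts = np.zeros(len(RANKS))
    for c in classifications:
        counts[: c.lineage.depth] += 1
    return pd.Series(counts / n, index=list(RANKS))


def classifications_table(classifications: list[ReadClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in classifications],
            "lineage": [c.lineage.to_string() for c in classifications],
            "deepest_rank": [c.deepest_rank for c in classifications],
            "n_orfs_used": [c.n_orfs_used for c in classifications],
        }
    ).set_index("read_id")


def normalize_per_genome(
    gene_counts: pd.DataFrame, ribo_depths: pd.DataFrame
) -> pd.DataFrame:
    """Scale gene counts to copies per genome equivalent.

    ``gene_counts`` is genes × samples; ``ribo_depths`` holds the 16
    single-copy ribosomal protein marker depths (rows) per sample
    (columns). Each sample's counts are divided by its marker mean depth;
    samples whose markers are all zero are excluded with a warning.
    """
    if ribo_depths.shape[0] != N_MARKER_GENES:
        raise ValueError(
            f"expected {N_MARKER_GENES} marker rows, got {ribo_depths.shape[0]}"
        )
    missing = [c for c in gene_counts.columns if c not in ribo_depths.columns]
    if missing:
        raise ValueError(f"samples without marker depths: {missing}")
    means = ribo_depths[gene_counts.columns].mean(axis=0)
    dead = means[means == 0].index.tolist()
    if dead:
        logger.warning(
            "excluding %d sample(s) with all-zero marker depths: %s", len(dead), dead
        )
    kept = [c for c in gene_counts.columns if c not in dead]
    return gene_counts[kept] / means[kept]
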