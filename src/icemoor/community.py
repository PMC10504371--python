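"""Occupancy-based community partitioning and fraction–environment links.

ASVs are split into resident / intermittent / transient fractions by how
often they are detected across a sampling time series: residents occur in
more than 90% of samples, intermittents in 25–90% (both boundaries
inclusive), transients in fewer than 25%. The per-sample summed relative
abundance of each fraction is then correlated against environmental
covariates (Atlantic-water fraction, ice cover, daylight, ...) to ask
which fraction tracks which regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .lineage import TaxLineage

RESIDENT = "resident"
INTERMITTENT = "intermittent"
TRANSIENT = "transient"
GROUPS = (RESIDENT, INTERMITTENT, TRANSIENT)

#: occupancy thresholds: f > 0.90 resident, 0.25 <= f <= 0.90 intermittent
RESIDENT_MIN_FREQUENCY = 0.90
TRANSIENT_MAX_FREQUENCY = 0.25


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined on the given input (e.g. a
    constant series offered to a Pearson correlation)."""


@dataclass
class CommunityMatrix:
    """ASV × sample count table with optional taxonomy.

    ``counts`` is indexed by ASV id with sample ids as columns. Samples
    whose column is entirely zero are dropped on construction (they carry
    no compositional information), with a warning.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, TaxLineage] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate ASV or sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        empty = self.counts.columns[(self.counts.sum(axis=0) == 0)]
        if len(empty):
            warnings.warn(
                f"dropping {len(empty)} all-zero sample(s): {list(empty)}",
                stacklevel=2,
            )
            self.counts = self.counts.drop(columns=empty)

    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalised view; each sample sums to 1."""
        return self.counts / self.counts.sum(axis=0)


@dataclass
class OccupancyRecord:
    asv_id: str
    detection_frequency: float
    group: str
    max_relative_abundance: float = field(default=float("nan"))


def detection_frequency(
    matrix: CommunityMatrix, min_count: int = 1
) -> pd.Series:
    """Fraction of samples in which each ASV reaches ``min_count`` reads."""
    if min_count < 1:
        raise ValueError("min_count must be at least 1")
    if matrix.n_samples == 0:
        raise ValueError("empty community matrix")
    detected = (matrix.counts >= min_count).sum(axis=1)
    return detected / matrix.n_samples


def classify_group(frequency: float) -> str:
    if not 0 <= frequency <= 1:
        raise ValueError(f"detection frequency {frequency} outside [0, 1]")
    if frequency > RESIDENT_MIN_FREQUENCY:
        return RESIDENT
    if frequency >= TRANSIENT_MAX_FREQUENCY:
        return INTERMITTENT
    return TRANSIENT


def classify_occupancy(
    frequencies: Mapping[str, float] | pd.Series,
    max_relabund: Mapping[str, float] | pd.Series | None = None,
) -> list[OccupancyRecord]:
    """Assign each ASV to resident / intermittent / transient.

    Boundary frequencies 0.25 and 0.90 both fall in the intermittent class
    (a closed 25–90% interval); the three classes partition [0, 1].
    """
    records = []
    for asv_id, f in dict(frequencies).items():
        records.append(
            OccupancyRecord(
                asv_id=asv_id,
                detection_frequency=float(f),
                group=classify_group(float(f)),
                max_relative_abundance=(
                    float(max_relabund[asv_id]) if max_relabund is not None else float("nan")
                ),
            )
        )
    return records


def occupancy_table(matrix: CommunityMatrix, min_count: int = 1) -> pd.DataFrame:
    """Convenience: frequency, group and max relative abundance per ASV."""
    freqs = detection_frequency(matrix, min_count)
    relab = matrix.relative_abundance().max(axis=1)
    records = classify_occupancy(freqs, relab)
    return pd.DataFrame(
        {
            "asv_id": [r.asv_id for r in records],
            "frequency": [r.detection_frequency for r in records],
            "group": [r.group for r in records],
            "max_relabund": [r.max_relative_abundance for r in records],
        }
    ).set_index("asv_id")


def group_abundance_series(
    matrix: CommunityMatrix, records: Sequence[OccupancyRecord]
) -> pd.DataFrame:
    """Per-sample summed relative abundance of each occupancy group.

    Returns a samples × 3 table whose rows sum to 1 (the groups partition
    the ASV set).
    """
    group_of = {r.asv_id: r.group for r in records}
    missing = [a for a in matrix.asv_ids if a not in group_of]
    if missing:
        raise ValueError(f"ASVs missing from occupancy records: {missing[:5]}")
    rel = matrix.relative_abundance()
    labels = pd.Series([group_of[a] for a in rel.index], index=rel.index)
    series = rel.groupby(labels).sum().T
    for g in GROUPS:
        if g not in series.columns:
            series[g] = 0.0
    return series[list(GROUPS)]


def fraction_env_correlation(
    series: pd.Series | np.ndarray, env_values: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between a fraction's abundance series and one
    environmental covariate, with a two-sided t-distribution p-value."""
    x = np.asarray(series, dtype=float)
    y = np.asarray(env_values, dtype=float)
    if len(x) != len(y):
        raise ValueError("series and covariate lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("Pearson r undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bray_curtis(matrix: CommunityMatrix) -> pd.DataFrame:
    """Sample × sample Bray-Curtis dissimilarity on relative abundances."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rel = matrix.relative_abundance().T.to_numpy()
    dist = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(dist, index=matrix.sample_ids, columns=matrix.sample_ids)


def shared_unique(
    matrix: CommunityMatrix,
    site_of_sample: Mapping[str, str],
    min_count: int = 1,
) -> dict[str, float]:
    """Proportions of detected ASVs shared between the two sites versus
    unique to each, over ASVs detected anywhere."""
    sites = sorted(set(site_of_sample.values()))
    if len(sites) != 2:
        raise ValueError(f"expected exactly two site labels, got {sites}")
    site_samples = {
        s: [c for c in matrix.sample_ids if site_of_sample[c] == s] for s in sites
    }
    for s, cols in site_samples.items():
        if not cols:
            raise ValueError(f"site {s!r} has no samples")
    detected = {
        s: (matrix.counts[cols] >= min_count).any(axis=1)
        for s, cols in site_samples.items()
    }
    a, b = sites
    any_det = detected[a] | detected[b]
    n = int(any_det.sum())
    if n == 0:
        raise ValueError("no ASV detected at either site")
    both = int((detected[a] & detected[b]).sum())
    only_a = int((detected[a] & ~detected[b]).sum())
    only_b = int((detected[b] & ~detected[a]).sum())
    return {
        "shared": both / n,
        f"unique_{a}": only_a / n,
        f"unique_{b}": only_b / n,
    }
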