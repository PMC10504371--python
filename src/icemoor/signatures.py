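"""Environmental-signature ASVs: selection, clustering, genus summaries.

An ASV is a *signature* of an environmental regime when its relative
abundance correlates with at least one covariate beyond fixed thresholds
(|r| > 0.4 at p < 0.05 by default). Signature ASVs are grouped into
clusters by the similarity of their full correlation profiles
(agglomerative, average linkage on Euclidean distance between r-vectors),
and each cluster is summarised by its prominent genera — members reaching
at least 1% relative abundance, grouped by genus, reporting each genus's
maximum abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .community import CommunityMatrix
from .network import fdr_adjust

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.4
DEFAULT_P_MAX = 0.05
DEFAULT_ABUNDANCE_CUTOFF = 0.01


@dataclass
class SignatureCluster:
    cluster_id: int
    members: list[str]
    sign_pattern: dict[str, str] = field(default_factory=dict)
    prominent_genera: dict[str, float] = field(default_factory=dict)


def env_correlation_profiles(
    matrix: CommunityMatrix,
    env: pd.DataFrame,
    covariates: list[str],
    exclude: list[str] | None = None,
    adjust_fdr: bool = False,
) -> pd.DataFrame:
    """Pearson r and p per (ASV, covariate) on relative abundances.

    Collinear covariates can be dropped via ``exclude`` (e.g. temperature
    and salinity when the Atlantic-water fraction is present). Constant ASV
    series yield NaN r/p and are flagged in the ``degenerate`` column.
    Columns: ``r_<cov>``, ``p_<cov>`` (and ``p_adj_<cov>`` when
    ``adjust_fdr``), aligned to the sample order of ``env``.
    """
    covariates = [c for c in covariates if c not in set(exclude or [])]
    missing = [c for c in covariates if c not in env.columns]
    if missing:
        raise ValueError(f"covariates absent from metadata: {missing}")
    if matrix.n_samples < 8:
        raise ValueError("need at least 8 samples for correlation profiles")
    env = env.set_index("sample_id").loc[matrix.sample_ids]
    rel = matrix.relative_abundance().to_numpy()
    n = rel.shape[1]

    out = pd.DataFrame(index=matrix.asv_ids.copy())
    degenerate = np.ptp(rel, axis=1) == 0
    for cov in covariates:
        y = env[cov].to_numpy(dtype=float)
        yc = y - y.mean()
        ynorm = np.linalg.norm(yc)
        xc = rel - rel.mean(axis=1, keepdims=True)
        xnorm = np.linalg.norm(xc, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ yc) / (xnorm * ynorm)
        r = np.clip(r, -1, 1)
        r[degenerate] = np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(r) * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(t, df=n - 2)
        p[np.abs(r) >= 1] = 0.0
        p[degenerate] = np.nan
        out[f"r_{cov}"] = r
        out[f"p_{cov}"] = p
        if adjust_fdr:
            padj = np.full_like(p, np.nan)
            ok = ~np.isnan(p)
            padj[ok] = fdr_adjust(p[ok])
            out[f"p_adj_{cov}"] = padj
    out["degenerate"] = degenerate
    if degenerate.any():
        logger.warning("%d constant ASV series marked degenerate", degenerate.sum())
    return out


def _covariates_of(profiles: pd.DataFrame) -> list[str]:
    return [c[len("r_"):] for c in profiles.columns if c.startswith("r_")]


def select_signatures(
    profiles: pd.DataFrame,
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Keep ASVs with at least one covariate at |r| strictly above
    ``r_min`` and p strictly below ``p_max``.

    Coefficient magnitude is compared, not signed value: clusters tied
    negatively to daylight or Atlantic water are signatures too. p-values
    are raw by default; pass ``use_adjusted`` to gate on BH-adjusted ones.
    """
    if not (0 < r_min < 1 and 0 < p_max < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if len(profiles) == 0:
        return profiles
    covs = _covariates_of(profiles)
    p_prefix = "p_adj_" if use_adjusted else "p_"
    keep = np.zeros(len(profiles), dtype=bool)
    for cov in covs:
        r = profiles[f"r_{cov}"].to_numpy(dtype=float)
        p = profiles[f"{p_prefix}{cov}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            keep |= (np.abs(r) > r_min) & (p < p_max)
    return profiles.loc[keep]


def cluster_profiles(
    significant: pd.DataFrame,
    k: int | str = "auto",
    k_range: tuple[int, int] = (2, 12),
    sign_r_min: float = DEFAULT_R_MIN,
) -> list[SignatureCluster]:
    """Group signature ASVs by correlation-profile similarity.

    Agglomerative clustering, average linkage, Euclidean distance on the
    r-vectors; rows are sorted by ASV id first so the result is independent
    of input order. ``k="auto"`` picks the cluster count maximising the
    silhouette score over ``k_range``. Cluster ids are assigned by
    decreasing size (ties broken by smallest member id); each cluster's
    consensus sign pattern marks a covariate +/− when the median member r
    clears ``sign_r_min`` in magnitude, else 0.
    """
    if len(significant) == 0:
        raise ValueError("no profiles to cluster")
    significant = significant.sort_index()
    covs = _covariates_of(significant)
    X = significant[[f"r_{c}" for c in covs]].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("cannot cluster degenerate (NaN) profiles")

    if k == "auto":
        lo, hi = k_range
        hi = min(hi, len(significant) - 1)
        if hi < lo:
            raise ValueError("too few profiles for automatic k selection")
        best_k, best_score = lo, -np.inf
        for kk in range(lo, hi + 1):
            labels = AgglomerativeClustering(
                n_clusters=kk, linkage="average", metric="euclidean"
            ).fit_predict(X)
            score = silhouette_score(X, labels, metric="euclidean")
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    k = int(k)
    if k > len(significant):
        raise ValueError(f"k={k} exceeds the {len(significant)} profiles")
    if k == 1 or len(significant) == 1:
        labels = np.zeros(len(significant), dtype=int)
    else:
        labels = AgglomerativeClustering(
            n_clusters=k, linkage="average", metric="euclidean"
        ).fit_predict(X)

    asv_ids = significant.index.to_numpy()
    raw_clusters: dict[int, list[str]] = {}
    for asv, lab in zip(asv_ids, labels):
        raw_clusters.setdefault(int(lab), []).append(asv)
    ordered = sorted(
        raw_clusters.values(), key=lambda m: (-len(m), min(m))
    )
    clusters = []
    for cid, members in enumerate(ordered, start=1):
        sub = significant.loc[members]
        pattern = {}
        for cov in covs:
            med = float(sub[f"r_{cov}"].median())
            if med > sign_r_min:
                pattern[cov] = "+"
            elif med < -sign_r_min:
                pattern[cov] = "-"
            else:
                pattern[cov] = "0"
        clusters.append(
            SignatureCluster(cluster_id=cid, members=sorted(members), sign_pattern=pattern)
        )
    return clusters


def prominent_genera(
    cluster: SignatureCluster,
    matrix: CommunityMatrix,
    abundance_cutoff: float = DEFAULT_ABUNDANCE_CUTOFF,
) -> dict[str, float]:
    """Per-genus maximum relative abundance among a cluster's prominent
    members.

    Members whose maximum relative abundance is below ``abundance_cutoff``
    (1% by default) are dropped; survivors are grouped by genus — or by
    their deepest assigned rank when no genus is recorded (logged) — and
    each group reports the maximum over its members' maxima.
    """
    if matrix.taxonomy is None:
        raise ValueError("community matrix carries no taxonomy")
    rel_max = matrix.relative_abundance().max(axis=1)
    out: dict[str, float] = {}
    for asv in cluster.members:
        peak = float(rel_max.get(asv, 0.0))
        if peak < abundance_cutoff:
            continue
        lineage = matrix.taxonomy.get(asv)
        if lineage is None or lineage.is_unclassified:
            logger.warning("ASV %s lacks taxonomy; grouped as 'unclassified'", asv)
            label = "unclassified"
        elif lineage.genus:
            label = lineage.genus
        else:
            label = lineage.names[lineage.depth - 1]
            logger.info(
                "ASV %s lacks a genus; grouped at %s (%s)",
                asv, lineage.deepest_rank, label,
            )
        out[label] = max(out.get(label, 0.0), peak)
    return out
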