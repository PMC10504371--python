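"""Fourier-oscillation co-occurrence networks with robustness thresholding.

Pipeline: irregular per-ASV abundance series are interpolated onto a fixed
weekly grid; for each ASV and each annual cycle the mean-removed discrete
Fourier transform yields an oscillation signal (the first K harmonics as
amplitude/phase pairs); ASV pairs are compared by Pearson correlation of
their signal vectors; p-values are Benjamini–Hochberg adjusted; and the
edge-strength cutoff is chosen by a robustness criterion — the largest
threshold at which the network's giant component survives any single node
removal (i.e. is biconnected). Centralities are computed on the final
network.

Signal vectors are built from per-harmonic Cartesian components
(a*cos(phase), a*sin(phase)) rather than raw (amplitude, phase) pairs:
phase is circular and a raw-phase vector has a discontinuity at +-pi that
corrupts correlations for pairs oscillating near the wrap point. The
Cartesian form carries the same information smoothly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_HARMONICS = 6
DEFAULT_GRID_DAYS = 7
DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.50, 0.96, 0.01), 2)


@dataclass
class OscillationSignal:
    """First-K-harmonic decomposition of one ASV's one-year series."""

    asv_id: str
    year: str
    amplitudes: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if (self.amplitudes < 0).any():
            raise ValueError("amplitudes must be non-negative")

    @property
    def cartesian(self) -> np.ndarray:
        """Interleaved (a*cos(phase), a*sin(phase)) per harmonic."""
        out = np.empty(2 * len(self.amplitudes))
        out[0::2] = self.amplitudes * np.cos(self.phases)
        out[1::2] = self.amplitudes * np.sin(self.phases)
        return out


@dataclass
class CoocNetwork:
    graph: nx.Graph
    threshold: float
    alpha: float
    node_stats: pd.DataFrame = field(default=None)


def regularize_series(
    dates, values, grid_days: int = DEFAULT_GRID_DAYS
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of an irregular series onto a fixed day grid.

    The grid starts at the first observation and steps by ``grid_days``; no
    extrapolation happens beyond the observed range (``numpy.interp`` holds
    edge values). Requires at least 4 observations spanning half a year.
    """
    dates = pd.to_datetime(pd.Series(list(dates)))
    values = np.asarray(values, dtype=float)
    if len(dates) < 4:
        raise ValueError("need at least 4 observations to regularize")
    day = (dates - dates.iloc[0]).dt.days.to_numpy(dtype=float)
    if day.max() < 182:
        raise ValueError("series must span at least half a year")
    if not np.all(np.diff(day) > 0):
        order = np.argsort(day)
        day, values = day[order], values[order]
    grid = np.arange(0, day.max() + 1, grid_days, dtype=float)
    return grid, np.interp(grid, day, values)


def oscillation_signal(
    series, n_harmonics: int = DEFAULT_HARMONICS, asv_id: str = "", year: str = ""
) -> OscillationSignal:
    """Mean-removed DFT of one regularized annual series, keeping harmonics
    1..K as (amplitude, phase).

    Amplitudes use the real-sinusoid convention ``2|F_k|/n`` so a pure
    cosine of amplitude ``a`` at harmonic k yields amplitude ``a`` there. A
    constant series yields all-zero amplitudes (valid, logged).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2 * n_harmonics + 1:
        raise ValueError(
            f"series of length {n} too short for {n_harmonics} harmonics"
        )
    x = x - x.mean()
    if np.ptp(x) == 0:
        logger.info("constant series for %s/%s: zero oscillation", asv_id, year)
    coeffs = np.fft.rfft(x)[1 : n_harmonics + 1]
    return OscillationSignal(
        asv_id=asv_id,
        year=year,
        amplitudes=2 * np.abs(coeffs) / n,
        phases=np.angle(coeffs),
    )


def signals_from_series(
    series: pd.DataFrame,
    weeks_per_year: int = 52,
    n_harmonics: int = DEFAULT_HARMONICS,
) -> dict[str, list[OscillationSignal]]:
    """Per-year oscillation signals for every ASV of a gridded weekly
    series table (ASVs x weeks, columns in time order). Years with no
    observations contribute zero-amplitude blocks."""
    n_weeks = series.shape[1]
    n_years = int(np.ceil(n_weeks / weeks_per_year))
    out: dict[str, list[OscillationSignal]] = {}
    for asv_id, row in series.iterrows():
        values = row.to_numpy(dtype=float)
        sigs = []
        for y in range(n_years):
            chunk = values[y * weeks_per_year : (y + 1) * weeks_per_year]
            if len(chunk) < 2 * n_harmonics + 1 or np.all(np.isnan(chunk)):
                logger.info("ASV %s absent in year %d: zero block", asv_id, y)
                sigs.append(
                    OscillationSignal(
                        asv_id, str(y), np.zeros(n_harmonics), np.zeros(n_harmonics)
                    )
                )
            else:
                sigs.append(
                    oscillation_signal(
                        np.nan_to_num(chunk), n_harmonics, asv_id, str(y)
                    )
                )
        out[asv_id] = sigs
    return out


def signal_vector(signals: list[OscillationSignal]) -> np.ndarray:
    """Concatenated per-year Cartesian harmonic components for one ASV."""
    return np.concatenate([s.cartesian for s in signals])


def signal_correlations(
    signals: dict[str, list[OscillationSignal]],
    method: str = "t",
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlations between all ASV pairs' signal vectors.

    Returns an edge table (``asv_i`` < ``asv_j`` lexicographically) with
    ``r`` and two-sided ``p_raw`` (t-approximation by default; set
    ``method="permutation"`` for a seeded permutation test, advisable for
    very short vectors). Zero-variance signal vectors are skipped and
    logged.
    """
    if len(signals) < 2:
        raise ValueError("need at least 2 ASVs")
    asv_ids = sorted(signals)
    vectors = {a: signal_vector(signals[a]) for a in asv_ids}
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError("signal vectors differ in length across ASVs")
    usable = []
    for a in asv_ids:
        if np.ptp(vectors[a]) == 0:
            logger.warning("zero-variance signal vector for %s: skipped", a)
        else:
            usable.append(a)
    X = np.array([vectors[a] for a in usable])
    n_comp = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    R = (Xc @ Xc.T) / np.outer(norms, norms)
    R = np.clip(R, -1.0, 1.0)

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(len(usable), k=1)
    r_flat = R[iu, ju]
    if method == "t":
        df = n_comp - 2
        with np.errstate(divide="ignore"):
            tstat = np.abs(r_flat) * np.sqrt(df / (1 - r_flat**2))
        p_flat = 2 * stats.t.sf(tstat, df)
        p_flat[np.abs(r_flat) >= 1] = 0.0
    elif method == "permutation":
        p_flat = np.empty(len(r_flat))
        for k, (i, j) in enumerate(zip(iu, ju)):
            null = np.empty(n_permutations)
            xi = Xc[i]
            for b in range(n_permutations):
                perm = rng.permutation(n_comp)
                null[b] = xi @ Xc[j][perm] / (norms[i] * norms[j])
            p_flat[k] = (np.sum(np.abs(null) >= abs(r_flat[k])) + 1) / (
                n_permutations + 1
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    edges = pd.DataFrame(
        {
            "asv_i": [usable[i] for i in iu],
            "asv_j": [usable[j] for j in ju],
            "r": r_flat,
            "p_raw": p_flat,
        }
    )
    edges["p_adj"] = fdr_adjust(edges["p_raw"].to_numpy()) if len(edges) else []
    return edges


def _pearson_p(r: float, n: int) -> float:
    """Two-sided p for Pearson r via the exact beta distribution (the
    t-distribution transform), matching ``scipy.stats.pearsonr``."""
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * np.sqrt(df / (1 - r * r))
    return 2 * stats.t.sf(t, df)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- robustness thresholding ----------------------------------------------

def _graph_at(edges: pd.DataFrame, threshold: float, alpha: float) -> nx.Graph:
    keep = edges[(edges["r"] >= threshold) & (edges["r"] > 0) & (edges["p_adj"] < alpha)]
    g = nx.Graph()
    for _, row in keep.iterrows():
        g.add_edge(row["asv_i"], row["asv_j"], r=row["r"], p_adj=row["p_adj"])
    return g


def giant_component(graph: nx.Graph) -> nx.Graph:
    if graph.number_of_nodes() == 0:
        return graph
    nodes = max(nx.connected_components(graph), key=len)
    return graph.subgraph(nodes)


def is_disrupted(graph: nx.Graph) -> bool:
    """True if the giant component contains an articulation point, i.e.
    one node's removal would disconnect it."""
    giant = giant_component(graph)
    if giant.number_of_nodes() < 3:
        return False
    return next(nx.articulation_points(giant), None) is not None


def robust_threshold(
    edges: pd.DataFrame,
    grid=DEFAULT_THRESHOLD_GRID,
    alpha: float = 0.05,
) -> float | None:
    """Largest grid threshold at which the network is non-trivial (giant
    component of >= 3 nodes) and robust to any single node removal (its
    giant component is biconnected). Below a robust threshold, weaker
    edges re-attach pendant nodes whose cut vertices would disrupt the
    network. Returns ``None`` if no grid point qualifies."""
    if len(edges) == 0:
        raise ValueError("empty edge list")
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0) or grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("grid must be ascending within (0, 1)")
    for t in grid[::-1]:
        g = _graph_at(edges, t, alpha)
        if giant_component(g).number_of_nodes() >= 3 and not is_disrupted(g):
            return float(t)
    return None


def build_network(
    edges: pd.DataFrame, threshold: float, alpha: float = 0.05
) -> CoocNetwork:
    """Retain positive, significant, strong edges and compute per-node
    degree, normalized shortest-path betweenness, and closeness centrality
    within each connected component."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    g = _graph_at(edges, threshold, alpha)
    if g.number_of_edges() == 0:
        warnings.warn("no edges survive the thresholds: empty network", stacklevel=2)
        return CoocNetwork(
            graph=g, threshold=threshold, alpha=alpha,
            node_stats=pd.DataFrame(columns=["degree", "betweenness", "closeness"]),
        )
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    stats_df = pd.DataFrame(
        {
            "degree": dict(g.degree()),
            "betweenness": betweenness,
            "closeness": closeness,
        }
    ).sort_index()
    stats_df.index.name = "asv_id"
    return CoocNetwork(graph=g, threshold=threshold, alpha=alpha, node_stats=stats_df)


def group_connectivity(
    network: CoocNetwork, groups: dict[str, str]
) -> dict[str, float]:
    """Mean degree per occupancy group over the network's nodes. Groups
    with no nodes in a non-empty network are absent from the result; an
    empty network reports 0 for every labelled group."""
    if network.graph.number_of_nodes() == 0:
        return {g: 0.0 for g in set(groups.values())}
    degrees: dict[str, list[int]] = {}
    for node, deg in network.graph.degree():
        if node not in groups:
            raise ValueError(f"node {node!r} missing a group label")
        degrees.setdefault(groups[node], []).append(deg)
    return {g: float(np.mean(d)) for g, d in degrees.items()}
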