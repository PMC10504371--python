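"""Synthetic Arctic mooring time-series data with planted ground truth.

Every downstream stage of the package is exercised on data from this
module: an environmental series emulating weekly-to-fortnightly sampling at
two East Greenland Current mooring sites at 79° N (Atlantic-water fraction,
sea-ice cover, photoperiod, temperature, chlorophyll); community count
matrices with planted resident/intermittent/transient dynamics coupled to
those covariates; ORF-vs-reference protein hit tables with known true read
lineages; and per-position genome coverage profiles with outlier regions.
Each generator records what it planted in a :class:`GroundTruth` so
recovery can be scored exactly.

All randomness flows from a single user-supplied seed through a local
``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .lineage import TaxLineage
from .magquant import DepthProfile

SITES = ("MIZ", "core-EGC")

#: covariates offered for environmental coupling, in metadata column order
COUPLING_COVARIATES = (
    "aw_fraction",
    "ice_cover_pct",
    "past_ice_cover_pct",
    "daylight_h",
    "temperature_C",
)


@dataclass
class GroundTruth:
    """What a generator planted, keyed so recovery tests can score exactly.

    Only the fields relevant to the producing generator are populated.
    """

    asv_labels: dict[str, str] = field(default_factory=dict)
    coupling: dict[str, dict[str, float]] = field(default_factory=dict)
    seasonal: dict[str, tuple[float, float]] = field(default_factory=dict)
    genus_map: dict[str, str] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)
    read_lineages: dict[str, TaxLineage] = field(default_factory=dict)
    #: noise-free abundance series (oscillation generator only)
    latent_series: pd.DataFrame | None = None
    #: planted (asv_a, asv_b, co_oscillating) tuples (oscillation generator)
    pairs: list[tuple[str, str, bool]] | None = None


# -- photoperiod -----------------------------------------------------------

# Piecewise 79° N photoperiod keyed to day-of-year: polar night (0 h) from
# late October to mid February, polar day (24 h) mid April to early
# September, with linear ramps between. Only the qualitative polar
# night/day contrast matters downstream, so no astronomical formula.
_NIGHT_END = 45    # ~Feb 14
_DAY_START = 103   # ~Apr 13
_DAY_END = 252     # ~Sep 9
_NIGHT_START = 299  # ~Oct 26


def daylight_hours(day_of_year: int | np.ndarray) -> np.ndarray:
    """Hours of daylight at 79° N for a given day of year (1..366)."""
    doy = np.asarray(day_of_year, dtype=float)
    hours = np.zeros_like(doy)
    spring = (doy > _NIGHT_END) & (doy < _DAY_START)
    hours[spring] = 24 * (doy[spring] - _NIGHT_END) / (_DAY_START - _NIGHT_END)
    hours[(doy >= _DAY_START) & (doy <= _DAY_END)] = 24.0
    autumn = (doy > _DAY_END) & (doy < _NIGHT_START)
    hours[autumn] = 24 * (_NIGHT_START - doy[autumn]) / (_NIGHT_START - _DAY_END)
    return hours


# -- environmental series --------------------------------------------------

def generate_env_series(
    n_years: int,
    site: str,
    sampling_interval_days: int = 7,
    seed: int = 0,
    past_ice_window_days: int = 14,
    start: str = "2016-07-01",
) -> pd.DataFrame:
    """Weekly-to-fortnightly environmental series for one mooring site.

    The core-EGC profile has year-round dense ice cover (median >= 70%)
    and a near-zero Atlantic-water baseline with rare pulses; the MIZ has
    strongly seasonal ice and episodic AW intrusions. ``past_ice_cover_pct``
    is the trailing mean of sampled ice cover over ``past_ice_window_days``
    (inclusive of the sampling day), emulating the average ice cover of the
    days preceding each sampling event.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; expected one of {SITES}")
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    if not 7 <= sampling_interval_days <= 14:
        raise ValueError("sampling interval must be within 7..14 days")
    rng = np.random.default_rng(seed)

    dates = pd.date_range(
        start=start, periods=round(n_years * 365 / sampling_interval_days) + 1,
        freq=f"{sampling_interval_days}D",
    )
    doy = dates.dayofyear.to_numpy()
    n = len(dates)

    if site == "core-EGC":
        ice = 88 + 6 * np.cos(2 * np.pi * (doy - 60) / 365) + rng.normal(0, 4, n)
        aw = np.full(n, 0.03) + rng.normal(0, 0.01, n)
        pulses = rng.random(n) < 0.04
        aw[pulses] += rng.uniform(0.15, 0.4, pulses.sum())
    else:  # MIZ
        ice = 55 + 35 * np.cos(2 * np.pi * (doy - 75) / 365) + rng.normal(0, 10, n)
        aw = 0.15 + 0.05 * np.sin(2 * np.pi * (doy - 200) / 365) + rng.normal(0, 0.03, n)
        pulses = rng.random(n) < 0.15
        aw[pulses] += rng.uniform(0.2, 0.6, pulses.sum())
    ice = np.clip(ice, 0, 100)
    aw = np.clip(aw, 0, 1)

    # trailing mean of sampled ice values within the window, current included
    day_num = (dates - dates[0]).days.to_numpy()
    past_ice = np.array(
        [
            ice[(day_num >= day_num[i] - past_ice_window_days) & (day_num <= day_num[i])].mean()
            for i in range(n)
        ]
    )

    daylight = daylight_hours(doy)
    temperature = -1.6 + 3.5 * aw + 0.3 * daylight / 24 + rng.normal(0, 0.15, n)
    chlorophyll = (
        rng.gamma(2.0, 0.4, n) * (daylight / 24) * (1 - 0.6 * ice / 100)
    )
    chlorophyll = np.clip(chlorophyll, 0, None)

    return pd.DataFrame(
        {
            "sample_id": [f"{site}_{i:03d}" for i in range(n)],
            "date": dates,
            "site": site,
            "aw_fraction": aw,
            "ice_cover_pct": ice,
            "past_ice_cover_pct": past_ice,
            "daylight_h": daylight,
            "temperature_C": temperature,
            "chlorophyll_au": chlorophyll,
        }
    )


# -- community matrices ----------------------------------------------------

#: per-group default mean latent log-baseline, occurrence probability and
#: environmental coupling signs (AW: resident -, intermittent +, transient -;
#: ice: transient +)
GROUP_DEFAULTS = {
    "resident": {
        "baseline": 2.0,
        "occurrence_p": 0.98,
        "coupling": {"aw_fraction": -0.3},
    },
    "intermittent": {
        "baseline": 0.0,
        "occurrence_p": 0.5,
        "coupling": {"aw_fraction": 1.0},
    },
    "transient": {
        "baseline": -1.0,
        "occurrence_p": 0.12,
        "coupling": {"aw_fraction": -0.3, "ice_cover_pct": 0.5},
    },
}

#: genera observed in Arctic marine communities, used to label synthetic ASVs
_GENUS_POOL = (
    ("Bacteroidota", "Flavobacteriaceae", "Polaribacter"),
    ("Bacteroidota", "Flavobacteriaceae", "Aurantivirga"),
    ("Bacteroidota", "Flavobacteriaceae", "Flavobacterium"),
    ("Bacteroidota", "Flavobacteriaceae", "NS2b"),
    ("Bacteroidota", "NS9_Marine_Group", "NS9_Marine_Group"),
    ("Proteobacteria", "Pelagibacteraceae", "SAR11_Clade_Ia"),
    ("Proteobacteria", "Pelagibacteraceae", "SAR11_Clade_II"),
    ("Proteobacteria", "AEGEAN-169", "AEGEAN-169"),
    ("Proteobacteria", "Thioglobaceae", "SUP05"),
    ("Proteobacteria", "Porticoccaceae", "SAR92"),
    ("Proteobacteria", "SAR86", "SAR86"),
    ("Proteobacteria", "Colwelliaceae", "Colwellia"),
    ("Proteobacteria", "Rhodobacteraceae", "Amylibacter"),
    ("Proteobacteria", "Magnetospiraceae", "Magnetospira"),
    ("Verrucomicrobiota", "Rubritaleaceae", "Luteolibacter"),
    ("SAR324", "SAR324", "SAR324"),
    ("Marinimicrobia", "Marinimicrobia", "Marinimicrobia"),
)


def _asv_lineage(rng: np.random.Generator) -> TaxLineage:
    phylum, family, genus = _GENUS_POOL[rng.integers(len(_GENUS_POOL))]
    return TaxLineage(
        ("Bacteria", phylum, f"{phylum}_c", f"{family}_o", family, genus, "")
    )


def generate_community(
    env: pd.DataFrame,
    n_resident: int = 231,
    n_intermittent: int = 1943,
    n_transient: int = 1909,
    depth_per_sample: int = 100_000,
    noise: float = 0.3,
    seed: int = 0,
    occurrence_probs: dict[str, float] | None = None,
    baselines: dict[str, float] | None = None,
    baseline_sd: float = 0.5,
) -> tuple[CommunityMatrix, GroundTruth]:
    """Count matrix with planted occupancy structure and env coupling.

    Per-ASV latent log-abundance = baseline + amplitude*cos(2pi(week-phase)/52)
    + sum(coupling * standardised covariate) + Normal(0, noise); presence is
    an independent Bernoulli draw per sample at the group's occurrence
    probability; counts are a multinomial of size ``depth_per_sample`` over
    the present ASVs' intensities (fixed library size, so all downstream
    statistics are compositional). Group sizes and sampling default to the
    study's scale: 231 residents, 1943 intermittents, 1909 transients.
    """
    if len(env) == 0:
        raise ValueError("environmental series is empty")
    if n_resident + n_intermittent + n_transient == 0:
        raise ValueError("all group sizes are zero")
    if min(n_resident, n_intermittent, n_transient) < 0 or depth_per_sample <= 0:
        raise ValueError("group sizes must be >= 0 and depth positive")
    rng = np.random.default_rng(seed)

    groups = (
        ["resident"] * n_resident
        + ["intermittent"] * n_intermittent
        + ["transient"] * n_transient
    )
    n_asv = len(groups)
    asv_ids = [f"asv{i + 1:05d}" for i in range(n_asv)]

    # standardised covariates (constant columns contribute zero)
    cov = {}
    for name in COUPLING_COVARIATES:
        x = env[name].to_numpy(dtype=float)
        sd = x.std()
        cov[name] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    week = env["date"].dt.isocalendar().week.to_numpy(dtype=float)

    truth = GroundTruth()
    taxonomy: dict[str, TaxLineage] = {}
    n_samples = len(env)
    latent = np.empty((n_asv, n_samples))
    present = np.empty((n_asv, n_samples), dtype=bool)
    for i, (asv, group) in enumerate(zip(asv_ids, groups)):
        spec = GROUP_DEFAULTS[group]
        p_occ = (occurrence_probs or {}).get(group, spec["occurrence_p"])
        baseline = (baselines or {}).get(group, spec["baseline"]) + rng.normal(
            0, baseline_sd
        )
        amplitude = rng.uniform(0.0, 0.8)
        phase = rng.uniform(0, 52)
        coupling = dict(spec["coupling"])
        lam = baseline + amplitude * np.cos(2 * np.pi * (week - phase) / 52)
        for name, coef in coupling.items():
            lam = lam + coef * cov[name]
        lam = lam + rng.normal(0, noise, n_samples)
        latent[i] = lam
        present[i] = rng.random(n_samples) < p_occ
        lineage = _asv_lineage(rng)
        taxonomy[asv] = lineage
        truth.asv_labels[asv] = group
        truth.coupling[asv] = coupling
        truth.seasonal[asv] = (amplitude, phase)
        truth.genus_map[asv] = lineage.genus

    intensity = np.exp(latent) * present
    counts = np.zeros((n_asv, n_samples), dtype=int)
    for j in range(n_samples):
        total = intensity[:, j].sum()
        if total > 0:
            counts[:, j] = rng.multinomial(
                depth_per_sample, intensity[:, j] / total
            )

    matrix = CommunityMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(asv_ids, name="asv_id"),
            columns=env["sample_id"].tolist(),
        ),
        taxonomy=taxonomy,
    )
    return matrix, truth


# -- oscillating abundance series ------------------------------------------

def generate_oscillating_pairs(
    n_cooc_pairs: int = 50,
    n_indep_pairs: int = 50,
    n_years: int = 2,
    noise_sd: float = 0.1,
    n_harmonics: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Weekly abundance series for planted co-oscillating and independent
    ASV pairs.

    Each co-oscillating pair shares one latent waveform per year (a random
    mixture of the first ``n_harmonics`` annual harmonics, unit standard
    deviation); members observe it under independent Gaussian noise.
    Members of an independent pair each get their own waveform. The
    noise-free series are kept in ``GroundTruth.latent_series`` so that
    detected edges can be scored against latent correlation rather than
    pair membership.
    """
    rng = np.random.default_rng(seed)
    weeks_per_year = 52
    t = np.arange(weeks_per_year)

    def waveform() -> np.ndarray:
        coef = rng.normal(0, 1, 2 * n_harmonics)
        x = np.zeros(weeks_per_year)
        for k in range(1, n_harmonics + 1):
            x += coef[2 * (k - 1)] * np.cos(2 * np.pi * k * t / weeks_per_year)
            x += coef[2 * k - 1] * np.sin(2 * np.pi * k * t / weeks_per_year)
        return x / x.std()

    truth = GroundTruth(pairs=[])
    latent: dict[str, np.ndarray] = {}
    for p in range(n_cooc_pairs):
        shared = np.concatenate([waveform() for _ in range(n_years)])
        a, b = f"cooc{p:03d}_a", f"cooc{p:03d}_b"
        latent[a] = shared
        latent[b] = shared.copy()
        truth.pairs.append((a, b, True))
    for p in range(n_indep_pairs):
        a, b = f"indep{p:03d}_a", f"indep{p:03d}_b"
        latent[a] = np.concatenate([waveform() for _ in range(n_years)])
        latent[b] = np.concatenate([waveform() for _ in range(n_years)])
        truth.pairs.append((a, b, False))

    n_weeks = n_years * weeks_per_year
    observed = {
        asv: series + rng.normal(0, noise_sd, n_weeks)
        for asv, series in latent.items()
    }
    columns = [f"wk{w:03d}" for w in range(n_weeks)]
    truth.latent_series = pd.DataFrame.from_dict(
        latent, orient="index", columns=columns
    )
    series = pd.DataFrame.from_dict(observed, orient="index", columns=columns)
    series.index.name = "asv_id"
    return series, truth


# -- correlation profiles for signature clustering -------------------------

#: eight sign patterns over (AW, ice, past ice, daylight, temperature):
#: C1-like (+AW, -ice) through C8-like (-AW, +ice), plus daylight-keyed
#: mixtures, emulating distinct environmental regimes
SIGNATURE_PATTERNS = (
    (+1, -1, -1, 0, +1),
    (+1, 0, 0, 0, +1),
    (0, -1, -1, +1, 0),
    (0, +1, +1, +1, 0),
    (0, 0, +1, -1, 0),
    (-1, 0, 0, +1, -1),
    (0, -1, 0, -1, 0),
    (-1, +1, +1, 0, -1),
)

#: member counts per planted cluster; the three largest hold ~88% of ASVs
SIGNATURE_SIZES = (160, 130, 88, 12, 11, 10, 10, 9)


def generate_correlation_profiles(
    noise_sd: float = 0.05,
    magnitude: float = 0.6,
    n_samples: int = 84,
    seed: int = 0,
    sizes: tuple[int, ...] = SIGNATURE_SIZES,
    patterns: tuple[tuple[int, ...], ...] = SIGNATURE_PATTERNS,
) -> tuple[pd.DataFrame, GroundTruth]:
    """ASV-by-covariate correlation profiles with planted sign-pattern
    clusters (defaults: 430 ASVs in 8 clusters, r-noise sigma 0.05).

    The returned frame has ``r_<cov>`` and ``p_<cov>`` columns; p-values
    are the two-sided t-distribution values implied by r at ``n_samples``.
    """
    if len(sizes) != len(patterns):
        raise ValueError("one size per pattern required")
    rng = np.random.default_rng(seed)
    from scipy import stats as _stats

    rows, truth = [], GroundTruth()
    idx = 0
    for cluster, (size, pattern) in enumerate(zip(sizes, patterns), start=1):
        center = magnitude * np.asarray(pattern, dtype=float)
        for _ in range(size):
            asv = f"sig{idx + 1:04d}"
            r = np.clip(center + rng.normal(0, noise_sd, len(pattern)), -0.999, 0.999)
            tstat = r * np.sqrt((n_samples - 2) / (1 - r**2))
            p = 2 * _stats.t.sf(np.abs(tstat), df=n_samples - 2)
            rows.append((asv, *r, *p))
            truth.cluster_labels[asv] = cluster
            idx += 1
    columns = (
        ["asv_id"]
        + [f"r_{c}" for c in COUPLING_COVARIATES]
        + [f"p_{c}" for c in COUPLING_COVARIATES]
    )
    profiles = pd.DataFrame(rows, columns=columns).set_index("asv_id")
    return profiles, truth


def planted_robustness_edges(
    n_core: int = 8,
    n_pendant: int = 5,
    core_r: float = 0.70,
    seed: int = 0,
) -> pd.DataFrame:
    """Edge table with a biconnected core at exactly ``core_r`` plus
    pendant nodes attached by weaker edges.

    The core is a cycle with chords (2-connected, no articulation point);
    every core edge carries ``r = core_r``. Each pendant hangs off one core
    node with ``r`` drawn from [0.5, core_r), so any threshold below
    ``core_r`` re-attaches cut vertices and disrupts the network. All
    p-values are far below any reasonable alpha.
    """
    if n_core < 4:
        raise ValueError("need at least 4 core nodes for a chorded cycle")
    rng = np.random.default_rng(seed)
    rows = []
    core = [f"core{i:02d}" for i in range(n_core)]
    for i in range(n_core):
        rows.append((core[i], core[(i + 1) % n_core], core_r))
        rows.append((core[i], core[(i + 2) % n_core], core_r))
    for j in range(n_pendant):
        anchor = core[rng.integers(n_core)]
        rows.append((f"pend{j:02d}", anchor, float(rng.uniform(0.5, core_r - 0.005))))
    rows = [(min(a, b), max(a, b), r) for a, b, r in rows]
    edges = pd.DataFrame(rows, columns=["asv_i", "asv_j", "r"]).drop_duplicates(
        subset=["asv_i", "asv_j"]
    )
    edges["p_raw"] = 1e-8
    edges["p_adj"] = 1e-6
    return edges


# -- ORF hit tables --------------------------------------------------------

def make_lineage_pool(
    n_families: int = 12,
    genera_per_family: int = 3,
    species_per_genus: int = 2,
    seed: int = 0,
) -> list[TaxLineage]:
    """Hierarchical pool of synthetic species-level lineages. Families are
    spread over three phyla so decoys can be near or far taxonomically."""
    del seed  # naming is deterministic; kept for interface symmetry
    phyla = ("Proteobacteria", "Bacteroidota", "Verrucomicrobiota")
    pool = []
    for f in range(n_families):
        phylum = phyla[f % len(phyla)]
        for g in range(genera_per_family):
            for s in range(species_per_genus):
                pool.append(
                    TaxLineage(
                        (
                            "Bacteria",
                            phylum,
                            f"{phylum}_c",
                            f"Order{f % 4 + 1:02d}",
                            f"Family{f + 1:02d}",
                            f"Genus{f + 1:02d}{chr(97 + g)}",
                            f"Genus{f + 1:02d}{chr(97 + g)} sp{s + 1}",
                        )
                    )
                )
    return pool


def within_family_decoys(pool: list[TaxLineage]) -> dict[str, list[TaxLineage]]:
    """Map each pool lineage's string to the other lineages of its family."""
    by_family: dict[str, list[TaxLineage]] = {}
    for lin in pool:
        by_family.setdefault(lin.name_at("family"), []).append(lin)
    return {
        lin.to_string(): [o for o in by_family[lin.name_at("family")] if o != lin]
        for lin in pool
    }


def generate_read_hits(
    lineage_pool: list[TaxLineage],
    n_reads: int = 1000,
    orfs_per_read: tuple[int, int] = (1, 5),
    hits_per_orf: tuple[int, int] = (1, 5),
    noise_rate: float = 0.0,
    seed: int = 0,
    decoy_pool: dict[str, list[TaxLineage]] | None = None,
    noise_pass_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, TaxLineage], GroundTruth]:
    """BLAST-tabular hit table for simulated long reads with known lineages.

    Each read draws a true lineage from ``lineage_pool``; each of its ORFs
    receives hits whose subject lineage is the truth with probability
    ``1 - noise_rate`` and a decoy otherwise (by default any other pool
    lineage; pass a ``decoy_pool`` map to confine decoys, e.g. within the
    true family). True hits always pass the downstream identity/coverage/
    e-value/top-bitscore filters; a ``noise_pass_fraction`` of decoy hits
    pass them too, the rest fail one filter each.

    Returns the hit table, the subject→lineage map, and the ground truth.
    """
    if not lineage_pool:
        raise ValueError("lineage pool is empty")
    if not 0 <= noise_rate <= 1:
        raise ValueError("noise_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    subject_of = {lin.to_string(): f"prot{i:05d}" for i, lin in enumerate(lineage_pool)}
    subject_lineages = {sid: lin for lin, sid in zip(lineage_pool, subject_of.values())}

    def subject_for(lin: TaxLineage) -> str:
        key = lin.to_string()
        if key not in subject_of:
            sid = f"prot{len(subject_of):05d}"
            subject_of[key] = sid
            subject_lineages[sid] = lin
        return subject_of[key]

    truth = GroundTruth()
    rows = []
    for r in range(n_reads):
        read_id = f"read{r:06d}"
        true = lineage_pool[rng.integers(len(lineage_pool))]
        truth.read_lineages[read_id] = true
        n_orfs = rng.integers(orfs_per_read[0], orfs_per_read[1] + 1)
        for o in range(1, n_orfs + 1):
            orf_id = f"{read_id}_orf{o}"
            base_bitscore = rng.uniform(180, 250)
            n_hits = rng.integers(hits_per_orf[0], hits_per_orf[1] + 1)
            for _ in range(n_hits):
                is_noise = rng.random() < noise_rate
                if is_noise:
                    if decoy_pool is not None:
                        candidates = decoy_pool[true.to_string()]
                    else:
                        candidates = [l for l in lineage_pool if l != true]
                    lin = candidates[rng.integers(len(candidates))] if candidates else true
                    if rng.random() < noise_pass_fraction:
                        pident = rng.uniform(66, 80)
                        qcov = rng.uniform(70, 100)
                        evalue = 10.0 ** rng.uniform(-30, -15)
                        bitscore = base_bitscore * rng.uniform(0.96, 1.0)
                    else:  # fail exactly one filter
                        pident = rng.uniform(66, 80)
                        qcov = rng.uniform(70, 100)
                        evalue = 10.0 ** rng.uniform(-30, -15)
                        bitscore = base_bitscore * rng.uniform(0.96, 1.0)
                        mode = rng.integers(4)
                        if mode == 0:
                            pident = rng.uniform(20, 49)
                        elif mode == 1:
                            pident = rng.uniform(50, 64)
                        elif mode == 2:
                            evalue = 10.0 ** rng.uniform(-9, -2)
                        else:
                            bitscore = base_bitscore * rng.uniform(0.5, 0.9)
                else:
                    lin = true
                    pident = rng.uniform(75, 99)
                    qcov = rng.uniform(70, 100)
                    evalue = 10.0 ** rng.uniform(-50, -20)
                    bitscore = base_bitscore * rng.uniform(0.96, 1.0)
                length = int(rng.integers(80, 300))
                mismatch = int(round(length * (1 - pident / 100)))
                qstart = int(rng.integers(1, 50))
                rows.append(
                    (
                        orf_id,
                        subject_for(lin),
                        round(pident, 1),
                        length,
                        mismatch,
                        0,
                        qstart,
                        qstart + length - 1,
                        1,
                        length,
                        evalue,
                        round(bitscore, 1),
                        round(qcov, 1),
                    )
                )
    from .io import HIT_COLUMNS

    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits, subject_lineages, truth


# -- coverage profiles -----------------------------------------------------

def generate_depth_profile(
    genome_length: int,
    mean_depth: float,
    spike_fraction: float = 0.0,
    spike_multiplier: float = 1.0,
    seed: int = 0,
    unit_id: str = "genome",
) -> DepthProfile:
    """Poisson per-position depths with an optional contiguous spike region
    (emulating conserved regions recruiting non-specific reads)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    if not 0 <= spike_fraction < 0.5:
        raise ValueError("spike_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    depths = rng.poisson(mean_depth, genome_length).astype(float)
    n_spike = int(round(spike_fraction * genome_length))
    if n_spike > 0:
        start = int(rng.integers(0, genome_length - n_spike + 1))
        depths[start : start + n_spike] = np.round(
            depths[start : start + n_spike] * spike_multiplier
        )
    return DepthProfile(unit_id=unit_id, depths=depths)


def generate_marker_depths(
    mean_depth: float,
    n_markers: int = 16,
    gene_length: int = 900,
    seed: int = 0,
) -> np.ndarray:
    """Per-gene mean depths for the single-copy marker set: each gene's
    depth is the mean of Poisson per-position depths over its length."""
    rng = np.random.default_rng(seed)
    return np.array(
        [rng.poisson(mean_depth, gene_length).mean() for _ in range(n_markers)]
    )
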