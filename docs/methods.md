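# Methods

This note records the models, conventions and design choices behind each
analysis stage, what the synthetic generators do and do not emulate, and
the numerical details a maintainer would need to reason about edge cases.

## Occupancy partitioning

Detection of an ASV in a sample means reaching `min_count` reads (default
1, i.e. presence/absence of the denoised table). Detection frequency is
the fraction of all provided samples with detection; the provided matrix
is treated as the universe of sampling events. Classes: resident
(*f* > 0.90), intermittent (0.25 ≤ *f* ≤ 0.90), transient (*f* < 0.25) —
both interval boundaries belong to the intermittent class, reading
"25–90%" as closed. Frequencies are computed over the pooled sample set by
default; restricting to one site is done by subsetting the matrix columns
before calling.

Group abundance series are sums of relative abundances, so the three
series partition 1 per sample exactly. Fraction–environment association
uses Pearson's r with the two-sided t-distribution p-value (n − 2 df);
constant inputs raise an explicit `DegenerateInputError` rather than
returning NaN. Bray-Curtis dissimilarity is computed on relative
abundances via `scipy.spatial.distance` and cross-checked in the tests
against an element-wise Σ|x−y|/Σ(x+y) oracle.

## Oscillation signals and co-occurrence networks

Irregular series are linearly interpolated onto a 7-day grid anchored at
the first observation; no extrapolation occurs (edge values are held), so
a series must span at least half a year and contain ≥ 4 points.

Per annual cycle (52 weekly points) the mean-removed real DFT is taken and
harmonics 1..K retained, K = 6 by default — enough to represent seasonal
shapes up to two-monthly structure while keeping signal vectors short.
Amplitudes use the real-sinusoid convention 2|F_k|/n, so a pure cosine of
amplitude *a* at harmonic *k* scores amplitude *a*; the retained sinusoid
power Σa²/2 is bounded by the series variance (Parseval), which the tests
assert. A constant series yields zero amplitudes and is logged, not
rejected.

Signals are compared by Pearson correlation of concatenated per-year
harmonic vectors. The vectors use Cartesian components per harmonic,
(a·cos φ, a·sin φ), not raw (amplitude, phase) pairs: phase is circular,
and a raw-phase vector has a ±π discontinuity that corrupts correlations
for ASVs oscillating near the wrap point, whereas the Cartesian form
carries identical information smoothly. ASVs absent in a year contribute
zero-amplitude blocks (logged); zero-variance vectors are skipped.
P-values come from the t-approximation by default; a seeded permutation
test (999 permutations) is available for short vectors, where treating
harmonic components as independent observations is most strained.

Edges are Benjamini–Hochberg adjusted; retention requires r > 0,
r ≥ threshold and p_adj < α. "Network disruption" is operationalised as
the existence of an articulation point in the giant component; the
robustness threshold is the largest value on a 0.50–0.95 grid (step 0.01)
whose network is non-trivial (giant component ≥ 3 nodes) and biconnected.
Lowering the threshold below this value re-attaches weakly linked pendant
nodes whose anchors become cut vertices. Betweenness centrality is
shortest-path based and normalised; closeness is computed within each
connected component (no across-component scaling).

## Environmental signature clustering

ASV–environment association is scored by Pearson r of relative abundance
against each covariate. Selection keeps ASVs with at least one covariate
at |r| strictly greater than 0.4 and p strictly below 0.05 — magnitude,
not signed value, since signatures of polar-night or polar-water regimes
correlate negatively. P-values are raw by default (an FDR option exists):
the selection threshold is a descriptive cutoff, not an inference claim.
Covariates that are collinear stand-ins for one another (e.g. temperature
tracking AW fraction) can be excluded by configuration.

Significant profiles are clustered on the Euclidean distance between
r-vectors with average-linkage agglomerative clustering. Rows are sorted
by ASV id before fitting, making the result input-order independent, and
the distance is coordinate-symmetric, so consistent covariate reordering
cannot change memberships. `k="auto"` maximises the silhouette score over
k ∈ [2, 12]. Cluster ids are assigned by decreasing size with ties broken
by smallest member id. A cluster's consensus sign for a covariate is the
sign of the median member r when its magnitude clears the selection
threshold, else 0. Prominent-genus summaries drop members whose maximum
relative abundance is below 1%, group survivors by genus (or by deepest
assigned rank when the genus is missing, logged), and report each genus's
maximum.

## Two-stage LCA classification

Lineages are ordered rank paths over (domain, phylum, class, order,
family, genus, species) with GTDB prefixes; a gap truncates everything
deeper, making longest-common-prefix comparison well defined. The LCA of
a set is that longest common prefix; it is order-independent, idempotent,
and can only become shallower as hits are added — properties the test
suite asserts.

Hit filtering: stage 1 applies the aligner-level thresholds — identity
≥ 50%, query coverage ≥ 60%, and bitscore within 5% of the ORF's best
(the conventional meaning of a "top 5" retention flag). The best bitscore
is computed among stage-1 identity/coverage survivors, so an off-target
high-bitscore hit cannot set the bar. Stage 2 then requires identity
strictly above 65% and e-value strictly below 1e-10. Each ORF's retained
hits are LCA-collapsed to one lineage; a second LCA over the ORFs of a
read yields the read lineage. Fully unclassified ORFs are excluded from
the read-level LCA by default (configurable): an ORF without any reference
homolog carries no taxonomic evidence and should not erase its
neighbours'.

Per-genome normalisation divides each sample's gene counts by the mean
depth of 16 universal single-copy ribosomal proteins (default set: L2,
L3, L4, L5, L6, L14, L15, L16, L18, L22, L24, S3, S8, S10, S17, S19),
yielding copies per genome equivalent; samples with all-zero markers are
excluded with a warning.

## TAD80 genome quantification

Per-position depths are read from samtools-depth-style tables with absent
positions imputed as zero, so breadth of coverage matters: a genome with
under 10% breadth has TAD80 = 0 by construction. TAD with central
fraction *f* sorts the depths and removes floor((1−f)/2 · n) positions
from each tail (the floor is guarded by a 1e-9 epsilon against binary
representation of the tail fraction shifting the count); the remainder is
averaged. Relative abundance is TAD80 over the arithmetic mean depth of
the 16 markers; values above 1 are flagged, zero marker depth excludes
the sample. Detection uses TAD80 ≥ 1× inclusively, keeping a single depth
statistic throughout (plain-mean detection is available via
`central_fraction=1`).

Note that truncation is not unbiased for skewed depth distributions: for
Poisson-distributed depths at mean 2, TAD80 sits near 1.91, so a genome
planted at 10% of genome equivalents is recovered at ≈ 0.095. This is a
property of the statistic, shared with any truncated mean, and is well
inside the ±0.02 recovery tolerance used in the tests.

## Synthetic data: what it emulates, and what it does not

The environmental generator produces weekly-to-fortnightly series over
whole years with a piecewise 79° N photoperiod (polar night to polar day
with linear ramps — the qualitative contrast is all that matters
downstream), dense year-round ice with a near-zero AW baseline and rare
pulses at the core-EGC site, seasonal ice and episodic AW intrusions at
the MIZ, temperature tied to AW fraction, and a daylight-and-ice gated
chlorophyll bloom. "Past ice cover" is the trailing mean of sampled ice
values within a configurable window (default 14 days, current sample
included) so the field is recomputable from the emitted table alone.

Community matrices use a latent log-abundance per ASV — baseline +
annual cosine + Σ(coupling × standardised covariate) + Gaussian noise —
masked by an independent per-sample Bernoulli occurrence draw at the
group's occurrence probability, then thinned by a multinomial of fixed
library size (100,000 reads by default, matching the order of a deep
amplicon run). The fixed library size means all downstream statistics are
compositional, as they are for real relative-abundance tables. Default
group sizes (231 / 1943 / 1909) and the sign structure of the planted
couplings (resident −AW, intermittent +AW, transient −AW/+ice) mirror a
two-mooring Fram Strait amplicon study's scale. Not emulated: taxonomic
phylogenetic structure beyond a genus label, sequencing error, sample
dropout, or autocorrelated occupancy (presence draws are independent
across samples).

Oscillation fixtures plant pairs sharing one random waveform per year (a
unit-variance mixture of the first six annual harmonics) observed under
independent Gaussian noise; independent pairs get unrelated waveforms.
Because two unrelated waveforms can genuinely align by chance, the
noise-free series are stored as ground truth and a retained edge counts
as spurious only when its latent signal correlation is below 0.7 — the
detector is judged on what it detects (correlation), not on pair labels.

ORF-hit fixtures assign each read a true lineage and give every hit
either the true subject lineage or a decoy (optionally confined, e.g.
within the true family); true hits always pass the filter thresholds
while a configurable fraction of decoy hits fails exactly one threshold
each. Coverage fixtures are Poisson depth with an optional contiguous
multiplied spike region. All generators draw from a single seeded
`numpy.random.Generator`; no global RNG state is used or mutated.

Passing recovery tests on these fixtures demonstrates the correctness of
the analysis logic under the planted generative model; they do not
certify performance on real data, where occupancy is autocorrelated,
noise is not Gaussian, reference databases are incomplete, and coverage
biases are structured.

## Problem sizes

The recovery analyses run at the study's own scale where that is cheap
(4100 ASVs × 84 samples for occupancy; 1000 reads for LCA; 430 profiles
in 8 clusters; 1000 random depth profiles up to 100 kb; 100 planted
oscillation pairs over 2 years, 20 replicate seeds), chosen so the whole
suite and the acceptance script each complete in minutes on one CPU.
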