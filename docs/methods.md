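# Methods

`minfluxpair` post-processes 2D MINFLUX localization tables into the spatial
statistics used to characterize membrane-receptor organization in flat
structures such as the NK-cell immune synapse: are receptors monomeric,
paired, or clustered, and at what separations? This note records the model
behind each stage, the defaults and why, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Data model

A **localization** is one position estimate of an emitting fluorophore, with
two quality metrics: `efo` (background-corrected emission rate, Hz; high
values indicate background) and `cfr` (center-frequency ratio; values near
or above ~1 indicate poor localizations). A **trace** is the group of
localizations from one emission event of one fluorophore, identified by
`trace_id`. All coordinates are nanometers in the imaging plane; the
analysis is strictly 2D. A `z_nm` column in input files is ignored with a
warning — separations with an out-of-plane component are measured as their
projection, a known limitation of 2D acquisition that the pipeline reports
but does not correct.

## Quality filtering

Localizations with `efo > 50,000 Hz` **or** `cfr > 0.95` are removed
(strictly greater: boundary values are kept), then traces left with fewer
than 3 localizations are removed entirely. The order matters — the
trace-length rule is applied to the *survivors* of the per-localization
cuts — and is fixed. The filter is idempotent and preserves row order; all
removal counts are recorded in the output provenance.

## Trace centers

Each surviving trace is collapsed to one 2D point by running DBSCAN on that
trace's own localizations (search radius 4 nm, threshold 3 localizations)
and averaging the largest cluster. Conventions, fixed because the result
depends on them:

- the neighborhood count includes the point itself, and the radius test is
  inclusive (d ≤ r);
- a border point reachable from several clusters joins the cluster of its
  lowest-index core point;
- ties between equal-size largest clusters resolve to the cluster containing
  the earliest-time localization;
- a trace with no DBSCAN cluster yields no center and is dropped;
- DBSCAN runs per trace, never across traces, so two distinct emitters
  closer than 4 nm are not conflated;
- rows are put in canonical (time, x, y) order first, and the mean is
  computed about the first member, so the center is invariant to input row
  order and exactly equals the molecule position on noiseless data.

**Center precision.** With per-localization, per-axis precision σ and m
localizations, the naive center precision is σ/√m. The DBSCAN subset mean is
measurably noisier: selecting the largest spatially coherent subset at a
4 nm radius (≈1.6σ at σ = 2.5 nm) conditions on configuration, and the
measured per-axis center error variance is ≈1.36 nm² at σ = 2.5 nm, λ = 8,
versus 0.78 nm² for σ²/m̄ (the plain all-points trace mean reproduces the
naive value exactly). This inflation propagates into measured pair
distances; see the bias law below.

## Pair and cluster detection

All spatial statistics operate on trace centers.

**Isolated pairs** are DBSCAN clusters of exactly 2 centers at a 40 nm
search radius (min_pts = 2). Because DBSCAN chains, a size-2 cluster
guarantees there is no third center within 40 nm of either member — the two
centers are mutual nearest neighbors. The implementation verifies this on
every reported pair (recording the distance to the nearest third center)
rather than applying any further cut. Each pair carries its exact member
distance, midpoint, and the member localization counts.

**Clusters** are DBSCAN components with at least 4 centers at a 40 nm
radius. Per cluster the report gives composition (member count), size
(maximum pairwise member distance — the diameter), convex-hull area, and
density (composition/area). Degenerate hulls (collinear members) fall back
to a ribbon of area size × 1 nm and are flagged. Size and density are not
uniquely defined in the field; these definitions are recorded in every
report so alternatives can be compared unambiguously. Note that a 4-member
Gaussian cluster of spread comparable to the search radius occasionally
contains no core point (p ≈ 0.13 at sd 15 nm) and is then undetectable;
exact count recovery is only guaranteed for compact clusters.

**Nearest-neighbor distances** use an exact ball-tree index; results are
identical to exhaustive search.

**Ripley K/L/H** on a rectangular ROI uses
K̂(r) = (A / (n(n−1))) · Σ_{i≠j} e_ij · 1[d_ij ≤ r], with e_ij = 1
(uncorrected) or the translation edge correction
e_ij = A / ((w − |Δx|)(h − |Δy|)). L = √(K/π) and H = L − r; H > 0 indicates
clustering at scale r, H < 0 dispersion. The maximum radius must not exceed
half the shorter ROI side. The default grid is 5–200 nm in 5 nm steps; the
pipeline clips the grid (with a warning) when the ROI — by default the
centers' bounding rectangle — is smaller. On complete spatial randomness the
uncorrected H is biased below zero at large r; the translation-corrected H
is unbiased, which the test suite checks against a Monte-Carlo CSR envelope.

**Condition comparison** (e.g. per-cell pair counts with vs without
opsonization) uses the two-sided Mann–Whitney U test: exact p by enumeration
of all group assignments of the midranks when both samples have n ≤ 8
(ties handled naturally), normal approximation with tie correction
otherwise.

## The distance bias of measured separations

Two points truly d apart, each localized with isotropic per-axis error
σ_point, yield a measured distance following a Rice distribution with
location d and scale σ_point·√2; its mean *always exceeds d*,
by ≈ σ_point²/d for d ≫ σ_point and saturating at the Rayleigh mean
σ_point·√(2π)/√2 as d → 0. `expected_pair_distance(d, sigma_point)`
evaluates this mean in closed form via exponentially scaled Bessel
functions (validated to <1e-6 relative error against quadrature and against
a 10⁷-draw Monte-Carlo oracle); `invert_pair_distance` solves it for d with
Brent's method, clamping to 0 below the Rayleigh floor.

For pipeline outputs, σ_point is the *center* precision. Two practical
notes:

- using σ_loc·√(mean(1/m)) over the pair members' localization counts is a
  good working estimate, but the DBSCAN selection inflation above means the
  true center error is somewhat larger; at d ≈ 18 nm, σ_loc = 2.5 nm the
  residual error after inversion is ≲0.1 nm, while at d ≈ 5 nm it reaches
  ~0.1–0.15 nm. Separation estimates far below the search radius and close
  to the precision scale should be treated accordingly.
- on mixed fields the pooled pair-distance *median* is inverted, not the
  mean: detected pairs include a contaminant population (chance monomer
  pairs and two-labeled-member cluster fragments, ~10% of detections at the
  default densities) with distances spread over 0–40 nm, which shifts the
  pooled mean by ~0.5–1 nm but the median by ≲0.1 nm. The Rice distribution
  is nearly symmetric at d/σ ≳ 10, so its median is interchangeable with its
  mean there.

## Synthetic data generator

The generator provides ground truth for every stage. Within a field
(default 5 × 5 µm, a typical synapse-scale ROI):

- **monomers**: homogeneous Poisson process (default 2.0 /µm²);
- **dimers**: Poisson-placed anchor (default 1.0 /µm²) with the partner at
  exactly `pair_separation_d` (default 18 nm) in a uniform random direction;
- **clusters**: Poisson-placed centers (default 0.2 /µm²) with
  `cluster_size_n` = 4 members at isotropic Gaussian offsets (sd 15 nm).

Density defaults are a sparse-synapse regime chosen so a 25 µm² field holds
tens of molecules of each class — enough pairs per "cell" for pooled
statistics at realistic sparsity. Each molecule is labeled independently
with probability `label_efficiency_p` (default 0.7, a typical effective
SNAP-tag labeling efficiency); unlabeled molecules are invisible, so a dimer
is detectable as a pair only with probability p², the labeling-efficiency
law the tests verify. Each labeled molecule emits one trace (optionally a
second with `reactivation_prob` — off by default, as re-activation
masquerades as ~0 nm pairs and is an explicit confound switch); trace
lengths are ≥1-truncated Poisson (rate λ = 8, mean λ/(1−e^{−λ}) ≈ 8.003);
localizations are the molecule position plus independent per-axis Gaussian
noise (σ = 2.5 nm, interpreted as per-localization, per-axis precision).
Signal efo is log-normal (median 20 kHz, σ_log 0.4) with cfr uniform on
[0.1, 0.9]; background traces (0.2 /µm²) draw efo log-normal (median 80 kHz)
and cfr uniform on [0.9, 1.2], so the large majority fail the quality
filters — a generator convention chosen to make filter efficacy testable,
not an estimate of real background. `min_anchor_spacing` (default 0 = off)
rejection-samples anchors to a minimum mutual distance, used by controlled
isolated-dimer experiments.

Not emulated: photophysics kinetics (on/off rates, bleaching), stage drift
(hardware-stabilized instruments), 3D structure, spatially varying labeling
or background. Passing tests therefore demonstrate correctness of the
*analysis* under the stated statistical model, not robustness to
instrument-specific artifacts.

In validation experiments that assert exact identities (noiseless pair
recovery, the p² recall law, exact cluster counts) the trace-length rate is
raised to λ = 20: at λ = 8 about 1.3% of traces have fewer than 3
localizations and are removed by the trace-length filter, which would turn
those identities into statistical statements.

## Recovery scoring

`evaluate_recovery` matches detected pairs to true dimers greedily,
closest-cost first, where a pair may match a dimer only if each detected
center lies within 10 nm (≈4× center precision) of a distinct member.
Precision = matched/detected, recall = matched/all true dimers (so sub-100%
labeling caps recall near p²). With zero detections precision is reported as
1.0 and flagged `precision_undefined` — a fixed convention rather than an
undefined value. Cluster count recall greedily matches detected cluster
centroids to true cluster-group centroids within 30 nm. Greedy matching
(not optimal assignment) is deterministic and adequate at the simulated
densities, where candidate matches are rarely contested.

## Problem sizes and determinism

Validation experiments use: 200 randomized instances (n ≤ 200) for the
brute-force oracle checks; 2,000 dimers per separation for the distance-bias
law; 100 fields of n = 500 for the CSR Ripley envelope; 100 fields (~1,000
dimers) for the labeling law; and 12 cells for the synapse-scale recovery
experiment, mirroring a typical per-condition cell count. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`; the
same configuration and seed reproduce reports byte-for-byte (reports carry
no timestamps). The known red result: at d = 5 nm the measured mean pair
distance exceeds the σ_loc/√m̄ Rice prediction by ~0.12 nm (≈ +3–4 SE at
n = 2,000) because of the DBSCAN center-selection variance described above;
the effect decays as 1/d and is within noise for d ≥ 10 nm.

## Limitations

- 2D projection: out-of-plane separation components are not corrected.
- The pair definition is operational (DBSCAN size-2 at 40 nm); at high
  center density, chaining suppresses genuine pairs and chance pairs
  contaminate detections — quantified above for the default densities.
- Cluster size/density depend on the stated definitions (diameter,
  hull area); both are echoed in every report.
- The generator's efo/cfr distributions are conventions; real instruments
  should be filtered with thresholds chosen from their own distributions.
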