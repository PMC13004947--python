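# Methods

This note documents the models, parameter choices, numerical details, and
known limitations of each analysis stage, and what the synthetic-data
generators do and do not emulate.

## Diffusion-state inference from single-molecule trajectories

Trajectories are 2D localization sequences at 10 ms per frame with no
blinking gaps. The model assumes each trajectory keeps one diffusion
coefficient for its whole (short) life and that the population is a mixture
over a fixed grid of 100 log-spaced coefficients spanning 0.001–100 µm²/s,
covering the biologically plausible range from chromatin-bound to freely
diffusing protein.

**Likelihood.** For a trajectory of n jumps with per-axis localization error
σ (treated as a known input, default 0.030 µm, because it is estimated
separately from chromatin-bound histone data), the per-axis jump vector is
multivariate Gaussian with tridiagonal Toeplitz covariance: diagonal
`2DΔt + 2σ²`, off-diagonal `−σ²` (consecutive jumps subtract and re-add the
shared middle localization's noise). This matrix has eigenvalues
`2DΔt + 2σ²(1 − cos(kπ/(n+1)))` in the discrete sine basis, so one
orthonormal DST of each trajectory's jump components gives sufficient
statistics for the entire grid. The exact form matters in practice: the
cheaper approximation that treats squared jump lengths as independent
exponentials (also implemented, `likelihood="independent"`) is blind to the
negative jump autocorrelation; fitted to realistic data it is over-dispersed
and the EM compensates by splitting occupancy mass toward the grid edges,
ruining slow-state recovery. The exact likelihood's low-frequency modes
suppress the noise term, which is what makes D ≪ σ²/Δt identifiable at all.

**EM.** Only the mixture weights are free. Weights start uniform and are
updated for at most 200 iterations (relative log-likelihood tolerance
1e-8). No Dirichlet regularization is applied; the variational state-array
treatment with unit concentration parameters has no exact analog in plain
maximum-likelihood EM and is deliberately not imitated.

**State boundaries.** The occupancy curve is smoothed with a Gaussian kernel
of 3 grid points (≈0.15 decade) and interior minima with prominence ≥1% of
the peak become state cut points; the first state runs from the grid
minimum, the last to the grid maximum. With exactly two boundaries the
states are labeled bound / intermediate / fast. When comparing drug
conditions, boundaries fit on the vehicle condition should be frozen and
re-applied (`fit-kinetics --boundaries-from`).

**Per-trajectory D and fractions.** Each trajectory receives the
posterior-weighted geometric mean of the grid, `exp(Σ wᵢ ln Dᵢ)`; kinetic
fractions are per-field counts in each state bin, summarized as mean ± sd
across fields of view. Hard assignment of short noisy trajectories inflates
the slow state by roughly two percentage points at the default track length;
this bias is inherent to the per-trajectory assignment convention and is
visible in the recovery tests.

**Localization error.** For effectively immobile emitters the distance
between consecutive localizations is Rayleigh with scale √2·σ, hence mean
σ√π. The estimator selects trajectories with assigned D in the lowest 5th
percentile (the threshold for "slowest subset" was an open choice), computes
the mean consecutive displacement m, and returns m/√π. The √π conversion is
this package's documented convention; reporting the raw mean displacement
would overstate σ by ~77%.

## Bound-fraction decomposition and statistics

Triptolide blocks pre-initiation-complex formation, so its residual bound
fraction is read as non-specific chromatin interaction; α-amanitin stalls
elongation, so its residual adds the initiating component. The decomposition
is pure subtraction and always reassembles to the vehicle bound fraction.
Negative components (possible with noisy inputs or incomplete drug action)
are returned as-is, flagged, and warned about — never clipped. Differences
propagate sds in quadrature; ratios propagate relative errors
(`sd_r = r·√((sd_a/a)² + (sd_b/b)²)`), which matches Monte-Carlo propagation
to within a few percent while relative errors stay below ~25%.

Kinetic fractions are compositional (they sum to 1), so group comparisons
CLR-transform each field's composition (`ln(xᵢ/g(x))`, g the geometric mean)
before a two-sided Mann-Whitney U test; zero parts are multiplicatively
replaced by half the smallest nonzero part of their row. The test is exact
for ≤10 fields per group without ties, otherwise tie-corrected normal; fully
tied data returns p = 1. Single components (e.g. bound fraction inside
clusters) may be compared untransformed (`mode="raw"`).

## Displacement anisotropy

Turning angles come from the arccos of the normalized dot product of
consecutive jump vectors, clamped to [−1, 1] before arccos for numerical
safety at collinearity. Jumps shorter than 0.2 µm are excluded (set by the
jitter scale of bound histone controls), and bound-state trajectories are
removed first, since localization noise on stationary molecules mimics
strong reversals. The fold-anisotropy windows [150°, 180°] and [0°, 30°] are
closed on both ends. Uncertainty uses 20 subsamples of 50% of the angles
drawn *without* replacement — a half-sample jackknife, not the classical
bootstrap — mirroring how such error bars are usually produced for angle
pools. When an angle is labeled by region (inside/outside a cluster), the
label of its central localization decides.

## Trajectory clustering and control spots

Trajectory mean positions are clustered with DBSCAN at eps = 0.2 µm and 15
minimum samples; an eps scan utility supports the elbow-plot parameter
choice but performs no automatic knee selection. Cluster radius is the
maximum member distance to the centroid. Border points reachable from two
clusters follow scikit-learn's first-come assignment; the printed parameters
make such ties rare, and the test suite checks equality with a brute-force
density-reachability oracle on the unambiguous parts (core partition and
noise set). Clusters that are simultaneously above the 95th percentile in
member count and radius within a nucleus can be dropped as likely
histone-locus bodies or random accumulations (the exact cutoffs were an open
choice; both are configurable).

Each detected cluster gets 30 control spots of the same effective radius,
rejection-sampled inside the (circular) nuclear mask so that no spot
overlaps any cluster or any other spot. Placement failure after a bounded
number of attempts returns a partial list with a warning. Inside / outside /
control bound fractions carry binomial sds and enrichment folds with
propagated errors.

## Volumetric cluster segmentation and lifetimes

Voxels are 0.108 × 0.108 × 0.3 µm. Each nucleus is divided by its mean
intensity so values read as fold enrichment. Segmentation: 3×3×3 median
filter → grayscale erosion with a ball of radius 2 voxels → morphological
reconstruction by dilation → subtraction of the reconstruction (a top-hat
that isolates local peaks) → Otsu threshold of the residue inside the mask →
local maxima (min separation 3 voxels) as watershed markers → region
properties. The kernel sizes and the Otsu choice are this package's
defaults where only the operator chain is established; all are configurable.
Clusters below mean enrichment 1.65 are discarded. Histone locus bodies are
found by a per-slice difference of Gaussians (σ = 1 and 5 voxels)
thresholded at the 99.95th percentile; among clusters under that response,
the two brightest are flagged and removed (a nucleus carries at most two).

Lifetimes link clusters frame-to-frame by nearest xy neighbor, gated at
|Δz| ≤ 0.6 µm (two z-slices) and xy ≤ 0.5 µm; the xy gate has no published
counterpart (the manual protocol constrained only z) and sits below typical
inter-cluster spacing. A track ends at its first unlinked frame. Normalized
lifetime divides by the movie duration. The lifetime distribution is fit by
a two-component Gaussian mixture on raw lifetimes in minutes (10 restarts,
variance floor 1e-4 min²), components ordered by mean; the weight
uncertainty is the binomial `√(w(1−w)/n)` with n the number of clusters fit.
Optional subsampling flags reproduce the sampling protocol (≤8 clusters per
nucleus).

## MS2/MCP burst analysis

Spots: 3D difference of Gaussians (σ = 1.5, 6) → percentile threshold
(default 99.9; adjust per dataset, as thresholds were tuned visually in the
source protocol) → objects <6 voxels dropped → objects outside nuclear
labels dropped → brightest object per nucleus, located at its
intensity-weighted centroid. Traces: per frame, a 3-slice max projection
around the spot's z; RNAPII is the integrated intensity in an 11-pixel
(1.2 µm) diameter disc normalized to the per-frame nuclear mean; MCP is the
brightest 2×2 square. Gaps of ≤2 frames are linearly interpolated, longer
gaps split the trace. Both channels are smoothed by a centered 3-sample
(27 s) moving average — shorter than the minimum burst so it cannot erase
one.

Bursts are intervals between consecutive local minima of the smoothed MCP
trace (prominence ≥5% of range; endpoints count as boundaries; flat
baseline flanks are trimmed to the burst's support), kept when longer than
30 s. The loading rate is the least-squares slope of the RNAPII enrichment
from burst start to its maximum — the rising-phase definition; whether the
original measurements used the RNAPII or MCP rise is not stated, so the
RNAPII choice is documented here rather than asserted. Cross-correlations
are full discrete linear correlations of mean-centered traces normalized by
n·sd·sd, so the lag-0 value is exactly the Pearson coefficient; control
correlations use same-size regions placed randomly in the nucleus, disjoint
from the locus in every frame.

## Polymerase-loading simulator

Parameters (defaults): k_on per 0.1 s step (free), k_off = 0.001 per step
(no published value; configurable), promoter ON window t_on = 15 min,
elongation 2.5 kb/min, gene 2.8 kb, nucleus diameter 5 µm, molecule diameter
15 nm, gene-region disc 1 µm, PSF FWHM 400 nm, 50,000 total molecules,
sampling every 9 s, pixel 0.108 µm. The background count in a rendered frame
is the nuclear total scaled by the exact spherical-slab volume fraction of
the central 3 × 0.3 µm slab (≈26.7% for a 5 µm nucleus). Engaged molecules
are rendered at the locus point — justified because 2.8 kb of chromatin is
far smaller than the PSF. Background molecules are resampled independently
per frame (no background diffusion dynamics): only the static enrichment
contrast matters for detectability, and this is the main simplification to
keep in mind. Rendering deposits unit flux at the nearest pixel and
convolves once with the Gaussian PSF; enrichment traces instead count
molecules directly in the gene-region disc (the PSF moves <0.2% of a locus
molecule's flux outside the 1 µm disc, so counting and integrating agree)
divided by the expected background count in an equal disc. One ON window per
simulation; OFF→ON cycling is out of scope. A k_on sweep tabulates loading
rate, burst duration and max enrichment per replicate, with detectability
defined as max enrichment ≥ 1.65 to match the imaging filter.

With k_off = 0 the gene is an M/D/∞ queue: mean engaged count =
(k_on/Δt)·(gene length / elongation rate). The test and acceptance runs
check this to 5% using 8 replicates of 15 simulated minutes (warm-up of
three traversal times discarded) — sizes chosen to keep the whole suite in
tens of seconds on one CPU while leaving the Monte-Carlo error well inside
the tolerance.

## Synthetic data: what it does and does not emulate

The trajectory generator draws a state per trajectory (no within-trajectory
switching, matching the one-D-per-trajectory analysis convention), a
geometric track length (memoryless photobleaching; minimum 3 localizations
so turning angles exist; the real track-length distribution is not
published, so the geometric mean of 8 frames is a stand-in), a start
position uniform in a circular nucleus (optionally concentrated in bound
hotspots), Brownian steps with per-axis variance 2DΔt reflected radially at
the nuclear boundary, and adds independent Gaussian localization noise per
localization (noisy localizations may fall marginally outside the boundary;
true positions never do). The movie generator renders an ellipsoidal nucleus
of uniform baseline with isotropic Gaussian clusters whose lifetimes come
from a two-component Gaussian mixture (defaults mirroring the measured
short/long populations: weight 0.33, means 2 and 7 min, sds 0.8 and 2 min),
plus up to two bright persistent HLB blobs and additive Gaussian noise —
additive rather than Poisson because the real inputs are deconvolved, which
already distorts shot statistics. Coupled burst traces take the MCP channel
proportional to the engaged-polymerase count and the RNAPII channel from the
simulator's gene-region enrichment.

Passing recovery tests on these generators therefore demonstrates
correctness of the estimators under the stated model — single-state
trajectories, isotropic Gaussian clusters, additive noise — not robustness
to real-data pathologies (defocus loss, state switching, anisotropic PSFs,
drift, segmentation errors in crowded nuclei), none of which are modeled.

## Numerical conventions

Voxel indices are 0-based; physical coordinates are point localizations in
µm; trajectory CSVs carry µm and 0.108 µm-pixel columns; stacks are TIFF in
(T, Z, Y, X) order with JSON voxel metadata. All randomness flows from one
global seed through per-stage SHA-256-derived seeds (< 2³¹). Degenerate
inputs fail loudly: empty trajectory lists, zero-variance traces, zero
nuclear masks and zero denominators raise; undefined fold-anisotropy (empty
forward window) reports NaN rather than infinity.
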