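# Methods

This note documents the models implemented in `bioscatter`, the
parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Scan handling and QVP construction

A `PolarScan` is one constant-elevation PPI sweep (rays × gates) of
Z_H, Z_V [dBZ], Z_DR [dB], ρ_HV [–] and K_DP [° km⁻¹].  Calibration is
additive in dB on Z_H and Z_DR (offsets are user configuration, default
0; the package does not derive them).  After calibration Z_V is
recomputed as Z_H − Z_DR so the reflectivity triplet stays
algebraically consistent.  Sector masks are inclusive azimuth intervals
(degrees clockwise from North) and blank whole rays; the shipped
default in the examples, 45°–185°, represents a radar with obstructed
easterly views.

Beam height above the antenna uses either the flat-earth form
h = r·sinθ (default) or the 4/3-effective-earth-radius form
√(r² + R′² + 2rR′sinθ) − R′, R′ = (4/3)·6371 km.  At 3° elevation the
flat model gives 1.570 km at 30 km slant range — the radius of a
60-km-diameter QVP cone; the two models differ by <1 % over that span,
which is why the flat model is an acceptable default at short range.

QVP averaging: the reflectivity factors are averaged across azimuths in
linear units (mm⁶ m⁻³) and converted back to dBZ; Z_DR, ρ_HV and K_DP
arithmetically in native units.  ρ_HV estimates above 1 (a known noisy
estimator; tolerated to 1.2 at ingest) are clipped to 1 before
averaging.  Gates are assigned to fixed-width height bins (default 25 m
from 0 to 2 km) by beam height; multiple gates in a bin combine with
contribution-count weights, and bins with fewer than `min_count` = 30
azimuth samples are masked so a heavily blocked sweep cannot yield
single-ray "profiles".  A median option exists for robustness
experiments; the mean is the default because azimuthal *averaging* is
the defining QVP operation.  Night windows are explicit UTC intervals
supplied by the user; no twilight ephemeris is computed.

## The classification algorithm

Input: the cells × 5 matrix of all complete (time, height) cells,
globally z-scored (cells with any missing variable are dropped, not
imputed — the QVP mask already encodes data quality).  The algorithm is
divisive ("top-down"): all points start as one cluster and leaves are
recursively considered for splitting.

**Inner loop (split proposal).**  The leaf's points are re-standardized
locally and projected onto the principal components that cumulatively
explain ≥ `variance_retained` = 0.95 of local variance (minimum 2
components).  For k = 1…`k_max` = 6 a centre-based partition is fitted
(scikit-learn k-means, greedy seeding, `n_init` = 10 restarts, seeded
per node from the global seed), and the compactness
C(k) = mean Euclidean distance of points to their cluster barycentre is
recorded.  On the normalized curve ρ(k) = C(k)/C(1) the proposal is the
smallest k ≥ 2 whose marginal gain ρ(k) − ρ(k+1) falls below
`elbow_epsilon` = 0.05 (with ρ(k_max+1) ≡ ρ(k_max)) — the point where
the clusters have reached "their most compact form".  If even the best
two-way split retains ρ(2) > `split_reject_rho` = 0.90 (splitting buys
< 10 % compactness), the leaf proposes no split.  In the full
five-variable space a single isotropic population has ρ(2) ≈ 0.92, so
the rejection threshold separates genuine structure from noise; in very
low-dimensional projections a spurious proposal can pass this gate and
is then caught by the outer loop.

**Outer loop (split acceptance).**  For a candidate leaf set, one
full-covariance Gaussian is fitted per leaf in the *global* standardized
space with mixture weight equal to the leaf fraction; covariances are
ridge-regularized by 10⁻⁶·trace/d (raised to 10⁻³ for leaves smaller
than d+1, with a warning).  The posterior score is the mean over all
points of the maximum posterior membership probability — exactly 1 for
a single leaf, near 1 for well-separated leaves, and ≈ the mixture
overlap when a homogeneous population is cut arbitrarily.  A split is
committed only if the new score ≥ max(`posterior_min` = 0.80,
previous score − `posterior_drop_tol` = 0.01).  Recursion also stops at
`n_min` = 50 cells, at `max_depth` = 6, or at a no-split proposal.

The score is invariant to leaf relabeling and to any affine rescaling
applied to all points, and the procedure is deterministic for a fixed
seed: per-node k-means seeds are derived from (global seed, node id),
so identical inputs always produce identical trees — a stability
property the tests assert bit-exactly.

These realizations of "compactness", "elbow" and "posterior
probability" are this package's explicit choices, isolated behind
`BCAConfig` so alternatives can be swapped in.

## Cluster profiling

Box-plot summaries use linear-interpolation quartiles and Tukey
whiskers (most extreme points within 1.5 IQR of the box; everything
beyond counts as an outlier).  The convention is documented because
quartile definitions differ between packages.  The meteorological flag
picks the cluster with the highest mean ρ_HV and requires
mean ρ_HV > 0.95 and |mean Z_DR| < 0.5 dB — the light-rain signature of
near-spherical, homogeneous targets; both thresholds are configurable.
The set of bioscatterer cluster ids is an explicit input to the nightly
abundance counter rather than being hard-coded to four.

## Ecological linkage

Traits: six measured morphometrics (mm) are extended by fresh mass
(allometric, mass = a·L^b with package defaults a = 0.04, b = 2.5 —
about 70 mg at L = 20 mm; override when a calibrated allometry is
available), thorax depth (an explicit per-species value when supplied,
else the circular-cross-section fallback depth = width) and the lateral
(body length / thorax depth) and anterior (thorax width / thorax depth)
aspect ratios.  Trait PCA is the correlation-matrix eigenproblem on
z-scored traits; component signs are fixed so each retained component's
loading sum is non-negative (PC1 then reads as overall size, PC2 as
shape).

CCA follows the classical chi-square formulation: with community matrix
Y (nights × clusters; row-proportional scalings are equivalent under
the chi-square metric, so relative or absolute cluster abundances give
the same ordination), P = Y/y.., row/column sums r and c, the residual
matrix is Q = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} and total inertia ‖Q‖².
Constraints are row-weight centred and scaled; columns that centre to
zero (e.g. an intercept) are dropped as null; remaining rank deficiency
is an error.  Q is projected onto the weighted constraint span; the SVD
of the projection gives the constrained eigenvalues, its complement the
unconstrained ones, and the two sums reconstruct the total inertia to
10⁻⁸ relative — an invariant the tests enforce, alongside agreement
with an independent generalized-eigenproblem solution.  Permutation
tests use pseudo-F = (constrained/q)/(residual/(n−q−1)) with whole-row
permutation of the constraints for the overall and per-axis tests;
sequential ("terms") and marginal ("margin") term tests permute the
residuals of the term after regressing out the previously entered (or
all other) terms.  p = (1+#{F* ≥ F})/(1+n_perm), default n_perm = 999,
seeded.  Four constraint variants are fitted — CWM-PC1/PC2 weighted by
abundance or by biomass, plus summed abundance and either summed
biomass or mass-squared abundance (MSA = Σ mass²·n, intended to scale
more nearly with reflectivity) — and the variant with the largest
proportion of constrained inertia wins, ties to the lowest number.

Shannon diversity is −Σp ln p in nats (the base is a convention; nats
chosen).  FDis embeds the Bray–Curtis dissimilarities of the raw
species × trait matrix by principal coordinates — negative eigenvalues
(Bray–Curtis is non-Euclidean) are dropped with a warning, or damped
with the square-root correction option — and returns the
abundance-weighted mean distance of species to the abundance-weighted
centroid.  The correlation battery screens both margins with
Shapiro–Wilk at α = 0.05 and uses Pearson only when both pass, else
Spearman with average ranks; results print in the R(df) style with
df = n − 2.  Nights with zero total catch are dropped from ordination
and diversity (their CWMs are undefined), mirroring the treatment of
non-sampling nights.

## The synthetic generator

`preset_fig4` encodes five scatterer populations as truncated
multivariate normals in the five-variable space, with means
(Z_H, Z_V, Z_DR, ρ_HV, K_DP):

| population | mean vector | envelope |
|---|---|---|
| bio1 | (−10, −12, 1.0, 0.68, −0.5) | 100–800 m, all night, sparse |
| bio2 | (0, −1, 1.0, 0.695, −1.0) | 0–300 m, mid-night, dense |
| bio3 | (−5, −7, 2.0, 0.60, −0.8) | 300–500 m, mid-to-late night |
| bio4 | (−4, −4, 0.0, 0.65, −2.5) | 0–300 m, late night |
| rain | (18, 19, 0.0, 0.97, 0.3) | full column, mid-night interludes on every 3rd night |

Diagonal SDs (2 dB, 2 dB, 0.3 dB, 0.02, 0.3 ° km⁻¹) are well below the
between-population separations, so the preset is separable by design; a
`fig4_hard` variant doubles them for stress tests.  ρ_HV draws outside
(0, 1] are rejection-resampled, which pulls the realized rain mean
≈ 0.003 below the nominal 0.97.  Envelope overlaps resolve to the
later-listed population.  Each night is generated from a seed derived
from (seed, night index), so a season equals the concatenation of its
single-night generations — a commutation property the tests assert.
Per population and night a lognormal activity factor (σ = 0.4)
modulates the fill probability, giving the nightly abundance variation
the linkage analysis needs.  The default grid is 33 nights × 16 scans ×
40 height bins (25 m to 1 km) ≈ 21 000 cells, of which roughly 11–12
thousand are filled; this size keeps a full clustering run near one
second while leaving per-population Monte-Carlo standard errors far
smaller than the acceptance tolerances.

The catch generator draws a nightly total around
exp(α + β·log(1 + bioscatterer cells)) with lognormal noise and
allocates individuals to species by a fixed log-series profile; two
sites are produced, the second active on 16 of the 33 nights.  Defaults
α = −1.5, β = 1.0, σ = 0.3 yield ≈ 60 moths per night and a Spearman
correlation of ≈ 0.55–0.6 between catch totals and radar cell counts —
the coupling strength the analysis is designed to detect.  β = 0
decouples the two sides for null calibration.

**What the generator does not emulate:** no electromagnetic scattering
physics (Rayleigh/Mie), no wind advection or insect flight behaviour,
no spatial correlation within a sweep (cells are conditionally
independent given population and envelope), no birds or bats, and no
within-night trend in the polarimetric means.  Passing tests therefore
demonstrate that the algorithmic chain recovers the structure it
assumes — separable Gaussian-ish populations with distinct polarimetric
signatures — not that real radar data satisfy those assumptions.

## Numerical conventions and degenerate inputs

* Missing data are masks end to end; a cell missing any variable is
  excluded from clustering.
* A constant variable across all cells (zero-variance z-score) is an
  error, as is a constant trait column in the PCA.
* Singular leaf covariances in the posterior score are
  ridge-regularized with a warning rather than failing.
* CCA community matrices must have positive row and column sums;
  constraints constant across sites are null, not errors.
* All randomness (scene, k-means restarts, permutations, catches) flows
  through named integer seeds; repeated runs are bit-identical.

## Known limitations

* The inner-loop elbow rule evaluates k-means partitions, which are
  spherical-cluster biased in the PCA space; strongly anisotropic or
  curved clusters may be over-split (then usually vetoed by the outer
  loop) or under-split.
* The posterior acceptance threshold effectively requires near-disjoint
  Gaussian leaves (score ≥ previous − 0.01 from a starting score of 1);
  heavily overlapping real populations would stop the recursion early,
  yielding coarser trees than the truth.
* Bray–Curtis on raw trait values weights large traits (mass) more than
  ratios; standardizing traits before FDis is a reasonable alternative
  the package does not default to.
* The fresh-mass allometry default is a placeholder magnitude, not a
  fitted model; analyses where absolute biomass matters must supply
  calibrated coefficients.
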