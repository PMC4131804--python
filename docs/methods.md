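# Methods

## Model and procedure

The package models an area-level incidence rate y (possibly
log10-transformed) as a linear combination of spatial eigenvectors derived
only from site coordinates:

    y = β0 + Σ_k β_k · v_k + ε,   ε ~ N(0, σ²) i.i.d.

The spatial vectors v_k are principal coordinates of a truncated Euclidean
distance matrix. Construction, in order:

1. One representative point per area: the population-weighted centroid of
   its settlement points. Coordinates must already be planar meters; the
   package refuses coordinate ranges that look like lon/lat degrees unless
   the caller explicitly asserts planarity, because silently treating
   degrees as meters deforms every distance.
2. D = Euclidean distance matrix; t = the longest minimum-spanning-tree
   edge, i.e. the smallest threshold keeping the ≤t graph connected.
3. W: w_ij = d_ij if d_ij ≤ t (inclusive), else 4t. The 4t constant is a
   device that pushes beyond-threshold pairs far enough away that the
   eigenvectors describe within-threshold structure; it is not a
   meaningful weight, which is why the Moran's I diagnostic uses binary
   within-t weights instead.
4. Gower double-centering of −½ W∘W, symmetric eigendecomposition,
   retention of eigenvalues λ > positivity_tol·λ_max (default 1e-9
   relative — separates true positives from floating-point zeros).
   Positive-λ vectors model positive spatial autocorrelation;
   negative-eigenvalue vectors are out of scope by design.

Assumptions worth stating: the response is a rate whose spatial mean
structure is linear in the eigenvectors; errors are homoskedastic and
independent given the spatial mean (no residual spatial error model); the
study areas are fixed, not sampled.

## Centering convention

The source method description says only that eigenvectors are extracted
from the "centered" W. The package's default is the standard
PCNM construction (PCoA of the truncated matrix, i.e. double-centering of
−½ W², `centering="gower_sq"`), which is what the reference R
implementation (`vegan::pcnm`) computes — the test suite asserts exact
eigenvalue agreement with it. A literal alternative that double-centers W
itself is available as `centering="raw"` for sensitivity analysis.

## Eigenvector conventions

Scores are returned unit-norm with zero mean; a √λ rescaling
(`EigenMap.scaled_scores()`) reproduces intersite distances when the map
is untruncated. The regression is invariant to column scaling
(standardized coefficients are reported), so unit norm is the simpler
default. Signs are fixed deterministically: each column's
largest-magnitude entry is made positive, ties broken by lowest site
index. Vectors are numbered 1-based, broadest (largest λ) first.

## Incidence rates

rate_i = scale · (Σ_years cases_i) / (Σ_years person-years_i), scale
defaulting to 1,000. Pooling precedes division, so zero-case years are
absorbed rather than producing zero or undefined annual rates. Sex-specific
responses require the matching sex-specific denominator; a missing sex
column under a sex filter is an error, not a warning. Age adjustment is
deliberately absent: the question the pipeline answers is how much spatial
structure *alone* explains.

Normality gate: Lilliefors-corrected Kolmogorov–Smirnov by default (mean
and sd are estimated from the data, so the uncorrected KS is
anti-conservative); `variant="plain-ks"` reproduces toolchains that use
the plain test. Rates failing the test at alpha (default 0.05) are
log10-transformed. A zero pooled rate under log10 is a hard error by
default; `zero_policy="offset"` adds half the smallest nonzero rate and is
meant for exploration, not production.

## Forward selection and the double stop

Entry statistic: the partial-F test of the entering coefficient (computed
by projecting each candidate off the current design; equal to the
coefficient's t-test, and asserted equal to per-candidate OLS refits in
the tests). Ties are broken by larger r² increment, then by lower vector
number (broader scale preferred). Pure forward selection — no backward
elimination step.

The ceiling r²_adj(full) is the adjusted r² of the model containing every
candidate vector. Selection stops when no candidate attains p < alpha
(`alpha_exhausted`) or when the running adjusted r² has reached the
ceiling (`r2_ceiling_reached`), checked before each entry — so under a
pure-noise response, where the full-model adjusted r² sits near zero,
selection terminates almost immediately, which is the point of the rule.
If the candidate count m ≥ n − 1 the full model is unfittable; the package
falls back to the broadest n/2 vectors for the ceiling and warns. An
optional global pre-test of the full model exists but is off by default.
No multiple-testing adjustment is applied across separate disease models;
each response is analysed independently, as is conventional here.

Diagnostics: internally studentized residuals e_i/(s√(1−h_ii)) (a raw
e_i/s variant exists); outliers flagged at |z| > 3 and by single-pass
Chauvenet (flag when n·P(|Z|>|z|) < 0.5, critical |z| = Φ⁻¹(1−0.25/n) ≈
3.16 at n = 320, which is why Chauvenet flags are a subset of |z|>3 flags
at registry-scale n).

## Synthetic study systems

The generator emulates the study design the pipeline targets: a few
hundred irregular sites (default 320 in a 1,100 km × 550 km 2:1
rectangle — national scale without any real geography), responses planted
as linear combinations of known eigenvectors plus Gaussian noise, and
Poisson case counts cases ~ Poisson(rate·py/1000) over per-site
person-years (default 10⁵ per site-year scale). Poisson, not
negative-binomial: constant rate per area is the assumption the pooling
already makes; overdispersion is a documented extension.

What the generator does *not* emulate — and hence what green tests do not
establish about real registry data: clustered settlement geography
(uniform layouts retain ~55–62% positive eigenvectors vs ~52% for a real
clustered national layout), migration between areas, temporal rate trends
within the pooling window, and non-Poisson overdispersion. Recovery
results transfer only insofar as real spatial signals resemble sparse
linear combinations of the leading eigenvectors.

## Numerical choices

- Eigendecomposition: `numpy.linalg.eigh` on the explicitly symmetrized
  centered matrix; positivity tolerance relative to λ_max.
- MST: scipy's csgraph on the dense distance matrix; co-located sites
  (d = 0) are kept connected by a constant edge-weight shift that leaves
  the MST edge set unchanged, and trigger a warning since their scores are
  non-unique.
- Entry-test degeneracy: candidates whose projection off the current
  design is numerically zero (relative 1e-12) are treated as
  non-admissible (p = 1) rather than producing 0/0.
- Perfect fits (SSE ≈ 0) return studentized residuals of exactly 0 instead
  of 0/0.
- Determinism: all generators take explicit seeds through
  `numpy.random.default_rng`; the pipeline writes no file until every
  stage has succeeded, and a config hash (analytic fields only, output
  path excluded) is recorded in the report.

## Problem sizes

Tests and the acceptance script run on lattices up to 10×10, transects of
50 sites, national-scale layouts of 320 random sites, and 100-replicate
selection experiments — sizes chosen so the full suite completes in well
under a minute while leaving the selection experiments enough replicates
for stable rates.

## Known limitations

- Planar coordinates only; no geodesic distances or reprojection.
- No negative-eigenvalue vectors, no variation partitioning, no spatial
  error or Bayesian smoothing models; PCNM complements, not replaces,
  small-area smoothing.
- The exact spatial wavelength per vector is undefined on irregular
  layouts; sign-change counts and Moran's I are reported as scale proxies.
- Forward selection inherits the usual caveats of stepwise procedures;
  the double stop curbs, but does not eliminate, selection noise (a few
  small spurious vectors typically enter at realistic noise levels).
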