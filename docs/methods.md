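# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `floralevo`, and what the synthetic-data validation does and
does not establish.

## Trees and units

Trees are rooted, may contain polytomies, and carry branch lengths in the
units of the source phylogeny (typically ML substitutions/site). Ages of
allopolyploid origins (Myr) are registry metadata only; branches are never
rescaled by age, and origin anchors are located topologically (where the
homeolog copy tip attaches to its progenitor lineage). Zero-length branches
are permitted at tips (multiple accessions of one species attach as a
zero-length polytomy); for likelihood work every near-zero branch is floored
at ε = 10⁻⁸ and the number of floored edges is reported on the fit object.
Unlabeled internal nodes receive stable generated names (`nd<i>`, preorder
index at parse time) so reconstruction output is addressable across pruned
views.

## Brownian-motion ancestral reconstruction

Model: a univariate trait follows a Brownian random walk with rate σ²
(trait-units²/branch-unit) from an unknown root state μ. Tips are jointly
normal, x ~ N(μ1, σ²C), C the shared-path-length matrix.

Estimation is fully closed-form and deterministic: μ̂ is the GLS mean, σ̂²
the n-divided ML estimate, and internal states are conditional expectations
E[state | tips], which are independent of σ². The states coincide with the
joint-ML (graph-Laplacian / weighted harmonic) solution; the test suite
verifies this equivalence on random trees and the fixture values against an
independent R implementation. Note the σ² *convention*: we report the
tip-likelihood ML value (divide by n); implementations that maximize the
joint likelihood of states and rate report a value smaller by
n_tips/n_edges. States are unaffected.

Shape is treated as two independent BM traits (PC1, PC2) reconstructed
separately and paired per node afterward — matching the univariate tooling
the analysis chain mirrors; a correlated-BM reconstruction is out of scope.

Progenitor phenotypes at an allopolyploid's origin: all homeolog copy tips
are pruned (the diploid view; pruning preserves path lengths and records
where each suppressed node sits on the surviving edges), states are
reconstructed from diploid data only, and each anchor point is evaluated by
the Brownian-bridge conditional mean
(x_parent·d_child + x_child·d_parent)/(d_parent + d_child) on its edge.
When the anchor coincides with a surviving diploid node the two routes are
identical; the interpolation is equivalent to marginalizing data-less tips.

## Substantial shifts

A shift is an edge (internal→internal, or internal→tip using the extant
value) whose absolute trait change strictly exceeds `fraction` × extant
range. Default fraction 0.10 — of the order of median intraspecific
variation relative to the interspecific range. Scalar ranges are max − min;
the 2-D shape range is the maximum pairwise Euclidean distance among extant
(PC1, PC2) means, and the shape shift magnitude is the Euclidean norm of
(ΔPC1, ΔPC2). Per-axis thresholds are a config alternative. The root has no
parent edge and contributes no row.

## Divergence vectors and the Moore-Rayleigh test

Vector planes: (tube_length, tube_width) in cm, or (PC1, PC2)
dimensionless. Axes are *not* z-scaled by default (the planes are plotted
and tested raw; optional standardization exists but changes the question
being asked). Diploid vectors: child minus parent value across every edge
of the diploid tree. Allopolyploid vectors: accession mean minus progenitor
midpoint (elementwise mean of the two progenitor phenotypes, extant or
reconstructed). Zero-magnitude vectors carry no direction; they are
excluded from the tested set and kept on a flagged side list. Axis-aligned
vectors get explicit "unchanged" labels instead of an arbitrary quadrant.

Moore's statistic ranks magnitudes ascending (average ranks on ties — ties
are essentially impossible with continuous data but the behavior is
deterministic) and computes R* = |Σ r_i e^{iθ_i}|/n^{3/2}. p-values are
+1-corrected Monte Carlo under fixed ranks and uniform angles; the
implementation was validated against every published (R*, N, bound) triple
of the study's headline table. Bonferroni correction divides α by the
number of tests actually run (14 in the default pipeline). Monte Carlo
defaults: 10⁵ replicates, seed mandatory.

The hierarchical replicate design (photos in flowers in plants in
accessions in species) is averaged strictly as means-of-means, one level at
a time, so unequal replicate counts never reweight higher levels.

## Phylogenetic signal

Blomberg's K uses the standard ratio-of-ratios with the phylogenetically
corrected mean; its randomization test permutes tip labels and compares the
variance of Felsenstein's standardized contrasts (polytomies resolved
internally with zero-length connectors), p = (1 + #{var_perm ≤
var_obs})/(B + 1), one-sided, B = 1000 by default. Pagel's λ multiplies
off-diagonal entries of C, is profiled on [0, 1] by bounded scalar
optimization (endpoint candidates checked explicitly so boundary optima are
representable), and is tested against λ = 0 by a χ²₁ LRT.

Boundary caveat, deliberate: when the truth is λ = 0 the estimate sits at
the boundary in roughly half or more of replicates, so the LRT statistic is
a point-mass mixture and its χ²₁ p-values concentrate at 1 rather than
being uniform. The acceptance suite asserts the idealized uniformity check
anyway and that assertion fails by design; the calibration that *is*
attainable (median λ̂ ≈ 0 under the null, K centered on 1 under BM, type-I
control of the randomization test) is asserted separately and holds.

## Convergent-regime search

Hansen model: trait pulled with strength α toward the optimum θ of the
regime painting each edge; root state equals the root regime's optimum.
Tip expectations are exponentially weighted sums of optima along each
lineage; covariance Cov(i,j) = σ²/(2α)·e^{−α d_ij}(1 − e^{−2α t_ij}) with
t_ij the root-to-MRCA time and d_ij the tip-tip path distance — valid for
non-ultrametric trees and continuous in α → 0 (BM limit), implemented with
`expm1` so α = 10⁻⁹ is numerically exact to ~10⁻⁹. A diagonal ridge of
10⁻⁹ × tree height keeps factorization stable when polytomy accessions
coincide. Per trait, θ̂ and σ̂² are GLS-profiled given α; α is optimized by
bounded scalar search on [10⁻⁸, 50/height] with an explicit near-zero
(BM-like) candidate check. All traits share the painting; parameters are
per-trait.

Model score: AICc with k = n_traits × (2 + n_regimes) parameters and
sample size n = n_tips (traits are measured on the same species and do not
multiply the independent phylogenetic units), **plus** a positional cost of
2·ln(n_edges) per shift. The positional term prices the fact that each
shift's edge is chosen by search over all edges (the standard
changepoint-selection argument); without it, best-of-all-edges selection
accepts spurious shifts on a majority of null datasets. With it, the search
keeps a single regime on ≥ 90% of single-regime OU simulations (24-tip
trees) while still recovering strongly planted two-clade convergence and
merging it in the backward phase. This is a simplified reimplementation of
the stepwise Hansen-model search, not a bit-compatible port of any existing
package; recovery of planted regimes, not output equality, is the
validation standard. After the backward phase, no-op shifts (a shift whose
regime equals the regime directly above it) are dropped and regime ids
renumbered contiguously; convergent regimes are those with ≥ 2 surviving
independent origins.

## Spectra and landmarks

Smoothing: centered rolling average, window specified in nm (9 nm default)
converted to the nearest odd sample count on the instrument grid, three
passes by default; edges use truncated windows (a constant spectrum is
exactly invariant; interior points equal the triple-convolved kernel).
Normalization: trapezoidal area over exactly [300, 700] nm (interpolated
band endpoints) scaled to 1; idempotent and intensity-invariant. PCA:
spectra linearly resampled to the 17-point 25-nm grid, covariance PCA,
retain components with variance fraction strictly > 0.05. Sign convention
everywhere: the largest-|loading| element of each component is positive, so
downstream quadrant labels are stable.

Landmarks: 15 per photograph. Full generalized Procrustes: center, scale to
unit centroid size, iteratively rotate to the mean (SVD rotation with
reflections disallowed — photographs are taken consistently), re-estimate
until the mean moves < 10⁻¹⁰ (max 1000 iterations; typically ≤ 5). Shape
PCA operates on the flattened 30-coordinate vectors. Tangent-space
projection is omitted: at the small Procrustes variances of flower-limb
data the aligned coordinates are already effectively tangent-plane, an
approximation relative to relative-warps outputs that we document rather
than assert away.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the study scale and serve as the fixed validation
conditions: a Yule tree with 32 diploid tips (birth rate 1; tip edges
extended by the waiting time to the next unrealized speciation, so no
zero-length terminals); six allopolyploid origin events at ages (0, 0.4,
0.6, 0.7, 1.4, 4.3) Myr contributing 13 young and 7 old accessions with
distinct random progenitor pairs; BM trait rates σ² = 1 (shape PCs, tube
length) and 0.04 (tube width) from roots (0, 0, 4 cm, 0.8 cm), tube values
floored at small positive constants (BM is unbounded; the floor is rare and
recorded); displacement of each accession mean from its *extant* progenitor
midpoint with von Mises direction (length/width plane: κ = 4 toward 135°,
i.e. shorter-wider; shape plane: κ = 0, uniform) and magnitude 0.25 × extant
range × U(0.5, 1.5) (the jitter gives distinct magnitude ranks); replicate
noise at 5%/3%/2% of the extant range for plant/flower/photo levels;
origin anchors placed a fraction age/(1.25·max age) up the progenitor's
terminal edge, with true anchor states drawn from the exact Brownian
bridge. Spectra are baseline-minus-Gaussian-dip archetypes under intensity
scaling and noise; landmark specimens deform a 15-point flower-limb
template along a round-to-stellate axis under random similarity transforms.

What passing on these data shows: the estimators and tests are correctly
implemented, calibrated under their own model assumptions, and able to
recover planted effects of realistic size. What it does not show: behavior
under model violations present in real data — measurement error correlated
across traits, non-Brownian evolution, tree misestimation, transgressive
(non-midpoint-displaced) polyploid phenotypes, or pigment-specific spectral
structure.

## Problem sizes and determinism

All randomness flows through explicit seeds (`numpy.random.Generator`;
child streams via `SeedSequence.spawn`), and every pipeline output is
byte-reproducible under a fixed config. The validation suite uses Monte
Carlo sizes chosen as the package's own accuracy/runtime balance: 10⁵ null
replicates for published-bound checks (2×10⁵ in the acceptance script),
5000 datasets per sample size for type-I calibration, 1000 BM replicates
for K calibration, 500 replicates for power/size of the displacement test,
100 null and 12 planted searches for the convergence operating
characteristics, and 200 random trees for oracle equivalence.

## Known limitations

* Univariate BM/OU throughout; no correlated-trait or rate-heterogeneous
  models.
* λ̂ is bounded above at 1.0 (not the algebraic maximum of C).
* The Moore-Rayleigh test conditions on magnitude ranks; magnitudes enter
  only ordinally.
* The convergence search is greedy; it can stop at a local AICc optimum,
  and its penalty convention (documented above) is a design decision that
  anyone comparing against other Hansen-search implementations should keep
  in mind.
* The diploid edge-vector count includes every edge of the diploid tree
  (2n − 2 for a bifurcating rooted tree); whether to exclude root-adjacent
  edges is exposed, not decided, by the data model — the default excludes
  nothing.
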