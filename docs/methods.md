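# Methods

## The model

`buds` infers a latent one-dimensional coordinate τ_i ∈ [0, 1] for each of
n samples from their pairwise dissimilarities d_ij. The premise is that the
samples lie near a one-dimensional manifold (a depth gradient, a
developmental time course, an ideological spectrum), so observed
dissimilarities are noisy versions of distances along that hidden axis.

Dissimilarities are modeled as Gamma random variables in the mean/variance
parameterization (shape = μ²/σ², rate = μ/σ²):

    d_ij ~ Gamma(μ_ij = b + ρ·|τ_i − τ_j|,  σ²_ij = s²_ij · σ_ε²)
    τ_i ~ Beta(α_τ, β_τ)
    α_τ, β_τ ~ Cauchy⁺(1, γ_τ)       ρ ~ Cauchy⁺(1, γ_ρ)
    b ~ Cauchy⁺(0, γ_b)              σ_ε ~ Cauchy⁺(0, γ_ε)

The Gamma has positive support, matching nonnegative dissimilarities, and
the variance factors into a per-pair relative scale s²_ij (estimated from
the data, mean-normalized to 1) times a global magnitude σ_ε² (a latent
variable). The shift/scale pair (b, ρ) reconciles the range of d_ij, which
lives on whatever scale the chosen metric produces, with distances on
[0, 1]; it is on by default and can be disabled. The hierarchical Beta
prior on τ is centered at the uniform (α_τ, β_τ near 1) but can tilt to
represent uneven sampling density along the gradient. Cauchy⁺(c, γ) is a
Cauchy located at c truncated to (0, ∞), with its truncation normalizer
included so joint densities are comparable across hyperparameters.

Assumptions worth stating: a single dominant 1-D gradient (no branching),
independent Gamma noise across pairs (in truth the n(n−1)/2 dissimilarities
share n underlying points, so they are correlated; the model ignores this,
as pair-likelihood models generally do), and strictly positive observed
dissimilarities (exact duplicate samples are rejected with instructions to
deduplicate rather than silently jittered).

### Identifiability

Two directions are weakly identified by construction. The reflection
τ → 1 − τ leaves the likelihood invariant; `orient` resolves it after
fitting by aligning τ with the first principal coordinate of the input
dissimilarities. An approximate affine trade-off between the spread of τ
and (b, ρ) is constrained only by the [0, 1] support and the Beta prior;
it inflates marginal uncertainty in τ without affecting the ordering.

## Dissimilarities and noise scales

Three metrics cover the intended input types: Jaccard distance on
presence/absence (counts thresholded at > 0; no rarefaction — library-size
normalization is left to the user), the scaled Pearson correlation distance
(1 − ρ)/2 for continuous profiles such as log-expression, and the
normalized L1 / Hamming fraction for binary vote-style data. Any
user-supplied symmetric matrix also works. The optional ordinal transform
d̃ = 1 − sqrt(1 − rank(d)/m), with m = n(n−1)/2 upper-triangle values and
average ranks for ties, spreads distributions concentrated away from zero;
it is off by default.

The relative noise scale for pair (i, j) pools the distances from x_i to
the K nearest neighbors of x_j and from x_j to the K nearest neighbors of
x_i — excluding x_i and x_j themselves, so a self-distance of zero can
never inflate the estimate — and takes the unbiased variance of that pool.
K defaults to 10; the estimates are intentionally only relative, so they
are divided by their off-diagonal mean, and σ_ε carries the absolute
magnitude. Numerical guards: raw variances are floored at
1e−6 × (mean d)², preventing zero scales on degenerate equidistant or
duplicated data, and KNN ties at the K-th neighbor break by sample index
after a stable sort so neighborhoods are platform-independent.

## Inference

The default backend is mean-field ADVI implemented directly in numpy:
parameters map to an unconstrained space (logit for τ, log for the positive
scalars), the posterior is approximated there by a diagonal Gaussian, and
the ELBO is maximized with Adam (learning rate 0.02, 2 reparameterized
gradient samples per step) using the model's analytic gradients. The
optimizer runs at most 10⁴ iterations, evaluating the ELBO every 25
iterations on 8 fresh samples, and stops when 100 consecutive evaluations
fail to improve the best ELBO by a relative 1e−4. Variational means for τ
initialize at the rank order of the first principal coordinate of D mapped
evenly into (0, 1) — classical scaling already captures the dominant
gradient, and a cold start risks permutation-type local optima. Final draws
(default 500) are sampled from the fitted Gaussian and pushed through the
constraining bijections. Everything consumes one seeded generator, so a
(seed, backend, inputs) triple reproduces draws bitwise.

The point estimate reported for each τ_i is the posterior mean of the
oriented draws; with a Gaussian variational family the mean and mode
coincide in the unconstrained space. Intervals are highest-posterior-
density intervals: the narrowest contiguous window of sorted draws holding
⌈mass·T⌉ of them (default mass 0.95).

Mean-field ADVI is fast and recovers orderings accurately, but it cuts the
correlated affine direction described above, so its marginal HPDIs for τ
under-cover the truth — a known property of mean-field approximations, and
the reason an MCMC backend exists. `backend="mcmc"` runs an
affine-invariant ensemble sampler (emcee) on the same unconstrained
posterior. The ensemble sampler mixes well for small problems (tens of
samples; coverage checks in the test suite use n = 12) and poorly in the
higher-dimensional regimes where ADVI is the practical choice; treat it as
a calibration tool, not a default.

## Ordering products

Seriation orders heatmap columns by ascending τ̂ and rows by the feature
score z_k = (x̃_k·τ̂)/(x̃_k·1), where x̃_k is row k of the
column-normalized matrix (unit column sums by default — the compositional
view; unit-norm columns are available). z_k is the expected latent location
where feature k resides, so features entering sequentially along a gradient
produce a banded/triangular reordered matrix. All-zero feature rows carry
no location information and sort last. Covariate association is the
Spearman rank correlation (average ranks for ties) between τ̂ and an
external variable. Feature trends are LOESS local-linear fits (tricube
weights, span 0.5, no robustness iterations — keeping the smoother
deterministic and exact on linear signals) evaluated on the sorted unique
τ̂ values.

## Posterior geometry

PCoA is classical scaling: eigendecomposition of the double-centered
squared-distance matrix, coordinates scaled by the square root of the
positive eigenvalues, percent variance over positive eigenvalues only.
Axis signs are fixed deterministically (largest-magnitude coordinate
positive, or oriented by τ̂ when provided). t-SNE runs on the precomputed
matrix with a fixed seed.

For uncertainty visualization the model runs generatively: each posterior
draw defines latent distances δ*_ij = b + ρ|τ_i − τ_j| and a simulated
dissimilarity matrix with independent Gamma entries on the upper triangle,
mirrored to symmetric. The stack of t such matrices (default 50, matching
the number of posterior trajectories drawn in embedding plots) forms a data
cube registered by DiSTATIS: per-slice double-centered cross-products are
normalized by their leading eigenvalue (the canonical normalization; a
trace-normalization variant is available, and the choice is recorded in
the result's `normalization` tag), weighted by the leading eigenvector of their
RV-coefficient matrix, and summed into a compromise whose eigenpairs give
consensus coordinates; each slice projects into that space.

Density clouds are Gaussian KDEs (Scott's plug-in bandwidth, recorded in
the output) over all t×n projected positions on a 128² grid padded by four
bandwidths, which keeps the trapezoid-rule integral within 2% of 1.
Per-sample confidence contours are highest-density regions of that sample's
t projected positions at levels {0.5, 0.8, 0.95}; thresholds come from the
sorted-density cumulative mass on the grid, polylines from marching
squares. Clouds need at least 10 slices; degenerate (zero-variance or
collinear) clouds are flagged rather than contoured.

## Synthetic data

The generator plants a known gradient so every stage is testable without
external data. τ_true is drawn from Beta(a, b): (1, 1) for even coverage,
(3, 1) to emulate the uneven sampling designs where uncertainty should
visibly widen in the sparse tail. Counts mode gives each of p features a
Gaussian response curve along τ (centers equally spaced on [0, 1], width
0.15 so a species spans roughly a third of the gradient — enough overlap
to produce the horseshoe curvature typical of gradient data in linear
ordinations) with peak heights uniform on [20, 100] and Poisson sampling;
this yields the banded presence/absence structure Jaccard works well on.
Continuous mode uses random sigmoid kinetics (amplitude 1–3, slopes 5–20,
random direction) plus Gaussian noise, emulating smooth expression
dynamics. Binary mode thresholds logistic responses, emulating vote
matrices. Poisson rather than negative-binomial counts are the default —
the simplest model that produces gradient-structured supports; real
sequencing data adds overdispersion, library-size variation and taxon
correlation structure that these fixtures deliberately omit, so passing
tests demonstrate correct method behavior on clean gradients, not
robustness to every real-data artifact.

`generate_model_draw` samples dissimilarities from the model itself
(defaults n = 50, b = 0.05, ρ = 1, σ_ε = 0.3, uniform scales) and is the
fixture for exact-model parameter recovery. Gamma draws are floored at
1e−12 because at σ_ε ≈ 0.3 with means near b the implied shape is of order
0.03 and the sampler can underflow to exactly zero, which is outside the
likelihood's support.

## Problem sizes and tolerances

The test suite and the acceptance script run the recovery studies at
n = 50–60 samples with 10 seeds each and 500 posterior draws, sizes at
which a single fit takes a few seconds and results are stable. Oracle
comparisons (log-density, KNN neighbor sets, HPDI windows, DiSTATIS) use
tiny instances (n ≤ 8, t = 2) where from-definition reference
implementations are feasible, with agreement required to 1e−8 or exactly.
PCoA must reproduce Euclidean configurations to 1e−8 (Gower's theorem).
Monte-Carlo identities (cube entry means) are checked inside 3σ bands at
t = 2000.

## Known limitations

- Mean-field ADVI under-covers τ marginals (see Inference); use the MCMC
  backend when calibrated intervals matter and the problem is small.
- The ensemble MCMC backend mixes poorly beyond a few dozen samples.
- A single gradient is assumed; branching trajectories, clusters without
  an ordering, or two independent gradients violate the model.
- Exact duplicate samples (zero dissimilarity) are rejected, not merged
  automatically; deduplicate before fitting.
- k = 1 latent dimension only; no alternative likelihoods.
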