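# Methods

## Model and test

Let g₁, …, g_k be populations of undirected graphs on a common vertex set
size n, each population assumed to be an i.i.d. sample from some
random-graph process.  The null hypothesis is that all k processes are the
same, expressed through spectral distributions: H₀ holds when
KL(ρ_gᵢ ‖ ρ_gM) = 0 for every i, where ρ_gᵢ is population i's spectral
density and ρ_gM the average of the k densities.  The statistic

Δ = Σᵢ KL(ρ̂_gᵢ ‖ ρ̂_gM)

is nonnegative, zero iff all estimated densities coincide, and finite by
construction: wherever ρ̂_gᵢ > 0, the reference satisfies
ρ̂_gM ≥ ρ̂_gᵢ/k > 0.  For k = 2, Δ equals twice the (unnormalized)
Jensen–Shannon divergence.

Because the null distribution of Δ is not known analytically, inference is
by permutation: graph-to-population labels are reshuffled without
replacement preserving the group sizes |gᵢ|, Δ̂\* recomputed B times, and
the p-value taken as #{Δ̂\* ≥ Δ̂}/B (ties count as exceedances).  An
optional (1 + #)/(B + 1) correction is available for reporting; the plain
fraction is the default so simulation calibration matches the permutation
construction exactly.  A plain-fraction zero means "below 1/B".

The permutation test is exact under exchangeability of graphs across
populations, which holds under H₀ whenever the graphs are i.i.d. draws.
Its key modelling assumption is therefore only that graphs within a
population are independent samples; the per-graph model parameters may
themselves be random, provided they come from a distribution with finite
variance.

## Spectral density estimation

Per graph: eigenvalues of the (possibly weighted) symmetric adjacency
matrix; Gaussian kernel placed on each eigenvalue; renormalization so the
trapezoid integral over the evaluation grid is one.  The bandwidth is
(λ₁ − λₙ)/m with m = ⌈log₂ n + 1⌉ (Sturges), recomputed per graph from its
own spectrum.  Population densities are arithmetic means of per-graph
densities; since each integrates to one and the integral is linear, the
mean does too.

Numerical choices:

* **Common grid.**  All densities entering one analysis are evaluated on a
  single grid spanning [min λ − 3·h_max, max λ + 3·h_max] over every graph,
  512 equally spaced points by default.  Cross-density operations on
  mismatched grids raise immediately.
* **Bandwidth floor.**  The effective kernel width is floored at the grid
  spacing: a kernel narrower than one grid cell cannot be resolved and can
  lose all its mass between grid points.  This matters for degenerate
  spectra — an empty graph has all eigenvalues 0 and spread 0, for which
  the bandwidth alone falls back to max(10⁻³, |λ₁|·10⁻³) with a logged
  warning.  Under the truncated-normal parameter law such graphs occur
  regularly (edge probabilities near 0), so the floor is load-bearing.
* **KL integration.**  Trapezoid rule on the shared grid with the
  0·log(0/·) = 0 convention and a mass floor of 10⁻¹²: values of q below
  the floor where p is above it trigger the +∞ branch (support violation).
  On analytic densities spanning very wide grids this branch can fire in
  the far tails; in the test suite grids are chosen so both densities stay
  above the floor, with truncation error below 10⁻⁷.
* **Eigenvalue scaling.**  Dividing all eigenvalues by n or √n is offered
  but defaults to off: when every graph in an analysis has the same n, a
  common affine rescaling rescales the grid, bandwidths and density values
  together and leaves every KL term — hence Δ and the p-value — unchanged
  (asserted as a test).  The raw scale keeps the numerics in a convenient
  range.
* **Caching.**  Per-graph densities are label-invariant, so they are
  estimated once and the permutation loop only re-averages rows of the
  density matrix.  This path is asserted to be bitwise identical to naive
  re-estimation.

## Random-graph models and parameter laws

The five generators take a normalized parameter θ ∈ [0, 1] in the
simulations: edge probability (Erdős–Rényi), connection radius in the unit
square (geometric, d = 2, open boundary, strict inequality), vertex degree
(k-regular), rewiring probability (Watts–Strogatz, one-dimensional ring,
4 neighbours per side in the simulations), and preferential-attachment
exponent (Barabási–Albert, one seed vertex, one edge per arrival,
attachment weight degree^power with 0⁰ ≔ 1 and a uniform fallback while
all weights are zero).

θ is drawn per graph from a truncated normal with bounds 0 and 10, mean 1
(shifted alternatives: 1.5) and unit variance, divided by the upper bound.
Sampling is by inverse CDF on the truncated interval, so a fixed seed gives
a fixed draw without rejection loops.  Integer-valued parameters (degree,
attachment exponent) use ⌊10·θ⌋; draws that make the generator infeasible
(degree 0, odd n·deg) are resampled and counted.  Applying the integer rule
to the attachment exponent — which need not be an integer — follows the
simulation design being reproduced and is kept literal.

The k-regular sampler uses the pairing (configuration) model with retries
to guarantee a simple graph of exact degree, via networkx's regular-graph
generator; exact uniformity over regular graphs is not required by any
property tested here.  The Watts–Strogatz rewiring walks the lattice lap by
lap (distance-1 edges first), keeps the lattice-order endpoint and
re-targets the other uniformly avoiding self-loops and duplicates, so the
edge count n·nei is conserved exactly — the feature that makes the model a
blind spot for edge-count comparisons.

## Simulation study

Four scenarios on three populations: (1) all Erdős–Rényi with one shared
parameter law — type-I error; (2) the middle population's law shifted to
mean 1.5 — power vs group size; (3) as (2) with unequal group sizes —
balance penalty; (4) the middle population Watts–Strogatz instead of
Erdős–Rényi, with an optional fraction of graphs generated from the other
group's model while keeping the label (mislabeling, applied symmetrically
by default with a direction flag).  Replicated runs yield rejection
proportion vs nominal threshold (ROC-style curves, nondecreasing by
construction).

The feature benchmark generates the same three-population design for each
model and compares the spectral test against one-way ANOVA on edge count,
mean betweenness, mean closeness, degree assortativity, transitivity and
global efficiency (computed via igraph; verified against a brute-force
shortest-path oracle in the tests).  Disconnected graphs use the 1/∞ = 0
convention for closeness and efficiency; assortativity of zero-degree-
variance graphs (all k-regular graphs) is recorded as missing and that
replicate's ANOVA is skipped with a count.  ANOVA on inputs with no
variability at all returns p = 1 by convention — consequential for the
Watts–Strogatz edge count, which is *exactly* constant, so the edge-count
ANOVA never rejects there rather than rejecting at the nominal rate.
Rejection proportions carry Wilson 95% intervals, which behave near 0
and 1.

**Problem sizes.**  Default simulation sizes are scaled for a single CPU:
60-vertex graphs, groups of 20 (benchmark: 100 vertices, groups of 30),
200 replicates, 100 permutations.  The original study sizes (300 vertices,
groups of 50–125, 1,000 replicates and permutations) are reachable through
the same configuration objects and the CLI's `--full` flag.  Statistical
power depends on both n and the group size; at groups of 30 the
between-graph parameter dispersion (normalized truncated-normal sd ≈ 0.08
against a mean shift of 0.035) caps the power of *any* method near 0.3–0.4,
while at groups of 100 the spectral test reaches ≈ 0.9 for both the
Erdős–Rényi and Watts–Strogatz designs.  Scaled runs preserve the
qualitative orderings (calibration, power monotonicity in size and balance,
mislabeling degradation, the edge-count blind spot), not the absolute
power levels of the full-size study.

## Connectivity pipeline

Per subject: Spearman correlation between all ROI pairs (average-rank
ties, two-sided p-values from the t approximation), Fisher z-transform
(|ρ| = 1 clipped at 1 − 10⁻⁷ with a warning), then per-edge OLS
residualization of the subjects × edges matrix against an intercept plus
site, gender, age and scrubbing proportion (categoricals one-hot encoded
with a reference level; collinear designs fall back to the minimum-norm
fit — residuals stay orthogonal to the design either way).  "GLM" here is
ordinary least squares with identity link: the response is a continuous
z-value.  Edgewise p-values can be Benjamini–Hochberg adjusted; sub-network
graphs are principal submatrices over the ROIs carrying a label, weighted
by residual z by default (the spectrum of any symmetric matrix is
well-defined, negative weights included) or binarized at an FDR cutoff
behind a flag — no published rule fixes this choice, so both paths are
kept and tested.

## Synthetic cohort generator

Stands in for a real imaging cohort; it is synthetic by design and named
accordingly.  Each subject's ROI series is multivariate normal with a
block-structured correlation template: one block per canonical sub-network
(somatomotor, visual, default-mode, cerebellar, fronto-parietal), 0.3
within blocks and 0.05 between by default — magnitudes typical of
resting-state functional correlations.  A planted group effect raises one
group's named block by δ = 0.25 on the correlation scale, a strong but
plausible group difference chosen once so recovery is expected rather than
marginal.  Nuisance covariates shift *every* edge's correlation on the
Fisher-z scale with known coefficients (site 0.15, gender 0.08, age 0.012
per year, scrubbing 0.4), making confound removal verifiable by
construction: after residualization the edge–age correlation is zero up to
floating point, because age is a design column.  Templates perturbed off
positive definiteness are repaired by eigenvalue clipping with a logged
warning.

What the generator does *not* emulate: temporal autocorrelation of BOLD
signals, site-specific noise spectra, heavy-tailed motion artifacts,
subject-level variation in the block structure beyond sampling noise, and
edge-specific (rather than global) confound loadings.  Passing tests
demonstrate that the pipeline recovers planted covariance effects and
removes linear confounds under these idealized conditions — not that it
would do so on real imaging data.

## Known limitations

* Undirected graphs only; directed adjacency spectra are complex-valued
  and out of scope.
* The permutation p-value has resolution 1/B; localized claims below that
  need a larger B.
* The k-regular sampler is not exactly uniform over regular graphs.
* Pairwise post-hoc comparisons report raw p-values by default (a BH
  adjustment is behind a flag), mirroring how such screens are usually
  reported.
* The grand average ρ̂_gM weights populations equally regardless of size;
  with very unequal groups the reference tilts toward no one population,
  which is the intended behaviour but worth knowing when reading per-
  population KL terms.
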