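# Methods

## The generating model

A synthetic community is a signed interaction network plus a log-normal
abundance law. The network is a preferential-attachment graph with triad
closure (a power-law-cluster construction: `density_param` edges per new
node, default 2; triangle probability 0.1), which produces the sparse,
heavy-tailed, small-world topology expected of microbial association
networks. Each edge carries a sign, +1 or -1 with equal probability by
default. Taxa are split into two kingdoms ('A' and 'B'), by default 50/50 —
comparable to real paired surveys where similar taxon counts per kingdom are
retained — and the model is relabelled so kingdom A occupies the first
block of indices; every concatenation in the package is A-then-B.

The covariance Σ over log-abundances starts from the identity, places a
uniform(0.2, 1.0) magnitude with the edge's sign on each edge, and then
loads the diagonal uniformly by (ε − λ_min) whenever the smallest eigenvalue
λ_min falls at or below the floor ε = 0.01. Diagonal loading is used
deliberately: it touches no off-diagonal entry, so the support and signs of
Σ equal the graph exactly — an invariant the evaluation layer depends on.
The side effect is that hub-rich graphs get diagonals well above 1
(log-variances of roughly 2–6 at the default scales), i.e. strongly
dispersed abundances, which is the regime in which compositional artifacts
matter. Mean log-abundances are uniform on (−4, 4).

Structural variants act on the graph *before* covariance construction (so
positive-definiteness is always re-enforced afterwards): the number of
cross-kingdom edges is scaled by `cross_density_factor` (additions drawn
uniformly from absent cross pairs, removals uniformly from present ones)
and every cross-kingdom edge's sign is redrawn, negative with probability
`cross_negative_prob`. (1.0, 0.5) is the neutral default.

## Read simulation

Absolute abundances are exp of multivariate-normal draws (Cholesky sampling
from Σ and μ). Sequencing is simulated per (sample, kingdom): a depth is
drawn from Normal(100 000, 10 000), rounded and floored at 1 000 (the floor
sits ~10 SD below the mean, so it exists only to make the generator total),
and counts are a single multinomial draw with probabilities equal to the
within-kingdom relative abundances — distributionally identical to drawing
reads one at a time, and far cheaper. Depths are drawn independently for the
two kingdoms of a sample, matching the unrelated library sizes of real
16S/ITS pairs. An optional depth multiplier (default 1.0) exposes
zero-heavy low-depth regimes. No sequencing error, copy-number variation or
misclassification is modelled: the simulation is deliberately a near
best-case for network reconstruction, so results are necessary rather than
sufficient evidence that a method works on real data.

## The six estimators

All six take the paired count tables and return a covariance estimate over
the concatenated taxon set. Log-based methods add a +1 pseudocount before
logs (the dominant convention; configurable, and `pseudocount=None` runs on
already-positive data unchanged — which is how the scale-invariance
properties are exactly stated and tested).

- **log_covariance** — empirical covariance (divisor n−1 throughout) of log
  counts. No compositional handling at all.
- **clr_mixed** — CLR on each concatenated row, then covariance. Corrects a
  single per-sample scale factor; cannot cancel two.
- **clr_split** — CLR per kingdom, concatenate, covariance. Invariant to
  per-sample per-kingdom rescaling: the paired-data correction.
- **sparcc** — basis correlations from the variation matrix
  T_ab = Var[log(x_a/x_b)] under the sparsity assumption, on the
  concatenated tables. The linear system is t = ((D−2)I + 11')w on the row
  sums of T; pairs whose |ρ| exceeds 0.1 are excluded iteratively (up to 10
  rounds, stopping early if an exclusion would make the system singular),
  and 20 Dirichlet(counts+1) resamples are aggregated by entrywise medians.
  Output is returned on the covariance scale, ρ_ab √(ω_a ω_b) with the basis
  variances ω on the diagonal; the correlation form is kept in `meta`.
  Non-positive solved variances fall back to absolute values with a warning.
- **glasso_mixed / glasso_split** — graphical lasso (ℓ1-penalized Gaussian
  maximum likelihood, off-diagonals penalized) on the mixed / split CLR
  covariance, with the fitted precision inverted so all methods live on one
  scale.

### Graphical-lasso regularization

Two numerical facts shaped this part. First, CLR covariances are singular
by construction (each CLR block has the all-ones null vector), and at the
benchmark's p ≈ n the coordinate descent only converges reliably at a loose
duality-gap tolerance; the default is `tol=1e-2`, which on these problems
changes fitted entries at the 1e-4 level while avoiding spurious
non-convergence. Second, likelihood-based penalty selection degenerates in
this regime: extended BIC (γ = 0.5), plain BIC, and a held-out-likelihood
rule all prefer the *empty* precision matrix, because each edge buys only a
tiny likelihood gain at p ≈ n. The default selection is therefore
deterministic **sparsity targeting**: walk the log-spaced grid
([10⁻³, 1] × max|off-diagonal of S|, 20 points) from the fully penalized
end and keep the converged fit whose precision edge density is closest to
`target_edge_density` (default 5% of taxon pairs, comparable to the true
graph density at benchmark scale). This plays the role that
subsampling-based stability selection plays in practice — pinning the fit
to a realistic sparsity — at a fraction of the cost and with no extra
randomness; EBIC remains available via `selection="ebic"`.

## Evaluation

Edge metrics use the strict upper triangle, split into intra- and
cross-kingdom groups. The bias signature is the mean signed edge value per
group divided by the largest |edge| of the estimate, with a two-sided
tie-corrected Mann-Whitney U test between the groups. Edge accuracy is the
R² of OLS of true on estimated edge values (true zeros included; degenerate
fits score 0). Edge detection treats |estimate| as a classifier score for
ground-truth support, ignoring sign; the strongest-true-edge variant keeps
the top 25% of true edges (by |true value|) as positives and drops the
remaining true edges from the negatives as well, since they are neither
positives nor clean negatives. Top-N accuracy calls an inferred edge
correct iff the true value is nonzero with matching sign (N ∈ {10, 25, 50,
100} by default).

Node and community metrics run on thresholded networks keeping the top 10%
of edges by absolute strength (the same fraction used for network figures),
with deterministic tie-breaking. Centralities (betweenness, degree,
eigenvector) use the unweighted topology, eigenvector per connected
component with isolated nodes scored 0. Keystoneness parameterizes a
generalized Lotka-Volterra system dx/dt = x(r + Ax) from the estimate: off-
diagonal interactions scaled so the largest magnitude is 0.5,
self-interaction −1, growth rate 1, integrated to t = 500 with LSODA; each
taxon's score is the Bray-Curtis dissimilarity between the remaining
community's baseline and knockout steady states, with divergent dynamics
flagged at score 1. This gLV construction is one documented choice among
several plausible ones; the unit tests pin it against analytic interior
equilibria. Louvain communities are detected on |edge|-weighted thresholded
graphs (seeded, deterministic) and scored per reconstructed community by
best Jaccard overlap and by inclusion (largest intersection over the
community's own size).

## Benchmark grid and real-data runner

The default experiment configuration is the study setup: 500 taxa, sample
sizes 75/150/300, 15 replicate trials for edge metrics and 20 for hub
metrics, depth Normal(100 000, 10 000). Every stage's randomness descends
from one master seed through fixed (seed, sample-size, trial) paths, so
reports reproduce bit-for-bit. Method failures inside a trial are recorded
and excluded from aggregates rather than aborting the grid. Method
comparisons are two-sided Mann-Whitney tests of each method's metric
distribution against the CLR-Split reference across trials, reported raw
(no multiple-testing correction — the comparisons are descriptive).

The real-data runner filters each kingdom's table to its most abundant
taxa (default top 2% for the fungal table and 1% for the bacterial one,
fractions chosen to retain similar taxon counts per kingdom), ranking by
mean within-sample relative abundance so deep libraries do not dominate,
then pairs shared samples and reports the bias diagnostic per method:
pooled intra-vs-cross Mann-Whitney p-values plus each kingdom's intra block
against the cross block separately.

## Scaled test conditions

The acceptance tests run the benchmark at 100 taxa, 150 samples and 5
replicates (the full 500-taxon grid is a production run, not a test), with
parameter-recovery checks at 60 taxa and oracle checks on hand-sized
instances. These sizes were chosen so the whole suite completes in well
under a minute while the replicate-level claims remain statistically
resolvable.

## Known limitations

- The cross-kingdom bias signature is method-dependent in a way worth
  stating precisely: for the CLR-Mixed and SparCC estimators the cross
  block is systematically pushed negative by the shared Var[log(q/r)] term,
  but for the raw log-covariance the cross entries reduce to approximately
  +Cov[log q, log r], which vanishes for balanced networks — so
  log-covariance reliably shows the *positive intra* half of the signature
  while its cross shift hovers near zero with random sign. The acceptance
  suite asserts the full two-sided signature per method and the
  log-covariance case fails that assertion by design of the method, not of
  the test.
- GLASSO estimates are only as sparse as the density target; the package
  does not implement subsampling-based stability selection, and no
  bootstrap edge-significance procedure is provided.
- The simulator omits real-data confounders (environmental covariates,
  copy-number variation, spatial heterogeneity); passing these benchmarks
  is evidence a method handles paired-compositionality, not that it
  recovers real ecological interactions.
- Communities and hubs are evaluated on one thresholding convention (top
  10%); conclusions can shift with the threshold.
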