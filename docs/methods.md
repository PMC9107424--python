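# Methods

This note records the scientific and numerical choices behind the package,
in the spirit of a model-description document: what is computed, under which
assumptions, and where the design was genuinely open.

## Geometry of the SPD cone

Connectomes are Pearson-correlation matrices: symmetric, unit diagonal,
positive semi-definite. Adding μI (default μ = 10⁻¹⁰) moves them strictly
inside the SPD cone. If the result is still numerically singular the ridge
escalates by factors of 10 up to 10⁻⁴ before an error names the offending
subject; a valid correlation matrix (smallest eigenvalue ≥ −10⁻⁸ by the
input contract) is always cured well before that bound.

All computations use the **Log-Euclidean** metric. Its defining property is
that the matrix logarithm maps the cone isometrically onto the flat space of
symmetric matrices, so

* geodesic distance d(P, Q) = ‖log Q − log P‖_F,
* parallel transport is path independent and acts as a translation in log
  coordinates; the tangent matrix of the geodesic from P to Q, transported
  to the identity, is therefore exactly log Q − log P.

The second point is a (standard) derived identity rather than a quoted
formula: because the log map is a metric-preserving flattening, transport of
log_P(Q) from T_P to T_I is the identity map on the log-coordinate
representation. The test suite checks its two observable consequences —
isometry (‖tangent‖ = distance, to 10⁻¹⁰) and antisymmetry under argument
swap — together with the metric axioms, orthogonal-congruence invariance and
inversion invariance (log P⁻¹ = −log P).

Matrix log/exp go through the symmetric eigendecomposition (never a Padé or
series approximation) and outputs are re-symmetrized as (M + Mᵀ)/2, so
symmetry is exact. Round-trip accuracy degrades with the spread of the log
spectrum (conditioning of exp); the tests draw log matrices with O(1)
spectra, the regime of correlation-like data.

## Graph features of tangent matrices

A tangent matrix has signed entries. For the centrality measures the edge
weight between nodes i and j is |S_ij| (diagonal ignored): the magnitude of
the connectivity change carries the signal, and the graph topology is
unchanged. Modes and their dimensions for d ROIs:

| mode | content | length |
|------|---------|--------|
| tm   | row-major upper triangle incl. diagonal | d(d+1)/2 |
| dc   | degree centrality Σ_j |S_ij| / (d−1) | d |
| ec   | eigenvector centrality of |S| | d |
| cc   | closeness centrality, edge length 1/|S_ij| | d |
| cnu  | dc ‖ ec ‖ cc | 3d |
| cns  | the same, each block min-max scaled | 3d |
| g    | Log-Euclidean distance | 1 |
| a    | Euclidean distance of connectome upper triangles | 1 |

Numerical choices:

* **Eigenvector centrality** uses power iteration (tolerance 10⁻¹⁰, at most
  1000 iterations, uniform start — fully deterministic) on the shifted
  matrix |S| + cI with c the maximum row sum. The shift leaves eigenvectors
  unchanged but makes the Perron eigenvalue strictly dominant, so the
  iteration cannot oscillate on bipartite(-like) graphs. The result is
  normalized to unit Euclidean norm with non-negative entries.
* **Closeness** uses Dijkstra shortest paths on edge lengths 1/|S_ij| and
  the Wasserman–Faust component scaling (r_i/(d−1)) · (r_i/Σδ), which
  reduces to (d−1)/Σδ on connected graphs and gives isolated nodes 0.
* **Min-max scaling** is (v − min)/(max − min); a constant vector maps to
  all zeros (avoids 0/0). An alternative sign convention that lands in
  [−1, 0] differs only by an affine shift, which the downstream linear
  regressor absorbs.
* tm vectorization order is fixed as the row-major upper triangle including
  the diagonal.

## Sample selection

Within each outer training split, an inner N-fold loop (default N = 5; any
N ≥ 2 works — the depth is not dictated by the method) builds all
train-in pair features and targets |IQ_i − IQ_j|, fits ordinary least
squares with intercept (the minimum-norm solution when the feature dimension
exceeds the pair count, as can happen for tm), predicts the score difference
for every (train-in, holdout) pair, and, **for each holdout subject**,
increments the counters of the k train-in subjects with the smallest
predicted difference. After the loop the k subjects with the highest
cumulative counts are selected.

Determinism and tie handling: the fold assignment shuffles subject positions
with a seeded generator (remainder spread over the first folds); ties in
predicted differences and in cumulative frequency break by ascending subject
id. Predicted differences are used as-is for ranking (no clipping — ranking
is invariant under monotone shifts). Selection always operates on the
μ-regularized matrices *with* their negative correlations; negatives are
only removed later for network training.

A structural property worth knowing: each holdout subject's k increments go
to k members of its own score neighborhood, so when the data contain tight,
well-separated score clusters, every cluster accumulates k near-tied
high-frequency candidates. The cumulative top-k therefore ranks
*candidates*, not clusters, and is not guaranteed to cover each cluster
exactly once — the shipped tests assert the properties that do hold
(conservation Σcounts = k·n, determinism, within-cluster increment locality,
and exact agreement with an independent longhand re-implementation). For the
same reason, pure-noise targets do **not** drive the frequency map to
uniformity: the fitted map retains nonzero coefficients and its rankings
correlate across holdout subjects.

## The network

Architecture as in the README: two Kipf–Welling graph convolutions
(d → 64 → 1, H⁽⁰⁾ = I, symmetric normalization with self-loops), dropout
only after the first convolution (inverted scaling, so evaluation is a plain
forward pass), and a linear readout with bias. Defaults follow the published
protocol: dropout 0.1, Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), learning rate
10⁻³, weight decay 5·10⁻⁴, 100 epochs, d = 116.

Choices the protocol leaves open, resolved here:

* **Negative values**: the default zeroes negative *correlations* entrywise
  (positive correlations dominate brain-network analyses, and a correlation
  matrix has no negative eigenvalues to clamp); an alternative
  `clamp_eigenvalues` mode reconstructs with negative eigenvalues set to
  zero and removes residual negative entries.
* **Loss**: mean squared error (MAE is the reported metric, not necessarily
  the loss). Weight decay is classical L2-in-loss, applied to all parameter
  blocks.
* **Batching**: full batch — the selected training sets hold at most a few
  dozen subjects, and this removes ordering nondeterminism.
* **Initialization**: seeded uniform Glorot-style bounds. The second
  convolution's single output column acts on a non-negative input
  (Â H⁽¹⁾ ≥ 0), so a signed random column makes all of its pre-activations
  share one sign; in the negative case the ReLU silences the embedding with
  no gradient path to recover. That column is therefore initialized
  non-negative (it may change sign during training). The readout bias
  starts at the training-set mean score (toggleable to zero), which removes
  the long plateau of dragging the bias toward IQ scale.
* **Optimization at desk scale**: Adam's per-epoch parameter travel is
  bounded by the learning rate, so 100 epochs at 10⁻³ cannot fit residuals
  of tens of IQ points — appropriate for fine-tuning on real cohorts, far
  from convergence on small synthetic tasks. Pipeline examples, capacity
  tests and the acceptance script therefore run 500 epochs at learning rate
  10⁻², and capacity (overfit) checks additionally disable dropout and
  weight decay. Near convergence (training MSE below ~1) Adam dithers, so
  the monotone-loss check applies to 50-epoch windows above that floor.
* Dropout is applied only after the first convolution, per the architecture
  description; gradients are analytic and verified against finite
  differences to 10⁻⁴ relative error.

Model files are NumPy `.npz` archives (portable, self-describing shapes).
Region importance is the descending |readout weight| ranking, ties by
ascending ROI index; rankings across the k sweep are aggregated by averaging
absolute weights before ranking.

## Synthetic cohorts

The generator emulates the *structure* of a connectome-regression study —
correlation matrices with unit diagonal and planted cluster geometry, IQ
scores with realistic moments (defaults: mean 111.573, sd 12.056, matching a
neurotypical full-scale-IQ cohort) — not the physiology of fMRI. Generation
happens in log-matrix coordinates so that the planted geometry is exactly
the geometry the selection method assumes: a shared base log matrix, cluster
centers spaced `cluster_separation` apart (in log-Frobenius units) along a
random zero-diagonal unit direction U, and per-subject deviations of
Frobenius scale `within_cluster_sd`. Matrices are exponentiated and rescaled
to unit diagonal; the rescaling slightly distorts the planted geometry
(zero-diagonal directions keep the distortion second order), and all
invariants are validated after rescaling.

Score couplings: `cluster_only` (cluster center + Gaussian noise),
`linear_in_tangent` (deviations lie along U with coordinate t;
score = center + β·t with β = coupling_score_sd/within_cluster_sd, so score
differences are exactly linear in the planted tangent coordinate and the
pairwise regression is solvable to R² ≈ 1), and `pure_noise` (scores
independent of the connectomes). Everything is deterministic given the seed.

What passing tests on these cohorts do *not* show: robustness to site and
scanner effects, head motion, heavy-tailed score distributions, or
parcellation choices — none of which the generator models.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: geometry
checks up to d = 116, selection oracles on ≤ 12 subjects at d = 6, the
end-to-end pipeline on 60 subjects at d = 30 (three clusters, cluster-only
coupling), and recovery statistics over 10–20 seeds. These sizes were chosen
so the full suite completes in about a minute while keeping every check at
the full algorithmic depth (nested CV, all eight feature modes, the complete
k = 2..15 sweep).

## Known limitations

* The selection's frequency map ranks candidates within score
  neighborhoods; it does not guarantee coverage of k distinct clusters (see
  above).
* The Log-Euclidean tangent identity is exact, but unit-diagonal rescaling
  in the generator means planted log coordinates are recovered only
  approximately; tests use tolerances or symmetric modes accordingly.
* Only the Log-Euclidean metric is implemented (no affine-invariant metric,
  Fréchet means, or geodesic interpolation beyond the midpoint identity
  used in tests).
* Training is CPU NumPy; it is sized for cohorts of tens to hundreds of
  subjects, not for large-scale hyperparameter sweeps.
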