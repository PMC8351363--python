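# Methods

## Problem setting

A bipartite network over two entity types (here called diseases and genes)
is encoded as a binary matrix **Y** ∈ {0,1}<sup>n×m</sup>. Prediction is a
ranking problem over cells: the model assigns every (disease, gene) pair a
real score so that unobserved true associations rank above true negatives.
Scores are used only ordinally; no probability calibration is attempted.

## Kernels

Four kernel builders cover the usual similarity sources.

* **GIP** (Gaussian interaction profile): `K(i,j) = exp(−γ‖y_i − y_j‖²)` on
  rows or columns of **Y**. The bandwidth γ is an absolute constant
  (default 0.5, the value used on the gene–disease benchmark), not
  normalized by the mean profile norm. On long, sparse profiles this makes
  GIP sharply peaked (close to the identity); that is the literal
  definition and is kept. GIP must always be rebuilt from the *training*
  matrix inside cross-validation — `run_cv` does this automatically.
* **Semantic similarity over a DAG**: each term *d* assigns a contribution
  `D_d(t)` to every ancestor *t* (1 at *d* itself, and Δ times the best
  child contribution for proper ancestors, children restricted to *d*'s
  ancestor closure, evaluated by memoized recursion). Similarity is shared
  contribution mass over total mass; the diagonal is exactly 1. Δ defaults
  to 0.5. The kernel is not guaranteed positive semidefinite; this is
  inherent to the definition and harmless because the solver's system
  matrices are made positive definite by the ridge term.
* **Cosine similarity** of per-entity feature vectors. A zero vector has
  similarity 0 to everything and 1 to itself — the 0/0 case is defined
  away rather than propagated.
* **Normalized alignment scores**: `s_ij / √(s_ii s_jj)` from a raw
  pairwise score matrix (e.g. Smith–Waterman output); symmetrized as
  (K + Kᵀ)/2, diagonal forced to 1. The package consumes raw score
  matrices; it contains no alignment engine. Kernels computed by external
  tools (e.g. GO semantic similarity) are registered as precomputed
  matrices.

## CKA multiple kernel learning

Candidate kernels are double-centered (`Kᶜ = U K U`, `U = I − 11ᵀ/N`);
the ideal kernel `Y_train Yᵀ_train` (or transposed product) is *not*
centered by default, matching the alignment objective as written;
`center_ideal=True` switches to centering both. The simplex-constrained
QP is solved exactly by enumerating candidate active sets: for each
support subset the equality-constrained KKT system is solved and the
feasible candidate with the lowest objective wins. This is exact for a
convex objective and costs 2^k − 1 small solves — negligible for the
handful of kernels used per side (2–6). `M` receives a +1e-12·tr(M)/k·I
ridge so duplicated kernels cannot make the KKT systems singular; weights
below 1e-10 are snapped to zero and renormalized.

The ideal kernel is recomputed per cross-validation fold from the masked
training matrix only, so no held-out association influences the weights.

## Hypergraph regularization

One hyperedge per vertex: the center plus its k most similar other
vertices (self-similarity excluded from the ranking; ties broken toward
the lower index for determinism). The hyperedge weight is the sum of the k
neighbor similarities, normalized so that all weights sum to 1. The
Laplacian `Lʰ = I − D_v^{−1/2} H D_w D_e^{−1} Hᵀ D_v^{−1/2}` uses the
*unweighted* vertex degree `d(v)` = number of incident hyperedges. Under
this convention `Lʰ` is positive semidefinite for any weights in [0,1]
(each hyperedge contributes a PSD rank-one-per-edge term bounded by the
unit-weight case), which the suite verifies spectrally; the classical
null-vector identity `Lʰ D_v^{1/2}1 = 0` holds in the unit-weight case,
where vertex degree and weighted degree coincide. With unit weights and
all hyperedges of size two, `Lʰ` reduces exactly to half the normalized
graph Laplacian of the induced multigraph — the identity used to check
the implementation and to relate the hypergraph and plain-graph variants.

The normalized graph Laplacian is implemented in its symmetric form
`D^{−1/2}(D − K)D^{−1/2}`. An asymmetric variant `D^{−1/2}(D − K)D^{1/2}`
exists behind a flag for fidelity experiments but is not PSD and is never
used by the solver.

## Solver

The objective couples the two sides through the shared residual
`K*_d α_d + (K*_g α_g)ᵀ − 2Y`. The target is scaled by 2 and the
prediction divided by 2; both factors are kept literally (they are
immaterial for ranking metrics). Initialization is `α_g = 0`, so the first
half-step is a pure kernel ridge fit on the disease side; updates then
alternate `α_d`, `α_g`. Each update solves a symmetric positive-definite
system `(K² + βI + λ K L K) α = rhs` via Cholesky factorization (never an
explicit inverse), falling back to least squares if factorization fails.
Because every half-step exactly minimizes a convex quadratic in one block,
the recorded objective trace is non-increasing — asserted on hundreds of
random instances. With λ = 0 the problem is jointly strictly convex and
the alternation converges to the unique minimizer; the suite checks the
fixed point against a stacked normal-equations solve to 1e-6.

Defaults: λ_d = 1, λ_g = 0.25, β = 1, k = 50 neighbors, 10 alternating
rounds — the configuration selected on the gene–disease benchmark. An
optional relative-objective tolerance stops early. When a kernel has fewer
than k+1 entities the neighbor count is capped at N−1 so the default grid
value remains usable on small problems.

## Cross-validation and metrics

* **CV1** (pair holdout): the observed 1-cells are partitioned into folds
  by a seeded shuffle; each fold's training matrix zeroes its held-out
  positives, and the fold is scored micro-style over the held-out
  positives plus *all* zero cells as negatives.
* **CV2** (cold start): rows are partitioned; a fold's rows are zeroed
  entirely in training and all their cells are scored. GIP kernels and
  ideal kernels are always rebuilt from the masked matrix, so a held-out
  disease contributes nothing to any kernel — the cold start is leak-free.
  A partition leaving some fold without a single positive is re-drawn with
  a shifted seed (leave-one-out CV2 on a matrix with an all-zero row can
  therefore never succeed, by design).

AUC is the Mann–Whitney statistic (ties half credit); AUPR is average
precision with tied scores processed as one threshold group. Both are
delegated to scikit-learn and verified against brute-force pair-counting /
precision-at-rank oracles, exactly, on a thousand random vectors.
`grid_search` scans an arbitrary parameter grid exhaustively and selects
by mean AUPR, the selection rule used on the original benchmark (the
default grid is k ∈ {10,…,100}, λ ∈ {2⁻⁵,…,2⁵} per side, β = 1).

## Synthetic data

The generator plants `n_blocks` balanced co-clusters: matching
disease/gene blocks get edge probability `density_in` (default 0.85),
non-matching pairs `density_out` (0.05), and every label flips with
probability `flip_noise` (0.02). Side information follows the same blocks:
a star-of-subtrees DAG (root → block node → member diseases) feeds the
semantic kernel, and noisy block-indicator vectors feed the gene cosine
kernel. All randomness flows from one seed through a single generator.

What this emulates — and what it does not: real association matrices are
much sparser, have heavy-tailed degree distributions, and their side
kernels are noisier and only partially block-structured. Passing the
planted-recovery tests therefore demonstrates that the pipeline recovers
clean cluster structure end to end, not that it attains any particular
performance on real data.

Two consequences of the default noise levels are worth stating explicitly.
First, background and flipped edges are statistically independent of the
planted blocks, so no ranker can separate them from true zeros: the
Bayes-optimal CV1 AUC of the default generator (score = true block
membership) is ≈ 0.874, and the fitted model's 0.87–0.88 sits at that
ceiling. Second, at the ceiling the hypergraph regularizer cannot improve
AUC materially over the λ = 0 ridge ablation; its benefit shows in AUPR
and under per-dataset λ selection, which is why the planted-signal
comparison selects λ by the AUPR grid-search rule (on a reduced grid,
λ ∈ {2⁻⁵, 2⁻¹, 2, 2³, 2⁵}² with k = 20, sized to the 80×80 problem)
before comparing against the ablation.

## Numerical choices and degenerate inputs

* Kernel matrices are symmetrized on construction (tolerance 1e-8) and
  validated for finiteness; association matrices must be exactly 0/1.
* All-zero training matrices make the ideal kernel zero-norm; CKA refuses
  them rather than returning arbitrary weights.
* Prediction ties in file output are broken lexicographically by ids.
* Problem sizes in the test suite and acceptance script (≤ 12 entities for
  oracle checks, 80×80 for the planted study, 100-instance batches) were
  chosen so each check finishes in seconds while still exercising every
  code path.

## Known limitations

* The active-set QP enumeration is exponential in the number of kernels;
  fine for the intended 2–6 kernels per side, wrong tool beyond ~15.
* Dense linear algebra throughout; networks beyond a few thousand entities
  per side would need sparse/iterative solvers.
* The semantic kernel assumes the DAG fits in memory and that ancestor
  closures are small; no ontology parsing is included.
* CV1 uses all zero cells as negatives, matching common practice for this
  model family; subsampled-negative protocols would need a custom fold
  builder.
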