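# dhrls

Link prediction in bipartite biological networks by **dual hypergraph
regularized least squares (DHRLS)** with **centered kernel alignment (CKA)
multiple kernel learning**.

The package is aimed at problems like gene–disease association discovery: a
binary matrix **Y** ∈ {0,1}<sup>n×m</sup> records which of *n* diseases are
known to involve which of *m* genes, and the task is to rank the unobserved
cells so that true-but-unrecorded associations come out on top. Several
heterogeneous similarity sources exist per side (ontology-based semantic
similarity between diseases, functional/sequence/interaction-network
similarity between genes, and interaction-profile similarity from **Y**
itself); the method fuses them and exploits higher-order neighborhood
structure on both sides.

## The model

Each side gets a fused kernel `K* = Σᵢ ωᵢ Kᵢ` whose simplex-constrained
weights maximize the alignment (Frobenius cosine) between the centered
combined kernel and the label-derived ideal kernel `Y Yᵀ` (disease side) or
`Yᵀ Y` (gene side). The maximization reduces to the convex quadratic
program `min_{ω≥0, Σω=1} ωᵀMω − 2ωᵀa` with `M_ij = ⟨Kᵢᶜ, Kⱼᶜ⟩_F` and
`a_i = ⟨Kᵢᶜ, K_ideal⟩_F`.

A kNN hypergraph is built per side from `K*` — one hyperedge per vertex,
containing the vertex and its k most similar peers — and its Laplacian
`Lʰ = I − D_v^{−1/2} H D_w D_e^{−1} Hᵀ D_v^{−1/2}` regularizes the fit:

```
min  ‖K*_d α_d + (K*_g α_g)ᵀ − 2Y‖²_F
   + λ_d tr(α_dᵀ K*_d Lʰ_d K*_d α_d) + λ_g tr(α_gᵀ K*_g Lʰ_g K*_g α_g)
   + β (‖α_d‖²_F + ‖α_g‖²_F)
```

Each block update of the alternating least-squares solver is a closed-form
linear solve, so the objective is non-increasing; predictions are
`F* = (K*_d α_d + (K*_g α_g)ᵀ)/2`. Replacing `Lʰ` by the normalized graph
Laplacian gives the DGRLS baseline; a single-side LapRLS baseline is also
included.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_cross_validation.py` evaluates the pipeline on a
generated network with four planted disease–gene co-clusters
(80×80, within-block edge density 0.85, background 0.05, 2% label flips):

```
CV1 (pair holdout)       AUC=0.8747  AUPR=0.4228
CV2 (cold start, fused)  AUC=0.7452  AUPR=0.4737
CV2 (cold start, GIP)    AUC=0.4827  AUPR=0.2572
```

CV1 masks one fifth of the known associations per fold and ranks them
against all zero cells; an AUC of 0.87 here is essentially the ranking
ceiling of this generator, since background and flipped edges carry no
recoverable structure. CV2 holds out whole diseases: with only
interaction-profile (GIP) kernels a new disease has an empty profile and
ranking collapses to chance (0.48), while the DAG-semantic and feature
kernels restore cold-start AUC to 0.75 — the point of multi-kernel fusion.

Library-first usage:

```python
from dhrls import (SyntheticSpec, generate, run_cv, CvScheme, SolverParams)
data = generate(SyntheticSpec(seed=7))
report = run_cv(data.Y, CvScheme("CV1", 5, seed=7), SolverParams(),
                disease_kernels=data.disease_side_kernels,
                gene_kernels=data.gene_side_kernels)
print(report.mean_auc, report.mean_aupr)
```

A thin CLI wraps the same pipeline for file-based workflows
(`dhrls synth | stats | kernels | cv | predict`); all inputs and outputs
are plain TSV/JSON, and every run writes a manifest (config hash, seed,
library versions) for reproducibility.

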