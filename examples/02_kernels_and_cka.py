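"""Building per-side kernels and fusing them with CKA weights.

Generates a small planted-structure network, builds a semantic kernel from
the disease DAG, a cosine kernel from gene features, and GIP kernels from
the adjacency matrix, then asks centered kernel alignment which mixture of
kernels best matches the label-derived ideal kernel.
"""

from dhrls import (
    KernelBundle,
    SyntheticSpec,
    combine,
    generate,
    gip_kernel,
    ideal_kernel,
    solve_weights,
)

data = generate(SyntheticSpec(n=40, m=40, n_blocks=4, seed=1))

for side, side_kernels in (
    ("disease", data.disease_side_kernels),
    ("gene", data.gene_side_kernels),
):
    bundle = KernelBundle(side_kernels + [gip_kernel(data.Y, side=side)])
    weights = solve_weights(bundle, ideal_kernel(data.Y, side=side))
    K_star = combine(bundle)
    report = ", ".join(f"{n}={w:.3f}" for n, w in zip(bundle.names, weights))
    print(f"{side:8s} weights: {report}   combined kernel {K_star.values.shape}")

# A weight near 1 means that kernel alone already aligns best with the
# training labels; weights are simplex-constrained (nonnegative, sum 1).
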