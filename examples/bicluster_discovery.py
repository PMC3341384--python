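"""Discover maximal temporally coherent modules in a small time series.

Builds a synthetic 100-gene x 6-time-point matrix with one planted module
(20 genes rising twice, plateauing, then falling), enumerates all maximal
CCC-biclusters via the generalized suffix tree, scores them against the
per-column null, and prints the most significant ones.
"""

from regsnap import (
    discretize_transitions,
    enumerate_maximal_ccc_biclusters,
    filter_biclusters,
    generate_planted_expression,
    normalize_by_gene,
    score_biclusters,
    transform_alphabet,
)
from regsnap.biclustering import build_generalized_suffix_tree

expr, truth = generate_planted_expression(
    n_genes=100, n_timepoints=6,
    modules=[(20, (1, 5), ("U", "U", "N", "D", "D"))],
    noise_sd=0.0, seed=42,
)
expr = normalize_by_gene(expr)
d = discretize_transitions(expr, tau=0.0)
tree = build_generalized_suffix_tree(transform_alphabet(d))
biclusters = score_biclusters(enumerate_maximal_ccc_biclusters(tree, d), d)
kept = filter_biclusters(biclusters, p_cut=0.01, jac_cut=0.25)

print(f"{len(biclusters)} maximal CCC-biclusters, {len(kept)} after filtering\n")
print("id   genes  columns  pattern  corrected p")
for b in kept[:5]:
    print(f"{b.id:<4} {b.n_genes:<6} {b.c_start}-{b.c_end:<6} "
          f"{''.join(b.pattern):<8} {b.corrected_pvalue:.3g}")

planted = truth.modules[0]
best = max(kept, key=lambda b: len(set(b.rows) & set(planted.gene_indices)))
overlap = len(set(best.rows) & set(planted.gene_indices))
print(f"\nplanted module: {len(planted.genes)} genes, columns "
      f"{planted.c_start}-{planted.c_end}; best filtered bicluster recovers "
      f"{overlap}/{len(planted.genes)} of its genes.")
# Each row above is one module: a gene set sharing the exact U/N/D pattern
# over the contiguous transition columns shown, with the probability that a
# matrix of this size would produce it by chance (Bonferroni corrected).
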