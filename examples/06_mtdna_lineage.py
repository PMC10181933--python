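"""Clone inference from mtDNA heteroplasmy.

Two clones (50 cells each) carry disjoint sets of three heteroplasmic
variants at allele fraction 0.4.  Variants are called per cell, kept
only if seen in >= 2 cells by each of two caller settings and by both,
genotyped into an allele-frequency matrix, filtered, and clustered with
complete linkage.  Expected: cutting the dendrogram at k = 2 recovers
the planted clones exactly (adjusted Rand index 1.0).
"""

from circlescope import evaluate

result = evaluate.lineage_benchmark(seed=17, n_cells=100)
print(f"cells clustered:     {result['n_cells_clustered']}")
print(f"adjusted Rand index: {result['ari']:.3f}")
print(f"AF equation exact:   {result['af_equation_exact']}")
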