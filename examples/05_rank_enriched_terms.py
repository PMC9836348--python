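"""Rank over-represented annotation terms in a gene cluster by strength.

Annotates a 300-gene background with one planted term (30 genes) and
decoys, then tests a 25-gene cluster containing 20 of the planted term's
genes: hypergeometric p-values, BH FDR, and ranking by
strength = log10(observed / expected).
"""

import numpy as np

from sgascreen.enrichment import AnnotationSet, curate_rank, enrich_gene_set

rng = np.random.default_rng(5)
background = [f"g{i:03d}" for i in range(300)]
pairs = [(g, "PLANTED") for g in background[:30]]
for t in range(15):
    members = rng.choice(background, size=15, replace=False)
    pairs += [(g, f"DECOY_{t:02d}") for g in members]
annotations = AnnotationSet.from_pairs(pairs)

cluster = background[:20] + background[280:285]  # 20/30 planted + 5 random
rows = enrich_gene_set(cluster, annotations)
ranked = curate_rank(rows, annotations=annotations, fdr_max=0.05, top_n=10)

print(f"background: {len(annotations.background)} annotated genes, "
      f"{len(annotations.term_genes)} terms; cluster of {len(cluster)} genes")
print("term        k/K    strength   FDR")
for r in ranked.itertuples():
    print(f"{r.term:<10} {r.k:>2}/{r.K:<3}   {r.strength:+.2f}    {r.fdr:.2e}")
# strength = log10(k / (n*K/N)): +1 means tenfold more annotated genes in
# the cluster than a random gene set of the same size would carry.
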