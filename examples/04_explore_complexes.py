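"""Explore a map: complex identification, neighbors, enrichment.

A planted complex should be *identified*: its within-complex cosine
distribution should differ from the member-vs-outside distribution
(two-sample KS test, p < .01).  Neighbor queries plus hypergeometric
enrichment then suggest functions for individual genes.
"""

from permap import (
    SimConfig, simulate, pipeline_preset, run_pipeline,
    identify_complexes, top_neighbors, enrich,
)

cfg = SimConfig(n_genes=150, n_unexpressed=0, n_complexes=5,
                complex_size=12, dims=20, n_batches=4,
                replicates_per_gene=6, controls_per_batch=30,
                effect_scale=0.8, noise_sd=1.0, batch_shift_scale=4.0,
                batch_scale_spread=0.8, seed=2)
units, catalog, _ = simulate(cfg)
_amap, sim = run_pipeline(units, pipeline_preset("pca-tvn", k=20))

results = identify_complexes(sim, catalog, min_genes=10, alpha=0.01)
print("complex identification (KS test, within vs in/out cosines):")
for r in results:
    mark = "identified" if r.identified else "missed"
    print(f"  {r.name}: KS={r.ks_statistic:.2f} p={r.p_value:.2e} -> {mark}")

query = catalog.complexes["complex003"][0]
neighbors = top_neighbors(sim, query, k=10)
print(f"\ntop 10 neighbors of {query}: {neighbors}")

# treat the planted complexes as a gene-set collection and ask which sets
# the neighbor list is enriched for
collection = dict(catalog.complexes)
enr = enrich(set(neighbors), collection, set(sim.genes), min_term_size=10)
for r in enr:
    if r.significant:
        print(f"enriched: {r.term} overlap={r.overlap} "
              f"corrected p={r.corrected_p:.2e}")
# The query's own complex should dominate its neighbor list, and the
# enrichment test should flag exactly that complex.
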