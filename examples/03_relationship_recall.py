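"""Relationship-recall benchmark: how alignment choice changes a map.

Recall = percentage of annotated (here: planted within-complex) gene
pairs whose cosine similarity lands in the extreme 5% tails of the map's
full pair distribution.  A random map scores 10%.  Under strong batch
artifacts, covariance-level alignment (TVN) recovers relationships that
per-feature scaling (CS) or no alignment miss.
"""

from permap import SimConfig, simulate, pipeline_preset, run_pipeline, recall

cfg = SimConfig(n_genes=300, n_unexpressed=0, n_complexes=10,
                complex_size=12, dims=24, n_batches=6,
                replicates_per_gene=6, controls_per_batch=40,
                effect_scale=0.4, noise_sd=1.0, batch_shift_scale=8.0,
                batch_scale_spread=1.5, seed=11)
units, _, pairs = simulate(cfg)
print(f"planted within-complex pairs: {len(pairs)}")

for name in ("pca", "pca-cs", "pca-tvn"):
    _amap, sim = run_pipeline(units, pipeline_preset(name, k=24))
    res = recall(sim, pairs, tail=0.05)
    print(f"{name:8s} recall = {res.recall_percent:5.1f}%  "
          f"(cuts [{res.lower_cut:+.3f}, {res.upper_cut:+.3f}], "
          f"{res.n_eval_pairs} pairs)")
# Expected ordering: pca-tvn > pca-cs > pca, all well above the 10%
# random baseline — the alignment stage, not the embedding, is decisive
# when batch artifacts dominate.
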