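"""Build a bipartite interaction network from all-vs-all predictions.

Trains on synthetic pairs, scores the full protein x RNA grid of a held-out
subset, keeps the positively scored edges, and writes a SIF file with a
node-degree (hub) summary.
"""

import rpilearn as rp

prot, rna, pairs = rp.generate(rp.SynthConfig(n_pairs=200, seed=42))
# balanced training split: 75 positives (records 0-74) + 75 negatives (100-174)
train = rp.PairTable(pairs.records[:75] + pairs.records[100:175])
model = rp.train(train, prot, rna, rp.KernelConfig(k=3, l=4), lam="auto")

# query panel: 5 motif-carrying proteins/RNAs and 5 background ones
panel_p = [p.id for p in prot[90:95] + prot[190:195]]
panel_r = [r.id for r in rna[90:95] + rna[190:195]]
scored = rp.predict(model, rp.all_vs_all_pairs(panel_p, panel_r), prot, rna)
print(f"scored {len(scored)} pairs (10 proteins x 10 RNAs)")

edges = rp.edges_from_scores(scored, threshold=0.0)
rp.write_sif("scratch_network.sif", edges)
print(f"{len(edges)} positive edges written to scratch_network.sif")

summary = rp.degree_summary(edges)
print("\ntop nodes by degree (hubs):")
print(summary.head(5).to_string(index=False))
print("degree sum == 2 x edges:", summary["degree"].sum() == 2 * len(edges))
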