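"""Template-size grid search: which (k, l) best separates the classes?

Cross-validates every (protein k-mer size, RNA l-mer size) cell on the
same stratified folds and prints the mean accuracy and AUC tables.  The
planted motifs are 3 amino acids and 4 nucleotides long, so cells around
(k=3, l=4) should carry the most signal.
"""

import rpilearn as rp

prot, rna, pairs = rp.generate(rp.SynthConfig(n_pairs=200, seed=11))
res = rp.grid_search(pairs, prot, rna, k_range=[1, 2, 3], l_range=[2, 3, 4, 5],
                     n_folds=5, seed=11)

print("mean accuracy (rows k, columns l):")
print(res.accuracy_table.round(3))
print("\nmean AUC:")
print(res.auc_table.round(3))
print(f"\nselected cell: k={res.best_k}, l={res.best_l} "
      f"(accuracy {res.best.mean_accuracy:.3f}, ties break to smaller k+l)")
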