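"""Neural responses and the derived kernel on toy sequences.

Builds the k-mer frequency profile of a few short RNAs, evaluates the raw
and correlation-normalized layer-2 kernels, and shows the tensor-product
similarity between two (RNA, protein) pairs.
"""

import rpilearn as rp

r1 = rp.canonicalize_rna("ACACACGUAC", seq_id="r1")
r2 = rp.canonicalize_rna("CACAUGGUAC", seq_id="r2")

f1 = rp.neural_response(r1, 2)
f2 = rp.neural_response(r2, 2)
print("dimer profile of r1:", {t: round(v, 3) for t, v in sorted(f1.entries.items())})
print("raw layer-2 kernel      :", round(rp.k2_raw(f1, f2, 4), 6))
print("normalized (cosine) form:", round(rp.k2_normalized(f1, f2, 4), 6))
print("self-kernel (always 1)  :", rp.k2_normalized(f1, f1, 4))
# The raw value carries a 1/4^2 uniform-measure factor; normalization
# cancels it, leaving the cosine similarity of the dimer profiles.

p1 = rp.canonicalize_protein("MKVAHELKVVRSTWY" * 3, seq_id="p1")
p2 = rp.canonicalize_protein("GGASTWYYHHMKVAH" * 3, seq_id="p2")
cfg = rp.KernelConfig(k=2, l=2)
print("pair kernel ((r1,p1) vs (r2,p2)):", round(rp.pair_kernel(r1, p1, r2, p2, cfg), 6))
# The pair value is the product of the RNA-RNA and protein-protein kernels,
# so it is high only when both sides are similar.

reduced = rp.reduce_protein(p1)
print("7-group reduction of p1:", reduced.residues)
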