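"""Curating a labeled pair table: dedupe, length filter, negatives.

Starts from a redundant positive table, removes duplicate molecules and
under-length chains, and builds a balanced negative set by permuting the
protein column while keeping RNAs fixed.
"""

import rpilearn as rp

prot, rna, pairs = rp.generate(rp.SynthConfig(n_pairs=60, seed=8))
positives = rp.PairTable([r for r in pairs.records if r.label == 1])

# add a decoy chain id that duplicates an existing protein's residues
dup = rp.Sequence("P_dup", prot[0].residues, prot[0].alphabet)
prot_all = list(prot) + [dup]
redundant = rp.PairTable(
    positives.records + [rp.PairRecord("P_dup", positives.records[0].rna_id, 1)]
)
deduped = rp.dedupe_pairs(redundant, prot_all, rna)
print(f"dedupe: {len(redundant)} rows -> {len(deduped)} (residue-identical pair dropped)")

kept, log = rp.apply_length_filter(deduped, prot_all, rna)
print(f"length filter (<25 aa or <15 nt): kept {len(kept)}, dropped {len(log)}")

negatives = rp.sample_negatives(kept, seed=8)
overlap = set(negatives.pair_ids) & set(kept.pair_ids)
print(f"negatives: {len(negatives)} pairs, overlap with positives = {len(overlap)}")
# The protein multiset and RNA column of the negatives match the positives
# exactly, so both classes share identical sequence marginals.
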