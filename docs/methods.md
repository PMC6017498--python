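# Methods

## Model and assumptions

`rpilearn` treats RNA–protein interaction prediction as binary
classification of (RNA, protein) pairs using only primary sequence. The
similarity between sequences is a two-layer derived kernel: layer 1 is
exact match between equal-length k-mers; layer 2 pools layer-1 matches over
all sliding windows, which reduces to the k-mer frequency profile
("neural response") of the sequence. After correlation normalization the
sequence kernel is exactly the cosine similarity of k-mer frequency
vectors; pair similarity is the product of the RNA-side and protein-side
kernels. The modelling assumptions are therefore:

- interaction signal is carried by contiguous k-mer composition — repeated
  or conserved short motifs — not by long-range structure;
- similar RNAs binding similar proteins behave similarly (the
  tensor-product assumption), which shares statistical strength across
  binding partners;
- positional information is discarded: two sequences with identical k-mer
  profiles are indistinguishable (kernel exactly 1).

The learner is kernel regularized least squares: coefficients solve
(K + λI)c = y, scores are Σᵢ cᵢK̂(xᵢ,·), and the sign rule maps score ≤ 0 to
non-interaction. RLS is used rather than, say, an SVM because the
leave-one-out selection of λ is then closed-form: with one
eigendecomposition of K, LOO predictions for every λ in the grid follow
from the hat-matrix identity, so the λ search is essentially free.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k` (protein template size) | 2 | k-mer length on the protein side; 1..4 on the full alphabet (20ᵏ templates grow fast; the cap is liftable), 1..6 on the reduced alphabet. k=2 is the empirically best full-alphabet operating point. |
| `l` (RNA template size) | 5 | k-mer length on the RNA side, 1..8. l=5 pairs with k=2 at the best full-alphabet operating point; the reduced-alphabet optimum sits near k=3, l=4. |
| `alphabet_mode` | `full20` | `reduced7g` recodes amino acids into 7 physicochemical groups (dipole moment / side-chain volume), shrinking the template space and allowing larger k at some loss of residue diversity. |
| λ grid | e⁻¹⁵..e¹⁵ | 31 log-spaced ridge values; selection by LOO classification accuracy, ties to the larger (more regularized) λ. |
| `objective_scaling` | `eq_sum` | `eq_sum` solves (K+λI)c = y (unscaled squared loss); `eq_mean` divides the loss by m, equivalent to ridge λm. Both are kept because a reported "optimal λ" is only meaningful relative to one scaling. |
| length filter | 25 aa / 15 nt | pairs with shorter chains are dropped before training (strict inequalities; a 25-residue protein is kept). |

## Numerical choices

- Neural responses are sparse maps over observed k-mers only; the uniform-
  measure factor 1/|Aᵏ| appears in the raw kernel for fidelity to the inner-
  product definition but provably cancels under normalization (tests assert
  this).
- Self-kernels are asserted equal to 1 within 1e−12, then the Gram diagonal
  is clamped to exactly 1; off-diagonal values are clipped to [0,1] against
  rounding excursions.
- Batched Gram assembly goes through L2-normalized sparse count matrices
  (scipy CSR) and equals the scalar kernel path to 1e−12 (tested).
- The RLS solve asserts residual ‖(K+λI)c − y‖ ≤ 1e−8‖y‖; for λ > 0 on a
  PSD Gram this always holds.
- In the LOO shortcut, a diagonal hat value Hᵢᵢ = 1 (interpolation limit)
  makes the held-out prediction degenerate; it is reported as 0, the
  no-information score, which the sign rule maps to non-interaction.
- Sequences shorter than the template size are a hard error, not a zero
  vector: the length filter guarantees n ≥ k for supported ranges, and a
  silent zero would poison normalization.
- Stratified folds: within-class shuffle (seeded PCG64) then round-robin
  dealing, giving per-fold class counts within ±1 of proportionality.
- Grid-search tie-break: among cells with equal mean accuracy (to 1e−12),
  the smaller k+l wins, then the smaller k — the cheaper kernel.
- Negative sampling re-draws whole permutations of the protein column; a
  slot is in conflict if it reproduces a positive pair *or duplicates
  another sampled pair* (the duplicate case is unavoidable bookkeeping once
  proteins or RNAs repeat). After half the restart budget a pairwise-swap
  repair pass fixes conflicting slots, since pure rejection is
  astronomically slow on hub-heavy tables; an infeasible instance (e.g. a
  protein partnering every RNA) fails with that diagnosis.

## The synthetic generator

`generate` emulates a balanced curated interaction set: every pair gets a
fresh i.i.d. background protein (uniform over 20 amino acids, length
50–200) and RNA (uniform over ACGU, length 30–120); interacting pairs carry
a short protein motif (default `WCH`, 3 aa) and RNA motif (default `GCGC`,
4 nt) written over background residues at a random position, so lengths are
unchanged. The default motifs are arbitrary fixed choices at the motif
lengths a k-mer kernel can resolve within the supported template range;
`signal_rate` thins the planted signal and `label_noise` flips labels, down
to a pure null. An optional composition table skews the background, which
emulates the organism-level amino-acid bias that genuinely degrades
composition-based kernels (the known failure mode of this model family).

What the generator does **not** emulate: RNA secondary structure, binding-
site biophysics, homology between pairs, shared hub proteins, or realistic
length/composition distributions. A green end-to-end test therefore
establishes that the pipeline recovers a planted co-occurring k-mer signal
under the stated protocol — not that it reproduces benchmark accuracy on
curated interaction databases, which require externally downloaded data.

## Design decisions taken where the design was open

- LOO selection optimizes classification accuracy of the signed held-out
  scores (the task is binary), not squared error; ties prefer stronger
  regularization.
- AUC uses the Mann–Whitney rank form with half-counted ties.
- Redundancy removal judges molecule identity on residues, not chain ids
  (structural chains frequently share sequences under different ids);
  id-based identity remains available.
- Negative sampling enforces only global non-overlap with the positive set,
  not a per-protein derangement — the weaker, stated condition.
- Cross-validation reports per-fold means with standard deviations *and*
  pooled-over-folds metrics, since either convention is defensible.
- Ambiguous residues (N, X, B, Z, …) are rejected by default or dropped
  with the record under an explicit policy; never silently substituted.
- Model archives are JSON with floats serialized as hex, so a round-trip
  reproduces scores bit-for-bit on the same platform.

## Known limitations

- Composition kernels saturate on very long sequences: a short planted
  motif contributes O(1/n) to the profile, so signal recovery degrades as
  sequences grow, and organism-scale composition bias can dominate.
- The Gram matrix is dense O(m²) memory and the eigendecomposition O(m³):
  comfortable to a few thousand training pairs on a desktop, not beyond.
- Template sizes beyond the supported ranges (k > 6, l > 8) are refused
  rather than approximated; derived-kernel layers beyond two are out of
  scope.
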