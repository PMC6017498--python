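# rpilearn

Sequence-only prediction of RNA–protein interactions (RPIs). Given nothing
but primary sequences — protein chains and RNA chains as FASTA, plus a
labeled table of interacting / non-interacting pairs — `rpilearn` trains a
kernel classifier that scores any candidate (RNA, protein) pair and can
assemble the positively scored pairs into a bipartite interaction network.
It is aimed at computational biologists who have interaction lists (e.g.
curated from structural interface databases or CLIP-style experiments) and
want quantitative predictions for unseen pairs without structural features.

## The model

**Derived string kernel.** For a sequence *f* of length *n* over an alphabet
*A*, the layer-2 *neural response* is its k-mer frequency profile

N₂(f)(t) = (1/(n−k+1)) Σᵢ 𝟙[f(i..i+k−1) = t],  t ∈ T₁ = Aᵏ,

i.e. sliding-window counts pooled by averaging. Two sequences are compared
by the L2 inner product of their responses under the uniform measure on T₁,
followed by correlation normalization

K̂(f,g) = K(f,g) / √(K(f,f)·K(g,g)),

which makes the kernel the cosine similarity of the k-mer profiles, with
K̂(x,x) = 1 for every x.

**Tensor-product pair kernel.** A pair of pairs is compared by
K̂((r,p),(r′,p′)) = K̂_R(r,r′) · K̂_P(p,p′): similar interactions need both a
similar RNA and a similar protein. Proteins use either the full 20-letter
alphabet (k ≤ 4) or a 7-group reduced alphabet based on dipole moment and
side-chain volume ({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E},
{C}; k ≤ 6); RNA uses A,C,G,U with l ≤ 8.

**Regularized least squares.** With training labels yᵢ ∈ {−1,+1} and Gram
matrix K, the classifier solves (K + λI)c = y and scores a query x as
f(x) = Σᵢ cᵢ K̂(xᵢ, x); score ≤ 0 predicts non-interaction. λ is picked from
{eⁿ : n = −15..15} by leave-one-out cross-validation, computed for all 31
grid values from a single eigendecomposition via the hat-matrix identity
ŷᵢ^(−i) = (f(xᵢ) − Hᵢᵢyᵢ)/(1 − Hᵢᵢ).

The package also ships the evaluation protocol (stratified 10-fold CV with
per-fold λ selection, SE/SP/accuracy/AUC, a (k,l) template-size grid
search), the dataset-curation rules (residue-identity dedupe, <25 aa /
<15 nt length filter, balanced negative sampling by permuting the protein
column against fixed RNAs), and a synthetic motif-planting generator so
everything is testable without external databases.

## Worked example

```python
import rpilearn as rp

prot, rna, pairs = rp.generate(rp.SynthConfig(n_pairs=200, seed=11))
res = rp.cross_validate(pairs, prot, rna, rp.KernelConfig(k=3, l=4), seed=11)
print(res.summary().round(3))
```

prints

```
           mean     sd  pooled
se        1.000  0.000   1.000
sp        0.820  0.132   0.820
accuracy  0.910  0.066   0.910
auc       0.987  0.025   0.988
```

Reading: across ten stratified folds the classifier recovers every planted
interaction (sensitivity 1.0), wrongly calls 18% of background pairs
interacting (specificity 0.82), and ranks positives above negatives almost
everywhere (mean AUC 0.987). `examples/` contains one narrative script per
capability: kernel basics, train/predict with model serialization,
cross-validation, the (k,l) grid search, dataset curation, and network
export (SIF + hub summary).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates random RNA (15–120 nt) and protein (25–200 aa) sequences from
the seed, evaluates the correlation-normalized kernel of every sequence
with itself at all supported template sizes on all alphabets, and writes
the resulting value (the self-similarity the normalization guarantees) with
the number of evaluations performed.
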