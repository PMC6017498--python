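"""Two-layer derived string kernel and the tensor-product pair kernel.

The layer-1 kernel is exact match between equal-length k-mers.  The layer-2
"neural response" of a sequence is the vector of its contiguous k-mer
frequencies (window counts divided by the number of windows), indexed by the
template set T1 = A^k.  The layer-2 kernel is the L2 inner product of two
neural responses under the uniform measure on T1; after correlation
normalization it equals the cosine similarity of the k-mer frequency
vectors, so every self-similarity is exactly 1.

Similarity between two (RNA, protein) pairs is the product of the RNA-RNA
and protein-protein normalized kernels (a tensor-product kernel, positive
semidefinite because both factors are).

T1 is never materialized: responses are sparse maps holding only observed
k-mers (20^4 = 160,000 protein templates would otherwise be enumerated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Iterable, Literal, Sequence as TypingSequence

import numpy as np
import scipy.sparse as sp

from .seqio import (
    PROTEIN7G,
    PROTEIN20,
    RNA4,
    PairTable,
    Sequence,
    SequenceError,
    reduce_protein,
)

__all__ = [
    "KernelConfig",
    "NeuralResponse",
    "GramMatrix",
    "neural_response",
    "k2_raw",
    "k2_normalized",
    "pair_kernel",
    "gram",
    "cross_gram",
    "sequence_kernel_matrix",
    "cross_kernel_matrix",
    "ResponseCache",
    "write_gram_tsv",
]

AlphabetMode = Literal["full20", "reduced7g"]

#: explored template-size ranges: proteins up to 4 on the full alphabet
#: (20^k templates grow fast) and up to 6 on the 7-group alphabet; RNA up to 8.
K_MAX_FULL20 = 4
K_MAX_REDUCED = 6
L_MAX = 8


@dataclass(frozen=True)
class KernelConfig:
    """Template sizes and protein-alphabet mode for the pair kernel.

    ``k`` is the protein template (k-mer) size, ``l`` the RNA template size.
    Defaults are the empirically best operating point on the full alphabet.
    ``allow_large_k`` lifts the default cap of k <= 4 on the full alphabet.
    """

    k: int = 2
    l: int = 5
    alphabet_mode: AlphabetMode = "full20"
    allow_large_k: bool = False

    def __post_init__(self) -> None:
        if self.alphabet_mode not in ("full20", "reduced7g"):
            raise ValueError(f"unknown alphabet_mode {self.alphabet_mode!r}")
        k_cap = K_MAX_REDUCED if (self.alphabet_mode == "reduced7g" or self.allow_large_k) else K_MAX_FULL20
        if not 1 <= self.k <= k_cap:
            raise ValueError(
                f"protein template size k={self.k} outside supported range "
                f"1..{k_cap} for alphabet_mode={self.alphabet_mode!r}"
            )
        if not 1 <= self.l <= L_MAX:
            raise ValueError(f"RNA template size l={self.l} outside 1..{L_MAX}")

    @property
    def protein_alphabet_size(self) -> int:
        return PROTEIN7G.size if self.alphabet_mode == "reduced7g" else PROTEIN20.size

    def encode_protein(self, seq: Sequence) -> Sequence:
        return reduce_protein(seq) if self.alphabet_mode == "reduced7g" else seq


@dataclass(frozen=True)
class NeuralResponse:
    """Sparse layer-2 neural response: template -> window frequency.

    Entries sum to 1 (each of the ``n_windows`` sliding windows contributes
    exactly 1/n_windows to its template); absent templates are 0.
    """

    template_size: int
    entries: dict[str, float]
    n_windows: int

    def self_raw(self, alphabet_size: int) -> float:
        return sum(v * v for v in self.entries.values()) / alphabet_size**self.template_size


def neural_response(seq: Sequence, template_size: int) -> NeuralResponse:
    """Frequency of every contiguous ``template_size``-mer of ``seq``.

    entries[t] = (# windows equal to t) / (n - k + 1).  Sequences shorter
    than the template are a hard error rather than a zero vector.
    """
    n = len(seq.residues)
    k = template_size
    if k < 1:
        raise ValueError("template_size must be >= 1")
    if n < k:
        raise SequenceError(
            f"sequence {seq.id!r} has length {n} < template size {k}"
        )
    n_windows = n - k + 1
    counts: dict[str, int] = {}
    res = seq.residues
    for i in range(n_windows):
        t = res[i : i + k]
        counts[t] = counts.get(t, 0) + 1
    inv = 1.0 / n_windows
    return NeuralResponse(k, {t: c * inv for t, c in counts.items()}, n_windows)


def _check_compatible(f: NeuralResponse, g: NeuralResponse) -> None:
    if f.template_size != g.template_size:
        raise ValueError(
            f"template size mismatch: {f.template_size} vs {g.template_size}"
        )


def k2_raw(f: NeuralResponse, g: NeuralResponse, alphabet_size: int) -> float:
    """Layer-2 inner-product kernel under the uniform measure on T1 = A^k.

    Returns (1/|T1|) * sum_t N2(f)(t) N2(g)(t).  The 1/|T1| factor cancels
    after correlation normalization but is kept here for fidelity to the
    inner-product definition.
    """
    _check_compatible(f, g)
    small, large = (f.entries, g.entries) if len(f.entries) <= len(g.entries) else (g.entries, f.entries)
    dot = sum(v * large.get(t, 0.0) for t, v in small.items())
    return dot / alphabet_size**f.template_size


def k2_normalized(f: NeuralResponse, g: NeuralResponse, alphabet_size: int = 4) -> float:
    """Correlation-normalized layer-2 kernel: K2(f,g)/sqrt(K2(f,f) K2(g,g)).

    Equals the cosine similarity of the sparse frequency vectors; the
    uniform-measure factor cancels, so ``alphabet_size`` only affects the
    intermediate raw values.  Always in [0, 1] with K(x, x) = 1.
    """
    _check_compatible(f, g)
    ff = f.self_raw(alphabet_size)
    gg = g.self_raw(alphabet_size)
    assert ff > 0.0 and gg > 0.0, "self-kernel must be positive when n_windows >= 1"
    value = k2_raw(f, g, alphabet_size) / sqrt(ff * gg)
    # guard against rounding excursions just above 1
    return min(value, 1.0)


class ResponseCache:
    """Memoizes neural responses keyed by (sequence id, template size, mode).

    A Gram matrix over N pairs touching P proteins and R RNAs then costs
    O(P^2 + R^2) sequence-kernel evaluations instead of O(N^2) recomputation.
    """

    def __init__(self) -> None:
        self._store: dict[tuple[str, int, str], NeuralResponse] = {}

    def response(self, seq: Sequence, template_size: int, mode: str = "") -> NeuralResponse:
        key = (seq.id, template_size, mode)
        found = self._store.get(key)
        if found is None:
            found = neural_response(seq, template_size)
            self._store[key] = found
        return found


def pair_kernel(
    r: Sequence,
    p: Sequence,
    r2: Sequence,
    p2: Sequence,
    cfg: KernelConfig,
    cache: ResponseCache | None = None,
) -> float:
    """Tensor-product similarity between pairs (r, p) and (r2, p2).

    The product of the RNA-RNA and protein-protein normalized kernels;
    in [0, 1], and 1 iff both factors are 1.
    """
    cache = cache or ResponseCache()
    mode = cfg.alphabet_mode
    fr = cache.response(r, cfg.l, "rna")
    fr2 = cache.response(r2, cfg.l, "rna")
    fp = cache.response(cfg.encode_protein(p), cfg.k, mode)
    fp2 = cache.response(cfg.encode_protein(p2), cfg.k, mode)
    krr = k2_normalized(fr, fr2, RNA4.size)
    kpp = k2_normalized(fp, fp2, cfg.protein_alphabet_size)
    return krr * kpp


# ---------------------------------------------------------------------------
# batched kernel matrices (sparse linear algebra route; same values as the
# scalar functions, asserted by tests)
# ---------------------------------------------------------------------------


def _response_matrix(
    responses: TypingSequence[NeuralResponse], vocab: dict[str, int]
) -> sp.csr_matrix:
    """Rows = L2-normalized sparse frequency vectors over a shared vocabulary."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for resp in responses:
        for t, v in resp.entries.items():
            idx = vocab.get(t)
            if idx is not None:
                indices.append(idx)
                data.append(v)
        indptr.append(len(indices))
    mat = sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(responses), len(vocab)),
    )
    norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
    # a zero row can only arise when the vocabulary excludes all of a row's
    # templates (cross-kernel against disjoint support) -> kernel value 0
    norms[norms == 0.0] = 1.0
    return sp.diags(1.0 / norms) @ mat


def _shared_vocab(*groups: Iterable[NeuralResponse]) -> dict[str, int]:
    vocab: dict[str, int] = {}
    for group in groups:
        for resp in group:
            for t in resp.entries:
                if t not in vocab:
                    vocab[t] = len(vocab)
    return vocab


def sequence_kernel_matrix(responses: TypingSequence[NeuralResponse]) -> np.ndarray:
    """Symmetric matrix of normalized layer-2 kernel values.

    Cosine similarity of the frequency vectors; diagonal clamped to exactly 1
    (self-kernels equal 1 within 1e-12 before clamping).
    """
    if not responses:
        return np.zeros((0, 0))
    vocab = _shared_vocab(responses)
    X = _response_matrix(responses, vocab)
    G = np.asarray((X @ X.T).todense())
    assert np.all(np.abs(np.diag(G) - 1.0) < 1e-12)
    np.fill_diagonal(G, 1.0)
    np.clip(G, 0.0, 1.0, out=G)
    return G


def cross_kernel_matrix(
    rows: TypingSequence[NeuralResponse], cols: TypingSequence[NeuralResponse]
) -> np.ndarray:
    """Normalized kernel values between two response sets (rows x cols).

    Each response is L2-normalized on its own full support, so values match
    ``k2_normalized`` even when supports differ.
    """
    if not rows or not cols:
        return np.zeros((len(rows), len(cols)))
    vocab = _shared_vocab(rows, cols)
    Xr = _response_matrix(rows, vocab)
    Xc = _response_matrix(cols, vocab)
    G = np.asarray((Xr @ Xc.T).todense())
    np.clip(G, 0.0, 1.0, out=G)
    return G


@dataclass
class GramMatrix:
    """Symmetric PSD matrix of tensor-product pair-kernel values."""

    values: np.ndarray
    row_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("Gram matrix must be square")
        if self.row_ids and len(self.row_ids) != v.shape[0]:
            raise ValueError("row_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        from scipy.linalg import eigvalsh

        return float(eigvalsh(self.values)[0])


def _resolve(pairs: PairTable, proteins, rnas):
    prot_index = {s.id: s for s in proteins}
    rna_index = {s.id: s for s in rnas}
    missing = [
        pid for pid, rid in pairs.pair_ids if pid not in prot_index
    ] + [rid for pid, rid in pairs.pair_ids if rid not in rna_index]
    if missing:
        raise SequenceError(f"unresolvable ids in pair table: {sorted(set(missing))[:5]}")
    return prot_index, rna_index


def _pair_responses(
    pairs: PairTable,
    prot_index: dict[str, Sequence],
    rna_index: dict[str, Sequence],
    cfg: KernelConfig,
    cache: ResponseCache,
) -> tuple[list[NeuralResponse], list[NeuralResponse]]:
    """One response per pair row (cache makes shared sequences free)."""
    too_short: list[str] = []
    for pid, rid in dict.fromkeys(pairs.pair_ids):
        if len(prot_index[pid]) < cfg.k:
            too_short.append(pid)
        if len(rna_index[rid]) < cfg.l:
            too_short.append(rid)
    if too_short:
        raise SequenceError(
            f"sequences shorter than the template size: {sorted(set(too_short))}"
        )
    prot_resp = [
        cache.response(cfg.encode_protein(prot_index[pid]), cfg.k, cfg.alphabet_mode)
        for pid, _ in pairs.pair_ids
    ]
    rna_resp = [cache.response(rna_index[rid], cfg.l, "rna") for _, rid in pairs.pair_ids]
    return prot_resp, rna_resp


def gram(
    pairs: PairTable,
    proteins: TypingSequence[Sequence],
    rnas: TypingSequence[Sequence],
    cfg: KernelConfig,
    cache: ResponseCache | None = None,
) -> GramMatrix:
    """Gram matrix of the tensor-product kernel over a set of pairs.

    Entry (i, j) is K_RNA(r_i, r_j) * K_protein(p_i, p_j); symmetric with
    unit diagonal, PSD up to numerical tolerance.
    """
    cache = cache or ResponseCache()
    prot_index, rna_index = _resolve(pairs, proteins, rnas)
    prot_resp, rna_resp = _pair_responses(pairs, prot_index, rna_index, cfg, cache)
    G = sequence_kernel_matrix(rna_resp) * sequence_kernel_matrix(prot_resp)
    np.fill_diagonal(G, 1.0)
    return GramMatrix(G, pairs.pair_ids)


def cross_gram(
    train_prot_resp: TypingSequence[NeuralResponse],
    train_rna_resp: TypingSequence[NeuralResponse],
    query_pairs: PairTable,
    proteins: TypingSequence[Sequence],
    rnas: TypingSequence[Sequence],
    cfg: KernelConfig,
    cache: ResponseCache | None = None,
) -> np.ndarray:
    """Tensor-product kernel values between training pairs (rows) and queries."""
    cache = cache or ResponseCache()
    prot_index, rna_index = _resolve(query_pairs, proteins, rnas)
    q_prot, q_rna = _pair_responses(query_pairs, prot_index, rna_index, cfg, cache)
    return cross_kernel_matrix(train_rna_resp, q_rna) * cross_kernel_matrix(
        train_prot_resp, q_prot
    )


def write_gram_tsv(path: str | Path, g: GramMatrix) -> None:
    """Export a Gram matrix as TSV with pair-id header row and column."""
    ids = ["|".join(pr) for pr in g.row_ids] or [str(i) for i in range(g.n)]
    with open(path, "w") as fh:
        fh.write("pair\t" + "\t".join(ids) + "\n")
        for name, row in zip(ids, g.values):
            fh.write(name + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")
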