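"""Pair-table construction: length filters, redundancy removal, negatives.

These operations apply the curation rules used to build balanced
interaction training sets from raw positive pair lists: drop pairs with
very short chains, collapse pairs whose protein and RNA sequences are
identical (PDB chains frequently share sequences under different ids), and
construct a same-size negative set by permuting the protein column while
keeping the RNA column fixed, re-permuting until no sampled pair also
appears in the positive set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .seqio import PairRecord, PairTable, Sequence, SequenceError

__all__ = [
    "FilterPolicy",
    "dedupe_pairs",
    "apply_length_filter",
    "sample_negatives",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Minimum chain lengths; pairs strictly below either bound are dropped."""

    min_protein_len: int = 25
    min_rna_len: int = 15

    def __post_init__(self) -> None:
        if self.min_protein_len <= 0 or self.min_rna_len <= 0:
            raise ValueError("length bounds must be positive")


def _index(seqs: TypingSequence[Sequence]) -> dict[str, Sequence]:
    return {s.id: s for s in seqs}


def dedupe_pairs(
    pairs: PairTable,
    proteins: TypingSequence[Sequence] | None = None,
    rnas: TypingSequence[Sequence] | None = None,
    by: Literal["residues", "ids"] = "residues",
) -> PairTable:
    """Keep one record per distinct (protein, RNA) pair.

    With ``by="residues"`` (default) identity is judged on the sequences
    themselves, so two chain ids carrying the same residue string count as
    the same molecule; ``by="ids"`` falls back to id-string identity.
    The first occurrence wins; idempotent.
    """
    if by == "residues":
        if proteins is None or rnas is None:
            raise ValueError("residue-identity dedupe needs the sequence sets")
        prot_index, rna_index = _index(proteins), _index(rnas)
        missing = [
            x
            for r in pairs.records
            for x in ((r.protein_id,) if r.protein_id not in prot_index else ())
            + ((r.rna_id,) if r.rna_id not in rna_index else ())
        ]
        if missing:
            raise SequenceError(f"unresolvable ids: {sorted(set(missing))[:5]}")

        def key(r: PairRecord):
            return (prot_index[r.protein_id].residues, rna_index[r.rna_id].residues)

    else:

        def key(r: PairRecord):
            return (r.protein_id, r.rna_id)

    seen: set = set()
    kept: list[PairRecord] = []
    for rec in pairs.records:
        k = key(rec)
        if k not in seen:
            seen.add(k)
            kept.append(rec)
    return PairTable(kept)


def apply_length_filter(
    pairs: PairTable,
    proteins: TypingSequence[Sequence],
    rnas: TypingSequence[Sequence],
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[PairTable, pd.DataFrame]:
    """Drop pairs with protein shorter than 25 aa or RNA shorter than 15 nt.

    Bounds are strict: a 25-residue protein and a 15-nucleotide RNA are
    kept.  Returns the kept table and a drop log with one reason per row.
    """
    prot_index, rna_index = _index(proteins), _index(rnas)
    kept: list[PairRecord] = []
    dropped: list[dict] = []
    for rec in pairs.records:
        p = prot_index.get(rec.protein_id)
        r = rna_index.get(rec.rna_id)
        if p is None or r is None:
            raise SequenceError(
                f"unresolvable id in pair ({rec.protein_id}, {rec.rna_id})"
            )
        reasons = []
        if len(p) < policy.min_protein_len:
            reasons.append(f"protein_len {len(p)} < {policy.min_protein_len}")
        if len(r) < policy.min_rna_len:
            reasons.append(f"rna_len {len(r)} < {policy.min_rna_len}")
        if reasons:
            dropped.append(
                {
                    "protein_id": rec.protein_id,
                    "rna_id": rec.rna_id,
                    "reason": "; ".join(reasons),
                }
            )
        else:
            kept.append(rec)
    log = pd.DataFrame(dropped, columns=["protein_id", "rna_id", "reason"])
    return PairTable(kept), log


def sample_negatives(
    positives: PairTable,
    seed: int = 0,
    max_restarts: int = 1000,
) -> PairTable:
    """Build a balanced negative set by permuting the protein column.

    The RNA column is kept fixed; the protein column is a random permutation
    of the positives' protein column, re-drawn until no generated pair
    occurs in the positive set.  Marginals are therefore conserved exactly.
    After ``max_restarts // 2`` failed whole-permutation draws, a local
    repair pass swaps conflicting entries pairwise (pure rejection can be
    astronomically slow when one protein partners many RNAs); if no valid
    assignment emerges within ``max_restarts`` attempts the sampler fails
    with a diagnosis instead of looping forever.
    """
    if len(positives) == 0:
        raise ValueError("positive set is empty")
    rng = np.random.default_rng(seed)
    prots = [r.protein_id for r in positives.records]
    rnas = [r.rna_id for r in positives.records]
    pos_set = set(zip(prots, rnas))

    # pigeonhole diagnosis: a protein paired with every distinct RNA can
    # never be placed without reproducing a positive
    rna_universe = set(rnas)
    partners: dict[str, set[str]] = {}
    for p, r in zip(prots, rnas):
        partners.setdefault(p, set()).add(r)
    hubs = [p for p, rs in partners.items() if rs >= rna_universe]
    n = len(prots)

    def conflicts(perm: np.ndarray) -> list[int]:
        """Slots that reproduce a positive pair or duplicate another slot."""
        made: dict[tuple[str, str], int] = {}
        for i in range(n):
            made[(prots[perm[i]], rnas[i])] = made.get((prots[perm[i]], rnas[i]), 0) + 1
        return [
            i
            for i in range(n)
            if (prots[perm[i]], rnas[i]) in pos_set
            or made[(prots[perm[i]], rnas[i])] > 1
        ]

    def try_repair(perm: np.ndarray) -> bool:
        """Resolve conflicts by swapping with a compatible partner slot."""
        for _ in range(n):
            bad = conflicts(perm)
            if not bad:
                return True
            progress = False
            for i in bad:
                order = rng.permutation(n)
                for j in order:
                    if j == i:
                        continue
                    pi, pj = prots[perm[i]], prots[perm[j]]
                    if (pj, rnas[i]) not in pos_set and (pi, rnas[j]) not in pos_set:
                        perm[i], perm[j] = perm[j], perm[i]
                        progress = True
                        break
            if not progress:
                return False
        return not conflicts(perm)

    attempt = 0
    while attempt < max_restarts:
        perm = rng.permutation(n)
        attempt += 1
        if not conflicts(perm):
            break
        if attempt > max_restarts // 2 and try_repair(perm):
            break
    else:
        detail = f"; protein(s) {hubs} partner every RNA" if hubs else ""
        raise RuntimeError(
            f"no conflict-free protein permutation found in {max_restarts} "
            f"attempts{detail}"
        )

    negatives = [
        PairRecord(prots[perm[i]], rnas[i], -1) for i in range(n)
    ]
    out_pairs = {(r.protein_id, r.rna_id) for r in negatives}
    assert len(out_pairs) == n and not (out_pairs & pos_set)
    return PairTable(negatives)
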