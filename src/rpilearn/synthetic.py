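"""Synthetic RNA/protein pair generator with a plantable interaction signal.

Interacting pairs are i.i.d. background sequences into which a short
protein motif and a short RNA motif are written (replacing residues, so
lengths are unchanged); non-interacting pairs are pure background.  The
co-occurring motifs are the only systematic difference between classes, so
a k-mer-composition kernel of sufficient template size can separate them.
``signal_rate`` controls the fraction of positives actually carrying the
motifs and ``label_noise`` flips labels after generation, giving a
continuous dial from fully separable data down to a pure null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .seqio import PROTEIN20, RNA4, PairRecord, PairTable, Sequence

__all__ = ["SynthConfig", "generate"]


@dataclass(frozen=True)
class SynthConfig:
    """Stated world for the generator.

    ``n_pairs`` is the total number of labeled pairs (balanced, so it must
    be even); every pair gets its own freshly drawn protein and RNA.
    Length ranges are inclusive and sit above the curation length filters
    (25 aa / 15 nt) so generated data always passes them.
    """

    n_pairs: int = 200
    protein_len_range: tuple[int, int] = (50, 200)
    rna_len_range: tuple[int, int] = (30, 120)
    protein_motif: str = "WCH"
    rna_motif: str = "GCGC"
    signal_rate: float = 1.0
    label_noise: float = 0.0
    seed: int = 0
    protein_composition: Mapping[str, float] | None = field(default=None, hash=False)
    rna_composition: Mapping[str, float] | None = field(default=None, hash=False)

    def __post_init__(self) -> None:
        if self.n_pairs < 2 or self.n_pairs % 2:
            raise ValueError("n_pairs must be an even number >= 2")
        for ch in self.protein_motif:
            if ch not in PROTEIN20:
                raise ValueError(f"protein motif residue {ch!r} not in PROTEIN20")
        for ch in self.rna_motif:
            if ch not in RNA4:
                raise ValueError(f"rna motif residue {ch!r} not in RNA4")
        if not 0.0 <= self.signal_rate <= 1.0:
            raise ValueError("signal_rate must be in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        for lo, hi, motif, what in (
            (*self.protein_len_range, self.protein_motif, "protein"),
            (*self.rna_len_range, self.rna_motif, "rna"),
        ):
            if lo > hi or lo < 1:
                raise ValueError(f"bad {what} length range ({lo}, {hi})")
            if len(motif) > lo:
                raise ValueError(f"{what} motif longer than minimum length {lo}")


def _weights(alphabet: str, comp: Mapping[str, float] | None) -> np.ndarray:
    if comp is None:
        return np.full(len(alphabet), 1.0 / len(alphabet))
    w = np.array([float(comp.get(ch, 0.0)) for ch in alphabet])
    if w.sum() <= 0:
        raise ValueError("composition weights must have positive mass")
    return w / w.sum()


def _draw(rng: np.random.Generator, alphabet: str, length: int, p: np.ndarray) -> list[str]:
    return list(rng.choice(list(alphabet), size=length, p=p))


def _plant(rng: np.random.Generator, residues: list[str], motif: str) -> None:
    start = int(rng.integers(0, len(residues) - len(motif) + 1))
    residues[start : start + len(motif)] = list(motif)


def generate(cfg: SynthConfig) -> tuple[list[Sequence], list[Sequence], PairTable]:
    """Draw a balanced labeled pair set; fully reproducible from cfg.seed.

    Returns (proteins, rnas, pairs) with ids P0001.../R0001...; pair i uses
    protein i and RNA i.  The first half of the pairs is generated as
    positives (motifs planted with probability ``signal_rate``), the second
    half as negatives; ``label_noise`` then flips each label independently.
    """
    rng = np.random.default_rng(cfg.seed)
    p_prot = _weights(PROTEIN20.symbols, cfg.protein_composition)
    p_rna = _weights(RNA4.symbols, cfg.rna_composition)
    n_pos = cfg.n_pairs // 2

    proteins: list[Sequence] = []
    rnas: list[Sequence] = []
    records: list[PairRecord] = []
    for i in range(cfg.n_pairs):
        is_positive = i < n_pos
        plen = int(rng.integers(cfg.protein_len_range[0], cfg.protein_len_range[1] + 1))
        rlen = int(rng.integers(cfg.rna_len_range[0], cfg.rna_len_range[1] + 1))
        prot = _draw(rng, PROTEIN20.symbols, plen, p_prot)
        rna = _draw(rng, RNA4.symbols, rlen, p_rna)
        if is_positive and rng.random() < cfg.signal_rate:
            _plant(rng, prot, cfg.protein_motif)
            _plant(rng, rna, cfg.rna_motif)
        pid, rid = f"P{i + 1:04d}", f"R{i + 1:04d}"
        proteins.append(Sequence(pid, "".join(prot), PROTEIN20))
        rnas.append(Sequence(rid, "".join(rna), RNA4))
        label = 1 if is_positive else -1
        if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
            label = -label
        records.append(PairRecord(pid, rid, label))
    return proteins, rnas, PairTable(records)
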