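"""Alphabets, sequence validation, reduced-alphabet encoding, and I/O.

Three alphabets are supported: the 20 standard amino acids, a 7-letter
reduced protein alphabet obtained by grouping amino acids with similar
dipole moment and side-chain volume, and the 4 ribonucleotides.  All
sequences entering the kernel machinery are validated against one of
these alphabets; ambiguous residues are rejected by default (silently
substituting them would perturb k-mer profiles invisibly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence as TypingSequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "PROTEIN20",
    "PROTEIN7G",
    "RNA4",
    "SEVEN_GROUPS",
    "Sequence",
    "PairRecord",
    "PairTable",
    "canonicalize_rna",
    "canonicalize_protein",
    "reduce_protein",
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "write_pairs",
]


class SequenceError(ValueError):
    """Raised for invalid residues, malformed records, or unresolvable ids."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of single-character residue tokens."""

    name: str
    symbols: str

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"alphabet {self.name!r} has duplicate symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, ch: str) -> bool:
        return ch in self.symbols


PROTEIN20 = Alphabet("PROTEIN20", "ACDEFGHIKLMNPQRSTVWY")

#: Physicochemical grouping of the 20 amino acids by dipole moment and
#: side-chain volume.  Group tokens are the digits 1-7 in listed order,
#: keeping reduced sequences printable and diff-able.
SEVEN_GROUPS: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

PROTEIN7G = Alphabet("PROTEIN7G", "1234567")
RNA4 = Alphabet("RNA4", "ACGU")

_GROUP_OF: dict[str, str] = {
    aa: str(i + 1) for i, group in enumerate(SEVEN_GROUPS) for aa in group
}
assert len(_GROUP_OF) == 20 and set(_GROUP_OF) == set(PROTEIN20.symbols)


@dataclass(frozen=True)
class Sequence:
    """A validated residue string over a declared alphabet."""

    id: str
    residues: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues):
            if ch not in self.alphabet:
                raise SequenceError(
                    f"sequence {self.id!r}: character {ch!r} at position "
                    f"{pos} is not in alphabet {self.alphabet.name}"
                )

    def __len__(self) -> int:
        return len(self.residues)


AmbiguityPolicy = Literal["reject", "drop"]

# characters tolerated on input; N is the conventional RNA wildcard
_RNA_INPUT = set("ACGUTacgut")
_RNA_AMBIGUOUS = set("NnRYSWKMBDHVryswkmbdhv")
_PROTEIN_AMBIGUOUS = set("XBZUOJxbzuoj")


class _DropSequence(Exception):
    """Internal: sequence contains an ambiguous residue under policy 'drop'."""


def canonicalize_rna(
    raw: str, seq_id: str = "rna", ambiguity: AmbiguityPolicy = "reject"
) -> Sequence:
    """Uppercase, map T to U (DNA-style input is common), validate over ACGU.

    Ambiguous nucleotides (N and other IUPAC codes) raise ``SequenceError``
    under the default policy and signal the caller to discard the record
    under policy ``"drop"``.
    """
    if not raw:
        raise SequenceError(f"sequence {seq_id!r} is empty")
    for pos, ch in enumerate(raw):
        if ch in _RNA_INPUT:
            continue
        if ch in _RNA_AMBIGUOUS:
            if ambiguity == "drop":
                raise _DropSequence(seq_id)
            raise SequenceError(
                f"sequence {seq_id!r}: ambiguous nucleotide {ch!r} at "
                f"position {pos} (policy 'reject')"
            )
        raise SequenceError(
            f"sequence {seq_id!r}: invalid nucleotide {ch!r} at position {pos}"
        )
    return Sequence(seq_id, raw.upper().replace("T", "U"), RNA4)


def canonicalize_protein(
    raw: str, seq_id: str = "protein", ambiguity: AmbiguityPolicy = "reject"
) -> Sequence:
    """Uppercase and validate over the 20 standard amino acids."""
    if not raw:
        raise SequenceError(f"sequence {seq_id!r} is empty")
    upper = raw.upper()
    for pos, ch in enumerate(upper):
        if ch in PROTEIN20:
            continue
        if ch in _PROTEIN_AMBIGUOUS or raw[pos] in _PROTEIN_AMBIGUOUS:
            if ambiguity == "drop":
                raise _DropSequence(seq_id)
            raise SequenceError(
                f"sequence {seq_id!r}: non-standard residue {raw[pos]!r} at "
                f"position {pos} (policy 'reject')"
            )
        raise SequenceError(
            f"sequence {seq_id!r}: invalid residue {raw[pos]!r} at position {pos}"
        )
    return Sequence(seq_id, upper, PROTEIN20)


def reduce_protein(seq: Sequence) -> Sequence:
    """Recode a protein sequence into the 7-group reduced alphabet.

    Each amino acid maps to the digit (1-7) of its physicochemical group;
    the mapping is total on the 20 standard amino acids and preserves
    sequence length.
    """
    if seq.alphabet is PROTEIN7G:
        return seq
    if seq.alphabet is not PROTEIN20:
        raise SequenceError(
            f"cannot reduce sequence {seq.id!r} over {seq.alphabet.name}"
        )
    return Sequence(seq.id, "".join(_GROUP_OF[aa] for aa in seq.residues), PROTEIN7G)


def read_fasta(
    path: str | Path,
    moltype: Literal["protein", "rna"],
    ambiguity: AmbiguityPolicy = "reject",
) -> list[Sequence]:
    """Read a multi-record FASTA file into validated sequences.

    The record id is the first whitespace-delimited token of the header.
    Duplicate ids and empty files are errors.  Under ``ambiguity="drop"``
    records containing ambiguous residues are silently discarded.
    """
    canon = canonicalize_protein if moltype == "protein" else canonicalize_rna
    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            out.append(canon(str(rec.seq), seq_id=rec.id, ambiguity=ambiguity))
        except _DropSequence:
            continue
    if not seen:
        raise SequenceError(f"no FASTA records found in {path}")
    return out


def write_fasta(path: str | Path, seqs: Iterable[Sequence], width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


@dataclass(frozen=True)
class PairRecord:
    protein_id: str
    rna_id: str
    label: int | None = None  # -1, +1, or None for unlabeled prediction input


@dataclass
class PairTable:
    """Labeled (protein_id, rna_id, label) records binding sequences to examples."""

    records: list[PairRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.protein_id, r.rna_id) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise SequenceError(f"duplicate pair rows: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[int | None]:
        return [r.label for r in self.records]

    @property
    def pair_ids(self) -> list[tuple[str, str]]:
        return [(r.protein_id, r.rna_id) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [r.protein_id for r in self.records],
                "rna_id": [r.rna_id for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


def _index_by_id(seqs: TypingSequence[Sequence]) -> dict[str, Sequence]:
    return {s.id: s for s in seqs}


def read_pairs(
    path: str | Path,
    proteins: TypingSequence[Sequence] | None = None,
    rnas: TypingSequence[Sequence] | None = None,
    label_dialect: Literal["pm1", "01"] = "pm1",
    require_labels: bool = True,
) -> PairTable:
    """Read a 2- or 3-column TSV pair table (protein_id, rna_id[, label]).

    Labels are canonicalized to -1/+1 (``label_dialect="01"`` maps 0 to -1).
    Unlabeled tables are accepted only with ``require_labels=False`` (for
    prediction input).  When sequence sets are given, every id must resolve.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    # tolerate an optional header row
    first_row = {str(v).strip().lower() for v in df.iloc[0]}
    if first_row & {"protein_id", "rna_id", "label", "protein", "rna"}:
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise SequenceError(f"pair table {path} has a header but no rows")
    if df.shape[1] not in (2, 3):
        raise SequenceError(
            f"pair table {path} has {df.shape[1]} columns; expected 2 or 3"
        )
    has_labels = df.shape[1] == 3
    if require_labels and not has_labels:
        raise SequenceError(f"pair table {path} is unlabeled")

    prot_index = _index_by_id(proteins) if proteins is not None else None
    rna_index = _index_by_id(rnas) if rnas is not None else None
    valid = {"pm1": {-1, 1}, "01": {0, 1}}[label_dialect]

    records: list[PairRecord] = []
    for row in df.itertuples(index=False):
        pid, rid = str(row[0]).strip(), str(row[1]).strip()
        if prot_index is not None and pid not in prot_index:
            raise SequenceError(f"pair table references unknown protein id {pid!r}")
        if rna_index is not None and rid not in rna_index:
            raise SequenceError(f"pair table references unknown rna id {rid!r}")
        label: int | None = None
        if has_labels:
            try:
                raw = int(str(row[2]).strip())
            except ValueError as exc:
                raise SequenceError(f"unparseable label {row[2]!r} for ({pid}, {rid})") from exc
            if raw not in valid:
                raise SequenceError(
                    f"label {raw} for ({pid}, {rid}) outside dialect {label_dialect!r}"
                )
            label = raw if label_dialect == "pm1" else (1 if raw == 1 else -1)
        records.append(PairRecord(pid, rid, label))
    return PairTable(records)


def write_pairs(path: str | Path, pairs: PairTable) -> None:
    with open(path, "w") as fh:
        for r in pairs.records:
            if r.label is None:
                fh.write(f"{r.protein_id}\t{r.rna_id}\n")
            else:
                fh.write(f"{r.protein_id}\t{r.rna_id}\t{r.label:+d}\n")
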