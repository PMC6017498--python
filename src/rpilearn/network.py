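"""Turn scored pairs into a bipartite interaction network.

Edges are the pairs scored above a threshold (default 0, matching the
classifier's sign rule).  Export is the simple SIF dialect
(``protein interacts rna``) plus a per-node degree summary, the usual
starting point for spotting protein or RNA hubs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["edges_from_scores", "write_sif", "degree_summary", "all_vs_all_pairs"]


def edges_from_scores(scores: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Rows of ``scores`` (protein_id, rna_id, score) with score > threshold."""
    required = {"protein_id", "rna_id", "score"}
    if not required <= set(scores.columns):
        raise ValueError(f"scores frame must have columns {sorted(required)}")
    return scores.loc[scores["score"] > threshold].reset_index(drop=True)


def write_sif(path: str | Path, edges: pd.DataFrame) -> None:
    """Write edges as SIF lines: ``<protein> interacts <rna>``."""
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.protein_id}\tinteracts\t{row.rna_id}\n")


def degree_summary(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-node degree in the undirected bipartite graph, hubs first.

    Degrees sum to twice the edge count (each edge touches one protein and
    one RNA node).
    """
    parts = []
    for col, kind in (("protein_id", "protein"), ("rna_id", "rna")):
        counts = edges[col].value_counts()
        parts.append(
            pd.DataFrame({"node": counts.index, "kind": kind, "degree": counts.values})
        )
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["node", "kind", "degree"]
    )
    return out.sort_values(["degree", "node"], ascending=[False, True]).reset_index(
        drop=True
    )


def all_vs_all_pairs(protein_ids, rna_ids):
    """Unlabeled pair table over the full bipartite grid (for scoring)."""
    from .seqio import PairRecord, PairTable

    return PairTable(
        [PairRecord(p, r, None) for p in protein_ids for r in rna_ids]
    )
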