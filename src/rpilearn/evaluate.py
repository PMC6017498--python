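"""Classification metrics, stratified cross-validation, and template grid search.

The evaluation protocol mirrors how the predictor is meant to be tuned:
pairs are split into ten stratified folds; within each fold's training
portion λ is chosen by leave-one-out cross-validation (test labels are
never touched during selection); sensitivity, specificity, accuracy and
rank-based AUC are computed on the held-out portion.  The grid search
repeats the whole procedure per (k, l) template-size cell and picks the
cell with the best mean accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .kernel import KernelConfig, ResponseCache, gram
from .rls import LAMBDA_GRID, fit_coefficients, loo_select_lambda
from .seqio import PairTable, Sequence

__all__ = [
    "ConfusionCounts",
    "confusion",
    "se_sp_acc",
    "auc",
    "stratified_folds",
    "cross_validate",
    "CVResult",
    "grid_search",
    "GridResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    scores: TypingSequence[float],
    labels: TypingSequence[int],
    threshold: float = 0.0,
) -> ConfusionCounts:
    """Count prediction outcomes under the sign rule.

    A pair is predicted interacting (+1) only when its score is strictly
    above the threshold; a score exactly at the threshold predicts -1, so a
    zero score on a true positive counts as a false negative.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if len(s) == 0:
        raise ValueError("empty input")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be -1/+1")
    pred = np.where(s > threshold, 1, -1)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == -1) & (y == -1))),
        fp=int(np.sum((pred == 1) & (y == -1))),
        fn=int(np.sum((pred == -1) & (y == 1))),
    )


def se_sp_acc(c: ConfusionCounts) -> tuple[float | None, float | None, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), overall accuracy.

    A zero denominator (no positives, or no negatives, evaluated) makes the
    corresponding rate undefined and it is reported as None, never as 0.
    """
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = (c.tp + c.tn) / c.total
    return se, sp, acc


def auc(scores: TypingSequence[float], labels: TypingSequence[int]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    The probability that a random positive outscores a random negative,
    ties counted half; 1 for perfect prediction, 0.5 for random.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties with half-counts
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def stratified_folds(
    labels: TypingSequence[int], n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Assign each index to one of ``n_folds`` class-balanced folds.

    Within each class, indices are shuffled by a seeded generator and dealt
    round-robin, so per-fold class counts differ from exact proportionality
    by at most one example.  Deterministic given (labels, n_folds, seed).
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls} has {len(idx)} examples; needs >= {n_folds}"
            )
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


@dataclass
class CVResult:
    """Per-fold metrics, their means/SDs, and pooled-over-folds metrics."""

    fold_metrics: pd.DataFrame  # fold, lambda, se, sp, accuracy, auc, n_test
    pooled: dict[str, float]
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(self.fold_metrics["auc"].mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_metrics["accuracy"].mean())

    def summary(self) -> pd.DataFrame:
        cols = ["se", "sp", "accuracy", "auc"]
        return pd.DataFrame(
            {
                "mean": self.fold_metrics[cols].mean(),
                "sd": self.fold_metrics[cols].std(ddof=1),
                "pooled": [self.pooled[c] for c in cols],
            }
        )


def _cv_on_gram(
    G: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    grid: np.ndarray,
    objective_scaling: str,
    seed: int,
) -> CVResult:
    rows = []
    all_scores = np.zeros(len(y))
    for fold in np.unique(folds):
        te = folds == fold
        tr = ~te
        K_tr = G[np.ix_(tr, tr)]
        lam, _ = loo_select_lambda(K_tr, y[tr], grid, objective_scaling)
        c = fit_coefficients(K_tr, y[tr], lam, objective_scaling)
        scores = c @ G[np.ix_(tr, te)]
        all_scores[te] = scores
        cm = confusion(scores, y[te])
        se, sp, acc = se_sp_acc(cm)
        rows.append(
            {
                "fold": int(fold),
                "lambda": lam,
                "se": np.nan if se is None else se,
                "sp": np.nan if sp is None else sp,
                "accuracy": acc,
                "auc": auc(scores, y[te]),
                "n_test": int(te.sum()),
            }
        )
    fold_metrics = pd.DataFrame(rows)
    cm = confusion(all_scores, y)
    se, sp, acc = se_sp_acc(cm)
    pooled = {"se": se, "sp": sp, "accuracy": acc, "auc": auc(all_scores, y)}
    return CVResult(fold_metrics, pooled, seed)


def cross_validate(
    pairs: PairTable,
    proteins: TypingSequence[Sequence],
    rnas: TypingSequence[Sequence],
    config: KernelConfig | None = None,
    grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    objective_scaling: str = "eq_sum",
    cache: ResponseCache | None = None,
) -> CVResult:
    """Stratified n-fold cross-validation of the pair-kernel RLS classifier.

    Per fold, λ is selected by leave-one-out on the training portion only;
    metrics are computed on the held-out portion.  The full Gram matrix is
    assembled once and sliced per fold.
    """
    config = config or KernelConfig()
    y = np.asarray(pairs.labels, dtype=float)
    if np.any(pd.isna(y)):
        raise ValueError("cross-validation needs labeled pairs")
    G = gram(pairs, proteins, rnas, config, cache or ResponseCache()).values
    folds = stratified_folds(y.astype(int), n_folds, seed)
    grid = LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    return _cv_on_gram(G, y, folds, grid, objective_scaling, seed)


@dataclass
class GridResult:
    """Mean CV metrics per (k, l) template-size cell and the selected cell."""

    auc_table: pd.DataFrame  # index k, columns l
    accuracy_table: pd.DataFrame
    se_table: pd.DataFrame
    sp_table: pd.DataFrame
    cell_results: dict[tuple[int, int], CVResult]
    best_k: int
    best_l: int
    seed: int

    @property
    def best(self) -> CVResult:
        return self.cell_results[(self.best_k, self.best_l)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (k, l), res in sorted(self.cell_results.items()):
            rows.append(
                {
                    "k": k,
                    "l": l,
                    "mean_auc": res.mean_auc,
                    "mean_accuracy": res.mean_accuracy,
                    "mean_se": res.fold_metrics["se"].mean(),
                    "mean_sp": res.fold_metrics["sp"].mean(),
                }
            )
        return pd.DataFrame(rows)


def grid_search(
    pairs: PairTable,
    proteins: TypingSequence[Sequence],
    rnas: TypingSequence[Sequence],
    k_range: TypingSequence[int],
    l_range: TypingSequence[int],
    alphabet_mode: str = "full20",
    grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    objective_scaling: str = "eq_sum",
) -> GridResult:
    """Full cross-validation per (k, l) cell over the template-size grid.

    The same stratified folds are reused across cells so cells differ only
    in the kernel.  Per-sequence kernel matrices are computed once per k and
    per l and combined elementwise, instead of re-assembling each cell's
    Gram from scratch.  Selection: argmax mean accuracy, ties toward the
    smaller k + l (then smaller k).
    """
    from .kernel import sequence_kernel_matrix, _pair_responses, _resolve

    y = np.asarray(pairs.labels, dtype=float)
    folds = stratified_folds(y.astype(int), n_folds, seed)
    grid = LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    cache = ResponseCache()
    prot_index, rna_index = _resolve(pairs, proteins, rnas)

    G_prot: dict[int, np.ndarray] = {}
    G_rna: dict[int, np.ndarray] = {}
    cell_results: dict[tuple[int, int], CVResult] = {}
    for k in k_range:
        for l in l_range:
            cfg = KernelConfig(k=k, l=l, alphabet_mode=alphabet_mode)  # validates ranges
            if k not in G_prot or l not in G_rna:
                prot_resp, rna_resp = _pair_responses(pairs, prot_index, rna_index, cfg, cache)
                if k not in G_prot:
                    G_prot[k] = sequence_kernel_matrix(prot_resp)
                if l not in G_rna:
                    G_rna[l] = sequence_kernel_matrix(rna_resp)
            G = G_rna[l] * G_prot[k]
            np.fill_diagonal(G, 1.0)
            cell_results[(k, l)] = _cv_on_gram(G, y, folds, grid, objective_scaling, seed)

    def table(metric: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                l: [cell_results[(k, l)].fold_metrics[metric].mean() for k in k_range]
                for l in l_range
            },
            index=list(k_range),
        )

    acc_tbl = table("accuracy")
    best_k, best_l = min(
        cell_results,
        key=lambda kl: (-round(cell_results[kl].mean_accuracy, 12), kl[0] + kl[1], kl[0]),
    )
    return GridResult(
        auc_table=table("auc"),
        accuracy_table=acc_tbl,
        se_table=table("se"),
        sp_table=table("sp"),
        cell_results=cell_results,
        best_k=best_k,
        best_l=best_l,
        seed=seed,
    )
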