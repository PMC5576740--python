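"""Turning a fitted factor model into node-pair scores and ranked candidates.

Node ``i`` is represented by column ``i`` of the consensus matrix ``V*``;
the score of a pair is the similarity of the two columns.  Cosine is the
default (bounded in [-1, 1] and invariant to positive rescaling of the
embedding); plain dot product and negative Euclidean distance are
alternatives that induce different orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .joint_nmf import FactorModel

__all__ = ["ScoreMatrix", "score_from_embeddings", "rank_candidates",
           "write_ranking", "SIMILARITIES"]

SIMILARITIES = ("cosine", "dot", "neg_euclidean")


@dataclass
class ScoreMatrix:
    """Symmetric node-pair scores; diagonal entries carry no ranking meaning."""

    S: np.ndarray
    masked: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n(self) -> int:
        return self.S.shape[0]


def score_from_embeddings(model: FactorModel | np.ndarray,
                          similarity: str = "cosine") -> ScoreMatrix:
    """Score every node pair by the similarity of their ``V*`` columns.

    Cosine between two zero columns is defined as 0.
    """
    X = model.Vstar if isinstance(model, FactorModel) else np.asarray(model)
    if X.ndim != 2:
        raise ValueError("embedding must be a k x n matrix")
    if similarity == "cosine":
        norms = np.linalg.norm(X, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        Y = X / safe
        S = Y.T @ Y
        zero = norms == 0
        S[zero, :] = 0.0
        S[:, zero] = 0.0
    elif similarity == "dot":
        S = X.T @ X
    elif similarity == "neg_euclidean":
        sq = (X ** 2).sum(axis=0)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X.T @ X)
        S = -np.sqrt(np.maximum(d2, 0.0))
    else:
        raise ValueError(
            f"unknown similarity {similarity!r}; expected one of {SIMILARITIES}")
    S = 0.5 * (S + S.T)  # exact symmetry against rounding
    return ScoreMatrix(S)


def rank_candidates(scores: ScoreMatrix, train_edges: set[tuple[int, int]],
                    top_L: int | None = None) -> list[tuple[tuple[int, int], float]]:
    """Non-observed pairs sorted by score descending.

    Candidates are all unordered off-diagonal pairs not in ``train_edges``.
    Ties break by lexicographic (i, j) order, so the ranking is
    deterministic.  ``top_L`` larger than the candidate count returns all
    candidates.
    """
    n = scores.n
    train = {(min(i, j), max(i, j)) for i, j in train_edges}
    iu, ju = np.triu_indices(n, k=1)
    keep = np.ones(len(iu), dtype=bool)
    if train:
        tr = np.array(sorted(train))
        flat = iu.astype(np.int64) * n + ju
        trflat = tr[:, 0].astype(np.int64) * n + tr[:, 1]
        keep = ~np.isin(flat, trflat)
    iu, ju = iu[keep], ju[keep]
    vals = scores.S[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    ranked = [((int(iu[o]), int(ju[o])), float(vals[o])) for o in order]
    if top_L is not None:
        ranked = ranked[: max(top_L, 0)]
    return ranked


def write_ranking(ranked, node_ids, path) -> None:
    """Write ranked candidates as TSV: node_a, node_b, score."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tscore\n")
        for (i, j), s in ranked:
            fh.write(f"{node_ids[i]}\t{node_ids[j]}\t{s:.10g}\n")
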