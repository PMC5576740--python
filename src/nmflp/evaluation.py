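"""Train/probe splitting, AUC and precision metrics, and the CV benchmark.

The observed edge set ``E`` is partitioned into a training part ``E_T``
(visible to the predictor) and a probe part ``E_P`` (held out).  The AUC
is the probability that a randomly chosen probe edge outscores a randomly
chosen nonexistent pair (a pair absent from all of ``E``), counting exact
score ties as one half: over ``n`` sampled comparisons with ``n'`` wins
and ``n''`` ties, ``AUC = (n' + 0.5 n'') / n``.  A random scorer therefore
calibrates to 0.5 and a perfect one to 1.0.  ``auc_exact`` evaluates the
same statistic exhaustively over every (probe, nonexistent) pair and is
the deterministic reference for the sampled estimate.

Precision@L ranks all non-observed pairs (``U - E_T``) and reports the
fraction of the top ``L`` that are probe edges.

``run_benchmark`` is the k-fold harness: edges are randomly partitioned
into folds, each fold in turn serves as probe while the predictor sees
only the remaining training graph, and per-method AUC (and optionally
precision) are averaged over folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import BASELINE_INDICES, baseline_scores
from .graph_io import AttributeMatrix, Graph
from .joint_nmf import FitConfig, fit
from .scoring import ScoreMatrix, rank_candidates, score_from_embeddings

logger = logging.getLogger(__name__)

__all__ = [
    "EvalSplit",
    "AucResult",
    "kfold_edge_splits",
    "auc_sampling",
    "auc_exact",
    "precision_at_L",
    "run_benchmark",
]


@dataclass
class EvalSplit:
    """One fold: disjoint train and probe edge sets whose union is E."""

    train_edges: set[tuple[int, int]]
    probe_edges: set[tuple[int, int]]
    fold_id: int = 0

    def __post_init__(self) -> None:
        if self.train_edges & self.probe_edges:
            raise ValueError("train and probe edge sets overlap")


@dataclass
class AucResult:
    """Sampled AUC with its comparison counts (wins n', ties n'')."""

    n: int
    n_higher: int
    n_equal: int

    @property
    def auc(self) -> float:
        return (self.n_higher + 0.5 * self.n_equal) / self.n


def kfold_edge_splits(graph: Graph, folds: int = 10, seed: int = 0
                      ) -> list[EvalSplit]:
    """Randomly partition the edges into near-equal folds.

    Split ``i`` uses group ``i`` as probe and the union of the others as
    training edges; every edge lands in exactly one probe set.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    edges = sorted(graph.edges)
    if len(edges) < folds:
        raise ValueError(f"{len(edges)} edges cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    groups = np.array_split(order, folds)
    splits = []
    for f, grp in enumerate(groups):
        probe = {edges[i] for i in grp}
        train = set(edges) - probe
        splits.append(EvalSplit(train_edges=train, probe_edges=probe, fold_id=f))
    return splits


def _nonexistent_pairs(n: int, split: EvalSplit) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of all off-diagonal pairs outside E = train ∪ probe."""
    mask = np.zeros((n, n), dtype=bool)
    for i, j in split.train_edges | split.probe_edges:
        mask[i, j] = mask[j, i] = True
    iu, ju = np.triu_indices(n, k=1)
    keep = ~mask[iu, ju]
    return iu[keep], ju[keep]


def auc_sampling(scores: ScoreMatrix, split: EvalSplit, n_samples: int = 10_000,
                 seed: int = 0) -> AucResult:
    """Monte-Carlo AUC: independent draws of (probe edge, nonexistent pair).

    Ties are exact floating-point score equality.
    """
    if not split.probe_edges:
        raise ValueError("probe set is empty")
    ni, nj = _nonexistent_pairs(scores.n, split)
    if len(ni) == 0:
        raise ValueError("no nonexistent pairs to compare against")
    probe = np.array(sorted(split.probe_edges))
    rng = np.random.default_rng(seed)
    pi = rng.integers(0, len(probe), size=n_samples)
    qi = rng.integers(0, len(ni), size=n_samples)
    sp = scores.S[probe[pi, 0], probe[pi, 1]]
    sq = scores.S[ni[qi], nj[qi]]
    n_higher = int(np.count_nonzero(sp > sq))
    n_equal = int(np.count_nonzero(sp == sq))
    return AucResult(n=n_samples, n_higher=n_higher, n_equal=n_equal)


def auc_exact(scores: ScoreMatrix, split: EvalSplit) -> float:
    """Exhaustive AUC over every (probe, nonexistent) comparison.

    Computed by ranking rather than an explicit outer product, so it scales
    to large candidate sets.
    """
    if not split.probe_edges:
        raise ValueError("probe set is empty")
    ni, nj = _nonexistent_pairs(scores.n, split)
    if len(ni) == 0:
        raise ValueError("no nonexistent pairs to compare against")
    probe = np.array(sorted(split.probe_edges))
    sp = np.sort(scores.S[probe[:, 0], probe[:, 1]])
    sq = np.sort(scores.S[ni, nj])
    # For each probe score: #nonexistent strictly below, and #ties.
    lo = np.searchsorted(sq, sp, side="left")
    hi = np.searchsorted(sq, sp, side="right")
    wins = lo.sum()
    ties = (hi - lo).sum()
    return float((wins + 0.5 * ties) / (len(sp) * len(sq)))


def precision_at_L(scores: ScoreMatrix, split: EvalSplit, L: int) -> float:
    """Fraction of the top-L ranked non-observed pairs that are probe edges."""
    if L < 1:
        raise ValueError("L must be >= 1")
    ranked = rank_candidates(scores, split.train_edges, top_L=None)
    if L > len(ranked):
        warnings.warn(
            f"L={L} exceeds the {len(ranked)} candidate pairs; using all")
        L = len(ranked)
    top = ranked[:L]
    m = sum(1 for pair, _ in top if pair in split.probe_edges)
    return m / L


Scorer = Callable[[Graph, EvalSplit], ScoreMatrix]


def _nmf_scorer(attrs: Optional[AttributeMatrix], config: FitConfig,
                similarity: str) -> Scorer:
    def scorer(train_graph: Graph, split: EvalSplit) -> ScoreMatrix:
        # fold-specific seed so the refit on each training graph is
        # independent but reproducible
        cfg = replace(config, seed=config.seed + 101 * (split.fold_id + 1))
        model = fit(train_graph, attrs, cfg)
        return score_from_embeddings(model, similarity)
    return scorer


def run_benchmark(graph: Graph, attrs: Optional[AttributeMatrix] = None,
                  methods: Sequence = ("NMF-LP",) + BASELINE_INDICES,
                  folds: int = 10, config: FitConfig = FitConfig(),
                  seed: int = 0, similarity: str = "cosine",
                  precision_L: Optional[int] = None) -> pd.DataFrame:
    """K-fold cross-validated comparison of predictors.

    ``methods`` entries are either known names (``"NMF-LP"`` or a baseline
    index) or ``(name, scorer)`` pairs where ``scorer(train_graph, split)``
    returns a :class:`ScoreMatrix` — the hook used for calibration scorers
    in the tests.  The factor model is refit on each fold's training graph;
    baselines likewise see only training edges.  Returns a tidy frame with
    one row per (method, fold) plus summary rows ``fold = "mean"``/``"std"``.
    """
    splits = kfold_edge_splits(graph, folds=folds, seed=seed)
    scorers: list[tuple[str, Scorer]] = []
    for method in methods:
        if isinstance(method, tuple):
            scorers.append(method)
        elif method == "NMF-LP":
            scorers.append((method, _nmf_scorer(attrs, config, similarity)))
        elif method in BASELINE_INDICES:
            scorers.append(
                (method, lambda g, s, _idx=method: baseline_scores(g, _idx)))
        else:
            raise ValueError(f"unknown method {method!r}")
    rows = []
    for name, scorer in scorers:
        per_fold = []
        for split in splits:
            train_graph = graph.subgraph_with_edges(split.train_edges)
            assert not (set(train_graph.edges) & split.probe_edges)
            scores = scorer(train_graph, split)
            row = {"method": name, "fold": split.fold_id,
                   "auc": auc_exact(scores, split)}
            if precision_L is not None:
                row["precision"] = precision_at_L(scores, split, precision_L)
            per_fold.append(row)
            logger.debug("%s fold %d: AUC %.4f", name, split.fold_id, row["auc"])
        rows.extend(per_fold)
        df_fold = pd.DataFrame(per_fold)
        for stat in ("mean", "std"):
            row = {"method": name, "fold": stat,
                   "auc": getattr(df_fold["auc"], stat)()}
            if precision_L is not None:
                row["precision"] = getattr(df_fold["precision"], stat)()
            rows.append(row)
    return pd.DataFrame(rows)
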