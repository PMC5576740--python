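"""Classical neighbourhood similarity indices for link prediction.

With ``Gamma(x)`` the neighbour set of ``x`` in the (training) graph,
``c = |Gamma(x) ∩ Gamma(y)|`` the common-neighbour count and ``k_x`` the
degree, the eight indices are

    CN        c
    Salton    c / sqrt(k_x k_y)
    Jaccard   c / |Gamma(x) ∪ Gamma(y)|
    Sorensen  2 c / (k_x + k_y)
    HPI       c / min(k_x, k_y)
    HDI       c / max(k_x, k_y)
    LHN_I     c / (k_x k_y)
    PA        k_x k_y

Any 0/0 is defined as 0, which ranks neighbourless pairs last.
"""

from __future__ import annotations

import numpy as np

from .graph_io import Graph
from .scoring import ScoreMatrix

__all__ = ["BASELINE_INDICES", "baseline_scores"]

BASELINE_INDICES = ("CN", "Salton", "Jaccard", "Sorensen", "HPI", "HDI",
                    "LHN_I", "PA")


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return np.divide(num, den, out=np.zeros_like(num, dtype=np.float64),
                     where=den > 0)


def baseline_scores(graph: Graph, index: str) -> ScoreMatrix:
    """All-pairs score matrix for one similarity index on ``graph``."""
    if index not in BASELINE_INDICES:
        raise ValueError(
            f"unknown index {index!r}; expected one of {BASELINE_INDICES}")
    A = graph.adjacency()
    deg = A.sum(axis=0)
    C = A @ A  # common-neighbour counts; diagonal = degree
    kx = deg[:, None]
    ky = deg[None, :]
    if index == "CN":
        S = C
    elif index == "Salton":
        S = _safe_div(C, np.sqrt(kx * ky))
    elif index == "Jaccard":
        S = _safe_div(C, kx + ky - C)
    elif index == "Sorensen":
        S = _safe_div(2.0 * C, kx + ky)
    elif index == "HPI":
        S = _safe_div(C, np.minimum(kx, ky))
    elif index == "HDI":
        S = _safe_div(C, np.maximum(kx, ky))
    elif index == "LHN_I":
        S = _safe_div(C, kx * ky)
    else:  # PA
        S = kx * ky
    np.fill_diagonal(S, 0.0)
    return ScoreMatrix(np.ascontiguousarray(S, dtype=np.float64))
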