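"""Synthetic graphs with planted structure for testing and benchmarking.

Two generators cover the two properties the factorization is supposed to
exploit: a stochastic block model with block-correlated binary attributes
(community structure, the realistic benchmark), and a low-rank planted
factorization (exact ``A = W H`` recovery, the numerical ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import AttributeMatrix, Graph

__all__ = ["PlantedSpec", "generate_sbm", "generate_low_rank",
           "BACKGROUND_ATTR_RATE"]

# Probability that a block's characteristic attribute shows up on a node of
# another block (annotation noise floor).
BACKGROUND_ATTR_RATE = 0.05


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of the attributed stochastic block model.

    ``n`` nodes are split into ``blocks`` near-equal communities; an edge
    appears with probability ``p_in`` within a block and ``p_out`` between
    blocks.  Each block owns ``m / blocks`` characteristic attributes,
    present on its members with probability ``attr_signal`` and elsewhere
    at the background rate.
    """

    n: int = 100
    blocks: int = 2
    p_in: float = 0.3
    p_out: float = 0.05
    m: int = 20
    attr_signal: float = 0.9
    background: float = BACKGROUND_ATTR_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not (0 <= self.attr_signal <= 1 and 0 <= self.background <= 1):
            raise ValueError("attribute probabilities must lie in [0, 1]")
        if self.blocks < 1 or self.n < self.blocks:
            raise ValueError("need at least one node per block")
        if self.m % self.blocks:
            raise ValueError("m must be divisible by the number of blocks")


def generate_sbm(spec: PlantedSpec) -> tuple[Graph, AttributeMatrix, np.ndarray]:
    """Sample an attributed SBM graph.

    Returns the graph, the raw binary attribute incidence (un-normalized, so
    tests can compare against the planted pattern directly), and the
    ground-truth block assignment.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = [spec.n // spec.blocks] * spec.blocks
    for b in range(spec.n % spec.blocks):
        sizes[b] += 1
    z = np.repeat(np.arange(spec.blocks), sizes)
    iu, ju = np.triu_indices(spec.n, k=1)
    p = np.where(z[iu] == z[ju], spec.p_in, spec.p_out)
    drawn = rng.random(len(iu)) < p
    edges = {(int(i), int(j)) for i, j in zip(iu[drawn], ju[drawn])}
    graph = Graph([f"n{i}" for i in range(spec.n)], edges)

    per_block = spec.m // spec.blocks
    owner = np.repeat(np.arange(spec.blocks), per_block)  # block owning each attribute
    probs = np.where(owner[:, None] == z[None, :], spec.attr_signal,
                     spec.background)
    incidence = (rng.random((spec.m, spec.n)) < probs).astype(np.float64)
    attrs = AttributeMatrix([f"a{b}_{i}" for b, i in
                             zip(owner, np.arange(spec.m) % per_block)],
                            incidence)
    return graph, attrs, z


def generate_low_rank(n: int, k: int, density_scale: float = 1.0,
                      seed: int = 0) -> tuple[Graph, np.ndarray]:
    """Plant a symmetric rank-``k`` non-negative product and threshold it.

    A factor ``W`` (``n x k``) is drawn uniform on [0, 1) and the planted
    product is ``P = W Wᵀ`` — the coefficient matrix is the transpose of the
    base matrix, which makes ``P`` symmetric with rank exactly ``k`` (an
    independent second factor would double the rank of any symmetrized
    product).  The adjacency keeps the pairs whose planted value exceeds
    the ``1 - density`` quantile, with expected density
    ``min(0.25 * density_scale, 1)``.

    Returns the graph and the real-valued planted product ``P`` used by the
    factorization-recovery tests.
    """
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    density = 0.25 * density_scale
    if density <= 0:
        raise ValueError("density_scale must be positive")
    density = min(density, 1.0)
    rng = np.random.default_rng(seed)
    W = rng.random((n, k))
    P = W @ W.T
    iu, ju = np.triu_indices(n, k=1)
    vals = P[iu, ju]
    thresh = np.quantile(vals, 1.0 - density)
    drawn = vals >= thresh
    edges = {(int(i), int(j)) for i, j in zip(iu[drawn], ju[drawn])}
    return Graph([f"n{i}" for i in range(n)], edges), P
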