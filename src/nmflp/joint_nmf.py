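"""Joint non-negative matrix factorization of topology and attributes.

The model factorizes the ``n x n`` adjacency matrix ``A ~ U V`` and, when
node attributes are available, the ``m x n`` attribute matrix
``B ~ U_B V_B``, with all factors non-negative and the two coefficient
matrices tied to a shared consensus embedding ``V*`` (shape ``k x n``,
one latent coordinate vector per node column).  The objective is

    J = ||A - U V||_F^2 + ||B - U_B V_B||_F^2
        + lam * ||Q V - V*||_F^2 + mu * ||Q_B V_B - V*||_F^2

where ``Q = diag(column sums of U)`` and ``Q_B = diag(column sums of U_B)``
absorb the scale freedom of the factor pairs: ``Q V`` is the coefficient
matrix expressed against column-normalized bases, so embeddings from the
two factorizations are compared on a common scale.

Optimization is block coordinate descent with multiplicative updates.
Each update rescales a factor entry-wise by a ratio of the negative and
positive parts of the block gradient, which preserves non-negativity and,
by the standard diagonal-majorization argument, never increases J.  The
consensus penalty enters every update with the same Q-weighting that J
itself uses, so the recorded J history is monotone non-increasing for any
``lam, mu >= 0``; with ``lam = mu = 0`` the updates reduce exactly to the
classical Lee-Seung rules for the Frobenius objective.

With no attribute matrix the B and mu terms vanish, the cycle is
U-update, V-update, ``V* := Q V``, and scoring uses ``V*`` as usual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .graph_io import AttributeMatrix, Graph

__all__ = [
    "FitConfig",
    "FactorModel",
    "default_rank",
    "init_factors",
    "update_U",
    "update_UB",
    "update_V",
    "update_VB",
    "update_Vstar",
    "objective_J",
    "reconstruction_error",
    "fit",
    "fit_matrices",
]


def default_rank(n: int, m: Optional[int] = None, i: int = 1) -> int:
    """Latent dimension from the halving schedule.

    Without attributes the compression condition ``2 n k < n^2`` bounds the
    rank by ``n / 2``, and the schedule is ``k = n / 2^i``.  With ``m``
    attributes the condition ``(n + m) k < n m`` motivates
    ``k = (n + m) / 2^(i+1)``.  ``i = 1`` (the largest rank of the schedule)
    is the default; the result is clamped to ``1 <= k < n``.
    """
    if m is None:
        k = n >> i
    else:
        k = (n + m) >> (i + 1)
    return max(1, min(k, n - 1))


@dataclass(frozen=True)
class FitConfig:
    """Hyper-parameters and stopping rules for a factorization run.

    Parameters
    ----------
    k : int or None
        Latent dimension.  ``None`` selects :func:`default_rank` for the
        problem at hand.
    lam, mu : float
        Non-negative consensus weights for the topology and attribute
        coefficient matrices.
    eps : float or None
        Absolute stopping threshold on the reconstruction error
        ``||A - U V||_F^2``.  ``None`` uses ``1e-4 * ||A||_F^2``.
    rel_tol : float
        Secondary stopping rule: relative decrease of J between
        consecutive iterations below this value stops the run.
    max_iter : int
        Iteration cap; reaching it flags the model as not converged.
    seed : int
        Seed for the factor initialization.  Restart ``r`` draws its
        factors from seed ``seed + r``.
    delta : float
        Small guard added to every update denominator.
    n_restarts : int
        Number of random initializations; the model with the lowest final
        objective J is kept.  Multiplicative updates only find local
        optima, so a few restarts guard against poor draws.
    """

    k: Optional[int] = None
    lam: float = 1.0
    mu: float = 1.0
    eps: Optional[float] = None
    rel_tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    delta: float = 1e-12
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 1:
            raise ValueError("latent dimension k must be >= 1")
        if self.lam < 0 or self.mu < 0:
            raise ValueError("consensus weights lam, mu must be >= 0")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def resolve_k(self, n: int, m: Optional[int]) -> int:
        k = self.k if self.k is not None else default_rank(n, m)
        if not 1 <= k < n:
            raise ValueError(f"latent dimension k={k} must satisfy 1 <= k < n={n}")
        return k


@dataclass
class FactorModel:
    """Factor matrices and fit diagnostics.

    ``U`` is ``n x k``, ``V``, ``VB`` and ``Vstar`` are ``k x n``, ``UB`` is
    ``m x k``.  ``Q`` and ``QB`` are the diagonal normalizers stored as
    length-``k`` vectors of column sums of ``U`` and ``UB``.  ``UB``, ``VB``
    and ``QB`` are ``None`` in no-attribute mode.  ``history_J`` and
    ``history_err`` record the objective and the reconstruction error once
    per full update cycle.
    """

    U: np.ndarray
    V: np.ndarray
    Vstar: np.ndarray
    Q: np.ndarray
    UB: Optional[np.ndarray] = None
    VB: Optional[np.ndarray] = None
    QB: Optional[np.ndarray] = None
    history_J: list[float] = field(default_factory=list)
    history_err: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    stopped_by: str = ""

    @property
    def k(self) -> int:
        return self.U.shape[1]

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def has_attributes(self) -> bool:
        return self.UB is not None

    def copy(self) -> "FactorModel":
        return FactorModel(
            U=self.U.copy(), V=self.V.copy(), Vstar=self.Vstar.copy(),
            Q=self.Q.copy(),
            UB=None if self.UB is None else self.UB.copy(),
            VB=None if self.VB is None else self.VB.copy(),
            QB=None if self.QB is None else self.QB.copy(),
            history_J=list(self.history_J),
            history_err=list(self.history_err),
            n_iter=self.n_iter, converged=self.converged,
            stopped_by=self.stopped_by,
        )


def _as_adjacency(graph) -> np.ndarray:
    if isinstance(graph, Graph):
        return graph.adjacency()
    A = np.asarray(graph, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if np.any(A < 0):
        raise ValueError("adjacency must be non-negative")
    return A


def _as_attr_matrix(attrs, n: int) -> Optional[np.ndarray]:
    if attrs is None:
        return None
    B = attrs.matrix if isinstance(attrs, AttributeMatrix) else np.asarray(
        attrs, dtype=np.float64)
    if B.ndim != 2 or B.shape[1] != n:
        raise ValueError(
            f"attribute matrix must have one column per node (n={n}), "
            f"got shape {B.shape}")
    if np.any(B < 0):
        raise ValueError("attribute matrix must be non-negative")
    return B


def init_factors(graph, attrs=None, config: FitConfig = FitConfig()) -> FactorModel:
    """Draw all factors i.i.d. uniform on (0, 1], reproducibly from the seed.

    Strictly positive initial entries guarantee the multiplicative updates
    can move every entry.  ``Q`` and ``QB`` are computed from the draws, and
    ``V*`` is initialized as their consensus average so the first objective
    value is already well-defined.
    """
    A = _as_adjacency(graph)
    n = A.shape[0]
    B = _as_attr_matrix(attrs, n)
    m = None if B is None else B.shape[0]
    k = config.resolve_k(n, m)
    rng = np.random.default_rng(config.seed)
    draw = lambda *shape: 1.0 - rng.random(shape)  # uniform on (0, 1]
    U = draw(n, k)
    V = draw(k, n)
    Q = U.sum(axis=0)
    if B is None:
        model = FactorModel(U=U, V=V, Vstar=Q[:, None] * V, Q=Q)
    else:
        UB = draw(m, k)
        VB = draw(k, n)
        QB = UB.sum(axis=0)
        Vstar = 0.5 * (Q[:, None] * V + QB[:, None] * VB)
        model = FactorModel(U=U, V=V, Vstar=Vstar, Q=Q, UB=UB, VB=VB, QB=QB)
    return model


def update_U(model: FactorModel, A: np.ndarray, config: FitConfig) -> FactorModel:
    """Multiplicative update of the topology base matrix U (in place).

    Entry (l, m) is rescaled by

        (A V^T + lam * r)_(l,m) / (U V V^T + lam * s_m q_m + delta)

    with ``r_m = sum_j V*_mj V_mj``, ``s_m = sum_j V_mj^2`` and
    ``q_m = sum_h U_hm``; this is the ratio of the negative and positive
    gradient parts of ``||A - U V||^2 + lam ||Q V - V*||^2`` in U (the
    consensus term couples through ``Q``).  ``Q`` is recomputed afterwards.
    """
    lam, d = config.lam, config.delta
    V, Vs = model.V, model.Vstar
    q = model.U.sum(axis=0)
    num = A @ V.T
    den = model.U @ (V @ V.T)
    if lam > 0:
        num = num + lam * (Vs * V).sum(axis=1)[None, :]
        den = den + lam * ((V ** 2).sum(axis=1) * q)[None, :]
    model.U *= num / (den + d)
    model.Q = model.U.sum(axis=0)
    return model


def update_UB(model: FactorModel, B: np.ndarray, config: FitConfig) -> FactorModel:
    """Update of the attribute base matrix U_B; mirrors :func:`update_U`."""
    mu, d = config.mu, config.delta
    VB, Vs = model.VB, model.Vstar
    qb = model.UB.sum(axis=0)
    num = B @ VB.T
    den = model.UB @ (VB @ VB.T)
    if mu > 0:
        num = num + mu * (Vs * VB).sum(axis=1)[None, :]
        den = den + mu * ((VB ** 2).sum(axis=1) * qb)[None, :]
    model.UB *= num / (den + d)
    model.QB = model.UB.sum(axis=0)
    return model


def update_V(model: FactorModel, A: np.ndarray, config: FitConfig) -> FactorModel:
    """Multiplicative update of the topology coefficient matrix V (in place).

    Gradient-ratio step for ``||A - U V||^2 + lam ||Q V - V*||^2`` in V:

        V <- V * (U^T A + lam Q V*) / (U^T U V + lam Q^2 V + delta)

    where Q acts as a row scaling.  The Q-weighted penalty is the one the
    objective J carries, so this step never increases J.
    """
    lam, d = config.lam, config.delta
    U, q = model.U, model.Q
    num = U.T @ A
    den = (U.T @ U) @ model.V
    if lam > 0:
        num = num + lam * q[:, None] * model.Vstar
        den = den + lam * (q ** 2)[:, None] * model.V
    model.V *= num / (den + d)
    return model


def update_VB(model: FactorModel, B: np.ndarray, config: FitConfig) -> FactorModel:
    """Update of the attribute coefficient matrix V_B; mirrors :func:`update_V`."""
    mu, d = config.mu, config.delta
    UB, qb = model.UB, model.QB
    num = UB.T @ B
    den = (UB.T @ UB) @ model.VB
    if mu > 0:
        num = num + mu * qb[:, None] * model.Vstar
        den = den + mu * (qb ** 2)[:, None] * model.VB
    model.VB *= num / (den + d)
    return model


def update_Vstar(model: FactorModel, config: FitConfig = FitConfig()) -> FactorModel:
    """Closed-form consensus update (exact minimizer of J in V*).

    With attributes, ``V* = (lam Q V + mu Q_B V_B) / (lam + mu)``, which at
    ``lam = mu`` is the plain average ``(Q V + Q_B V_B) / 2``; when both
    weights are zero J does not involve V* and the plain average is used as
    the convention.  Without attributes, ``V* = Q V``.
    """
    qv = model.Q[:, None] * model.V
    if model.UB is None:
        model.Vstar = qv
        return model
    qbvb = model.QB[:, None] * model.VB
    lam, mu = config.lam, config.mu
    if lam + mu > 0:
        model.Vstar = (lam * qv + mu * qbvb) / (lam + mu)
    else:
        model.Vstar = 0.5 * (qv + qbvb)
    return model


def reconstruction_error(model: FactorModel, A: np.ndarray) -> float:
    """``||A - U V||_F^2``."""
    return float(np.linalg.norm(A - model.U @ model.V) ** 2)


def objective_J(model: FactorModel, A: np.ndarray, B: Optional[np.ndarray] = None,
                config: FitConfig = FitConfig()) -> float:
    """The joint objective J; the attribute terms vanish when B is absent.

    The normalizers are recomputed from the current factor column sums (Q
    is a function of U, not an independent variable), so the value — and
    any numeric gradient of it — is consistent for arbitrary factors.
    """
    if A.shape != (model.n, model.n):
        raise ValueError(f"adjacency shape {A.shape} does not match model n={model.n}")
    J = reconstruction_error(model, A)
    qv = model.U.sum(axis=0)[:, None] * model.V
    if model.UB is not None:
        if B is None:
            raise ValueError("model has attribute factors but B was not given")
        if B.shape != (model.UB.shape[0], model.n):
            raise ValueError(f"attribute shape {B.shape} inconsistent with model")
        J += float(np.linalg.norm(B - model.UB @ model.VB) ** 2)
        J += config.lam * float(np.linalg.norm(qv - model.Vstar) ** 2)
        qbvb = model.UB.sum(axis=0)[:, None] * model.VB
        J += config.mu * float(np.linalg.norm(qbvb - model.Vstar) ** 2)
    else:
        J += config.lam * float(np.linalg.norm(qv - model.Vstar) ** 2)
    return J


def fit_matrices(A: np.ndarray, B: Optional[np.ndarray] = None,
                 config: FitConfig = FitConfig()) -> FactorModel:
    """Run the full block-coordinate cycle on raw matrices until convergence.

    One iteration is: update U, recompute Q, update U_B, recompute Q_B,
    update V, update V_B, update V*.  Stopping rules, checked after each
    cycle: reconstruction error ``<= eps`` (default ``1e-4 ||A||_F^2``),
    relative decrease of J below ``rel_tol``, or ``max_iter`` cycles; the
    model records which rule fired in ``stopped_by``, and ``converged`` is
    False only for the iteration cap.  With ``n_restarts > 1`` the run is
    repeated from fresh draws and the lowest-J model wins.
    """
    A = _as_adjacency(A)
    B = _as_attr_matrix(B, A.shape[0])
    best: Optional[FactorModel] = None
    for r in range(config.n_restarts):
        cfg = replace(config, seed=config.seed + r) if r else config
        model = _fit_once(A, B, cfg)
        if best is None or model.history_J[-1] < best.history_J[-1]:
            best = model
    return best


def _fit_once(A: np.ndarray, B: Optional[np.ndarray],
              config: FitConfig) -> FactorModel:
    model = init_factors(A, B, config)
    eps = config.eps if config.eps is not None else 1e-4 * float(
        np.linalg.norm(A) ** 2)
    prev_J = None
    for it in range(config.max_iter):
        update_U(model, A, config)
        if B is not None:
            update_UB(model, B, config)
        update_V(model, A, config)
        if B is not None:
            update_VB(model, B, config)
        update_Vstar(model, config)
        err = reconstruction_error(model, A)
        J = objective_J(model, A, B, config)
        model.history_err.append(err)
        model.history_J.append(J)
        model.n_iter = it + 1
        if err <= eps:
            model.converged, model.stopped_by = True, "eps"
            break
        if prev_J is not None and prev_J > 0 and (
                prev_J - J) < config.rel_tol * prev_J:
            model.converged, model.stopped_by = True, "rel_change"
            break
        prev_J = J
    else:
        model.converged, model.stopped_by = False, "max_iter"
    return model


def fit(graph, attrs=None, config: FitConfig = FitConfig()) -> FactorModel:
    """Factorize a :class:`Graph` (and optional attributes); see :func:`fit_matrices`."""
    A = _as_adjacency(graph)
    B = _as_attr_matrix(attrs, A.shape[0])
    return fit_matrices(A, B, config)
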