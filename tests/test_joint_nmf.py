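import numpy as np
import pytest

from nmflp import FitConfig, fit, fit_matrices
from nmflp.joint_nmf import (
    FactorModel,
    init_factors,
    objective_J,
    reconstruction_error,
    update_U,
    update_UB,
    update_V,
    update_VB,
    update_Vstar,
    default_rank,
)
from nmflp.synthetic import generate_low_rank

from conftest import random_instance


def make_model(seed, n=10, m=6, k=3, attrs=True):
    A, B = random_instance(seed, n=n, m=m, k=k)
    cfg = FitConfig(k=k, seed=seed)
    model = init_factors(A, B if attrs else None, cfg)
    return model, A, B, cfg


def block_objective_U(model, A, lam):
    """||A - U V||^2 + lam ||Q V - V*||^2 -- the part of J that U touches."""
    qv = model.U.sum(axis=0)[:, None] * model.V
    return (np.linalg.norm(A - model.U @ model.V) ** 2
            + lam * np.linalg.norm(qv - model.Vstar) ** 2)


def block_objective_V(model, A, lam):
    qv = model.Q[:, None] * model.V
    return (np.linalg.norm(A - model.U @ model.V) ** 2
            + lam * np.linalg.norm(qv - model.Vstar) ** 2)


class TestConfig:
    def test_invalid_values_rejected(self):
        for kwargs in ({"k": 0}, {"lam": -1.0}, {"mu": -0.5}, {"eps": 0.0},
                       {"max_iter": 0}, {"delta": 0.0}, {"n_restarts": 0}):
            with pytest.raises(ValueError):
                FitConfig(**kwargs)

    def test_k_must_be_below_n(self):
        A, B = random_instance(0, n=5)
        with pytest.raises(ValueError, match="k=5"):
            init_factors(A, None, FitConfig(k=5))

    def test_default_rank_schedules(self):
        # no attributes: n / 2^i; with m attributes: (n + m) / 2^(i+1)
        assert default_rank(100) == 50
        assert default_rank(100, i=3) == 12
        assert default_rank(100, m=20) == 30
        assert default_rank(100, m=20, i=2) == 15
        assert default_rank(4, i=6) == 1  # clamped from below
        assert default_rank(3) == 1


class TestInit:
    def test_same_seed_identical(self):
        m1, *_ = make_model(5)
        m2, *_ = make_model(5)
        assert np.array_equal(m1.U, m2.U) and np.array_equal(m1.V, m2.V)
        assert np.array_equal(m1.UB, m2.UB) and np.array_equal(m1.VB, m2.VB)
        assert np.array_equal(m1.Vstar, m2.Vstar)

    def test_different_seed_differs(self):
        m1, *_ = make_model(5)
        m2, *_ = make_model(6)
        assert not np.array_equal(m1.U, m2.U)

    @pytest.mark.parametrize("seed", range(10))
    def test_factors_strictly_positive(self, seed):
        model, *_ = make_model(seed)
        for X in (model.U, model.V, model.UB, model.VB, model.Vstar):
            assert np.all(X > 0)

    def test_q_matches_column_sums(self):
        model, *_ = make_model(2)
        assert np.allclose(model.Q, model.U.sum(axis=0))
        assert np.allclose(model.QB, model.UB.sum(axis=0))


class TestUpdateFixedPoints:
    """With lam = 0 an exact factorization is a fixed point of each update."""

    def test_update_U_exact_factorization_unchanged(self):
        rng = np.random.default_rng(0)
        U = rng.random((8, 3)) + 0.1
        V = rng.random((3, 8)) + 0.1
        A = U @ V
        model = FactorModel(U=U.copy(), V=V.copy(), Vstar=V.copy(),
                            Q=U.sum(axis=0))
        update_U(model, A, FitConfig(k=3, lam=0.0))
        assert np.allclose(model.U, U, rtol=1e-9)

    def test_update_V_exact_factorization_unchanged(self):
        rng = np.random.default_rng(1)
        U = rng.random((8, 3)) + 0.1
        V = rng.random((3, 8)) + 0.1
        A = U @ V
        model = FactorModel(U=U.copy(), V=V.copy(), Vstar=V.copy(),
                            Q=U.sum(axis=0))
        update_V(model, A, FitConfig(k=3, lam=0.0))
        assert np.allclose(model.V, V, rtol=1e-9)

    def test_update_UB_VB_exact_factorization_unchanged(self):
        rng = np.random.default_rng(2)
        UB = rng.random((6, 3)) + 0.1
        VB = rng.random((3, 8)) + 0.1
        B = UB @ VB
        model = FactorModel(U=np.ones((8, 3)), V=np.ones((3, 8)),
                            Vstar=VB.copy(), Q=np.full(3, 8.0),
                            UB=UB.copy(), VB=VB.copy(), QB=UB.sum(axis=0))
        update_UB(model, B, FitConfig(k=3, mu=0.0))
        update_VB(model, B, FitConfig(k=3, mu=0.0))
        assert np.allclose(model.UB, UB, rtol=1e-9)
        assert np.allclose(model.VB, VB, rtol=1e-9)


class TestUpdateDescent:
    """Each multiplicative step never increases its block of the objective."""

    @pytest.mark.parametrize("seed", range(8))
    def test_update_U_descends(self, seed):
        model, A, B, cfg = make_model(seed, n=6)
        before = block_objective_U(model, A, cfg.lam)
        update_U(model, A, cfg)
        assert np.all(model.U >= 0)
        assert block_objective_U(model, A, cfg.lam) <= before * (1 + 1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_update_V_descends(self, seed):
        model, A, B, cfg = make_model(seed, n=6)
        before = block_objective_V(model, A, cfg.lam)
        update_V(model, A, cfg)
        assert np.all(model.V >= 0)
        assert block_objective_V(model, A, cfg.lam) <= before * (1 + 1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_attribute_updates_descend_J(self, seed):
        model, A, B, cfg = make_model(seed, n=6)
        before = objective_J(model, A, B, cfg)
        update_UB(model, B, cfg)
        mid = objective_J(model, A, B, cfg)
        assert mid <= before * (1 + 1e-12)
        update_VB(model, B, cfg)
        assert objective_J(model, A, B, cfg) <= mid * (1 + 1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_vstar_is_exact_minimizer(self, seed):
        model, A, B, cfg = make_model(seed, n=6)
        update_Vstar(model, cfg)
        base = objective_J(model, A, B, cfg)
        rng = np.random.default_rng(seed + 100)
        for _ in range(5):
            bumped = model.copy()
            bumped.Vstar = model.Vstar + 0.05 * rng.standard_normal(
                model.Vstar.shape)
            assert objective_J(bumped, A, B, cfg) >= base

    def test_vstar_equal_inputs(self):
        model, A, B, cfg = make_model(3, n=6)
        # force Q V == QB VB, then V* must equal both
        model.VB = (model.Q[:, None] * model.V) / model.QB[:, None]
        update_Vstar(model, cfg)
        assert np.allclose(model.Vstar, model.Q[:, None] * model.V)

    def test_vstar_zero_coefficients(self):
        model, A, B, cfg = make_model(4, n=6)
        model.V[:] = 0.0
        model.VB[:] = 0.0
        update_Vstar(model, cfg)
        assert np.all(model.Vstar == 0)

    def test_all_zero_attribute_row_drives_UB_row_to_zero(self):
        model, A, B, cfg = make_model(5, n=8, m=5)
        B = B.copy()
        B[2, :] = 0.0
        cfg0 = FitConfig(k=3, mu=0.0, lam=0.0, seed=1)
        for _ in range(200):
            update_UB(model, B, cfg0)
            update_VB(model, B, cfg0)
        assert np.all(model.UB[2, :] < 1e-6)


class TestObjective:
    def test_exact_factorization_gives_zero(self):
        rng = np.random.default_rng(0)
        U = rng.random((6, 2))
        V = rng.random((2, 6))
        Q = U.sum(axis=0)
        UB = rng.random((4, 2))
        QB = UB.sum(axis=0)
        # choose VB so that QB VB = Q V, and V* equal to both
        VB = (Q[:, None] * V) / QB[:, None]
        model = FactorModel(U=U, V=V, Vstar=Q[:, None] * V, Q=Q,
                            UB=UB, VB=VB, QB=QB)
        assert objective_J(model, U @ V, UB @ VB, FitConfig(k=2)) == pytest.approx(0.0)

    def test_zero_factors_closed_form(self):
        A, B = random_instance(1, n=7, m=4)
        z = np.zeros
        model = FactorModel(U=z((7, 2)), V=z((2, 7)), Vstar=z((2, 7)),
                            Q=z(2), UB=z((4, 2)), VB=z((2, 7)), QB=z(2))
        expect = np.linalg.norm(A) ** 2 + np.linalg.norm(B) ** 2
        assert objective_J(model, A, B, FitConfig(k=2)) == pytest.approx(expect)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementwise_oracle(self, seed):
        model, A, B, cfg = make_model(seed, n=6, m=4)
        total = 0.0
        n, k = model.n, model.k
        m = B.shape[0]
        for i in range(n):
            for j in range(n):
                total += (A[i, j] - sum(model.U[i, l] * model.V[l, j]
                                        for l in range(k))) ** 2
        for i in range(m):
            for j in range(n):
                total += (B[i, j] - sum(model.UB[i, l] * model.VB[l, j]
                                        for l in range(k))) ** 2
        for l in range(k):
            ql = sum(model.U[h, l] for h in range(n))
            qbl = sum(model.UB[h, l] for h in range(m))
            for j in range(n):
                total += cfg.lam * (ql * model.V[l, j] - model.Vstar[l, j]) ** 2
                total += cfg.mu * (qbl * model.VB[l, j] - model.Vstar[l, j]) ** 2
        assert objective_J(model, A, B, cfg) == pytest.approx(total)

    def test_shape_mismatch_rejected(self):
        model, A, B, cfg = make_model(0, n=6)
        with pytest.raises(ValueError):
            objective_J(model, A[:4, :4], B, cfg)


class TestLeeSeungReduction:
    """With lam = mu = 0 the updates are the classical multiplicative rules."""

    @pytest.mark.parametrize("seed", range(5))
    def test_identical_to_classical_updates(self, seed):
        model, A, B, _ = make_model(seed, n=7)
        cfg = FitConfig(k=3, lam=0.0, mu=0.0, seed=seed, delta=1e-12)
        U0, V0 = model.U.copy(), model.V.copy()
        update_U(model, A, cfg)
        expect_U = U0 * (A @ V0.T) / (U0 @ V0 @ V0.T + cfg.delta)
        assert np.allclose(model.U, expect_U)
        update_V(model, A, cfg)
        expect_V = V0 * (model.U.T @ A) / (
            model.U.T @ model.U @ V0 + cfg.delta)
        assert np.allclose(model.V, expect_V)


class TestFit:
    @pytest.mark.parametrize("lam,mu", [(1.0, 1.0), (0.5, 2.0), (0.0, 0.0)])
    def test_objective_history_monotone(self, lam, mu):
        for seed in range(6):
            A, B = random_instance(seed, n=15, m=8)
            cfg = FitConfig(k=4, lam=lam, mu=mu, seed=seed, max_iter=120,
                            rel_tol=0.0, eps=1e-30)
            model = fit_matrices(A, B, cfg)
            h = np.array(model.history_J)
            assert np.all(np.diff(h) <= 1e-9 * h[:-1])

    def test_trivial_eps_stops_after_one_iteration(self):
        A, _ = random_instance(0, n=10)
        cfg = FitConfig(k=2, eps=float(np.linalg.norm(A) ** 2) + 1.0, seed=0)
        model = fit_matrices(A, None, cfg)
        assert model.n_iter == 1 and model.stopped_by == "eps"
        assert model.converged

    def test_iteration_cap_flags_non_convergence(self):
        A, B = random_instance(1, n=12)
        cfg = FitConfig(k=3, max_iter=3, eps=1e-30, rel_tol=0.0, seed=0)
        model = fit_matrices(A, B, cfg)
        assert not model.converged and model.stopped_by == "max_iter"

    def test_planted_factorization_recovery(self):
        _, P = generate_low_rank(n=30, k=3, seed=2)
        cfg = FitConfig(k=3, lam=0.0, seed=0, max_iter=500,
                        eps=1e-3 * float(np.linalg.norm(P) ** 2), rel_tol=0.0)
        model = fit_matrices(P, None, cfg)
        rel = reconstruction_error(model, P) / np.linalg.norm(P) ** 2
        assert rel < 1e-3

    def test_no_attribute_mode_consensus_is_QV(self):
        A, _ = random_instance(3, n=12)
        model = fit_matrices(A, None, FitConfig(k=3, seed=1, max_iter=50))
        assert model.UB is None and model.VB is None
        assert np.allclose(model.Vstar, model.Q[:, None] * model.V)

    def test_history_lengths_match_iterations(self):
        A, B = random_instance(4, n=10)
        model = fit_matrices(A, B, FitConfig(k=2, seed=0, max_iter=40))
        assert len(model.history_J) == model.n_iter
        assert len(model.history_err) == model.n_iter

    def test_restarts_pick_lowest_objective(self):
        A, B = random_instance(5, n=12)
        singles = [fit_matrices(A, B, FitConfig(k=3, seed=9 + r, max_iter=60))
                   for r in range(3)]
        multi = fit_matrices(A, B, FitConfig(k=3, seed=9, max_iter=60,
                                             n_restarts=3))
        assert multi.history_J[-1] == pytest.approx(
            min(s.history_J[-1] for s in singles))

    def test_non_negativity_throughout(self):
        A, B = random_instance(6, n=10)
        model = fit_matrices(A, B, FitConfig(k=3, seed=2, max_iter=80))
        for X in (model.U, model.V, model.UB, model.VB, model.Vstar):
            assert np.all(X >= 0)

    def test_delta_insensitivity(self):
        A, B = random_instance(7, n=12)
        cfgs = [FitConfig(k=3, seed=4, max_iter=300, delta=d, rel_tol=0.0,
                          eps=1e-30) for d in (1e-12, 2e-12)]
        J = [fit_matrices(A, B, c).history_J[-1] for c in cfgs]
        assert abs(J[0] - J[1]) <= 1e-6 * J[0]


class TestStationarity:
    """At convergence each factor satisfies its first-order conditions.

    The objective is checked by numeric central differences: at entries
    bounded away from zero the gradient must vanish; at entries pinned at
    the boundary it must be non-negative (complementary slackness).
    """

    @pytest.mark.parametrize("seed", range(3))
    def test_kkt_residuals_small(self, seed):
        A, B = random_instance(seed, n=7, m=5)
        cfg = FitConfig(k=2, seed=seed, max_iter=20000, rel_tol=0.0,
                        eps=1e-300)
        model = fit_matrices(A, B, cfg)

        def J_of():
            return objective_J(model, A, B, cfg)

        for X in (model.U, model.V, model.UB, model.VB, model.Vstar):
            g = central_difference(J_of, X)
            positive = X > 1e-6
            if positive.any():
                assert np.abs(g[positive]).max() < 1e-4
            if (~positive).any():
                assert g[~positive].min() > -1e-3


def central_difference(f, X, h=1e-6):
    g = np.zeros_like(X)
    it = np.nditer(X, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        x0 = X[idx]
        X[idx] = x0 + h
        fp = f()
        X[idx] = max(x0 - h, 0.0)
        lo = X[idx]
        fm = f()
        X[idx] = x0
        g[idx] = (fp - fm) / (h + (x0 - lo))
    return g
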