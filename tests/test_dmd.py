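"""Objective, multiplicative updates, fitting, and model-order selection."""

import numpy as np
import pytest

from devmeta.dmd import (
    DMDConfig,
    build_smoothness_graphs,
    compute_mtd,
    fit,
    objective,
    select_num_dms,
    split_blocks,
    stage_masks,
    update_U,
    update_V,
)
from devmeta.errors import ParameterError
from devmeta.stages import StagePartition


def oracle_update_U(blocks, U, V, partition, graphs, cfg):
    """Straight-line transcription of the U update rule, stage by stage.

    Written with explicit loops and mask matrices, independently of the
    vectorized implementation.
    """
    out = [u.copy() for u in U]
    for t in range(partition.G):
        Xt = blocks[t]
        Vt = V[partition.blocks[t], :]
        num = Xt @ Vt
        den = out[t] @ (Vt.T @ Xt.T @ out[t])
        for k in range(partition.G):
            w = graphs.W_U[t, k]
            num = num + cfg.alpha * w * out[k]
            den = den + cfg.alpha * w * (out[t] @ out[t].T @ out[k])
        out[t] = out[t] * np.sqrt(num / (den + cfg.epsilon))
    return out


def oracle_update_V(blocks, U, V, partition, graphs, cfg):
    """Straight-line transcription of the V update using explicit H^t masks."""
    H = stage_masks(partition)
    num = np.zeros_like(V)
    den = cfg.lam * V
    for t in range(partition.G):
        num = num + H[t] @ blocks[t].T @ U[t]
        den = den + H[t] @ H[t].T @ V @ (U[t].T @ U[t])
    D_V = np.diag(graphs.W_V.sum(axis=1))
    num = num + cfg.beta * graphs.W_V @ V
    den = den + cfg.beta * D_V @ V
    return V * num / (den + cfg.epsilon)


@pytest.fixture
def toy_instance():
    """Single-stage 3x2 toy with p = 1."""
    X = np.array([[2.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    partition = StagePartition(G=1, labels=[0, 0])
    U = [np.full((3, 1), 1.0 / np.sqrt(3))]
    V = np.array([[1.0], [1.0]])
    return X, partition, U, V


class TestSmoothnessGraphs:
    def test_single_stage_graph_is_empty(self):
        graphs = build_smoothness_graphs(StagePartition(G=1, labels=[0, 0, 0]))
        np.testing.assert_array_equal(graphs.W_U, [[0.0]])

    def test_chain_on_three_time_points(self):
        graphs = build_smoothness_graphs(StagePartition(G=3, labels=[0, 1, 2]))
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        np.testing.assert_array_equal(graphs.W_V, expected)
        np.testing.assert_array_equal(np.diag(graphs.D_V), [1.0, 2.0, 1.0])

    def test_chain_on_three_stages(self):
        graphs = build_smoothness_graphs(StagePartition(G=3, labels=[0, 0, 1, 2]))
        assert graphs.W_U[0, 1] == graphs.W_U[1, 2] == 1.0
        assert graphs.W_U[0, 2] == 0.0

    def test_masks_partition_identity(self):
        partition = StagePartition(G=2, labels=[0, 1, 0, 1])
        H = stage_masks(partition)
        total = sum(h @ h.T for h in H)
        np.testing.assert_array_equal(total, np.eye(4))


class TestObjective:
    def test_perfect_reconstruction_zero_penalties(self, rng):
        U = [np.abs(rng.random((6, 2)))]
        V = np.abs(rng.random((3, 2)))
        X = U[0] @ V.T
        partition = StagePartition(G=1, labels=[0, 0, 0])
        cfg = DMDConfig(p=2, lam=0.0, alpha=0.0, beta=0.0)
        graphs = build_smoothness_graphs(partition)
        assert objective(X, partition, U, V, graphs, cfg) == pytest.approx(0.0)

    def test_hand_evaluated_instance(self):
        # M=3, tau=2, G=1, p=1: J = 1/2(0+1+1) + 1/2 * 1 * ||V||^2 = 2
        X = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        U = [np.array([[1.0], [0.0], [0.0]])]
        V = np.array([[1.0], [1.0]])
        partition = StagePartition(G=1, labels=[0, 0])
        cfg = DMDConfig(p=1, lam=1.0, alpha=0.0, beta=0.0)
        graphs = build_smoothness_graphs(partition)
        assert objective(X, partition, U, V, graphs, cfg) == pytest.approx(2.0)

    def test_smoothness_vanishes_for_constant_factors(self, rng):
        M, tau, p = 8, 6, 2
        partition = StagePartition(G=2, labels=[0, 0, 0, 1, 1, 1])
        graphs = build_smoothness_graphs(partition)
        U_shared = np.abs(rng.random((M, p)))
        U = [U_shared.copy(), U_shared.copy()]
        V = np.tile(np.abs(rng.random((1, p))), (tau, 1))
        X = np.abs(rng.random((M, tau)))
        base = DMDConfig(p=p, lam=0.3, alpha=0.0, beta=0.0)
        smooth = DMDConfig(p=p, lam=0.3, alpha=0.9, beta=0.9)
        J0 = objective(X, partition, U, V, graphs, base)
        J1 = objective(X, partition, U, V, graphs, smooth)
        assert J1 == pytest.approx(J0)


class TestUpdates:
    def test_zeros_stay_zero(self, rng):
        M, tau, p = 10, 4, 2
        partition = StagePartition(G=2, labels=[0, 0, 1, 1])
        graphs = build_smoothness_graphs(partition)
        cfg = DMDConfig(p=p)
        X = np.abs(rng.random((M, tau)))
        blocks = split_blocks(X, partition)
        U = [np.abs(rng.random((M, p))) for _ in range(2)]
        U[0][3, 1] = 0.0
        V = np.abs(rng.random((tau, p)))
        V[2, 0] = 0.0
        U2 = update_U(blocks, U, V, partition, graphs, cfg)
        V2 = update_V(blocks, U2, V, partition, graphs, cfg)
        assert U2[0][3, 1] == 0.0
        assert V2[2, 0] == 0.0

    def test_exact_factorization_is_fixed_point(self):
        # orthonormal non-negative U, X = U V^T, alpha = beta = lam = 0
        U = [np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])]
        V = np.array([[2.0, 1.0], [1.0, 3.0]])
        X = U[0] @ V.T
        partition = StagePartition(G=1, labels=[0, 0])
        graphs = build_smoothness_graphs(partition)
        cfg = DMDConfig(p=2, lam=0.0, alpha=0.0, beta=0.0)
        blocks = split_blocks(X, partition)
        U2 = update_U(blocks, U, V, partition, graphs, cfg)
        V2 = update_V(blocks, U2, V, partition, graphs, cfg)
        np.testing.assert_allclose(U2[0], U[0], atol=1e-9)
        np.testing.assert_allclose(V2, V, atol=1e-9)

    def test_one_step_matches_straight_line_oracle(self, toy_instance):
        X, partition, U, V = toy_instance
        graphs = build_smoothness_graphs(partition)
        cfg = DMDConfig(p=1, lam=0.2, alpha=0.3, beta=0.4)
        blocks = split_blocks(X, partition)
        U_impl = update_U(blocks, U, V, partition, graphs, cfg)
        U_ref = oracle_update_U(blocks, U, V, partition, graphs, cfg)
        np.testing.assert_allclose(U_impl[0], U_ref[0], atol=1e-12)
        V_impl = update_V(blocks, U_impl, V, partition, graphs, cfg)
        V_ref = oracle_update_V(blocks, U_ref, V, partition, graphs, cfg)
        np.testing.assert_allclose(V_impl, V_ref, atol=1e-12)

    def test_multi_stage_step_matches_oracle(self, rng):
        M, tau, p = 12, 6, 2
        partition = StagePartition(G=3, labels=[0, 0, 1, 1, 2, 2])
        graphs = build_smoothness_graphs(partition)
        cfg = DMDConfig(p=p, lam=0.15, alpha=0.25, beta=0.35)
        X = np.abs(rng.random((M, tau)))
        blocks = split_blocks(X, partition)
        U = [np.abs(rng.random((M, p))) for _ in range(3)]
        V = np.abs(rng.random((tau, p)))
        U_impl = update_U(blocks, U, V, partition, graphs, cfg)
        U_ref = oracle_update_U(blocks, U, V, partition, graphs, cfg)
        for a, b in zip(U_impl, U_ref):
            np.testing.assert_allclose(a, b, atol=1e-12)
        V_impl = update_V(blocks, U_impl, V, partition, graphs, cfg)
        V_ref = oracle_update_V(blocks, U_ref, V, partition, graphs, cfg)
        np.testing.assert_allclose(V_impl, V_ref, atol=1e-12)


class TestFit:
    def test_nonnegativity_preserved(self, rng):
        X = np.abs(rng.random((15, 6)))
        partition = StagePartition(G=2, labels=[0, 0, 0, 1, 1, 1])
        res = fit(X, partition, DMDConfig(p=2, n_init=2, max_iter=50, seed=0))
        assert all(np.all(Ut >= 0) for Ut in res.U)
        assert np.all(res.V >= 0)

    def test_objective_trace_non_increasing(self, rng):
        X = np.abs(rng.random((20, 8)))
        partition = StagePartition(G=2, labels=[0, 0, 0, 0, 1, 1, 1, 1])
        res = fit(X, partition, DMDConfig(p=3, n_init=2, max_iter=120, seed=1))
        diffs = np.diff(res.objective_trace)
        assert np.max(diffs) <= 1e-9 * res.objective_trace[0]

    def test_deterministic_given_seed(self, rng):
        X = np.abs(rng.random((12, 6)))
        partition = StagePartition(G=2, labels=[0, 0, 0, 1, 1, 1])
        cfg = DMDConfig(p=2, n_init=3, max_iter=60, seed=42)
        a = fit(X, partition, cfg)
        b = fit(X, partition, cfg)
        np.testing.assert_array_equal(a.V, b.V)
        assert a.chosen_restart == b.chosen_restart

    def test_single_block_special_case_matches_reference(self, rng):
        """With alpha = beta = 0 and G = 1 the method reduces to plain
        single-block orthogonal NMF with a ridge on V: identical traces."""
        X = np.abs(rng.random((14, 5)))
        partition = StagePartition(G=1, labels=[0] * 5)
        lam = 0.2
        cfg = DMDConfig(
            p=2, lam=lam, alpha=0.0, beta=0.0, n_init=1, max_iter=40,
            tol=1e-15, seed=9,
        )
        res = fit(X, partition, cfg)
        # replicate the restart's rng stream to seed the reference
        child = np.random.SeedSequence(9).spawn(1)[0]
        ref_trace = single_block_onmf_trace_from_seedseq(X, 2, lam, 40, child)
        np.testing.assert_allclose(res.objective_trace, ref_trace, rtol=1e-10)

    def test_p_larger_than_data_rejected(self, rng):
        X = np.abs(rng.random((6, 4)))
        partition = StagePartition(G=1, labels=[0] * 4)
        with pytest.raises(ParameterError):
            fit(X, partition, DMDConfig(p=5, n_init=1, max_iter=5, seed=0))


def single_block_onmf_trace_from_seedseq(X, p, lam, n_iter, seedseq):
    def J(U, V):
        return 0.5 * np.sum((X - U @ V.T) ** 2) + 0.5 * lam * np.sum(V**2)

    rng = np.random.default_rng(seedseq)
    M, tau = X.shape
    U = 1.0 - rng.random((M, p))
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    V = 1.0 - rng.random((tau, p))
    recon = U @ V.T
    num, den = np.sum(X * recon), np.sum(recon**2)
    if den > 0 and num > 0:
        V *= num / den
    trace = [J(U, V)]
    for _ in range(n_iter):
        for eta in (0.5, 0.25, 0.125):
            cand = U * ((X @ V) / (U @ (V.T @ X.T @ U) + 1e-12)) ** eta
            if J(cand, V) <= trace[-1]:
                U = cand
                break
        V = V * (X.T @ U) / (V @ (U.T @ U) + lam * V + 1e-12)
        trace.append(J(U, V))
    return np.asarray(trace)


class TestMTD:
    def test_identical_columns_zero(self):
        V = np.ones((5, 2))
        assert compute_mtd(V) == pytest.approx(0.0)

    def test_orthogonal_unit_columns_sqrt_two(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        assert compute_mtd(V) == pytest.approx(np.sqrt(2.0))

    def test_hand_oracle_three_rows(self):
        # columns [1,0,1] and [0,1,1]: normalized difference has norm 1
        V = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        assert compute_mtd(V) == pytest.approx(1.0)

    def test_single_column_rejected(self):
        with pytest.raises(ParameterError):
            compute_mtd(np.ones((4, 1)))

    def test_mtd_is_min_over_pairs(self, rng):
        V = np.abs(rng.random((8, 4)))
        Vn = V / np.linalg.norm(V, axis=0)
        brute = min(
            np.linalg.norm(Vn[:, a] - Vn[:, b])
            for a in range(4)
            for b in range(a + 1, 4)
        )
        assert compute_mtd(V) == pytest.approx(brute)


class TestSelection:
    def test_tie_prefers_smallest_p(self, monkeypatch):
        import devmeta.dmd as dmd_mod

        class FakeRes:
            def __init__(self, p):
                self.V = np.eye(4)[:, :p]

        monkeypatch.setattr(
            dmd_mod, "fit", lambda X, partition, cfg: FakeRes(cfg.p)
        )
        monkeypatch.setattr(dmd_mod, "compute_mtd", lambda V: 0.7)
        p_star, curve, _ = dmd_mod.select_num_dms(
            np.abs(np.zeros((6, 4))),
            StagePartition(G=1, labels=[0] * 4),
            [2, 3],
            DMDConfig(p=2, n_init=1),
        )
        assert p_star == 2

    def test_fixed_range_returns_member(self, planted_default):
        data, model = planted_default
        cfg = DMDConfig(p=3, n_init=1, max_iter=200, tol=1e-5, seed=0)
        p_star, curve, fits = select_num_dms(data, model.partition, [3], cfg)
        assert p_star == 3 and set(curve) == {3}


class TestMonotonicityProperty:
    @pytest.mark.parametrize("case", range(10))
    def test_random_instances_non_increasing(self, case):
        rng = np.random.default_rng(1000 + case)
        tau = int(rng.integers(4, 9))
        G = int(rng.integers(1, 4))
        labels = np.sort(rng.integers(0, G, size=tau))
        # ensure every stage occupied
        labels[:G] = np.arange(G)
        labels = np.sort(labels)
        M = int(rng.integers(6, 31))
        p = int(rng.integers(1, 5))
        X = np.abs(rng.random((M, tau)))
        partition = StagePartition(G=G, labels=labels)
        cfg = DMDConfig(
            p=p,
            lam=float(rng.uniform(0, 0.5)),
            alpha=float(rng.uniform(0, 0.5)),
            beta=float(rng.uniform(0, 0.5)),
            n_init=1,
            max_iter=80,
            tol=1e-15,
            seed=case,
        )
        res = fit(X, partition, cfg)
        assert np.max(np.diff(res.objective_trace)) <= 1e-9 * res.objective_trace[0]


class TestOrthogonalityDiagnostic:
    def test_converged_noiseless_planted_gap_is_small(self):
        """On converged noiseless planted data the per-stage orthogonality
        gap ||U'U - I||_F stays at the method's near-orthogonality scale
        (well below the O(sqrt(p)) of unconstrained factors)."""
        from devmeta.synthetic import generate_planted_networks

        data, model = generate_planted_networks(seed=0, noise_sd=0.0)
        res = fit(
            data, model.partition,
            DMDConfig(p=3, n_init=2, max_iter=4000, tol=1e-9, seed=0),
        )
        assert max(res.orthogonality_gap) <= 0.35
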