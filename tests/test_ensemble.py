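"""Lattice coupling, IMEX stepping and ensemble summaries."""

import numpy as np
import pytest

import bioelectric as be
from bioelectric.ensemble import channel_rhs, fixed_points_for_ratio
from bioelectric.single_cell import ChannelParams, MembraneModel


def pure_coupling_model():
    """Channels disabled (zero conductances): dynamics are linear coupling only."""
    return MembraneModel(
        ChannelParams(0.0, -60.0, -25.0, 3.0, "inward"),
        ChannelParams(0.0, 0.0, -25.0, 3.0, "outward"),
        27.0,
        reference_conductance=1.0,
    )


class TestLaplacian:
    def test_single_cell_lattice_is_zero(self):
        L = be.build_laplacian(be.LatticeSpec(1, 1), be.CouplingParams(g=0.3))
        assert L.shape == (1, 1) and L.nnz == 0

    def test_two_cell_chain(self):
        L = be.build_laplacian(be.LatticeSpec(2, 1), be.CouplingParams(g=0.25)).toarray()
        assert np.allclose(L, [[0.25, -0.25], [-0.25, 0.25]])

    def test_center_degree_on_3x3(self):
        L = be.build_laplacian(be.LatticeSpec(3, 3), be.CouplingParams(g=0.7)).toarray()
        assert L[4, 4] == pytest.approx(4 * 0.7)
        corner_deg = [L[i, i] for i in (0, 2, 6, 8)]
        assert np.allclose(corner_deg, 2 * 0.7)

    def test_symmetric_psd_zero_row_sums(self):
        L = be.build_laplacian(be.LatticeSpec(4, 5), be.CouplingParams(g=0.25)).toarray()
        assert np.allclose(L, L.T)
        assert np.allclose(L.sum(axis=1), 0.0, atol=1e-14)
        assert np.linalg.eigvalsh(L).min() > -1e-12

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            be.CouplingParams(g=-0.1)

    def test_capacitive_coupling_rejected(self):
        with pytest.raises(ValueError):
            be.CouplingParams(g=0.25, capacitance_ratio=0.1)


class TestStepMatrix:
    def test_identity_without_coupling(self):
        L = be.build_laplacian(be.LatticeSpec(3, 3), be.CouplingParams(g=0.0))
        A = be.assemble_step_matrix(L, 0.05)
        assert np.allclose(A.toarray(), np.eye(9))

    def test_two_cell_entries(self):
        L = be.build_laplacian(be.LatticeSpec(2, 1), be.CouplingParams(g=0.25))
        A = be.assemble_step_matrix(L, 0.1)
        assert np.allclose(A.toarray(), [[1.025, -0.025], [-0.025, 1.025]])

    def test_smallest_eigenvalue_at_least_one(self):
        L = be.build_laplacian(be.LatticeSpec(4, 4), be.CouplingParams(g=0.6))
        A = be.assemble_step_matrix(L, 0.02)
        assert np.linalg.eigvalsh(A.toarray()).min() >= 1.0 - 1e-12

    def test_invalid_step_rejected(self):
        L = be.build_laplacian(be.LatticeSpec(2, 2), be.CouplingParams(g=0.1))
        with pytest.raises(ValueError):
            be.assemble_step_matrix(L, 0.0)


class TestChannelRhs:
    def test_zero_at_uniform_fixed_point(self, model):
        lat = be.LatticeSpec(3, 3)
        hyper, _ = be.stable_levels(model, 1.0)
        state = be.EnsembleState(np.full(9, hyper), 0.0, lat)
        rhs = channel_rhs(state, be.CellFields.uniform(lat, 1.0), model)
        assert np.allclose(rhs, 0.0, atol=1e-8)

    def test_matches_single_cell_hand_value(self, model):
        # v = -25/27: total current is 5 pA, dimensionless 5/27
        lat = be.LatticeSpec(1, 1)
        state = be.EnsembleState([-25.0 / 27.0], 0.0, lat)
        rhs = channel_rhs(state, be.CellFields.uniform(lat, 1.0), model)
        assert rhs[0] == pytest.approx(-5.0 / 27.0, abs=1e-12)

    def test_shape_mismatch_rejected(self, model):
        state = be.EnsembleState(np.zeros(4), 0.0, be.LatticeSpec(2, 2))
        with pytest.raises(ValueError):
            channel_rhs(state, be.CellFields(np.ones((3, 3))), model)


class TestStep:
    def test_uniform_fixed_point_is_stationary(self, model):
        lat = be.LatticeSpec(4, 4)
        hyper, _ = be.stable_levels(model, 1.0)
        L = be.build_laplacian(lat, be.CouplingParams(g=0.25))
        A = be.assemble_step_matrix(L, 0.01)
        state = be.EnsembleState(np.full(16, hyper), 0.0, lat)
        out = be.step(state, A, be.CellFields.uniform(lat, 1.0), model)
        assert np.max(np.abs(out.v - state.v)) < 1e-9

    def test_two_cell_relaxation_matches_closed_form(self):
        # pure coupling: the potential difference decays as exp(-2 g t)
        g, t_final, dt = 0.25, 2.0, 1e-4
        lat = be.LatticeSpec(2, 1)
        m = pure_coupling_model()
        init = be.EnsembleState([1.0, 0.0], 0.0, lat)
        traj = be.simulate(
            init, be.CellFields.uniform(lat, 0.0), m, be.CouplingParams(g=g),
            be.SimConfig(dt_hat=dt, t_hat_final=t_final),
        )
        diff = traj.final.v[0] - traj.final.v[1]
        assert diff == pytest.approx(np.exp(-2 * g * t_final), rel=5e-4)

    def test_pure_coupling_conserves_total_potential(self):
        rng = np.random.default_rng(7)
        lat = be.LatticeSpec(4, 5)
        m = pure_coupling_model()
        L = be.build_laplacian(lat, be.CouplingParams(g=0.4))
        A = be.assemble_step_matrix(L, 0.05)
        state = be.EnsembleState(rng.normal(size=20), 0.0, lat)
        total0 = state.v.sum()
        for _ in range(50):
            state = be.step(state, A, be.CellFields.uniform(lat, 0.0), m)
        assert state.v.sum() == pytest.approx(total0, abs=1e-10)

    def test_converges_to_euler_oracle_with_order_at_least_one(self, model, euler_reference):
        lat = be.LatticeSpec(5, 5)
        rng = np.random.default_rng(11)
        hyper, depol = be.stable_levels(model, 1.0)
        v0 = rng.uniform(hyper, depol, size=25)
        ratio = np.ones((5, 5))
        t_final, g = 0.5, 0.25

        ref = euler_reference(v0, lat, ratio, g, t_final / 50000, 50000, model)
        errs = []
        for dt in (0.02, 0.01, 0.005):
            traj = be.simulate(
                be.EnsembleState(v0, 0.0, lat), be.CellFields(ratio), model,
                be.CouplingParams(g=g), be.SimConfig(dt_hat=dt, t_hat_final=t_final),
            )
            errs.append(np.max(np.abs(traj.final.v - ref)))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) >= 0.9

    def test_mismatched_dt_rejected(self, model):
        lat = be.LatticeSpec(2, 2)
        A = be.assemble_step_matrix(be.build_laplacian(lat, be.CouplingParams(g=0.1)), 0.01)
        state = be.EnsembleState(np.zeros(4), 0.0, lat)
        with pytest.raises(ValueError):
            be.step(state, A, be.CellFields.uniform(lat, 1.0), model, dt_hat=0.02)

    def test_permutation_equivariance(self, model):
        import scipy.sparse as sp

        lat = be.LatticeSpec(3, 4)
        rng = np.random.default_rng(3)
        v0 = rng.uniform(-2.3, -0.2, size=12)
        ratio = rng.uniform(0.5, 2.0, size=(3, 4))
        perm = rng.permutation(12)
        P = sp.csr_matrix((np.ones(12), (np.arange(12), perm)), shape=(12, 12))

        L = be.build_laplacian(lat, be.CouplingParams(g=0.3))
        A = be.assemble_step_matrix(L, 0.01)
        out = be.step(be.EnsembleState(v0, 0.0, lat), A, be.CellFields(ratio), model)

        # relabel cells: same dynamics in permuted coordinates
        Lp = P @ L @ P.T
        Ap = be.assemble_step_matrix(Lp, 0.01)
        vp = P @ v0
        rp = (P @ ratio.ravel()).reshape(3, 4)
        outp = be.step(be.EnsembleState(vp, 0.0, lat), Ap, be.CellFields(rp), model)
        assert np.allclose(outp.v, P @ out.v, atol=1e-12)


class TestInitialConditions:
    def test_uniform(self):
        state = be.make_initial_condition(be.LatticeSpec(3, 3), "uniform", -2.0)
        assert np.all(state.v == -2.0)

    def test_central_patch_counts(self, model):
        hyper, depol = be.stable_levels(model, 1.0)
        state = be.make_initial_condition(
            be.LatticeSpec(50, 50), "central_patch", (hyper, depol), patch_shape=(10, 10)
        )
        assert int(np.sum(state.v == depol)) == 100
        assert int(np.sum(state.v == hyper)) == 2400

    def test_mask_pattern_equals_mask(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = mask[3, 0] = True
        state = be.make_initial_condition(be.LatticeSpec(4, 4), "mask", (0.0, 1.0), mask=mask)
        assert np.array_equal(state.grid == 1.0, mask)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            be.make_initial_condition(be.LatticeSpec(5, 5), "central_patch", (0.0, 1.0), patch_shape=(6, 6))

    def test_jitter_requires_explicit_rng(self):
        with pytest.raises(ValueError):
            be.make_initial_condition(be.LatticeSpec(3, 3), "uniform", 0.0, jitter_sd=0.1)
        state = be.make_initial_condition(
            be.LatticeSpec(3, 3), "uniform", 0.0, jitter_sd=0.1, rng=np.random.default_rng(0)
        )
        assert np.std(state.v) > 0


class TestSummarize:
    def test_uniform_hyperpolarized_fraction_zero(self, model):
        lat = be.LatticeSpec(5, 5)
        hyper, _ = be.stable_levels(model, 1.0)
        state = be.EnsembleState(np.full(25, hyper), 0.0, lat)
        assert be.summarize(state, model, be.CellFields.uniform(lat, 1.0))["fraction_depolarized"] == 0.0

    def test_patch_fraction(self, model):
        lat = be.LatticeSpec(50, 50)
        state = be.make_initial_condition(lat, "central_patch", be.stable_levels(model, 1.0))
        s = be.summarize(state, model, be.CellFields.uniform(lat, 1.0))
        assert s["fraction_depolarized"] == pytest.approx(100 / 2500)

    def test_monostable_field_classifies_by_single_root(self, model):
        # without the outward channel every cell is monostable hyperpolarized
        lat = be.LatticeSpec(4, 4)
        state = be.EnsembleState(np.full(16, -1.0), 0.0, lat)
        s = be.summarize(state, model, be.CellFields.uniform(lat, 0.0))
        assert s["fraction_depolarized"] == 0.0


class TestSimulate:
    def test_snapshots_at_requested_times_and_deterministic(self, model):
        lat = be.LatticeSpec(6, 6)
        init = be.make_initial_condition(lat, "central_patch", be.stable_levels(model, 1.0), patch_shape=(2, 2))
        cfg = be.SimConfig(dt_hat=0.01, t_hat_final=1.0, snapshot_times=(0.0, 0.5, 1.0))
        args = (be.CellFields.uniform(lat, 1.0), model, be.CouplingParams(g=0.2), cfg)
        t1 = be.simulate(init, *args)
        t2 = be.simulate(init, *args)
        assert t1.times == pytest.approx([0.0, 0.5, 1.0])
        for a, b in zip(t1.snapshots, t2.snapshots):
            assert np.array_equal(a.v, b.v)

    def test_early_stop_records_time(self, model):
        lat = be.LatticeSpec(4, 4)
        hyper, _ = be.stable_levels(model, 1.0)
        init = be.make_initial_condition(lat, "uniform", hyper)
        traj = be.simulate(
            init, be.CellFields.uniform(lat, 1.0), model, be.CouplingParams(g=0.2),
            be.SimConfig(dt_hat=0.01, t_hat_final=5.0, steady_state_tol=1e-6),
        )
        assert traj.stopped_early and traj.stop_t_hat is not None
        assert traj.stop_t_hat < 5.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            be.SimConfig(dt_hat=-0.01)
        with pytest.raises(ValueError):
            be.SimConfig(snapshot_times=(20.0,))
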