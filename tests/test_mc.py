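"""Dynamic MC: move proposal, acceptance rules, MSD, diffusion coefficient."""
import numpy as np
import pytest

import crowdperc as cp
from crowdperc.mc import MSDCurve, build_edge_grid, log_times

from _oracles import substep_crossings


class TestTrialMove:
    def test_support_and_moments(self):
        rng = np.random.default_rng(0)
        draws = np.array([cp.trial_move(rng, 0.01) for _ in range(2000)])
        assert (np.abs(draws) <= 0.01).all()
        n = 10**6
        big = np.array([cp.trial_move(rng, 0.01) for _ in range(5000)])
        big = np.vstack([big, rng.uniform(-0.01, 0.01, (n - 5000, 2))])
        assert abs(big[:, 0].mean()) < 3 * 0.01 / np.sqrt(3 * n)
        assert big[:, 0].var() == pytest.approx(0.01**2 / 3, rel=5e-3)

    def test_delta_validation(self):
        with pytest.raises(ValueError):
            cp.trial_move(np.random.default_rng(0), 0.0)


class TestCrossingCheck:
    def test_zero_length_segment(self, dense_network):
        out = cp.crossing_check((5.0, 5.0), (5.0, 5.0), dense_network)
        assert out == []

    def test_constructed_single_edge(self, gate_network):
        # a short hop across the gate channel crosses exactly that edge
        hits = cp.crossing_check((4.7, 5.0), (5.3, 5.0), gate_network)
        crossed = [e for e, _, _ in hits]
        gate_edges = [
            e for e in range(gate_network.n_edges)
            if not gate_network.passable[e]
        ]
        assert len(crossed) >= 1
        assert set(crossed) & set(gate_edges)

    def test_too_long_segment_raises(self, dense_network):
        with pytest.raises(ValueError):
            cp.crossing_check((0.0, 0.0), (30.0, 0.0), dense_network)

    def test_substep_point_location_oracle(self, dense_network, rng):
        # random short segments: exact intersections vs dense sub-stepping
        L = dense_network.L
        n_trials = 300
        agree = 0
        for _ in range(n_trials):
            old = rng.random(2) * L
            d = rng.uniform(-1.5, 1.5, 2)
            new = old + d
            exact = {e for e, _, _ in cp.crossing_check(old, new, dense_network)}
            approx = substep_crossings(old, new, dense_network, n_sub=1000)
            agree += exact == approx
        assert agree >= 0.98 * n_trials


class TestAcceptMove:
    def test_widely_spaced_obstacles_always_accept(self):
        # all channels passable and the path is clear: rule 1 and 2 both pass
        pos = np.array([[10.0, 10.0], [14.0, 11.0], [3.0, 3.0]])
        m = cp.ObstacleMatrix(pos, L=20.0, seed=0)
        net = cp.tessellate(m)
        assert net.passable.all()
        assert cp.accept_move((5.0, 6.0), (6.5, 7.5), m, net)

    def test_overlap_rejected(self, dense_matrix, dense_network):
        target = dense_matrix.positions[0]
        assert not cp.accept_move(
            target + np.array([1.5, 0.0]), target + np.array([0.2, 0.0]),
            dense_matrix, dense_network,
        )

    def test_forbidden_gap_jump(self, gate_matrix, gate_network):
        # jump across a channel narrower than the tracer diameter lands
        # overlap-free on the far side yet must be rejected
        old = np.array([3.8, 5.0])
        new = np.array([6.2, 5.0])
        d = gate_matrix.positions - new
        d -= gate_matrix.L * np.round(d / gate_matrix.L)
        assert (np.hypot(d[:, 0], d[:, 1]) >= 1.0).all()  # no overlap at target
        assert not cp.accept_move(old, new, gate_matrix, gate_network)
        # a conservative move on the same side is fine
        assert cp.accept_move(old, np.array([3.9, 5.1]), gate_matrix, gate_network)


class TestRunSimulation:
    def test_free_diffusion_matches_analytic_d0(self):
        curve = cp.msd_experiment(
            phi=0.0, L=50.0, delta=2.0, t_max=1000.0, n_configs=4,
            n_tracers=25, seed=21,
        )
        fit = cp.diffusion_coefficient(curve)
        d0 = cp.free_diffusivity(2.0)
        assert fit.value == pytest.approx(d0, abs=3 * max(fit.stderr, 0.01 * d0))

    def test_seed_reproducibility(self, dense_matrix, dense_network):
        p = cp.SimulationParams(delta=0.5, t_max=500.0, n_tracers=5, seed=77)
        a = cp.run_simulation(dense_matrix, dense_network, p)
        b = cp.run_simulation(dense_matrix, dense_network, p)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_no_overlap_along_trajectory(self, dense_matrix, dense_network):
        p = cp.SimulationParams(delta=1.0, t_max=2000.0, n_tracers=5, seed=31)
        ens = cp.run_simulation(dense_matrix, dense_network, p)
        L = dense_matrix.L
        for frame in ens.positions[::7]:
            for pos in frame:
                d = dense_matrix.positions - (pos % L)
                d -= L * np.round(d / L)
                assert (d**2).sum(axis=1).min() >= 1.0 - 1e-9

    def test_cluster_membership_conserved(self, dense_matrix, dense_network):
        # rule 2 confines each tracer to its initial cluster of pores
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(range(dense_network.n_triangles))
        for e in np.nonzero(dense_network.passable)[0]:
            G.add_edge(*dense_network.edge_tri[e])
        label = {}
        for i, comp in enumerate(nx.connected_components(G)):
            for t in comp:
                label[t] = i
        p = cp.SimulationParams(delta=2.0, t_max=3000.0, n_tracers=5, seed=13)
        ens = cp.run_simulation(dense_matrix, dense_network, p)
        L = dense_matrix.L
        for k in range(5):
            start_label = label[dense_network.locate(ens.start[k] % L)]
            for frame in ens.positions[::5]:
                assert label[dense_network.locate(frame[k] % L)] == start_label

    def test_trapped_pore_plateaus(self):
        # three mutually close obstacles enclose a pore with no passable side
        r = 1.8 / np.sqrt(3.0)
        ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
        pos = 5.0 + r * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        m = cp.ObstacleMatrix(pos, L=10.0, sigma=1.0, seed=0)
        net = cp.tessellate(m)
        start = np.array([[5.0, 5.0]])
        p = cp.SimulationParams(delta=0.8, t_max=5000.0, n_tracers=1, seed=3)
        ens = cp.run_simulation(m, net, p, tracers=start)
        disp2 = ((ens.positions[:, 0, :] - start[0]) ** 2).sum(axis=1)
        assert disp2.max() < 2.0  # confined to the closed pore

    def test_small_delta_equivalence_without_edge_grid(self, dense_matrix, dense_network):
        # rule 2 never fires when delta is below the smallest positive gap:
        # trajectories with and without the impassable-channel grid coincide
        min_gap = dense_network.gaps[dense_network.passable].min()
        delta = min(0.9 * min_gap / np.sqrt(2), 0.05)
        p = cp.SimulationParams(delta=float(delta), t_max=2000.0, n_tracers=4, seed=55)
        from crowdperc.mc import _empty_grid

        with_grid = cp.run_simulation(dense_matrix, dense_network, p)
        without = cp.run_simulation(
            dense_matrix, dense_network, p, edge_grid=_empty_grid()
        )
        np.testing.assert_array_equal(with_grid.positions, without.positions)


class TestMSD:
    def test_stationary_tracer_zero(self):
        ens = cp.TrajectoryEnsemble(
            times=np.arange(1.0, 5.0),
            positions=np.tile(np.array([[1.0, 2.0]]), (4, 1, 1)),
            start=np.array([[1.0, 2.0]]),
            phi=0.0, delta=0.1, L=10.0, seed=0,
        )
        assert (cp.msd([ens]).msd == 0).all()

    def test_free_walk_einstein_relation(self):
        curve = cp.msd_experiment(
            phi=0.0, L=50.0, delta=0.1, t_max=2000.0, n_configs=4,
            n_tracers=60, seed=8,
        )
        d0 = cp.free_diffusivity(0.1)
        expected = 4 * d0 * curve.times
        np.testing.assert_allclose(curve.msd, expected, rtol=0.2)

    def test_sliding_origin_consistency(self):
        curve = cp.msd_experiment(
            phi=0.0, L=50.0, delta=0.5, t_max=5000.0, n_configs=2,
            n_tracers=20, seed=9, sliding=True, n_frames=256,
        )
        d0 = cp.free_diffusivity(0.5)
        np.testing.assert_allclose(curve.msd, 4 * d0 * curve.times, rtol=0.1)


class TestDiffusionCoefficient:
    def test_subdiffusive_curve_raises(self):
        t = np.geomspace(1, 1e5, 60)
        curve = MSDCurve(times=t, msd=t**0.6, phi=0.21, delta=0.1, n_samples=10)
        with pytest.raises(cp.NoDiffusiveWindowError):
            cp.diffusion_coefficient(curve)

    def test_exact_linear_curve(self):
        t = np.geomspace(1, 1e4, 50)
        curve = MSDCurve(times=t, msd=4 * 0.02 * t, phi=0.1, delta=0.3, n_samples=10)
        fit = cp.diffusion_coefficient(curve)
        assert fit.value == pytest.approx(0.02, rel=1e-9)

    def test_obstruction_monotonicity(self):
        # D decreases with phi at fixed delta
        Ds = []
        for i, phi in enumerate((0.05, 0.10, 0.15)):
            curve = cp.msd_experiment(
                phi=phi, L=40.0, delta=0.5, t_max=1e5, n_configs=3,
                n_tracers=10, seed=60 + i, sliding=True, n_frames=256,
            )
            Ds.append(cp.diffusion_coefficient(curve).value)
        assert Ds[0] > Ds[1] > Ds[2]


def test_msd_roundtrip(tmp_path):
    curve = MSDCurve(
        times=np.array([1.0, 2.0, 4.0]), msd=np.array([0.5, 1.0, 2.0]),
        phi=0.15, delta=0.3, n_samples=40, L=50.0,
    )
    path = tmp_path / "msd.csv"
    cp.save_msd(curve, path)
    back = cp.load_msd(path)
    np.testing.assert_array_equal(back.times, curve.times)
    np.testing.assert_array_equal(back.msd, curve.msd)
    assert back.phi == curve.phi and back.delta == curve.delta


def test_log_times_strictly_increasing():
    t = log_times(1e5)
    assert (np.diff(t) > 0).all() and t[0] >= 1.0 and t[-1] == pytest.approx(1e5)
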