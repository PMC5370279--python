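"""Langevin integration: determinism, limits, crossing alignment."""

import numpy as np
import pytest

from statewell.latent import LatentTrajectory, linear_latent
from statewell.potential import LatentMap, PotentialShape, boltzmann_density, shape_to_canonical
from statewell.sde import (
    LatentCoverageError,
    NoCrossingError,
    SdeConfig,
    Trajectory,
    align_on_unstable_crossing,
    coefficients_over_time,
    fixed_points_over_time,
    simulate,
    simulate_endpoints,
    simulate_ensemble,
)


def tilted_monostable_map():
    # strong tilt: single stable point in the active well
    return LatentMap(s_min=0.0, s_max=1.0, a1=-0.6, a2=-0.6, d1=0.3, d2=0.3)


class TestSimulate:
    def test_same_seed_bitwise_identical(self, constant_latent, symmetric_map_a):
        cfg = SdeConfig(D=0.02, duration=50.0, x0=0.8, seed=9)
        a = simulate(cfg, constant_latent(), symmetric_map_a, -0.08)
        b = simulate(cfg, constant_latent(), symmetric_map_a, -0.08)
        assert np.array_equal(a.x, b.x)

    def test_noise_free_relaxes_to_stable_point(self, constant_latent):
        lmap = tilted_monostable_map()
        cfg = SdeConfig(D=0.0, duration=100.0, x0=0.1, seed=0)
        traj = simulate(cfg, constant_latent(), lmap, -0.08)
        from statewell.potential import fixed_points, latent_to_shape

        co = shape_to_canonical(latent_to_shape(0.0, lmap, -0.08))
        target = fixed_points(co)[0].x
        assert abs(traj.x[-1] - target) < 1e-6
        # monotone approach toward the fixed point
        gaps = np.abs(traj.x - target)
        assert np.all(np.diff(gaps) <= 1e-12)

    def test_latent_coverage_enforced(self, symmetric_map_a):
        short = LatentTrajectory(t=np.array([0.0, 10.0]), s=np.zeros(2))
        cfg = SdeConfig(D=0.02, duration=50.0, x0=0.5, seed=0)
        with pytest.raises(LatentCoverageError):
            simulate(cfg, short, symmetric_map_a, -0.08)

    def test_stationary_occupancy_split_evenly(self, constant_latent, symmetric_map_a):
        # symmetric well: both basins visited half the time
        cfg = SdeConfig(D=0.02, duration=4e4, x0=0.8, seed=2)
        traj = simulate(cfg, constant_latent(), symmetric_map_a, -0.08)
        frac = float((traj.x > 0.5).mean())
        # ~600 independent well residencies of ~68 s: 3 sigma ~ 0.06
        assert abs(frac - 0.5) < 0.07

    def test_stationary_histogram_matches_boltzmann(
        self, constant_latent, symmetric_map_a
    ):
        cfg = SdeConfig(D=0.02, duration=1e5, x0=0.8, seed=1)
        traj = simulate(cfg, constant_latent(), symmetric_map_a, -0.08)
        co = shape_to_canonical(PotentialShape(h=-0.08, d=0.3))
        edges = np.linspace(-0.5, 1.5, 201)
        hist, _ = np.histogram(traj.x, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        pb = boltzmann_density(centers, co, 0.02)
        l1 = float(np.sum(np.abs(hist - pb)) * (edges[1] - edges[0]))
        assert l1 < 0.05


class TestEnsemble:
    def test_single_member_equals_simulate(self, constant_latent, symmetric_map_a):
        cfg = SdeConfig(D=0.02, duration=20.0, x0=0.8, seed=5)
        solo = simulate(cfg, constant_latent(), symmetric_map_a, -0.08)
        ens = simulate_ensemble(cfg, constant_latent(), symmetric_map_a, -0.08, n=1)
        assert np.array_equal(ens[0].x, solo.x)

    def test_members_use_consecutive_seeds(self, constant_latent, symmetric_map_a):
        cfg = SdeConfig(D=0.02, duration=20.0, x0=0.8, seed=5)
        ens = simulate_ensemble(cfg, constant_latent(), symmetric_map_a, -0.08, n=3)
        cfg7 = SdeConfig(D=0.02, duration=20.0, x0=0.8, seed=7)
        assert np.array_equal(
            ens[2].x, simulate(cfg7, constant_latent(), symmetric_map_a, -0.08).x
        )

    def test_two_calls_bitwise_identical(self, constant_latent, symmetric_map_a):
        cfg = SdeConfig(D=0.02, duration=20.0, x0=0.8, seed=5)
        e1 = simulate_ensemble(cfg, constant_latent(), symmetric_map_a, -0.08, n=4)
        e2 = simulate_ensemble(cfg, constant_latent(), symmetric_map_a, -0.08, n=4)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.x, b.x)

    def test_endpoint_snapshots_reproducible(self, constant_latent, symmetric_map_a):
        cfg = SdeConfig(D=0.02, duration=30.0, x0=0.8, seed=5)
        s1 = simulate_endpoints(cfg, constant_latent(), symmetric_map_a, -0.08,
                                [10.0, 30.0], n=200)
        s2 = simulate_endpoints(cfg, constant_latent(), symmetric_map_a, -0.08,
                                [10.0, 30.0], n=200)
        assert np.array_equal(s1, s2)
        assert s1.shape == (2, 200)


class TestCrossingAlignment:
    def test_linear_descent_crosses_at_expected_time(self):
        dt = 0.01
        t = np.arange(0, 400, dt)
        traj = Trajectory(t=t, x=1.0 - 0.002 * t)
        n = len(t) - 1
        coeffs = (np.zeros(n), np.full(n, -1.7777777777777777),
                  np.full(n, 9.876543209876544))
        stamp = align_on_unstable_crossing(traj, coeffs)
        assert stamp == pytest.approx(250.0, abs=0.011)

    def test_never_leaving_active_basin_signals(self):
        dt = 0.01
        t = np.arange(0, 100, dt)
        traj = Trajectory(t=t, x=np.full(len(t), 0.9))
        n = len(t) - 1
        coeffs = (np.zeros(n), np.full(n, -1.7777777777777777),
                  np.full(n, 9.876543209876544))
        with pytest.raises(NoCrossingError):
            align_on_unstable_crossing(traj, coeffs)

    def test_never_bistable_signals(self):
        dt = 0.01
        t = np.arange(0, 100, dt)
        traj = Trajectory(t=t, x=1.0 - 0.01 * t)
        n = len(t) - 1
        co = shape_to_canonical(PotentialShape(h=-0.08, d=0.3, a=-0.6))
        coeffs = (np.full(n, co.a), np.full(n, co.b), np.full(n, co.c))
        with pytest.raises(NoCrossingError, match="never bistable"):
            align_on_unstable_crossing(traj, coeffs)

    def test_small_noise_crossing_concentrates_at_the_saddle_node(self):
        # a linear tilting that destroys the active well: exactly at zero
        # noise the lagging state never dips below the rising unstable
        # point before the wells merge (critical slowing), so the
        # deterministic limit is probed with vanishing noise — the stamp
        # must agree with a dense root-tracking oracle to one step and sit
        # just before the saddle-node where the barrier vanishes
        lat = linear_latent(-0.036, 1500.0, 0.01)
        lmap = LatentMap(s_min=lat.s_min, s_max=lat.s_max,
                         a1=0.6, a2=-0.1, d1=0.3, d2=0.6)
        cfg = SdeConfig(D=1e-4, duration=1500.0, x0=1.0, seed=3)
        traj = simulate(cfg, lat, lmap, -0.08)
        coeffs = coefficients_over_time(traj.t[:-1], lat, lmap, -0.08)
        stamp = align_on_unstable_crossing(traj, coeffs)
        _, x_un, _ = fixed_points_over_time(*coeffs)
        below = np.nonzero(~np.isnan(x_un) & (traj.x[:-1] <= x_un))[0]
        first = traj.t[below[0]]
        assert abs(stamp - first) <= 0.01 + 1e-9
        sn_time = traj.t[np.nonzero(~np.isnan(x_un))[0][-1]]
        assert sn_time - 10.0 <= stamp <= sn_time + 0.011
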