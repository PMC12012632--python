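"""Brownian-dynamics simulators: potentials, forces, integration, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinseq.errors import ConfigurationError, ParseError, PreconditionError
from kinseq.simulate import (
    IntegratorSpec,
    PolymerSpec,
    ToyPotentialSpec,
    Trajectory,
    four_state_spec,
    polymer_forces,
    polymer_potential_energy,
    read_trajectory,
    run_bd_polymer,
    run_bd_toy,
    straight_chain,
    three_state_spec,
    toy_force,
    toy_potential_energy,
    write_trajectory,
)


def reference_three_state_energy(x, y):
    """Independent one-line oracle for the three-well potential."""
    G = lambda u, u0: np.exp(-((u - u0) ** 2) / (2 * 0.8**2))
    return (
        0.0001 * (x**6 + y**6)
        - G(x, 0) * G(y, 0)
        - G(x, -1.5) * G(y, -1.5)
        - G(x, 1.5) * G(y, 1.5)
    )


class TestToyPotential:
    def test_energy_at_origin_matches_scalar_oracle(self):
        spec = three_state_spec()
        assert toy_potential_energy(spec, (0.0, 0.0)) == pytest.approx(
            reference_three_state_energy(0.0, 0.0)
        )
        # frozen oracle value
        assert toy_potential_energy(spec, (0.0, 0.0)) == pytest.approx(
            -1.0595, abs=1e-4
        )

    @given(
        st.floats(-3, 3), st.floats(-3, 3)
    )
    @settings(max_examples=50, deadline=None)
    def test_energy_matches_oracle_everywhere(self, x, y):
        spec = three_state_spec()
        assert toy_potential_energy(spec, (x, y)) == pytest.approx(
            reference_three_state_energy(x, y), rel=1e-12, abs=1e-12
        )

    def test_confining_term_dominates_far_away(self):
        spec = three_state_spec()
        vals = [toy_potential_energy(spec, (r, r)) for r in (5, 10, 20)]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 1e3

    def test_outer_wells_symmetric(self):
        spec = three_state_spec()
        assert toy_potential_energy(spec, (1.5, 1.5)) == pytest.approx(
            toy_potential_energy(spec, (-1.5, -1.5))
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            ToyPotentialSpec(kind="five_state")

    def test_wrong_center_count_rejected(self):
        with pytest.raises(ConfigurationError):
            ToyPotentialSpec(kind="four_state", well_centers=((0, 0),) * 3)


class TestToyForce:
    def test_zero_at_symmetric_stationary_point(self):
        np.testing.assert_allclose(toy_force(three_state_spec(), (0, 0)), 0, atol=1e-12)

    @pytest.mark.parametrize("spec_fn", [three_state_spec, four_state_spec])
    @pytest.mark.parametrize("point", [(0.3, -0.7), (1.2, 1.4), (-2.0, 0.5)])
    def test_matches_finite_differences(self, spec_fn, point):
        spec = spec_fn()
        h = 1e-5
        x, y = point
        fd = np.array(
            [
                (toy_potential_energy(spec, (x - h, y)) - toy_potential_energy(spec, (x + h, y))) / (2 * h),
                (toy_potential_energy(spec, (x, y - h)) - toy_potential_energy(spec, (x, y + h))) / (2 * h),
            ]
        )
        np.testing.assert_allclose(toy_force(spec, point), fd, rtol=1e-6, atol=1e-9)

    def test_four_state_origin_force_vanishes_by_inversion_symmetry(self):
        # the four outer centers form inversion-symmetric pairs
        # ((2,-1)/(-2,1) and (0.5,2)/(-0.5,-2)), so the origin is stationary
        np.testing.assert_allclose(toy_force(four_state_spec(), (0, 0)), 0.0,
                                   atol=1e-12)
        # off the symmetry point the force is finite
        assert np.linalg.norm(toy_force(four_state_spec(), (0.5, 0.3))) > 1e-3


class TestToyDynamics:
    def test_zero_temperature_at_stationary_point_is_static(self):
        integ = IntegratorSpec(dt=0.01, n_steps=500, save_stride=10, kT=0.0, seed=0)
        traj = run_bd_toy(three_state_spec(), integ, x0=(0.0, 0.0))
        np.testing.assert_array_equal(
            traj.frames, np.broadcast_to(traj.frames[0], traj.frames.shape)
        )

    def test_deterministic_given_seed(self):
        integ = IntegratorSpec(dt=0.01, n_steps=2000, save_stride=10, seed=123)
        t1 = run_bd_toy(three_state_spec(), integ)
        t2 = run_bd_toy(three_state_spec(), integ)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_free_diffusion_msd(self):
        # V = 0: MSD after n steps = 4 (kT/gamma) n dt in 2D
        spec = ToyPotentialSpec(
            "three_state", well_amplitude=0.0,
            well_centers=((100.0, 100.0), (101, 101), (102, 102)),  # far away
        )
        n_steps, dt = 100, 0.01
        reps = 1500
        disp = np.empty(reps)
        for r in range(reps):
            integ = IntegratorSpec(dt=dt, n_steps=n_steps, save_stride=n_steps, seed=r)
            traj = run_bd_toy(spec, integ, x0=(0.0, 0.0))
            disp[r] = np.sum((traj.frames[-1, 0] - traj.frames[0, 0]) ** 2)
        expected = 4 * 1.0 * n_steps * dt
        se = disp.std(ddof=1) / np.sqrt(reps)
        assert abs(disp.mean() - expected) < 3 * se

    def test_increment_variance_matches_fluctuation_dissipation(self):
        spec = ToyPotentialSpec(
            "three_state", well_amplitude=0.0,
            well_centers=((100.0, 100.0), (101, 101), (102, 102)),
        )
        integ = IntegratorSpec(dt=0.01, n_steps=100_000, save_stride=1,
                               gamma=2.0, kT=1.5, seed=3)
        traj = run_bd_toy(spec, integ, x0=(0.0, 0.0))
        inc = np.diff(traj.frames[:, 0, :], axis=0).ravel()
        expected = 2 * integ.kT * integ.dt / integ.gamma
        n = inc.size
        se = expected * np.sqrt(2.0 / n)  # SE of a variance estimate
        assert abs(inc.var() - expected) < 3 * se

    def test_boltzmann_well_occupancy_ratio(self, toy_trajectory):
        """Long-run occupancies of the wells match 2D quadrature of the
        Boltzmann weight over each basin."""
        from scipy import integrate

        spec = three_state_spec()
        kT = toy_trajectory.meta["integrator"].kT

        def boltz(y, x):
            return np.exp(-toy_potential_energy(spec, (x, y)) / kT)

        # basins: squares of half-width 1.05 around each well center
        w = 1.05
        Z = {}
        for cx, cy in spec.well_centers:
            Z[(cx, cy)], _ = integrate.dblquad(
                boltz, cx - w, cx + w, cy - w, cy + w, epsabs=1e-6
            )
        pos = toy_trajectory.frames[:, 0, :]
        occ = {}
        for cx, cy in spec.well_centers:
            occ[(cx, cy)] = np.mean(
                (np.abs(pos[:, 0] - cx) < w) & (np.abs(pos[:, 1] - cy) < w)
            )
        centers = list(spec.well_centers)
        # compare the center well against the mean of the two (symmetry-
        # equivalent) outer wells to reduce dwell-sampling noise
        expected = 2 * Z[centers[0]] / (Z[centers[1]] + Z[centers[2]])
        observed = 2 * occ[centers[0]] / (occ[centers[1]] + occ[centers[2]])
        assert observed == pytest.approx(expected, rel=0.25)

    def test_frame_count_invariant(self):
        integ = IntegratorSpec(dt=0.01, n_steps=105, save_stride=10, seed=0)
        traj = run_bd_toy(three_state_spec(), integ)
        assert traj.n_frames == 105 // 10 + 1


class TestPolymer:
    def test_straight_chain_at_rest_is_static(self):
        spec = PolymerSpec(n_beads=8, propulsion=0.0)
        r = straight_chain(spec)
        np.testing.assert_allclose(polymer_forces(spec, r), 0.0, atol=1e-9)
        integ = IntegratorSpec(dt=0.001, n_steps=200, save_stride=10,
                               gamma=200.0, kT=0.0, seed=0)
        traj = run_bd_polymer(spec, integ, init=r)
        np.testing.assert_allclose(
            traj.frames, np.broadcast_to(traj.frames[0], traj.frames.shape),
            atol=1e-12,
        )

    def test_conservative_forces_match_finite_differences(self):
        spec = PolymerSpec(n_beads=5)
        rng = np.random.default_rng(0)
        r = straight_chain(spec) + 0.05 * rng.standard_normal((5, 2))
        F = polymer_forces(spec, r, include_propulsion=False)
        h = 1e-6
        fd = np.zeros_like(r)
        for i in range(5):
            for d in range(2):
                rp, rm = r.copy(), r.copy()
                rp[i, d] += h
                rm[i, d] -= h
                fd[i, d] = -(
                    polymer_potential_energy(spec, rp)
                    - polymer_potential_energy(spec, rm)
                ) / (2 * h)
        np.testing.assert_allclose(F, fd, rtol=1e-5, atol=1e-4)

    def test_propulsion_split_equally_on_bond_beads(self):
        spec = PolymerSpec(n_beads=3, propulsion=4.0)
        r = straight_chain(spec)
        F = polymer_forces(spec, r) - polymer_forces(spec, r, include_propulsion=False)
        # ends get f_m/2 from one bond, the middle bead f_m/2 from each
        np.testing.assert_allclose(F[:, 0], [2.0, 4.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(F[:, 1], 0.0, atol=1e-12)

    def test_overlapping_init_rejected(self):
        spec = PolymerSpec(n_beads=3)
        bad = np.zeros((3, 2))
        with pytest.raises(PreconditionError):
            run_bd_polymer(spec, IntegratorSpec(dt=0.001, n_steps=10, gamma=200.0), init=bad)

    def test_active_chain_visits_spiral_and_extended_states(
        self, active_polymer_ensemble
    ):
        """The radius-of-gyration distribution over the ensemble covers both
        the compact spiral (small Rg) and the extended/bent state (large Rg),
        i.e. the time series is bimodal."""
        from kinseq.features import radius_of_gyration

        rg = np.concatenate(
            [radius_of_gyration(t) for t in active_polymer_ensemble]
        )
        assert (rg < 2.5).mean() > 0.05
        assert (rg > 3.5).mean() > 0.05
        # the intermediate region is depleted relative to the two modes
        assert ((rg > 2.8) & (rg < 3.4)).mean() < (rg < 2.5).mean()


class TestTrajectoryIO:
    @pytest.fixture()
    def small_traj(self):
        rng = np.random.default_rng(0)
        return Trajectory(rng.standard_normal((3, 4, 2)), dt_per_frame=0.1)

    @pytest.mark.parametrize("fmt", ["npy", "csv", "xyz"])
    def test_round_trip_identity(self, small_traj, fmt, tmp_path):
        path = tmp_path / f"t.{fmt}"
        write_trajectory(small_traj, path, format=fmt)
        back = read_trajectory(path, format=fmt, dt_per_frame=0.1)
        np.testing.assert_array_equal(back.frames, small_traj.frames)

    def test_csv_non_numeric_cell_errors_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,particle,x,y\n0,0,1.0,oops\n")
        with pytest.raises(ParseError, match="line 2"):
            read_trajectory(path)

    def test_xyz_frame_count_mismatch_errors(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("3\nframe 0\nX 0 0 0\nX 1 0 0\n")
        with pytest.raises(ParseError):
            read_trajectory(path)

    def test_unknown_format_rejected(self, small_traj, tmp_path):
        with pytest.raises(ConfigurationError):
            write_trajectory(small_traj, tmp_path / "t.weird", format="weird")
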