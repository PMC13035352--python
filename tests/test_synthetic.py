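import numpy as np
import pytest

from airdmd import (
    AerosolSpec,
    LinearFixture,
    WaveformConfig,
    advect_particles,
    default_field_spec,
    generate_flow_snapshots,
    make_linear_fixture,
    random_linear_fixture,
    sample_inlet_waveform,
    sample_particle_diameters,
    y_bifurcation_geometry,
)
from airdmd.errors import ConfigurationError


class TestWaveform:
    def test_quarter_period_hits_peak(self):
        cfg = WaveformConfig(vdot_max=50, T=2.4)
        assert sample_inlet_waveform(cfg, 0.6) == pytest.approx(50.0)

    @pytest.mark.parametrize("t", [0.0, 1.2])
    def test_zero_crossings(self, t):
        cfg = WaveformConfig(vdot_max=50, T=2.4)
        assert sample_inlet_waveform(cfg, t) == pytest.approx(0.0, abs=1e-12)

    def test_exhalation_is_negative(self):
        cfg = WaveformConfig(vdot_max=50, T=2.4)
        assert sample_inlet_waveform(cfg, 1.8) == pytest.approx(-50.0)

    def test_out_of_cycle_rejected(self):
        cfg = WaveformConfig()
        with pytest.raises(ConfigurationError):
            sample_inlet_waveform(cfg, 3.0)

    def test_overrunning_frame_count_rejected(self):
        with pytest.raises(ConfigurationError):
            WaveformConfig(n_frames=200)


class TestFlowSnapshots:
    def test_default_deck_spans_expected_time(self, field_spec):
        deck = generate_flow_snapshots(field_spec, 50.0, n_frames=144)
        assert deck.n_frames == 144
        assert deck.times[-1] == pytest.approx(143 * 0.015)  # 2.145 s

    def test_scaling_linearity(self, field_spec):
        d1 = generate_flow_snapshots(field_spec, 30.0)
        d2 = generate_flow_snapshots(field_spec, 60.0)
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_zero_field_at_sinusoid_zeros(self, geometry):
        # single fundamental mode: frames at t=0 and t=T/2 vanish
        spec = default_field_spec(geometry=geometry)
        spec.modes = [spec.modes[0]]
        deck = generate_flow_snapshots(spec, 50.0)
        norms = deck.frame_norms()
        assert norms[0] == pytest.approx(0.0, abs=1e-12)
        assert norms[80] == pytest.approx(0.0, abs=1e-12)  # t = 1.2 s

    def test_noiseless_decks_ignore_seed(self, field_spec):
        a = generate_flow_snapshots(field_spec, 50.0, seed=1)
        b = generate_flow_snapshots(field_spec, 50.0, seed=2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noisy_decks_deterministic_per_seed(self, geometry):
        spec = default_field_spec(geometry=geometry, noise_level=0.01)
        a = generate_flow_snapshots(spec, 50.0, seed=7)
        b = generate_flow_snapshots(spec, 50.0, seed=7)
        c = generate_flow_snapshots(spec, 50.0, seed=8)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_masks_copied_from_geometry(self, field_spec, geometry):
        deck = generate_flow_snapshots(field_spec, 50.0)
        np.testing.assert_array_equal(deck.masks["wall"], geometry.wall)


class TestDiameters:
    def test_degenerate_gsd_gives_constant(self):
        spec = AerosolSpec(mu=0.42, sigma_g=1.0, n_particles=50)
        np.testing.assert_array_equal(
            sample_particle_diameters(spec, seed=0), np.full(50, 0.42)
        )

    def test_sample_median_matches_spec(self):
        spec = AerosolSpec(mu=0.42, sigma_g=3.5, n_particles=100_000)
        d = sample_particle_diameters(spec, seed=123)
        assert np.median(d) == pytest.approx(0.42, rel=0.03)

    def test_reproducible(self):
        spec = AerosolSpec(n_particles=1)
        a = sample_particle_diameters(spec, seed=5)
        b = sample_particle_diameters(spec, seed=5)
        assert a == b

    def test_invalid_gsd_rejected(self):
        with pytest.raises(ConfigurationError):
            AerosolSpec(sigma_g=0.5)


class TestAdvection:
    def test_zero_velocity_keeps_particles_still(self, geometry):
        deck = generate_flow_snapshots(default_field_spec(geometry=geometry), 50.0)
        deck = deck.replace(values=np.zeros_like(deck.values))
        spec = AerosolSpec(n_particles=20)
        # capture radius 0 disables wall capture so nothing moves or deposits
        ens = advect_particles(deck, spec, geometry, seed=0, capture_radius=1e-12)
        first = ens.trajectories[:, :, :1]
        np.testing.assert_array_equal(
            ens.trajectories, np.repeat(first, deck.n_frames, axis=2)
        )
        assert not ens.deposited.any()

    def test_constant_axial_velocity_advances_linearly(self, geometry):
        deck = generate_flow_snapshots(default_field_spec(geometry=geometry), 50.0)
        c = 0.01  # m/s downward everywhere
        vals = np.zeros_like(deck.values)
        vals[2] = -c
        deck = deck.replace(values=vals)
        spec = AerosolSpec(n_particles=5)
        ens = advect_particles(deck, spec, geometry, seed=0, capture_radius=1e-12)
        k = 6
        drop = ens.trajectories[2, :, 0] - ens.trajectories[2, :, k]
        np.testing.assert_allclose(drop, c * k * deck.dt, rtol=1e-9)

    def test_immediate_capture_at_wall(self, geometry):
        deck = generate_flow_snapshots(default_field_spec(geometry=geometry), 50.0)
        spec = AerosolSpec(n_particles=30)
        # capture radius larger than the tube radius: inlet jitter lands
        # every particle within reach of a wall node at frame 0
        ens = advect_particles(deck, spec, geometry, seed=0, capture_radius=0.02)
        assert ens.deposited.all()
        assert (ens.deposition_frame == 0).all()
        first = ens.trajectories[:, :, :1]
        np.testing.assert_array_equal(
            ens.trajectories, np.repeat(first, deck.n_frames, axis=2)
        )

    def test_bookkeeping_partition(self, geometry, field_spec):
        from airdmd import drop_trailing_low_energy

        deck = drop_trailing_low_energy(generate_flow_snapshots(field_spec, 50.0))
        spec = AerosolSpec(n_particles=300)
        ens = advect_particles(deck, spec, geometry, seed=1, random_walk=0.006)
        n_dep = ens.deposited.sum()
        n_esc = ens.escaped.sum()
        assert n_dep + n_esc + np.sum(~ens.deposited & ~ens.escaped) == 300
        # deposited particles freeze at their deposition frame
        for j in np.flatnonzero(ens.deposited)[:10]:
            k = ens.deposition_frame[j]
            tail = ens.trajectories[:, j, k:]
            np.testing.assert_allclose(
                tail, np.repeat(tail[:, :1], tail.shape[1], axis=1), atol=1e-12
            )

    def test_empty_inlet_rejected(self, geometry, field_spec):
        import dataclasses

        deck = generate_flow_snapshots(field_spec, 50.0)
        bad = dataclasses.replace(geometry, inlet=np.zeros(geometry.n_nodes, bool))
        with pytest.raises(ConfigurationError):
            advect_particles(deck, AerosolSpec(n_particles=2), bad, seed=0)


class TestLinearFixture:
    def test_diagonal_powers(self):
        fix = LinearFixture(A=np.diag([0.9, 0.5]), x1=np.ones(2), n_snapshots=10)
        deck = make_linear_fixture(fix)
        flat = deck.values.reshape(-1, 10)
        for k in range(10):
            np.testing.assert_allclose(flat[0, k], 0.9**k, rtol=1e-12)
            np.testing.assert_allclose(flat[1, k], 0.5**k, rtol=1e-12)

    def test_identity_propagator(self):
        fix = LinearFixture(A=np.eye(3), x1=np.array([1.0, 2.0, 3.0]), n_snapshots=6)
        deck = make_linear_fixture(fix)
        flat = deck.values.reshape(-1, 6)
        np.testing.assert_array_equal(flat[:3], np.tile([[1], [2], [3]], 6))

    def test_scaled_rotation_norm_decay(self):
        phi = np.pi / 8
        A = 0.95 * np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        deck = make_linear_fixture(LinearFixture(A=A, x1=np.array([1.0, 0.0]), n_snapshots=12))
        norms = deck.frame_norms()
        np.testing.assert_allclose(norms[1:] / norms[:-1], 0.95, rtol=1e-12)

    def test_metadata_spectrum_matches_brute_force(self):
        fix = random_linear_fixture(7, seed=3)
        deck = make_linear_fixture(fix)
        got = np.sort_complex(deck.meta["spectrum"])
        want = np.sort_complex(np.linalg.eigvals(fix.A))
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_random_fixture_magnitudes_bounded(self):
        for seed in range(5):
            fix = random_linear_fixture(9, seed=seed)
            mags = np.abs(np.linalg.eigvals(fix.A))
            assert np.all(mags >= 0.85 - 1e-9)
            assert np.all(mags <= 1.0 + 1e-9)


class TestGeometry:
    def test_masks_disjoint_and_within_radius(self, geometry):
        assert not np.any(geometry.wall & geometry.inlet)
        assert not np.any(geometry.wall & geometry.outlet)
        assert not np.any(geometry.inlet & geometry.outlet)
        radii = np.linalg.norm(geometry.coords - geometry.p0, axis=1)
        assert radii.max() <= geometry.R * (1 + 1e-9)

    def test_has_all_regions(self, geometry):
        assert geometry.inlet.sum() > 0
        assert geometry.outlet.sum() > 0
        assert geometry.wall.sum() > 0
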