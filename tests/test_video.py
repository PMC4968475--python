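import numpy as np
import pytest

from spherewall.video import (
    VideoConfig,
    render_synthetic_video,
    rotation_from_area,
    track_particles,
    visible_area_fraction,
)


@pytest.fixture(scope="module")
def cfg():
    return VideoConfig()


class TestRenderer:
    def test_static_particle_frames_identical_up_to_noise(self, cfg):
        stack, _ = render_synthetic_video(cfg, u=0.0, omega=0.0, n_frames=6, seed=0)
        spread = stack.std(axis=0).max()
        assert spread < 4 * cfg.noise_sigma

    def test_area_signal_period_matches_rotation(self, cfg):
        """omega = 2 pi (25/12) gives an area period of exactly 12 frames."""
        quiet = VideoConfig(noise_sigma=0.0)
        omega = 2 * np.pi * quiet.frame_rate / 12.0
        stack, truths = render_synthetic_video(
            quiet, u=0.0, omega=omega, n_frames=37, seed=1,
            start_positions=[(100.0, 150.0)], phases=[0.0],
        )
        thr = 0.5 * (cfg.background + cfg.foreground)
        areas = (stack > thr).sum(axis=(1, 2))
        assert np.array_equal(areas[:12], areas[12:24])

    def test_area_follows_moon_phase_law(self, cfg):
        """One minimum and one maximum per revolution, with the peak
        matching the projected disc area."""
        omega = 2 * np.pi * cfg.frame_rate / 24.0
        stack, _ = render_synthetic_video(
            VideoConfig(noise_sigma=0.0), u=0.0, omega=omega, n_frames=24, seed=1,
            start_positions=[(100.0, 150.0)], phases=[0.0],
        )
        thr = 0.5 * (cfg.background + cfg.foreground)
        areas = (stack > thr).sum(axis=(1, 2)).astype(float)
        disc_px = np.pi * (5.0 / cfg.pixel_pitch) ** 2
        assert areas.max() == pytest.approx(disc_px, rel=0.1)
        frac = visible_area_fraction(omega * np.arange(24) / cfg.frame_rate)
        # single cycle: one max, one min, strong correlation with the law
        assert np.corrcoef(areas, frac * disc_px)[0, 1] > 0.99

    def test_nyquist_violation_refused(self, cfg):
        with pytest.raises(ValueError, match="Nyquist"):
            render_synthetic_video(cfg, u=0.0, omega=np.pi * cfg.frame_rate, n_frames=4)


class TestTracking:
    def test_small_particle_gated_out(self):
        cfg4 = VideoConfig(particle_diameter=4.0, noise_sigma=0.0)
        stack, _ = render_synthetic_video(
            cfg4, u=30.0, omega=0.0, n_frames=20, seed=2,
            start_positions=[(50.0, 150.0)], phases=[0.0],
        )
        assert track_particles(stack, cfg4) == []

    def test_two_separated_particles_two_tracks_no_swap(self):
        cfg = VideoConfig(noise_sigma=1.0)
        stack, truths = render_synthetic_video(
            cfg, u=30.0, omega=2.0, n_particles=2, n_frames=100, seed=3,
            start_positions=[(40.0, 80.0), (40.0, 240.0)], phases=[0.0, 0.0],
        )
        tracks = [t for t in track_particles(stack, cfg) if t.n_frames > 50]
        assert len(tracks) == 2
        for t in tracks:
            ys = np.asarray(t.centroids)[:, 1] * cfg.pixel_pitch
            assert np.ptp(ys) < 10.0  # no identity swap across lanes

    def test_empty_stack_no_tracks(self, cfg):
        stack = np.full((5, cfg.height, cfg.width), cfg.background, dtype=np.float32)
        assert track_particles(stack, cfg) == []


class TestRotationEstimate:
    def test_constant_area_flagged(self, cfg):
        """An unpainted (non-oscillating) sphere yields no estimate."""
        from spherewall.video import ParticleTrack

        tr = ParticleTrack(track_id=0)
        for f in range(100):
            tr.frames.append(f)
            tr.centroids.append((float(f), 0.0))
            tr.circle_centres.append((float(f), 0.0))
            tr.areas_px.append(46.0)
            tr.diameters_um.append(10.0)
        sig = rotation_from_area(tr, cfg)
        assert sig.flag == "no-estimate"
        assert sig.omega is None

    def test_short_track_flagged(self, cfg):
        from spherewall.video import ParticleTrack

        tr = ParticleTrack(track_id=0)
        for f in range(5):
            tr.frames.append(f)
            tr.areas_px.append(10.0 + 5 * f)
        assert rotation_from_area(tr, cfg).flag == "no-estimate"

    def test_doubling_omega_doubles_estimate(self, cfg):
        est = {}
        for om in (5.0, 10.0):
            stack, _ = render_synthetic_video(cfg, u=30.0, omega=om,
                                              n_frames=400, seed=4)
            tr = max(track_particles(stack, cfg), key=lambda t: t.n_frames)
            est[om] = rotation_from_area(tr, cfg).omega
        assert est[10.0] == pytest.approx(2 * est[5.0], rel=0.05)

    def test_estimate_invariant_to_intensity_and_translation(self, cfg):
        """Scaling the intensity or changing u leaves omega unchanged
        (the two measurements decouple)."""
        stack, _ = render_synthetic_video(cfg, u=30.0, omega=5.0, n_frames=400, seed=5)
        tr = max(track_particles(stack, cfg), key=lambda t: t.n_frames)
        om_ref = rotation_from_area(tr, cfg).omega
        # intensity scaling: threshold passed explicitly
        tr2 = max(track_particles(2.0 * stack, cfg,
                                  threshold=(cfg.background + cfg.foreground)),
                  key=lambda t: t.n_frames)
        om_scaled = rotation_from_area(tr2, cfg).omega
        assert om_scaled == pytest.approx(om_ref, rel=0.02)
        stack3, _ = render_synthetic_video(cfg, u=45.0, omega=5.0, n_frames=400, seed=5)
        tr3 = max(track_particles(stack3, cfg), key=lambda t: t.n_frames)
        om_moved = rotation_from_area(tr3, cfg).omega
        assert om_moved == pytest.approx(om_ref, rel=0.03)
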