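"""Simulator correctness: speckle rendering, warping, sequences, phantom."""

from __future__ import annotations

import numpy as np
import pytest

from cardiomotion.synthrf import (
    GroundTruth,
    Region,
    ScattererScene,
    TransmuralGradientMotion,
    UniformMotion,
    elliptical_transmural_coord,
    generate_sequence,
    make_lv_phantom,
    make_scatterer_field,
    render_rf_frame,
    warp_scene,
)


class TestScattererField:
    def test_reproducible_and_contained(self):
        region = Region(0.0, 10.0, -5.0, 5.0)
        scene1 = make_scatterer_field(region, 20.0, seed=7)
        scene2 = make_scatterer_field(region, 20.0, seed=7)
        assert scene1.n_scatterers == 2000
        assert np.array_equal(scene1.positions, scene2.positions)
        assert np.array_equal(scene1.amplitudes, scene2.amplitudes)
        assert region.contains(scene1.positions).all()

    def test_different_seed_differs(self):
        region = Region(0.0, 5.0, 0.0, 5.0)
        a = make_scatterer_field(region, 10.0, seed=1)
        b = make_scatterer_field(region, 10.0, seed=2)
        assert not np.array_equal(a.positions, b.positions)

    @pytest.mark.parametrize("density", [0.0, -3.0])
    def test_invalid_density(self, density):
        with pytest.raises(ValueError):
            make_scatterer_field(Region(0, 1, 0, 1), density)


class TestRender:
    def test_single_scatterer_equals_psf_kernel(self, psf):
        region = Region(0.0, 2.0, -1.0, 1.0)
        ds = psf.sample_spacing_mm
        # place the scatterer exactly on a grid node
        z_s = region.axial_min + 100 * ds
        x_s = region.lateral_min + 10 * psf.pitch
        scene = ScattererScene(positions=[(z_s, x_s)], amplitudes=[1.0], region=region)
        frame = render_rf_frame(scene, psf)
        z = frame.axial_positions_mm - z_s
        x = frame.lateral_positions_mm - x_s
        k = 4.0 * np.pi * psf.center_frequency / (psf.sound_speed * 1e3)
        sz, sx = psf.axial_sigma_mm, psf.lateral_beam_sigma
        expected = np.outer(
            np.exp(-0.5 * (z / sz) ** 2) * np.cos(k * z), np.exp(-0.5 * (x / sx) ** 2)
        )
        expected[np.abs(z) > 4.5 * sz, :] = 0.0
        expected[:, np.abs(x) > 4.5 * sx] = 0.0
        assert np.allclose(frame.samples, expected, atol=1e-12)

    def test_linearity_and_homogeneity(self, psf):
        region = Region(0.0, 3.0, -1.5, 1.5)
        rng = np.random.default_rng(0)
        pos = np.column_stack(
            [rng.uniform(0.5, 2.5, 20), rng.uniform(-1.0, 1.0, 20)]
        )
        amp = rng.normal(size=20)
        both = ScattererScene(pos, amp, region)
        first = ScattererScene(pos[:10], amp[:10], region)
        second = ScattererScene(pos[10:], amp[10:], region)
        f_both = render_rf_frame(both, psf).samples
        f_sum = render_rf_frame(first, psf).samples + render_rf_frame(second, psf).samples
        assert np.allclose(f_both, f_sum, atol=1e-12)
        doubled = ScattererScene(pos, 2.0 * amp, region)
        assert np.allclose(render_rf_frame(doubled, psf).samples, 2.0 * f_both, atol=1e-12)

    def test_shift_theorem_integer_samples(self, psf, speckle_frame):
        """Rendering a scene shifted by k samples equals shifting the frame."""
        region = Region(0.0, 6.0, -3.0, 3.0)
        scene = make_scatterer_field(region, 350.0, seed=11)
        k = 5
        shift_mm = k * psf.sample_spacing_mm
        shifted = warp_scene(
            scene, lambda p: np.column_stack([np.full(len(p), shift_mm), np.zeros(len(p))])
        )
        f_shifted = render_rf_frame(shifted, psf).samples
        rolled = np.roll(speckle_frame.samples, k, axis=0)
        tol = 1e-6 * np.abs(speckle_frame.samples).max()
        # compare away from the wrap-around edge
        assert np.allclose(f_shifted[k + 30 :], rolled[k + 30 :], atol=tol)


class TestWarp:
    def test_uniform_shift_and_roundtrip(self):
        region = Region(0.0, 10.0, -5.0, 5.0)
        scene = make_scatterer_field(region, 5.0, seed=3)
        shift = lambda p: np.tile([0.3, 0.0], (len(p), 1))
        unshift = lambda p: np.tile([-0.3, 0.0], (len(p), 1))
        moved = warp_scene(scene, shift)
        assert np.allclose(moved.positions[:, 0], scene.positions[:, 0] + 0.3)
        assert np.array_equal(moved.amplitudes, scene.amplitudes)
        back = warp_scene(moved, unshift)
        assert np.allclose(back.positions, scene.positions, atol=1e-15)

    def test_linear_field_pointwise(self):
        region = Region(0.0, 4.0, -1.0, 1.0)
        scene = ScattererScene([(2.0, 0.0), (1.0, 0.5)], [1.0, 1.0], region)
        a = 0.1
        moved = warp_scene(scene, lambda p: np.column_stack([a * p[:, 0], np.zeros(len(p))]))
        assert np.isclose(moved.positions[0, 0], 2.0 + 0.2)
        assert np.isclose(moved.positions[1, 0], 1.0 + 0.1)


class TestSequences:
    def test_uniform_cumulative_arithmetic(self, psf):
        filled = make_scatterer_field(Region(0.0, 4.0, -2.0, 2.0), 50.0, seed=2)
        # pad the region so the imposed motion cannot carry scatterers out
        scene = ScattererScene(filled.positions, filled.amplitudes, Region(0.0, 4.5, -2.0, 2.0))
        ds = psf.sample_spacing_mm
        motion = UniformMotion(2 * ds, 0.0, n_frames=5)
        frames, truth = generate_sequence(scene, psf, motion)
        assert len(frames) == 5
        pts = np.array([[2.0, 0.0], [1.0, -1.0]])
        cum = truth.cumulative(4, pts)
        assert np.allclose(cum[:, 0], 8 * ds)
        assert np.allclose(cum[:, 1], 0.0)

    def test_zero_motion_identical_frames(self, psf):
        region = Region(0.0, 3.0, -1.0, 1.0)
        scene = make_scatterer_field(region, 50.0, seed=4)
        frames, _ = generate_sequence(scene, psf, UniformMotion(0.0, 0.0, n_frames=2))
        assert np.array_equal(frames[0].samples, frames[1].samples)

    def test_incrementals_sum_to_cumulative(self):
        coord = elliptical_transmural_coord((1.0, 0.0), (4.0, 6.0), (6.0, 8.0))
        motion = TransmuralGradientMotion(coord, 0.01, 0.05, n_frames=6)
        truth = GroundTruth(motion)
        rng = np.random.default_rng(8)
        pts = np.column_stack([rng.uniform(1, 9, 50), rng.uniform(-6, 6, 50)])
        total = np.zeros((50, 2))
        for k in range(5):
            total += truth.incremental(k, pts)
        assert np.allclose(total, truth.cumulative(5, pts), atol=1e-15)

    def test_motion_exceeding_region_rejected(self, psf):
        region = Region(0.0, 2.0, -1.0, 1.0)
        scene = make_scatterer_field(region, 30.0, seed=1)
        with pytest.raises(ValueError, match="outside the scene region"):
            generate_sequence(scene, psf, UniformMotion(1.5, 0.0, n_frames=3))

    def test_transmural_truth_at_borders(self):
        """The analytic field differs endo vs epi by the imposed gradient."""
        center, inner, outer = (1.0, 0.0), (4.0, 6.0), (6.0, 8.0)
        coord = elliptical_transmural_coord(center, inner, outer)
        epi_rate, endo_rate = 0.01, 0.05
        motion = TransmuralGradientMotion(coord, epi_rate, endo_rate, n_frames=4)
        truth = GroundTruth(motion)
        endo_apex = np.array([[1.0 + 6.0, 0.0]])  # on the inner ellipse
        epi_apex = np.array([[1.0 + 8.0, 0.0]])  # on the outer ellipse
        cum_endo = truth.cumulative(3, endo_apex)[0, 0]
        cum_epi = truth.cumulative(3, epi_apex)[0, 0]
        assert np.isclose(cum_endo, 3 * endo_rate, atol=1e-9)
        assert np.isclose(cum_epi, 3 * epi_rate, atol=1e-9)
        assert np.isclose(cum_endo - cum_epi, 3 * (endo_rate - epi_rate), atol=1e-9)


class TestPhantom:
    def test_geometry_and_area(self):
        density = 350.0
        endo_kp, epi_kp, scene = make_lv_phantom(
            (4.0, 6.0), (6.0, 8.0), center=(1.0, 0.0), density_per_mm2=density, seed=5
        )
        # endo key points strictly inside the epi half-ellipse
        dz = endo_kp[:, 0] - 1.0
        dx = endo_kp[:, 1] - 0.0
        level = (dx / 6.0) ** 2 + (dz / 8.0) ** 2
        interior = slice(1, -1)  # basal endpoints sit on the open base line
        assert np.all(level[interior] < 1.0)
        # first and last key points of each border lie on the basal line
        for kp in (endo_kp, epi_kp):
            assert np.isclose(kp[0, 0], 1.0) and np.isclose(kp[-1, 0], 1.0)
        # scatterer count matches the analytic half-annulus area within 2 %
        analytic = 0.5 * np.pi * (6.0 * 8.0 - 4.0 * 6.0)
        assert scene.n_scatterers / density == pytest.approx(analytic, rel=0.02)

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            make_lv_phantom((6.0, 8.0), (4.0, 6.0))
        with pytest.raises(ValueError):
            make_lv_phantom((4.0, 6.0), (4.0, 8.0))

    def test_transmural_coord_on_borders(self):
        coord = elliptical_transmural_coord((0.0, 0.0), (10.0, 10.0), (16.0, 16.0))
        theta = np.linspace(0.1, np.pi - 0.1, 9)
        inner = np.column_stack([10 * np.sin(theta), 10 * np.cos(theta)])
        outer = np.column_stack([16 * np.sin(theta), 16 * np.cos(theta)])
        mid = np.column_stack([13 * np.sin(theta), 13 * np.cos(theta)])
        assert np.allclose(coord(inner), 1.0, atol=1e-9)
        assert np.allclose(coord(outer), 0.0, atol=1e-9)
        assert np.allclose(coord(mid), 0.5, atol=1e-9)
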