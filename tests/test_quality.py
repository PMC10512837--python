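"""SNR, displacement compensation, DCCCC and overlap selection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomotion.frames import RFFrame
from cardiomotion.quality import (
    QualityRecord,
    compensate_frame,
    dcccc,
    overlap_sweep,
    select_optimal_overlap,
    snr,
)
from cardiomotion.synthrf import (
    MotionModel,
    Region,
    ScattererScene,
    UniformMotion,
    generate_sequence,
    make_scatterer_field,
)
from cardiomotion.tracking import TrackingConfig

META = dict(center_frequency=21e6, sampling_frequency=84e6, pitch=0.09)


def frame_of(values: np.ndarray) -> RFFrame:
    return RFFrame(samples=np.asarray(values, dtype=float), **META)


class TestSnr:
    def test_hand_computed_examples(self):
        values = np.zeros((2, 3))
        values[0] = [1.0, 2.0, 3.0]
        mask = np.zeros((2, 3), dtype=bool)
        mask[0] = True
        # mean 2, sample sd 1
        assert snr(values, mask) == pytest.approx(2.0)
        values[0] = [5.0, 5.0, 5.0]
        assert snr(values, mask) == np.inf
        mask2 = np.zeros((2, 3), dtype=bool)
        mask2[0, :2] = True
        values[0, :2] = [-1.0, 1.0]
        assert snr(values, mask2) == pytest.approx(0.0)

    def test_single_pixel_roi_rejected(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            snr(np.ones((2, 2)), mask)

    def test_positive_scaling_invariance_and_signed_mean(self):
        rng = np.random.default_rng(0)
        values = rng.normal(1.0, 0.3, size=(8, 8))
        mask = np.ones((8, 8), dtype=bool)
        base = snr(values, mask)
        assert snr(3.0 * values, mask) == pytest.approx(base)
        # the signed mean flips the sign under negation (no absolute value)
        assert snr(-values, mask) == pytest.approx(-base)


class TestCompensate:
    def test_zero_displacement_is_identity(self):
        rng = np.random.default_rng(1)
        f = frame_of(rng.normal(size=(20, 10)))
        zero = np.zeros((20, 10))
        comp, valid = compensate_frame(f, zero, zero)
        assert np.array_equal(comp.samples, f.samples)
        assert valid.all()

    def test_integer_shift_exact_on_interior(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(size=(30, 12))
        post = np.roll(pre, 3, axis=0)
        f_post = frame_of(post)
        d = np.full((30, 12), 3.0)
        comp, valid = compensate_frame(f_post, d, np.zeros_like(d))
        assert np.array_equal(comp.samples[valid], frame_of(pre).samples[valid])
        assert not valid[-3:].any()  # lookups past the bottom edge

    def test_halfsample_shift_exact_for_linear_ramp(self):
        # columns linear in depth: bilinear interpolation is exact
        z = np.arange(40, dtype=float)[:, None]
        f_post = frame_of(np.tile(2.0 * z + 1.0, (1, 6)))
        d = np.full((40, 6), 0.5)
        comp, valid = compensate_frame(f_post, d, np.zeros_like(d))
        expected = 2.0 * (z + 0.5) + 1.0
        assert np.allclose(comp.samples[valid], np.tile(expected, (1, 6))[valid], atol=1e-12)

    def test_shape_mismatch_rejected(self):
        f = frame_of(np.zeros((10, 5)))
        with pytest.raises(ValueError):
            compensate_frame(f, np.zeros((9, 5)), np.zeros((10, 5)))


class TestDcccc:
    def test_perfect_compensation_gives_one(self):
        rng = np.random.default_rng(3)
        f = frame_of(rng.normal(size=(16, 8)))
        mask = np.ones((16, 8), dtype=bool)
        assert dcccc(f, f, mask) == pytest.approx(1.0)

    def test_anticorrelation_gives_minus_one(self):
        rng = np.random.default_rng(4)
        samples = rng.normal(size=(16, 8))
        samples -= samples.mean()
        f = frame_of(samples)
        g = frame_of(-samples)
        mask = np.ones((16, 8), dtype=bool)
        assert dcccc(f, g, mask) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        f = frame_of(np.ones((8, 8)))
        g = frame_of(np.arange(64, dtype=float).reshape(8, 8))
        with pytest.raises(ValueError, match="zero variance"):
            dcccc(f, g, np.ones((8, 8), dtype=bool))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        a = frame_of(rng.normal(size=(10, 6)))
        b = frame_of(rng.normal(size=(10, 6)))
        mask = rng.random((10, 6)) < 0.7
        if mask.sum() < 3:
            mask[:2, :2] = True
        value = dcccc(a, b, mask)
        assert -1.0 <= value <= 1.0

    def test_truth_beats_zero_compensation(self, psf):
        """Compensating with the true field raises DCCCC above no compensation."""
        filled = make_scatterer_field(Region(0.0, 4.0, -1.5, 1.5), 350.0, seed=21)
        scene = ScattererScene(filled.positions, filled.amplitudes, Region(0.0, 4.2, -1.5, 1.5))
        ds = psf.sample_spacing_mm
        frames, truth = generate_sequence(scene, psf, UniformMotion(2.3 * ds, 0.0, 2))
        f_pre, f_post = frames
        truth_axial, truth_lateral = truth.dense_incremental(0, f_pre)
        mask = np.zeros(f_pre.shape, dtype=bool)
        mask[40:-40, 4:-4] = True
        comp, valid = compensate_frame(f_post, truth_axial / ds, truth_lateral / f_pre.pitch)
        with_truth = dcccc(f_pre, comp, mask, valid)
        without = dcccc(f_pre, f_post, mask)
        assert with_truth > without

    def test_noisy_field_degrades_dcccc(self, psf):
        """The monotone-quality property on a handful of seeded simulations."""
        ds = psf.sample_spacing_mm
        wins = 0
        n_runs = 5
        for seed in range(n_runs):
            filled = make_scatterer_field(Region(0.0, 4.0, -1.5, 1.5), 350.0, seed=100 + seed)
            scene = ScattererScene(filled.positions, filled.amplitudes, Region(0.0, 4.2, -1.5, 1.5))
            rng = np.random.default_rng(seed)
            shift = rng.uniform(1.0, 3.0)
            frames, truth = generate_sequence(scene, psf, UniformMotion(shift * ds, 0.0, 2))
            f_pre, f_post = frames
            ta, tl = truth.dense_incremental(0, f_pre)
            mask = np.zeros(f_pre.shape, dtype=bool)
            mask[40:-40, 4:-4] = True
            comp, valid = compensate_frame(f_post, ta / ds, tl / f_pre.pitch)
            clean = dcccc(f_pre, comp, mask, valid)
            noise = rng.normal(0.0, 0.5, size=f_pre.shape)
            comp_n, valid_n = compensate_frame(f_post, ta / ds + noise, tl / f_pre.pitch)
            noisy = dcccc(f_pre, comp_n, mask, valid_n)
            wins += clean > noisy
        assert wins == n_runs


def record(overlap: float, value: float) -> QualityRecord:
    return QualityRecord(
        overlap_percent=overlap,
        snr=1.0,
        dcccc=value,
        roi_mean_displacement=0.0,
        roi_sd_displacement=0.0,
        roi_mean_pre=0.0,
        roi_mean_comp=0.0,
    )


class TestSelectOptimalOverlap:
    def test_plateau_with_spike_filtered_out(self):
        curve = {30.0: 0.80, 50.0: 0.90, 80.0: 0.92, 90.0: 0.99, 99.9: 0.92}
        records = [record(o, v) for o, v in curve.items()]
        assert select_optimal_overlap(records) == 80.0

    def test_constant_curve_returns_smallest(self):
        records = [record(o, 0.9) for o in (10.0, 30.0, 50.0, 80.0)]
        assert select_optimal_overlap(records) == 10.0

    def test_steep_increase_returns_largest(self):
        records = [record(o, v) for o, v in zip((10.0, 30.0, 50.0, 80.0), (0.2, 0.4, 0.6, 0.9))]
        assert select_optimal_overlap(records) == 80.0

    def test_permutation_invariant_and_deterministic(self):
        curve = {30.0: 0.80, 50.0: 0.90, 80.0: 0.92, 90.0: 0.99, 99.9: 0.92}
        records = [record(o, v) for o, v in curve.items()]
        shuffled = [records[i] for i in (3, 0, 4, 1, 2)]
        assert select_optimal_overlap(shuffled) == select_optimal_overlap(records) == 80.0

    def test_all_flagged_rejected(self):
        bad = record(50.0, float("nan"))
        bad.flagged = True
        with pytest.raises(ValueError):
            select_optimal_overlap([bad])


class TestOverlapSweep:
    def test_identical_frames_give_unit_dcccc(self, speckle_frame):
        mask = np.zeros(speckle_frame.shape, dtype=bool)
        mask[60:-60, 8:-8] = True
        overlaps = (30.0, 60.0, 90.0)
        # integer-lag matching finds the exact zero field on identical frames
        cfg = TrackingConfig(subsample_refinement=False)
        report = overlap_sweep(speckle_frame, speckle_frame, overlaps, mask, cfg)
        assert len(report.records) == len(overlaps)
        assert [r.overlap_percent for r in report.records] == sorted(overlaps)
        for r in report.records:
            assert r.dcccc == pytest.approx(1.0)
        assert report.selected_overlap in overlaps

    def test_finer_grid_resolves_shear(self, psf):
        """On a spatially varying pair, DCCCC at 80 % overlap >= at 30 %.

        The displacement varies sinusoidally with depth (period 1 mm), so
        the coarse 30 %-overlap node grid under-resolves it while the
        80 % grid does not; a linear-in-depth field would be interpolated
        exactly from any grid and show no difference.
        """

        class SineAxialMotion(MotionModel):
            kind = "sine"

            def __init__(self, amplitude_mm, period_mm, n_frames):
                super().__init__(n_frames)
                self.amplitude_mm, self.period_mm = amplitude_mm, period_mm

            def incremental(self, k, points):
                self._check_pair(k)
                p = np.atleast_2d(points)
                out = np.zeros_like(p, dtype=float)
                out[:, 0] = self.amplitude_mm * np.sin(2 * np.pi * p[:, 0] / self.period_mm)
                return out

        filled = make_scatterer_field(Region(0.0, 5.0, -1.5, 1.5), 350.0, seed=34)
        scene = ScattererScene(filled.positions, filled.amplitudes, Region(-0.1, 5.3, -1.5, 1.5))
        motion = SineAxialMotion(1.5 * psf.sample_spacing_mm, 1.0, 2)
        frames, _ = generate_sequence(scene, psf, motion)
        mask = np.zeros(frames[0].shape, dtype=bool)
        mask[40:-40, 4:-4] = True
        report = overlap_sweep(frames[0], frames[1], (30.0, 80.0), mask)
        d30, d80 = (r.dcccc for r in report.records)
        assert d80 >= d30
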