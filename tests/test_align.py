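"""Temporal trimming, downsampling, validity masking and spatial alignment."""

import dataclasses

import numpy as np
import pytest

from gesturecap import (
    AlignmentError,
    DegenerateFitError,
    EmptySequenceError,
    RigidTransform,
    ScaleEstimationError,
    SessionMeta,
    Stream3D,
    TARGET_NAMES,
    ValidityConfig,
    apply_alignment,
    build_validity_mask,
    downsample_uniform,
    estimate_scale,
    fit_alignment,
    trim_to_claps,
)
from gesturecap.align import resample_interpolated
from gesturecap.analysis import prepare_sequence, fit_participant_alignment
from gesturecap.simulate import (
    I_ELB_R,
    I_SHO_R,
    MONO_METHODS,
    SimulationConfig,
    build_cameras,
    generate_bundle,
)


def _stream3d(n, rng=None, frame_rate=30.0, conf=None, missing=None, frame="mocap"):
    rng = rng or np.random.default_rng(0)
    xyz = rng.normal(0, 300, (n, 13, 3))
    if missing is None:
        missing = np.zeros((n, 13), dtype=bool)
    xyz = xyz.copy()
    xyz[missing] = np.nan
    return Stream3D(frame_rate, frame, xyz, conf, missing, TARGET_NAMES)


class TestTrimToClaps:
    def test_exclusive_clap_convention_frame_count(self):
        # 70 s @ 30 fps: frames 0..2100, claps at 0 and 2100.
        # Content strictly between claps: 2099 frames; minus 150-frame
        # margins on both ends: 1799 frames.
        stream = _stream3d(2101)
        meta = SessionMeta("P01", 1, 0, 2100)
        out = trim_to_claps(stream, meta)
        assert out.n_frames == 2099 - 2 * 150
        np.testing.assert_array_equal(out.xyz[0], stream.xyz[151])

    def test_zero_margin_keeps_clap_to_clap_content(self):
        stream = _stream3d(2101)
        meta = SessionMeta("P01", 1, 0, 2100, margin_s=0.0)
        out = trim_to_claps(stream, meta)
        assert out.n_frames == 2099
        np.testing.assert_array_equal(out.xyz[0], stream.xyz[1])
        np.testing.assert_array_equal(out.xyz[-1], stream.xyz[2099])

    def test_mocap_rate_trimmed_at_matching_times(self):
        stream = _stream3d(7001, frame_rate=100.0)
        meta = SessionMeta("P01", 1, 0, 2100)  # video-frame indices
        out = trim_to_claps(stream, meta)
        # first retained mocap sample: ceil(1 * 100/30) = 4; plus 500 margin
        np.testing.assert_array_equal(out.xyz[0], stream.xyz[504])

    def test_margin_exhausting_sequence_raises(self):
        stream = _stream3d(400)
        meta = SessionMeta("P01", 1, 0, 399, margin_s=5.0)
        meta.margin_s = 7.0  # bypass construction-time invariant
        with pytest.raises(EmptySequenceError):
            trim_to_claps(stream, meta)

    def test_claps_outside_bounds_raise(self):
        stream = _stream3d(100)
        meta = SessionMeta("P01", 1, 0, 2100)
        with pytest.raises(AlignmentError):
            trim_to_claps(stream, meta)

    def test_synthetic_bundle_trims_to_generated_content(self, tiny_bundle,
                                                         tiny_config):
        out = trim_to_claps(tiny_bundle.cam_streams[0], tiny_bundle.meta)
        expected = tiny_config.n_content_frames - 2 * int(
            round(tiny_config.margin_s * tiny_config.video_fps)
        )
        assert out.n_frames == expected


class TestDownsample:
    def test_endpoints_preserved(self):
        stream = _stream3d(1000)
        out = downsample_uniform(stream, 300)
        assert out.n_frames == 300
        np.testing.assert_array_equal(out.xyz[0], stream.xyz[0])
        np.testing.assert_array_equal(out.xyz[-1], stream.xyz[-1])

    def test_identity_when_counts_match(self):
        stream = _stream3d(50)
        out = downsample_uniform(stream, 50)
        np.testing.assert_array_equal(out.xyz, stream.xyz)

    def test_index_formula_7_to_3(self):
        stream = _stream3d(7)
        out = downsample_uniform(stream, 3)
        for i, src in enumerate((0, 3, 6)):
            np.testing.assert_array_equal(out.xyz[i], stream.xyz[src])

    def test_upsampling_rejected(self):
        with pytest.raises(AlignmentError):
            downsample_uniform(_stream3d(5), 10)

    def test_missing_flags_carried_through(self):
        missing = np.zeros((10, 13), dtype=bool)
        missing[9, 2] = True
        stream = _stream3d(10, missing=missing)
        out = downsample_uniform(stream, 4)
        assert out.missing[3, 2]

    def test_interpolated_variant_matches_linear_blend(self):
        stream = _stream3d(7)
        out = resample_interpolated(stream, 4)
        np.testing.assert_allclose(out.xyz[0], stream.xyz[0])
        np.testing.assert_allclose(out.xyz[-1], stream.xyz[-1])
        np.testing.assert_allclose(out.xyz[1], stream.xyz[2])  # pos = 2.0


class TestValidityMask:
    def _setup(self, conf_value):
        mocap = _stream3d(5)
        conf = np.full((5, 13), conf_value)
        method = _stream3d(5, conf=conf, frame="camera1")
        return mocap, method

    def test_confidence_exactly_at_threshold_is_valid(self):
        mocap, method = self._setup(0.3)
        mask = build_validity_mask(mocap, [method], ValidityConfig(0.3))
        assert mask.valid.all()

    def test_confidence_below_threshold_invalid(self):
        mocap, method = self._setup(0.29999)
        mask = build_validity_mask(mocap, [method], ValidityConfig(0.3))
        assert not mask.valid.any()

    def test_reference_gap_invalidates_regardless_of_confidence(self):
        mocap_missing = np.zeros((5, 13), dtype=bool)
        mocap_missing[2, 4] = True
        mocap = _stream3d(5, missing=mocap_missing)
        conf = np.ones((5, 13))
        method = _stream3d(5, conf=conf, frame="camera1")
        mask = build_validity_mask(mocap, [method])
        assert not mask.valid[2, 4]
        assert mask.valid.sum() == 5 * 13 - 1

    def test_frame_count_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            build_validity_mask(
                _stream3d(5), [_stream3d(6, conf=np.ones((6, 13)))]
            )


class TestEstimateScale:
    def test_ratio_of_tape_to_estimated_length(self):
        xyz = np.zeros((4, 13, 3))
        xyz[:, I_SHO_R] = [0.0, 0.0, 0.0]
        xyz[:, I_ELB_R] = [0.0, -300.0, 0.0]
        stream = Stream3D(30.0, "mono_raw", xyz, None,
                          np.zeros((4, 13), dtype=bool), TARGET_NAMES)
        mask = np.ones((4, 13), dtype=bool)
        assert estimate_scale(stream, mask, 330.0) == pytest.approx(1.1)

    def test_hidden_premultiplied_scale_cancels_exactly(self):
        rng = np.random.default_rng(6)
        stream = _stream3d(20, rng)
        k = 1.37
        scaled = Stream3D(
            30.0, "mono_raw", stream.xyz * k, None, stream.missing, TARGET_NAMES
        )
        mask = np.ones((20, 13), dtype=bool)
        s_ref = estimate_scale(stream, mask, 300.0)
        s_scaled = estimate_scale(scaled, mask, 300.0)
        assert s_scaled * k == pytest.approx(s_ref, rel=1e-12)

    def test_no_valid_pair_raises(self):
        stream = _stream3d(5)
        mask = np.zeros((5, 13), dtype=bool)
        mask[:, I_SHO_R] = True  # elbow never valid
        with pytest.raises(ScaleEstimationError):
            estimate_scale(stream, mask, 300.0)


def _rot_z90():
    return np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


class TestFitAlignment:
    def test_identical_streams_give_identity(self):
        stream = _stream3d(10)
        mask = np.ones((10, 13), dtype=bool)
        params = fit_alignment(stream, stream, mask, 1.0)
        np.testing.assert_allclose(params.transform.R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(params.transform.t, 0.0, atol=1e-6)

    def test_recovers_known_transform(self):
        method = _stream3d(10)
        R0, t0 = _rot_z90(), np.array([10.0, 20.0, 30.0])
        mocap = Stream3D(
            30.0, "mocap", method.xyz @ R0.T + t0, None, method.missing,
            TARGET_NAMES,
        )
        mask = np.ones((10, 13), dtype=bool)
        params = fit_alignment(method, mocap, mask, 1.0)
        np.testing.assert_allclose(params.transform.R, R0, atol=1e-9)
        np.testing.assert_allclose(params.transform.t, t0, atol=1e-9)

    def test_alignment_reduces_error_on_noisy_data(self):
        rng = np.random.default_rng(9)
        method = _stream3d(50, rng)
        R0, t0 = _rot_z90(), np.array([100.0, -50.0, 20.0])
        mocap_xyz = method.xyz @ R0.T + t0 + rng.normal(0, 5, method.xyz.shape)
        mocap = Stream3D(30.0, "mocap", mocap_xyz, None, method.missing,
                         TARGET_NAMES)
        mask = np.ones((50, 13), dtype=bool)
        params = fit_alignment(method, mocap, mask, 1.0)
        aligned = apply_alignment(method, params)
        err_aligned = np.linalg.norm(aligned.xyz - mocap.xyz, axis=2).mean()
        err_raw = np.linalg.norm(method.xyz - mocap.xyz, axis=2).mean()
        assert err_aligned < err_raw

    def test_masked_out_entries_cannot_influence_the_fit(self):
        rng = np.random.default_rng(10)
        method = _stream3d(30, rng)
        mocap = _stream3d(30, np.random.default_rng(11))
        mask = rng.random((30, 13)) < 0.6
        a = fit_alignment(method, mocap, mask, 1.0)
        corrupted = Stream3D(
            30.0, method.coordinate_frame,
            np.where(mask[..., None], method.xyz, 1e9),
            None, method.missing, TARGET_NAMES,
        )
        b = fit_alignment(corrupted, mocap, mask, 1.0)
        np.testing.assert_array_equal(a.transform.R, b.transform.R)
        np.testing.assert_array_equal(a.transform.t, b.transform.t)

    def test_insufficient_correspondences_raise(self):
        stream = _stream3d(2)
        mask = np.zeros((2, 13), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(DegenerateFitError):
            fit_alignment(stream, stream, mask, 1.0)


class TestApplyAlignment:
    def test_identity_params_leave_stream_unchanged(self):
        from gesturecap.align import AlignmentParams

        stream = _stream3d(5)
        params = AlignmentParams("P01", "m", RigidTransform.identity())
        out = apply_alignment(stream, params)
        np.testing.assert_array_equal(out.xyz, stream.xyz)
        assert out.coordinate_frame == "aligned"

    def test_apply_then_inverse_restores(self):
        from gesturecap.align import AlignmentParams

        rng = np.random.default_rng(3)
        stream = _stream3d(5, rng)
        tf = RigidTransform(_rot_z90(), np.array([5.0, 6.0, 7.0]), 1.2)
        fwd = AlignmentParams("P01", "m", tf)
        back = AlignmentParams("P01", "m", tf.inverse())
        out = apply_alignment(apply_alignment(stream, fwd), back)
        np.testing.assert_allclose(out.xyz, stream.xyz, atol=1e-9)

    def test_params_json_round_trip(self):
        from gesturecap.align import AlignmentParams

        tf = RigidTransform(_rot_z90(), np.array([1.0, 2.0, 3.0]), 0.9)
        params = AlignmentParams("P03", "mono_a", tf)
        back = AlignmentParams.from_json(params.to_json())
        np.testing.assert_array_equal(back.transform.R, tf.R)
        assert back.transform.s == tf.s


class TestEndToEndRecovery:
    def test_noiseless_bundle_recovers_scale_rotation_translation(self):
        """With all noise off, alignment recovers the hidden mono scale
        within 1%, and stereo alignment matches the hidden scene pose to
        0.1 deg / 1 mm."""
        cfg = SimulationConfig(
            n_participants=1, n_sequences=2, duration_s=12.0, margin_s=1.0,
            pixel_noise_sd=0.0, dropout_prob=0.0, marker_offset_mm=0.0,
            mocap_dropout_hazard=0.0, mono_depth_noise_mm=0.0,
            mono_lateral_noise_mm=0.0, seed=21,
        )
        cameras, scene_to_world = build_cameras(cfg)
        seqs = [
            prepare_sequence(
                generate_bundle(cfg, 0, s, cameras, scene_to_world), cameras
            )
            for s in range(2)
        ]
        bundle = generate_bundle(cfg, 0, 0, cameras, scene_to_world)
        params = fit_participant_alignment(
            seqs, ["stereo_a", *MONO_METHODS]
        )
        for name in MONO_METHODS:
            s_est = params[name].transform.s
            assert s_est * bundle.true_mono_scales[name] == pytest.approx(
                1.0, rel=0.01
            )
        # stereo: transform should equal world->scene (inverse of hidden pose)
        expected = scene_to_world.inverse()
        got = params["stereo_a"].transform
        cos_angle = (np.trace(got.R @ expected.R.T) - 1.0) / 2.0
        assert np.degrees(np.arccos(np.clip(cos_angle, -1, 1))) < 0.1
        assert np.linalg.norm(got.t - expected.t) < 1.0
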