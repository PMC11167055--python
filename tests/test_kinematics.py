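"""Camera transform, normalization, alignment and flattening."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stitchgat.datamodel import ClipRef, KinematicFrame, SubSkill
from stitchgat.kinematics import (
    AlignmentError,
    align_to_clip,
    camera_frame_transform,
    flatten,
    normalize_positions,
    prepare_clip_kinematics,
    quat_conjugate,
    quat_multiply,
)
from tests.conftest import make_frame


def _frame(poses, camera, fid=0):
    return KinematicFrame(frame_id=fid, poses=np.asarray(poses, float),
                          camera=np.asarray(camera, float))


class TestCameraTransform:
    def test_pose_equal_to_camera_maps_to_origin_identity(self, rng):
        cam = np.concatenate([rng.normal(size=3), rng.normal(size=4)])
        cam[3:] /= np.linalg.norm(cam[3:])
        poses = np.tile(cam, (10, 1))
        out = camera_frame_transform([_frame(poses, cam)])[0]
        np.testing.assert_allclose(out.poses[:, :3], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.poses[:, 3:], [[1, 0, 0, 0]] * 10, atol=1e-12)

    def test_identity_camera_leaves_poses_unchanged(self, rng):
        poses = rng.normal(size=(10, 7))
        cam = np.array([0, 0, 0, 1, 0, 0, 0], dtype=float)
        out = camera_frame_transform([_frame(poses, cam)])[0]
        np.testing.assert_allclose(out.poses[:, :3], poses[:, :3], atol=1e-12)
        # orientations are unit-normalized by the transform
        expected = poses[:, 3:] / np.linalg.norm(poses[:, 3:], axis=1, keepdims=True)
        np.testing.assert_allclose(out.poses[:, 3:], expected, atol=1e-12)

    def test_roundtrip_recovers_original(self, rng):
        """Applying the transform then re-composing with the camera pose is
        the identity, to 1e-9."""
        frame = make_frame(0, rng)
        out = camera_frame_transform([frame])[0]
        cam = frame.camera
        q_c = cam[3:] / np.linalg.norm(cam[3:])
        R = Rotation.from_quat(q_c[[1, 2, 3, 0]]).as_matrix()
        rec_pos = out.poses[:, :3] @ R.T + cam[:3]
        rec_quat = quat_multiply(q_c, out.poses[:, 3:])
        orig_quat = frame.poses[:, 3:]  # unit already
        np.testing.assert_allclose(rec_pos, frame.poses[:, :3], atol=1e-9)
        np.testing.assert_allclose(rec_quat, orig_quat, atol=1e-9)

    def test_zero_camera_quaternion_errors(self, rng):
        poses = rng.normal(size=(10, 7))
        with pytest.raises(ValueError, match="zero-norm"):
            camera_frame_transform([_frame(poses, np.zeros(7))])

    def test_rigid_motion_invariance(self, rng):
        """A rigid motion applied to all poses and the camera leaves the
        camera-frame positions unchanged."""
        frames = [make_frame(i, rng) for i in range(5)]
        base = camera_frame_transform(frames)
        for _ in range(10):
            t = rng.normal(size=3)
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            R = Rotation.from_quat(q[[1, 2, 3, 0]]).as_matrix()
            moved = []
            for f in frames:
                poses = f.poses.copy()
                poses[:, :3] = poses[:, :3] @ R.T + t
                poses[:, 3:] = quat_multiply(q, poses[:, 3:])
                cam = f.camera.copy()
                cam[:3] = R @ cam[:3] + t
                cam[3:] = quat_multiply(q, cam[3:])
                moved.append(_frame(poses, cam, f.frame_id))
            out = camera_frame_transform(moved)
            for a, b in zip(base, out):
                np.testing.assert_allclose(a.poses[:, :3], b.poses[:, :3], atol=1e-6)


class TestQuaternions:
    def test_hamilton_product_vs_rotation_composition(self, rng):
        for _ in range(20):
            q1, q2 = rng.normal(size=4), rng.normal(size=4)
            q1 /= np.linalg.norm(q1)
            q2 /= np.linalg.norm(q2)
            prod = quat_multiply(q1, q2)
            R = Rotation.from_quat(prod[[1, 2, 3, 0]]).as_matrix()
            R12 = (Rotation.from_quat(q1[[1, 2, 3, 0]]) *
                   Rotation.from_quat(q2[[1, 2, 3, 0]])).as_matrix()
            np.testing.assert_allclose(R, R12, atol=1e-12)

    def test_conjugate_is_inverse(self, rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        np.testing.assert_allclose(
            quat_multiply(q, quat_conjugate(q)), [1, 0, 0, 0], atol=1e-12
        )


class TestNormalize:
    def test_max_norm_becomes_one(self, rng):
        poses = rng.normal(size=(10, 7))
        poses[0, :3] = [3, 4, 0]  # norm 5
        poses[1:, :3] *= 0.1
        out, degenerate = normalize_positions([_frame(poses, np.zeros(7))])
        assert not degenerate
        norms = np.linalg.norm(out[0].poses[:, :3], axis=1)
        assert norms.max() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_positions_flagged(self):
        poses = np.zeros((10, 7))
        poses[:, 3] = 1.0
        out, degenerate = normalize_positions([_frame(poses, np.zeros(7))])
        assert degenerate
        np.testing.assert_array_equal(out[0].poses[:, :3], 0.0)

    def test_max_norm_in_zero_one(self, rng):
        """Property: after normalization the max position norm is 0 or 1."""
        for _ in range(25):
            frames = [
                _frame(rng.normal(size=(10, 7)) * rng.exponential(), np.zeros(7), i)
                for i in range(rng.integers(1, 6))
            ]
            out, degenerate = normalize_positions(frames)
            m = max(np.linalg.norm(f.poses[:, :3], axis=1).max() for f in out)
            assert m == pytest.approx(0.0 if degenerate else 1.0, abs=1e-9)


def _clip(ids, skill=SubSkill.RP):
    return ClipRef(stitch_id="s", subskill=skill, frame_ids=list(ids))


class TestAlign:
    def _log(self, n, rng):
        return [make_frame(i, rng) for i in range(n)]

    def test_exact_length_is_identity_selection(self, rng):
        log = self._log(30, rng)
        ak = align_to_clip(log, _clip(range(24)), target_len=24)
        assert ak.frames.shape == (24, 70)
        assert ak.source_frame_ids == list(range(24))

    def test_downsample_uniform_stride(self, rng):
        """48 matching frames at target 24: every other frame, ends kept."""
        log = self._log(48, rng)
        ak = align_to_clip(log, _clip(range(48)), target_len=24)
        assert ak.source_frame_ids[0] == 0
        assert ak.source_frame_ids[-1] == 47
        expected = np.round(np.linspace(0, 47, 24)).astype(int).tolist()
        assert ak.source_frame_ids == expected

    def test_padding_repeats_last_frame(self, rng):
        log = self._log(10, rng)
        ak = align_to_clip(log, _clip(range(10)), target_len=24)
        assert ak.source_frame_ids == list(range(10)) + [9] * 14
        np.testing.assert_array_equal(ak.frames[9], ak.frames[-1])

    def test_frame_ids_are_join_keys_not_indices(self, rng):
        log = [make_frame(i, rng) for i in (5, 11, 20, 33)]
        ak = align_to_clip(log, _clip([11, 33]), target_len=2)
        assert ak.source_frame_ids == [11, 33]

    def test_no_matching_frames_errors(self, rng):
        log = self._log(5, rng)
        with pytest.raises(AlignmentError, match="s"):
            align_to_clip(log, _clip([99]), target_len=4)

    def test_pipeline_deterministic(self, rng):
        log = self._log(30, rng)
        clip = _clip(range(7, 29))
        a = prepare_clip_kinematics(log, clip, target_len=24)
        b = prepare_clip_kinematics(log, clip, target_len=24)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestFlatten:
    def test_default_length_1680(self, rng):
        log = [make_frame(i, rng) for i in range(24)]
        ak = align_to_clip(log, _clip(range(24)), target_len=24)
        assert flatten(ak).shape == (70 * 24,) == (1680,)

    def test_single_frame_length_70(self, rng):
        log = [make_frame(0, rng)]
        ak = align_to_clip(log, _clip([0]), target_len=1)
        assert flatten(ak).shape == (70,)

    def test_flatten_is_frame_major_and_invertible(self, rng):
        log = [make_frame(i, rng) for i in range(4)]
        ak = align_to_clip(log, _clip(range(4)), target_len=4)
        flat = flatten(ak)
        np.testing.assert_array_equal(flat[:70], ak.frames[0])
        np.testing.assert_array_equal(flat.reshape(4, 70), ak.frames)
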