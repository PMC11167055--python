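"""Kinematic preprocessing: camera-relative transform, normalization,
clip alignment to a fixed sequence length, and flattening for fusion.

Each raw frame carries ten tracked poses plus the camera pose.  Poses are
expressed in the camera frame (position ``R_c^-1 (p - p_c)``, orientation
``q_c^-1 * q``), then positions are scaled so the largest distance from the
origin within the clip equals one.  The per-clip scope of the normalization
keeps test-time preprocessing independent of any training corpus.

Quaternions use the (w, x, y, z) scalar-first convention with the Hamilton
product, unit-normalized after composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .datamodel import ClipRef, KinematicFrame, POSE_SCALARS, SubSkill

DEFAULT_TARGET_LEN = 24

__all__ = [
    "AlignedKinematics",
    "AlignmentError",
    "quat_multiply",
    "quat_conjugate",
    "camera_frame_transform",
    "normalize_positions",
    "align_to_clip",
    "flatten",
    "frames_to_array",
    "prepare_clip_kinematics",
]


class AlignmentError(ValueError):
    pass


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 * q2, scalar-first, broadcasting over leading axes."""
    w1, x1, y1, z1 = np.moveaxis(np.asarray(q1, dtype=np.float64), -1, 0)
    w2, x2, y2, z2 = np.moveaxis(np.asarray(q2, dtype=np.float64), -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def _unit(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    return q / n


def camera_frame_transform(frames: list[KinematicFrame]) -> list[KinematicFrame]:
    """Re-express every pose in the (per-frame) camera coordinate frame.

    Positions map to ``R_c^-1 (p - p_c)``; orientations to the unit-normalized
    ``q_c^-1 * q``.  The camera pose itself maps to the origin with identity
    orientation.
    """
    if not frames:
        return []
    cam = np.stack([np.asarray(f.camera, dtype=np.float64) for f in frames])  # (T, 7)
    poses = np.stack([np.asarray(f.poses, dtype=np.float64) for f in frames])  # (T, 10, 7)
    p_c, q_c = cam[:, :3], cam[:, 3:]
    norms = np.linalg.norm(q_c, axis=1)
    if (norms == 0).any():
        bad = frames[int(np.flatnonzero(norms == 0)[0])].frame_id
        raise ValueError(f"frame {bad}: zero-norm camera quaternion")
    q_c = q_c / norms[:, None]
    # scipy uses scalar-last ordering; batch rotation matrices
    R = Rotation.from_quat(q_c[:, [1, 2, 3, 0]]).as_matrix()  # (T, 3, 3)
    new_pos = np.einsum("tji,tpj->tpi", R, poses[:, :, :3] - p_c[:, None, :])
    new_quat = _unit(quat_multiply(quat_conjugate(q_c)[:, None, :], poses[:, :, 3:]))
    ident_cam = np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0])
    return [
        KinematicFrame(
            frame_id=f.frame_id,
            poses=np.concatenate([new_pos[t], new_quat[t]], axis=1),
            camera=ident_cam.copy(),
        )
        for t, f in enumerate(frames)
    ]


def normalize_positions(
    frames: list[KinematicFrame],
) -> tuple[list[KinematicFrame], bool]:
    """Scale positions by the clip-wide maximum distance from the origin.

    Returns ``(frames, degenerate)``; ``degenerate`` is True when every
    position is exactly zero, in which case positions pass through unchanged.
    """
    if not frames:
        return frames, True
    m = max(float(np.linalg.norm(np.asarray(f.poses)[:, :3], axis=1).max()) for f in frames)
    if m == 0.0:
        return frames, True
    out = []
    for f in frames:
        poses = np.asarray(f.poses, dtype=np.float64).copy()
        poses[:, :3] /= m
        out.append(KinematicFrame(frame_id=f.frame_id, poses=poses, camera=f.camera))
    return out, False


def _resample_indices(n: int, target: int) -> np.ndarray:
    """Uniform-index subsample (n > target) or last-frame padding (n < target)."""
    if n >= target:
        return np.round(np.linspace(0, n - 1, target)).astype(int)
    return np.concatenate([np.arange(n), np.full(target - n, n - 1)])


@dataclass
class AlignedKinematics:
    subskill: SubSkill
    frames: np.ndarray  # (target_len, 70)
    source_frame_ids: list[int]
    degenerate: bool = False


def frames_to_array(frames: list[KinematicFrame]) -> np.ndarray:
    """(T, 70) pose scalars in frame order; the camera pose is dropped."""
    return np.stack([np.asarray(f.poses, dtype=np.float64).ravel() for f in frames])


def align_to_clip(
    log: list[KinematicFrame],
    clip: ClipRef,
    target_len: int = DEFAULT_TARGET_LEN,
) -> AlignedKinematics:
    """Select log rows matching the clip's frame ids and fix the length.

    Rows whose ``frame_id`` appears in ``clip.frame_ids`` are kept in log
    order; more than ``target_len`` matches are uniform-index subsampled
    (first and last retained), fewer are padded by repeating the last frame.
    """
    wanted = set(clip.frame_ids)
    matched = [f for f in log if f.frame_id in wanted]
    if not matched:
        raise AlignmentError(
            f"stitch {clip.stitch_id}: no kinematic frames match clip "
            f"{clip.subskill.code}"
        )
    idx = _resample_indices(len(matched), target_len)
    chosen = [matched[i] for i in idx]
    return AlignedKinematics(
        subskill=clip.subskill,
        frames=frames_to_array(chosen),
        source_frame_ids=[f.frame_id for f in chosen],
    )


def flatten(ak: AlignedKinematics) -> np.ndarray:
    """Frame-major flattening: frame 0's 70 scalars, then frame 1's, ..."""
    arr = np.asarray(ak.frames, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != POSE_SCALARS:
        raise ValueError(f"expected (T, {POSE_SCALARS}) array, got {arr.shape}")
    return arr.reshape(-1)


def prepare_clip_kinematics(
    log: list[KinematicFrame],
    clip: ClipRef,
    target_len: int = DEFAULT_TARGET_LEN,
) -> AlignedKinematics:
    """Full pipeline: clip selection -> camera transform -> per-clip
    normalization -> length fixing."""
    wanted = set(clip.frame_ids)
    matched = [f for f in log if f.frame_id in wanted]
    if not matched:
        raise AlignmentError(
            f"stitch {clip.stitch_id}: no kinematic frames match clip "
            f"{clip.subskill.code}"
        )
    transformed = camera_frame_transform(matched)
    normalized, degenerate = normalize_positions(transformed)
    ak = align_to_clip(normalized, clip, target_len)
    ak.degenerate = degenerate
    return ak
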