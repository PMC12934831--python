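"""Pose feature construction.

Turns per-frame 3D joint tracks into the three feature families the
analysis compares:

* flattened full body joints — 45 joints x 3 coordinates x 2 agents = 270
  values, from the temporally averaged pose of each agent;
* 3D social pose features — per agent a face position (midpoint of the two
  eye joints) and a unit facing direction (normalized average of the
  head-center-to-nose and neck-to-nose vectors), 12 values total;
* 2D social pose features — the same with depth components (z, dz) dropped,
  8 values.

Also houses the depth-fusion rule used to combine a pose estimator's camera
translation with a separate metric depth estimate, and the completeness
filter that excludes videos with any failed frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import SkeletonTemplate
from .synthetic import JointTrack

POSE3D_COLUMNS = [
    f"a{a}_{c}" for a in (1, 2) for c in ("x", "y", "z", "dx", "dy", "dz")
]
POSE2D_COLUMNS = [
    f"a{a}_{c}" for a in (1, 2) for c in ("x", "y", "dx", "dy")
]
POSITION_COLUMNS = [c for c in POSE3D_COLUMNS if "d" not in c.split("_")[1]]
DIRECTION_COLUMNS = [c for c in POSE3D_COLUMNS if "d" in c.split("_")[1]]


class DegenerateGeometryError(ValueError):
    """Raised when the facing-direction construction is undefined
    (averaged head->nose / neck->nose vector is zero)."""


def fuse_depth(local_joints: np.ndarray, translation_a: np.ndarray,
               depth_b: float) -> np.ndarray:
    """Place body-local joints in the camera frame with a corrected depth.

    The x and y components of ``translation_a`` (one estimator's camera
    translation) are kept, but its depth (z) component is replaced by
    ``depth_b`` (another estimator's metric depth) before translating the
    joints.  Never alters x or y coordinates beyond the translation itself.
    """
    local_joints = np.asarray(local_joints, dtype=float)
    translation_a = np.asarray(translation_a, dtype=float)
    if depth_b <= 0:
        raise ValueError("depth_b must be positive")
    if not (np.all(np.isfinite(local_joints))
            and np.all(np.isfinite(translation_a))
            and np.isfinite(depth_b)):
        raise ValueError("non-finite input to fuse_depth")
    t = translation_a.copy()
    t[2] = depth_b
    return local_joints + t


def filter_complete_videos(
    tracks: list[JointTrack],
) -> tuple[list[str], list[str]]:
    """Split video ids into (kept, excluded) by the completeness rule.

    A video is kept only if both agents have every frame valid; any failed
    frame on either track excludes the whole clip.  Order is stable (first
    appearance in ``tracks``).  Videos without exactly two agents raise.
    """
    by_video: dict[str, list[JointTrack]] = {}
    order: list[str] = []
    for t in tracks:
        if t.video_id not in by_video:
            order.append(t.video_id)
        by_video.setdefault(t.video_id, []).append(t)
    kept, excluded = [], []
    for vid in order:
        pair = by_video[vid]
        if len(pair) != 2 or {t.agent for t in pair} != {0, 1}:
            raise ValueError(f"video {vid!r} does not have exactly two agents")
        if all(t.frame_valid.all() for t in pair):
            kept.append(vid)
        else:
            excluded.append(vid)
    return kept, excluded


def average_frames(track: JointTrack) -> np.ndarray:
    """Unweighted mean pose over the frame axis; requires all frames valid."""
    if not track.frame_valid.all():
        raise ValueError(
            f"track {track.video_id!r} agent {track.agent} has invalid "
            "frames; filter videos before averaging"
        )
    return track.coords.mean(axis=0)


def face_position(pose: np.ndarray, template: SkeletonTemplate) -> np.ndarray:
    """Midpoint of the two eye joints. ``pose`` is (45, 3) or (frames, 45, 3)."""
    li = template.landmark("left_eye")
    ri = template.landmark("right_eye")
    return 0.5 * (pose[..., li, :] + pose[..., ri, :])


def facing_direction(pose: np.ndarray, template: SkeletonTemplate) -> np.ndarray:
    """Unit facing vector: normalized average of the head-center-to-nose
    and neck-to-nose vectors.  Works per frame on (frames, 45, 3) input."""
    nose = pose[..., template.landmark("nose"), :]
    head = pose[..., template.landmark("head_center"), :]
    neck = pose[..., template.landmark("neck"), :]
    avg = ((nose - head) + (nose - neck)) / 2.0
    norm = np.linalg.norm(avg, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise DegenerateGeometryError(
            "averaged facing vector is zero; geometry is degenerate")
    return avg / norm


def order_agents(
    track_pair: tuple[JointTrack, JointTrack],
) -> tuple[JointTrack, JointTrack]:
    """Canonical agent order: ascending mean x over valid frames, ties
    broken by ascending mean depth.  Invariant to input order."""
    def key(t: JointTrack) -> tuple[float, float]:
        c = t.coords[t.frame_valid]
        return (float(c[..., 0].mean()), float(c[..., 2].mean()))

    a, b = track_pair
    return (a, b) if key(a) <= key(b) else (b, a)


def _social_parts(pose: np.ndarray, template: SkeletonTemplate) -> np.ndarray:
    """(…, 6) array of [position, direction] for one agent pose."""
    return np.concatenate(
        [face_position(pose, template), facing_direction(pose, template)],
        axis=-1,
    )


def assemble_social_vector(
    pose1: np.ndarray,
    pose2: np.ndarray,
    template: SkeletonTemplate,
    mode: str = "3D",
    frames_mode: str = "average_pose",
) -> np.ndarray:
    """Concatenate per-agent [position, direction] into the social vector.

    ``mode`` "3D" keeps all six values per agent (length 12); "2D" drops
    the depth components z and dz (length 8, a raw projection with no
    renormalization).  ``frames_mode`` "average_pose" expects temporally
    averaged (45, 3) poses; "per_frame_then_average" expects
    (frames, 45, 3) tracks, computes features per frame, then averages
    them (the unit directions are averaged plainly, without renormalizing).
    """
    if mode not in ("3D", "2D"):
        raise ValueError(f"mode must be '3D' or '2D', got {mode!r}")
    if frames_mode not in ("average_pose", "per_frame_then_average"):
        raise ValueError(f"unknown frames_mode {frames_mode!r}")

    parts = []
    for pose in (pose1, pose2):
        feats = _social_parts(np.asarray(pose, dtype=float), template)
        if frames_mode == "per_frame_then_average":
            if feats.ndim != 2:
                raise ValueError(
                    "per_frame_then_average needs (frames, 45, 3) input")
            feats = feats.mean(axis=0)
        parts.append(feats)
    vec = np.concatenate(parts)
    if mode == "2D":
        keep = [0, 1, 3, 4, 6, 7, 9, 10]  # drop z (2, 8) and dz (5, 11)
        vec = vec[keep]
    expected = 12 if mode == "3D" else 8
    assert vec.shape == (expected,)
    return vec


def flatten_joints(pose1: np.ndarray, pose2: np.ndarray) -> np.ndarray:
    """Agent-major, joint-major, coordinate-minor flattening to 270 values."""
    pose1, pose2 = np.asarray(pose1, float), np.asarray(pose2, float)
    if pose1.shape != pose2.shape or pose1.shape[-1] != 3:
        raise ValueError("poses must both be (n_joints, 3)")
    vec = np.concatenate([pose1.ravel(), pose2.ravel()])
    assert vec.shape == (2 * pose1.size,)
    return vec


def unflatten_joints(vec: np.ndarray, n_joints: int = 45) -> tuple[np.ndarray, np.ndarray]:
    vec = np.asarray(vec, float)
    half = n_joints * 3
    return vec[:half].reshape(n_joints, 3), vec[half:].reshape(n_joints, 3)


@dataclass
class FeatureTables:
    """Per-video feature tables for the three families, aligned by index."""

    joints: pd.DataFrame   # 270 columns f000..f269
    pose3d: pd.DataFrame   # 12 columns
    pose2d: pd.DataFrame   # 8 columns


def build_feature_tables(
    tracks: list[JointTrack], template: SkeletonTemplate
) -> FeatureTables:
    """Run the full feature pipeline over a batch of complete videos.

    Joint features use the average-pose-then-flatten route; social pose
    features the per-frame-then-average route.  Videos failing the
    completeness filter are dropped.
    """
    kept, _ = filter_complete_videos(tracks)
    by_video: dict[str, list[JointTrack]] = {}
    for t in tracks:
        by_video.setdefault(t.video_id, []).append(t)

    joints_rows, p3_rows, p2_rows = {}, {}, {}
    for vid in kept:
        t1, t2 = order_agents(tuple(by_video[vid]))
        pose1, pose2 = average_frames(t1), average_frames(t2)
        joints_rows[vid] = flatten_joints(pose1, pose2)
        p3_rows[vid] = assemble_social_vector(
            t1.coords, t2.coords, template, "3D", "per_frame_then_average")
        p2_rows[vid] = assemble_social_vector(
            t1.coords, t2.coords, template, "2D", "per_frame_then_average")

    joints = pd.DataFrame.from_dict(joints_rows, orient="index")
    joints.columns = [f"f{i:03d}" for i in range(joints.shape[1])]
    pose3d = pd.DataFrame.from_dict(p3_rows, orient="index",
                                    columns=POSE3D_COLUMNS)
    pose2d = pd.DataFrame.from_dict(p2_rows, orient="index",
                                    columns=POSE2D_COLUMNS)
    for df in (joints, pose3d, pose2d):
        df.index.name = "video_id"
    return FeatureTables(joints=joints, pose3d=pose3d, pose2d=pose2d)
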