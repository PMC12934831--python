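"""Canonical 45-joint skeleton template.

The joint set is the SMPL-X regressed layout used by modern whole-body pose
estimators: the 24 canonical SMPL body joints followed by 21 additional face,
hand, and foot landmarks (nose, eyes, ears, toes, heels, fingertips).  Only
five of the landmarks carry semantics downstream — the two eyes (face
position), and nose / head-center / neck (facing direction) — so the template
names them explicitly instead of hard-coding integer indices.

The rest pose is a rough standing figure in a canonical body frame:
x lateral (right positive), y up, z forward.  It is constructed so that the
facing-direction formula, ``normalize(((nose-head) + (nose-neck)) / 2)``,
evaluates exactly to the canonical facing axis ``+z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

JOINT_COUNT = 45

#: canonical facing axis of the rest pose (unit +z)
CANONICAL_FACING = np.array([0.0, 0.0, 1.0])

# 24 SMPL body joints, in the conventional order.
_SMPL_BODY = [
    "pelvis", "left_hip", "right_hip", "spine1", "left_knee", "right_knee",
    "spine2", "left_ankle", "right_ankle", "spine3", "left_foot", "right_foot",
    "neck", "left_collar", "right_collar", "head", "left_shoulder",
    "right_shoulder", "left_elbow", "right_elbow", "left_wrist", "right_wrist",
    "left_hand", "right_hand",
]

# 21 extra face / foot / hand landmarks appended by the SMPL-X joint regressor.
_EXTRA = [
    "nose", "right_eye", "left_eye", "right_ear", "left_ear",
    "left_big_toe", "left_small_toe", "left_heel",
    "right_big_toe", "right_small_toe", "right_heel",
    "left_thumb", "left_index", "left_middle", "left_ring", "left_pinky",
    "right_thumb", "right_index", "right_middle", "right_ring", "right_pinky",
]

JOINT_NAMES = _SMPL_BODY + _EXTRA


@dataclass(frozen=True)
class SkeletonTemplate:
    """A fixed 45-joint skeleton with named landmarks and a rest pose.

    Attributes
    ----------
    joint_count : int
        Always 45.
    landmark_index : dict
        Maps landmark names (``left_eye``, ``right_eye``, ``nose``,
        ``head_center``, ``neck``, ...) to joint indices.
    rest_pose : (45, 3) ndarray
        Joint coordinates in meters in the canonical body frame (feet near
        the ground plane, facing +z).
    """

    joint_count: int
    landmark_index: dict[str, int] = field(repr=False)
    rest_pose: np.ndarray = field(repr=False)

    def landmark(self, name: str) -> int:
        try:
            return self.landmark_index[name]
        except KeyError as exc:
            raise KeyError(f"template has no landmark named {name!r}") from exc


def _rest_pose() -> np.ndarray:
    # (x, y, z) meters; mirror-symmetric in x for paired joints.
    sym = {
        "hip": (0.10, 0.90, 0.0), "knee": (0.10, 0.50, 0.0),
        "ankle": (0.10, 0.10, 0.0), "foot": (0.10, 0.04, 0.12),
        "collar": (0.07, 1.44, 0.0), "shoulder": (0.18, 1.43, 0.0),
        "elbow": (0.23, 1.18, 0.0), "wrist": (0.25, 0.96, 0.0),
        "hand": (0.26, 0.88, 0.02),
        "eye": (0.033, 1.60, 0.08), "ear": (0.07, 1.58, 0.0),
        "big_toe": (0.09, 0.02, 0.19), "small_toe": (0.13, 0.02, 0.16),
        "heel": (0.10, 0.03, -0.06),
        "thumb": (0.24, 0.86, 0.06), "index": (0.27, 0.82, 0.04),
        "middle": (0.275, 0.81, 0.02), "ring": (0.27, 0.81, 0.00),
        "pinky": (0.26, 0.82, -0.02),
    }
    center = {
        "pelvis": (0.0, 0.95, 0.0), "spine1": (0.0, 1.05, 0.0),
        "spine2": (0.0, 1.16, 0.0), "spine3": (0.0, 1.28, 0.0),
        "neck": (0.0, 1.50, 0.0), "head": (0.0, 1.62, 0.0),
        # nose sits on the +z axis through the head/neck midpoint (y = 1.56)
        # so the averaged head->nose and neck->nose vectors point along +z.
        "nose": (0.0, 1.56, 0.11),
    }
    coords = np.zeros((JOINT_COUNT, 3))
    for i, name in enumerate(JOINT_NAMES):
        if name in center:
            coords[i] = center[name]
        else:
            side, base = name.split("_", 1)
            x, y, z = sym[base]
            coords[i] = (x if side == "right" else -x, y, z)
    return coords


def make_skeleton_template() -> SkeletonTemplate:
    """Build the fixed 45-joint template. Deterministic; no configuration."""
    landmark_index = {name: i for i, name in enumerate(JOINT_NAMES)}
    landmark_index["head_center"] = landmark_index["head"]
    rest = _rest_pose()
    rest.setflags(write=False)
    tpl = SkeletonTemplate(
        joint_count=JOINT_COUNT, landmark_index=landmark_index, rest_pose=rest
    )
    # construction invariants
    li, ri = tpl.landmark("left_eye"), tpl.landmark("right_eye")
    assert np.allclose(rest[li] * [-1, 1, 1], rest[ri])
    nose = rest[tpl.landmark("nose")]
    mid = 0.5 * (rest[tpl.landmark("head_center")] + rest[tpl.landmark("neck")])
    v = nose - mid
    assert np.allclose(v / np.linalg.norm(v), CANONICAL_FACING)
    return tpl
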