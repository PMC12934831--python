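"""Seeded synthetic two-agent scenes, joint tracks, ratings, and embeddings.

This module generates data with the statistical structure the downstream
analysis assumes: two people in front of a camera, 45-joint 3D tracks over 90
frames (emulating a pose-estimator's output, including occasional per-frame
failures), five behavioral ratings on a 1-5 scale derived from the latent
positions / facing directions / scene scale and averaged over simulated
raters, and model-embedding matrices with a controlled amount of linearly
decodable pose information.

Every sampling function takes an explicit integer ``seed``; identical seed
and configuration give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .skeleton import CANONICAL_FACING, SkeletonTemplate

RATING_COLUMNS = [
    "spatial_expanse", "interagent_distance", "agents_facing",
    "communicative", "physical",
]


@dataclass(frozen=True)
class SceneLatents:
    """Ground-truth latent variables of one synthetic scene.

    ``positions`` is a (2, 3) array of agent face positions in camera
    coordinates (meters, +z = depth away from the camera); ``facings`` a
    (2, 3) array of unit facing directions; ``scene_scale`` a positive
    scalar controlling the overall spatial expanse of the layout.
    """

    video_id: str
    positions: np.ndarray
    facings: np.ndarray
    scene_scale: float
    seed: int

    def __post_init__(self):
        if not np.allclose(np.linalg.norm(self.facings, axis=1), 1.0):
            raise ValueError("facing directions must be unit vectors")
        if self.scene_scale <= 0:
            raise ValueError("scene_scale must be positive")
        if np.any(self.positions[:, 2] <= 0):
            raise ValueError("agents must lie in front of the camera (z > 0)")


@dataclass(frozen=True)
class JointTrack:
    """Per-agent 3D joint coordinates over time, plus a validity mask.

    ``coords`` has shape (frames, 45, 3) in meters, camera frame.  Frames
    with ``frame_valid`` False emulate pose-estimation failures; their
    coordinates are NaN so accidental use is loud.
    """

    video_id: str
    agent: int
    coords: np.ndarray
    frame_valid: np.ndarray

    def __post_init__(self):
        if self.agent not in (0, 1):
            raise ValueError("agent must be 0 or 1")
        if not np.all(np.isfinite(self.coords[self.frame_valid])):
            raise ValueError("coords must be finite on valid frames")


@dataclass
class SceneConfig:
    """Distributional settings of the scene generator.

    Two agents are placed symmetrically about a midpoint drawn uniformly in
    a box in front of the camera, separated by a distance drawn from
    ``distance_range`` along a direction in the x-z quadrant (azimuth
    ``phi_range`` from the lateral axis toward depth, small vertical tilt
    ``tilt_range``).  Positions are then multiplied by a log-uniform scene
    scale.  With the default azimuth in [0, pi/2], about half the
    inter-agent displacement variance lies in depth; widen the lower bound
    (e.g. [pi/6, pi/2]) for depth-dominant layouts.
    """

    midpoint_x_range: tuple[float, float] = (-1.0, 1.0)
    midpoint_y_range: tuple[float, float] = (-0.3, 0.3)
    midpoint_depth_range: tuple[float, float] = (3.0, 7.0)
    distance_range: tuple[float, float] = (0.5, 3.0)
    phi_range: tuple[float, float] = (0.0, math.pi / 2)
    tilt_range: tuple[float, float] = (-0.15, 0.15)
    scale_range: tuple[float, float] = (0.7, 1.4)  # log-uniform
    facing_mode: str = "random"  # "random" | "mutual" | "noisy_mutual"
    facing_noise_sd: float = 0.3  # rad, used by noisy_mutual

    def validate(self) -> None:
        for name in ("midpoint_x_range", "midpoint_y_range",
                     "midpoint_depth_range", "distance_range", "phi_range",
                     "tilt_range", "scale_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be (low, high) with low <= high")
        if self.distance_range[0] <= 0:
            raise ValueError("distance_range must be positive")
        if self.scale_range[0] <= 0:
            raise ValueError("scale_range must be positive")
        if self.facing_mode not in ("random", "mutual", "noisy_mutual"):
            raise ValueError(f"unknown facing_mode {self.facing_mode!r}")


@dataclass
class NoiseConfig:
    """Rendering noise: isotropic per-frame joint jitter (meters) and a
    per-frame, per-track probability of a failed (invalid) frame."""

    jitter_sd: float = 0.01
    dropout_rate: float = 6e-4

    def validate(self) -> None:
        if self.jitter_sd < 0 or not 0 <= self.dropout_rate <= 1:
            raise ValueError("invalid noise configuration")


@dataclass
class RatingWeights:
    """Coefficients of the generative rating model (see generate_ratings)."""

    w_facing: float = 1.0
    w_distance: float = 0.5
    w_physical: float = 1.0
    contact_radius: float = 2.0  # rho, meters


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return v / np.linalg.norm(v, axis=axis, keepdims=True)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return _unit(v)


def sample_scene_latents(
    n_videos: int, config: SceneConfig | None = None, seed: int = 0
) -> list[SceneLatents]:
    """Draw ``n_videos`` seeded scene layouts.

    Agents are ordered left-to-right (agent 0 has the smaller x), matching
    the deterministic agent-ordering convention used downstream.
    """
    if n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    config = config or SceneConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    mid = np.column_stack([
        rng.uniform(*config.midpoint_x_range, n_videos),
        rng.uniform(*config.midpoint_y_range, n_videos),
        rng.uniform(*config.midpoint_depth_range, n_videos),
    ])
    dist = rng.uniform(*config.distance_range, n_videos)
    phi = rng.uniform(*config.phi_range, n_videos)
    tilt = rng.uniform(*config.tilt_range, n_videos)
    # displacement from agent 0 to agent 1: +x (rightward) and +z (deeper)
    disp = np.column_stack([
        np.cos(tilt) * np.cos(phi), np.sin(tilt), np.cos(tilt) * np.sin(phi)
    ]) * dist[:, None]
    scale = np.exp(rng.uniform(np.log(config.scale_range[0]),
                               np.log(config.scale_range[1]), n_videos))
    p0 = (mid - disp / 2) * scale[:, None]
    p1 = (mid + disp / 2) * scale[:, None]

    if config.facing_mode == "random":
        d0 = _random_unit_vectors(rng, n_videos)
        d1 = _random_unit_vectors(rng, n_videos)
    else:
        d0 = _unit(p1 - p0)
        d1 = -d0
        if config.facing_mode == "noisy_mutual":
            rot0 = Rotation.from_rotvec(
                rng.normal(0, config.facing_noise_sd, (n_videos, 3)))
            rot1 = Rotation.from_rotvec(
                rng.normal(0, config.facing_noise_sd, (n_videos, 3)))
            d0 = rot0.apply(d0)
            d1 = rot1.apply(d1)

    out = []
    for i in range(n_videos):
        out.append(SceneLatents(
            video_id=f"video_{i:04d}",
            positions=np.stack([p0[i], p1[i]]),
            facings=np.stack([d0[i], d1[i]]),
            scene_scale=float(scale[i]),
            seed=seed,
        ))
    return out


def _rotation_to(direction: np.ndarray) -> Rotation:
    """Minimal rotation taking the canonical facing axis onto ``direction``."""
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("degenerate (zero) facing direction")
    rot, _ = Rotation.align_vectors(d[None, :] / norm,
                                    CANONICAL_FACING[None, :])
    return rot


def render_joint_tracks(
    latents: SceneLatents,
    template: SkeletonTemplate,
    noise: NoiseConfig | None = None,
    frames: int = 90,
    seed: int = 0,
) -> tuple[JointTrack, JointTrack]:
    """Render both agents' joint tracks from one scene's latents.

    The rest pose is rigidly rotated so the canonical facing axis maps onto
    the agent's latent facing, then translated so the face (eye midpoint)
    sits at the latent position.  Per-frame isotropic Gaussian jitter of
    ``noise.jitter_sd`` emulates estimator noise; frames are independently
    dropped (marked invalid, coordinates NaN) at ``noise.dropout_rate``.
    """
    if frames < 1:
        raise ValueError("frames must be >= 1")
    noise = noise or NoiseConfig()
    noise.validate()
    rng = np.random.default_rng(seed)

    li = template.landmark("left_eye")
    ri = template.landmark("right_eye")
    eye_mid_rest = 0.5 * (template.rest_pose[li] + template.rest_pose[ri])

    tracks = []
    for agent in range(2):
        rot = _rotation_to(latents.facings[agent])
        posed = rot.apply(template.rest_pose - eye_mid_rest) + latents.positions[agent]
        coords = np.broadcast_to(posed, (frames, *posed.shape)).copy()
        if noise.jitter_sd > 0:
            coords += rng.normal(0, noise.jitter_sd, coords.shape)
        valid = rng.random(frames) >= noise.dropout_rate
        coords[~valid] = np.nan
        tracks.append(JointTrack(
            video_id=latents.video_id, agent=agent,
            coords=coords, frame_valid=valid,
        ))
    return tracks[0], tracks[1]


def raw_rating_scores(
    latents: list[SceneLatents], weights: RatingWeights | None = None
) -> pd.DataFrame:
    """Noiseless raw (unscaled) scores for each rating dimension.

    spatial_expanse  = log(scene_scale)
    interagent_dist  = ||p1 - p2||
    agents_facing    = mean of cos(angle between each agent's facing and the
                       direction toward the other agent); in [-1, 1],
                       symmetric under swapping agents.
    communicative    = w_facing * facing - w_distance * distance
    physical         = w_physical * max(0, 1 - distance / contact_radius)
    """
    weights = weights or RatingWeights()
    rows = {}
    for lat in latents:
        p0, p1 = lat.positions
        d0, d1 = lat.facings
        delta = p1 - p0
        dist = float(np.linalg.norm(delta))
        u01 = delta / dist
        facing = 0.5 * (float(d0 @ u01) + float(d1 @ -u01))
        rows[lat.video_id] = {
            "spatial_expanse": math.log(lat.scene_scale),
            "interagent_distance": dist,
            "agents_facing": facing,
            "communicative": weights.w_facing * facing - weights.w_distance * dist,
            "physical": weights.w_physical
            * max(0.0, 1.0 - dist / weights.contact_radius),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "video_id"
    return df[RATING_COLUMNS]


def _rescale_1_to_5(raw: pd.DataFrame) -> pd.DataFrame:
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = (hi - lo).replace(0.0, np.nan)
    scaled = 1.0 + 4.0 * (raw - lo) / span
    return scaled.fillna(3.0)  # constant raw score -> midpoint rating


def generate_ratings(
    latents: list[SceneLatents],
    weights: RatingWeights | None = None,
    n_raters: int = 10,
    rater_sd: float = 0.5,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> pd.DataFrame:
    """Simulate averaged human ratings on the five dimensions.

    Raw scores (see :func:`raw_rating_scores`) are affinely rescaled to the
    1-5 scale over the batch, then each simulated rater adds Gaussian noise
    of SD ``rater_sd`` and their clipped responses are averaged.  A
    ``split`` column assigns the first ``train_fraction`` of a seeded
    shuffle to ``train`` and the rest to ``test``.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if rater_sd < 0:
        raise ValueError("rater_sd must be non-negative")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    base = _rescale_1_to_5(raw_rating_scores(latents, weights))
    noise = rng.normal(0, rater_sd, (n_raters, *base.shape)) if rater_sd > 0 \
        else np.zeros((n_raters, *base.shape))
    responses = np.clip(base.to_numpy()[None, :, :] + noise, 1.0, 5.0)
    averaged = pd.DataFrame(responses.mean(axis=0), index=base.index,
                            columns=base.columns)

    n = len(base)
    n_train = max(1, min(n - 1, round(n * train_fraction)))
    order = rng.permutation(n)
    split = np.array(["test"] * n, dtype=object)
    split[order[:n_train]] = "train"
    averaged.insert(0, "split", split)
    return averaged.reset_index()


@dataclass(frozen=True)
class EmbeddingSet:
    """One model layer's video embeddings: (n_videos, dim) rows aligned
    with ``video_index``."""

    model_name: str
    layer_name: str
    matrix: np.ndarray
    video_index: list[str]

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.video_index):
            raise ValueError("matrix rows must align with video_index")
        if self.matrix.shape[1] < 1:
            raise ValueError("embedding dim must be >= 1")


def generate_embeddings(
    pose_features: pd.DataFrame,
    info_level: float,
    dim: int = 100,
    seed: int = 0,
    model_name: str = "synthetic",
    layer_name: str = "layer0",
) -> EmbeddingSet:
    """Synthesize an embedding matrix with a controlled amount of pose
    information.

    ``pose_features`` is a video-indexed table (e.g. the 12 columns of the
    3D social pose vector).  The embedding is a blend
    ``info_level * (F_std @ W) + (1 - info_level) * N`` with ``W`` a seeded
    Gaussian linear map and ``N`` unit Gaussian noise in the same columns:
    info_level 0 gives pure noise, 1 a noiseless (and, for dim >= n
    features, invertible) linear image of the features.
    """
    if not 0.0 <= info_level <= 1.0:
        raise ValueError("info_level must be in [0, 1]")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)

    F = pose_features.to_numpy(dtype=float)
    sd = F.std(axis=0)
    F_std = (F - F.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    k = F.shape[1]
    W = rng.normal(size=(k, dim)) / math.sqrt(k)
    noise = rng.normal(size=(F.shape[0], dim))
    matrix = info_level * (F_std @ W) + (1.0 - info_level) * noise
    return EmbeddingSet(
        model_name=model_name, layer_name=layer_name,
        matrix=matrix, video_index=list(pose_features.index),
    )


def scene_config_to_dict(config: SceneConfig) -> dict:
    return asdict(config)
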