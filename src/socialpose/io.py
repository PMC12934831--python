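"""On-disk layouts for joint tracks, ratings, features, and embeddings.

Joint tracks live in HDF5 as ``/videos/<video_id>/agent<0|1>`` datasets of
shape (frames, 45, 3) float64 with a boolean ``frame_valid`` companion; a
long-CSV alternative (video_id, agent, frame, joint, x, y, z) is provided
for text-only interchange.  Ratings and feature tables are plain CSV;
embeddings are HDF5 ``/models/<model>/<layer>`` matrices with a shared
``/video_index``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import EmbeddingSet, JointTrack, RATING_COLUMNS


def write_joint_tracks(path: str | Path, tracks: list[JointTrack]) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("videos")
        for t in tracks:
            grp = root.require_group(t.video_id)
            ds = grp.create_dataset(f"agent{t.agent}", data=t.coords)
            ds.attrs["frame_valid"] = t.frame_valid
    # attrs round-trip booleans; datasets keep float64 exactly


def read_joint_tracks(path: str | Path) -> list[JointTrack]:
    tracks = []
    with h5py.File(path, "r") as f:
        for vid in sorted(f["videos"]):
            grp = f["videos"][vid]
            for key in sorted(grp):
                ds = grp[key]
                tracks.append(JointTrack(
                    video_id=vid,
                    agent=int(key.removeprefix("agent")),
                    coords=ds[()],
                    frame_valid=np.asarray(ds.attrs["frame_valid"], dtype=bool),
                ))
    return tracks


def tracks_to_long_csv(tracks: list[JointTrack], path: str | Path) -> None:
    frames_list = []
    for t in tracks:
        n_frames, n_joints, _ = t.coords.shape
        fr, jo = np.meshgrid(np.arange(n_frames), np.arange(n_joints),
                             indexing="ij")
        frames_list.append(pd.DataFrame({
            "video_id": t.video_id, "agent": t.agent,
            "frame": fr.ravel(), "joint": jo.ravel(),
            "x": t.coords[..., 0].ravel(),
            "y": t.coords[..., 1].ravel(),
            "z": t.coords[..., 2].ravel(),
        }))
    pd.concat(frames_list, ignore_index=True).to_csv(path, index=False)


def tracks_from_long_csv(path: str | Path) -> list[JointTrack]:
    df = pd.read_csv(path)
    tracks = []
    for (vid, agent), g in df.groupby(["video_id", "agent"], sort=True):
        g = g.sort_values(["frame", "joint"])
        n_frames = g["frame"].max() + 1
        n_joints = g["joint"].max() + 1
        coords = g[["x", "y", "z"]].to_numpy().reshape(n_frames, n_joints, 3)
        valid = np.isfinite(coords).all(axis=(1, 2))
        tracks.append(JointTrack(video_id=str(vid), agent=int(agent),
                                 coords=coords, frame_valid=valid))
    return tracks


def write_ratings(path: str | Path, ratings: pd.DataFrame) -> None:
    cols = ["video_id", "split", *RATING_COLUMNS]
    ratings[cols].to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"video_id", "split", *RATING_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"ratings file missing columns: {sorted(missing)}")
    return df


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    """Feature tables are video-indexed; columns f000.. (or named)."""
    table.to_csv(path, index=True, index_label="video_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="video_id")


def write_embeddings(path: str | Path, sets: list[EmbeddingSet]) -> None:
    if not sets:
        raise ValueError("no embedding sets to write")
    index = sets[0].video_index
    for s in sets:
        if s.video_index != index:
            raise ValueError("all embedding sets must share a video index")
    with h5py.File(path, "w") as f:
        f.create_dataset("video_index",
                         data=np.array(index, dtype=h5py.string_dtype()))
        models = f.create_group("models")
        for s in sets:
            models.require_group(s.model_name).create_dataset(
                s.layer_name, data=s.matrix)


def read_embeddings(path: str | Path) -> list[EmbeddingSet]:
    sets = []
    with h5py.File(path, "r") as f:
        index = [v.decode() if isinstance(v, bytes) else str(v)
                 for v in f["video_index"][()]]
        for model in sorted(f["models"]):
            for layer in sorted(f["models"][model]):
                sets.append(EmbeddingSet(
                    model_name=model, layer_name=layer,
                    matrix=f["models"][model][layer][()],
                    video_index=list(index),
                ))
    return sets
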