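import math

import numpy as np
import pytest

import socialpose as sp
from socialpose.features import build_feature_tables


@pytest.fixture(scope="session")
def template():
    return sp.make_skeleton_template()


def make_dataset(
    n_videos=250,
    seed=0,
    scene=None,
    noise=None,
    n_raters=10,
    rater_sd=0.5,
    frames=90,
    template=None,
):
    """Generate one complete synthetic study: feature tables, ratings
    (aligned to the kept videos), train/test index arrays, and latents."""
    template = template or sp.make_skeleton_template()
    noise = noise or sp.NoiseConfig()
    rng = np.random.default_rng(seed)
    latents = sp.sample_scene_latents(n_videos, scene,
                                      seed=int(rng.integers(2 ** 31)))
    tracks = []
    for lat in latents:
        pair = sp.render_joint_tracks(lat, template, noise, frames=frames,
                                      seed=int(rng.integers(2 ** 31)))
        tracks.extend(pair)
    tables = build_feature_tables(tracks, template)
    ratings = sp.generate_ratings(latents, n_raters=n_raters,
                                  rater_sd=rater_sd,
                                  seed=int(rng.integers(2 ** 31)))
    ratings = ratings.set_index("video_id").loc[tables.pose3d.index]
    train_idx = np.flatnonzero((ratings["split"] == "train").to_numpy())
    test_idx = np.flatnonzero((ratings["split"] == "test").to_numpy())
    return tables, ratings, train_idx, test_idx, latents


#: scene layout meeting the depth-dominant condition: with azimuth phi in
#: [pi/6, pi/2], about 70% of the inter-agent displacement variance lies in
#: the depth (z) component.
DEPTH_DOMINANT_SCENE = sp.SceneConfig(phi_range=(math.pi / 6, math.pi / 2))


@pytest.fixture(scope="session")
def small_dataset(template):
    """A modest 80-video study shared by tests that only need plumbing."""
    return make_dataset(n_videos=80, seed=11, template=template)
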