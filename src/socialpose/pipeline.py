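"""End-to-end pipeline orchestration.

Runs the stages simulate -> features -> encode -> grouped -> semipartial ->
permtest -> report against a single run directory, with one global seed
fanned out deterministically to per-stage seeds.  Each stage reads and
writes the plain file formats defined by the other modules, so stages can
also be run individually (e.g. from the CLI) against an existing directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .encoding import (
    alpha_grid, decode_features, encode_feature_set,
    encode_with_layer_selection, fit_predict, grouped_ridge_search,
    jl_min_dim, sparse_random_projection,
)
from .features import (
    DIRECTION_COLUMNS, POSITION_COLUMNS, build_feature_tables,
)
from .permstats import (
    perm_corr_difference, perm_correlation, perm_group_vs_single,
    perm_paired_improvement, semipartial_encode, semipartial_residualize,
)
from .skeleton import make_skeleton_template
from .synthetic import (
    NoiseConfig, RATING_COLUMNS, RatingWeights, SceneConfig,
    generate_embeddings, generate_ratings, render_joint_tracks,
    sample_scene_latents,
)

log = logging.getLogger("socialpose")

_STAGES = ["simulate", "features", "encode", "grouped", "semipartial",
           "permtest", "report"]


@dataclass
class RunConfig:
    """All settings of a pipeline run.

    Defaults mirror the analysis conditions: 250 videos split 80/20, 90
    frames, ratings averaged over 10 raters, an alpha grid spanning
    1e-10..1e10, five-fold CV repeated twice, SRP at distortion eps=0.1,
    200 Dirichlet draws at concentrations 0.1 and 1.0, and 5,000
    permutations.
    """

    n_videos: int = 250
    frames: int = 90
    train_fraction: float = 0.8
    scene: SceneConfig = field(default_factory=SceneConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    weights: RatingWeights = field(default_factory=RatingWeights)
    n_raters: int = 10
    rater_sd: float = 0.5
    with_embeddings: bool = True
    n_models: int = 12
    embedding_dim: int = 100
    n_layers: int = 2
    n_alphas: int = 21
    folds: int = 5
    repeats: int = 2
    eps: float = 0.1
    n_gamma: int = 200
    concentrations: tuple[float, ...] = (0.1, 1.0)
    n_perm: int = 5000
    seed: int = 0

    def alphas(self) -> np.ndarray:
        return alpha_grid(self.n_alphas)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("scene", SceneConfig), ("noise", NoiseConfig),
                         ("weights", RatingWeights)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d[key].items()})
        if "concentrations" in d:
            d["concentrations"] = tuple(d["concentrations"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one global seed out to fixed per-stage seeds (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGES, children)}


def _paths(run_dir: Path) -> dict[str, Path]:
    return {
        "joints_h5": run_dir / "data" / "joints.h5",
        "ratings": run_dir / "data" / "ratings.csv",
        "embeddings": run_dir / "data" / "embeddings.h5",
        "feat_joints": run_dir / "features" / "joints.csv",
        "feat_pose3d": run_dir / "features" / "pose3d.csv",
        "feat_pose2d": run_dir / "features" / "pose2d.csv",
        "encoding": run_dir / "results" / "encoding.csv",
        "predictions": run_dir / "results" / "predictions.csv",
        "decoding": run_dir / "results" / "decoding.csv",
        "grouped": run_dir / "results" / "grouped.csv",
        "semipartial": run_dir / "results" / "semipartial.csv",
        "permtests": run_dir / "results" / "permtests.csv",
        "report": run_dir / "report",
    }


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, run_dir: Path, seed: int) -> None:
    run_dir.joinpath("data").mkdir(parents=True, exist_ok=True)
    p = _paths(run_dir)
    template = make_skeleton_template()
    rng = np.random.default_rng(seed)

    latents = sample_scene_latents(config.n_videos, config.scene,
                                   seed=int(rng.integers(2 ** 31)))
    ratings = generate_ratings(latents, config.weights, config.n_raters,
                               config.rater_sd,
                               seed=int(rng.integers(2 ** 31)),
                               train_fraction=config.train_fraction)
    spio.write_ratings(p["ratings"], ratings)

    tracks = []
    for lat in latents:
        t0, t1 = render_joint_tracks(lat, template, config.noise,
                                     frames=config.frames,
                                     seed=int(rng.integers(2 ** 31)))
        tracks.extend([t0, t1])
    spio.write_joint_tracks(p["joints_h5"], tracks)

    if config.with_embeddings:
        tables = build_feature_tables(tracks, template)
        sets = []
        levels = (np.linspace(0.0, 1.0, config.n_models)
                  if config.n_models > 1 else np.array([0.5]))
        for m, info in enumerate(levels):
            for layer in range(config.n_layers):
                # deeper synthetic "layers" carry progressively less pose info
                lvl = float(info) * (0.6 ** layer)
                sets.append(generate_embeddings(
                    tables.pose3d, info_level=lvl, dim=config.embedding_dim,
                    seed=int(rng.integers(2 ** 31)),
                    model_name=f"model_{m:03d}", layer_name=f"layer{layer}"))
        spio.write_embeddings(p["embeddings"], sets)
    log.info("simulate: %d videos written to %s", config.n_videos, run_dir)


def stage_features(config: RunConfig, run_dir: Path, seed: int) -> None:
    p = _paths(run_dir)
    run_dir.joinpath("features").mkdir(parents=True, exist_ok=True)
    tracks = spio.read_joint_tracks(p["joints_h5"])
    tables = build_feature_tables(tracks, make_skeleton_template())
    spio.write_feature_table(p["feat_joints"], tables.joints)
    spio.write_feature_table(p["feat_pose3d"], tables.pose3d)
    spio.write_feature_table(p["feat_pose2d"], tables.pose2d)
    kept = tables.joints.shape[0]
    log.info("features: %d videos kept, %d excluded", kept,
             len({t.video_id for t in tracks}) - kept)


def _load_analysis_set(p: dict[str, Path]):
    ratings = spio.read_ratings(p["ratings"]).set_index("video_id")
    feats = {name: spio.read_feature_table(p[f"feat_{name}"])
             for name in ("joints", "pose3d", "pose2d")}
    vids = list(feats["pose3d"].index)  # kept videos, generation order
    ratings = ratings.loc[vids]
    train_idx = np.flatnonzero((ratings["split"] == "train").to_numpy())
    test_idx = np.flatnonzero((ratings["split"] == "test").to_numpy())
    return ratings, feats, vids, train_idx, test_idx


def _load_models(p: dict[str, Path], vids: list[str], config: RunConfig):
    """Embedding matrices per model/layer, aligned to the kept videos and
    projected to the JL dimension when wider."""
    sets = spio.read_embeddings(p["embeddings"])
    jl = jl_min_dim(len(vids), config.eps)
    models: dict[str, dict[str, np.ndarray]] = {}
    for s in sets:
        pos = pd.Index(s.video_index).get_indexer(vids)
        if (pos < 0).any():
            raise ValueError("embedding video index does not cover features")
        X = sparse_random_projection(s.matrix[pos], jl, seed=config.seed)
        models.setdefault(s.model_name, {})[s.layer_name] = X
    return models


def stage_encode(config: RunConfig, run_dir: Path, seed: int) -> None:
    p = _paths(run_dir)
    run_dir.joinpath("results").mkdir(parents=True, exist_ok=True)
    ratings, feats, vids, tr, te = _load_analysis_set(p)
    alphas = config.alphas()
    records, pred_rows = [], []
    rng = np.random.default_rng(seed)

    def keep(res, preds):
        records.append(res.to_record())
        for vid, val in zip(np.array(vids)[te], preds):
            pred_rows.append({"target": res.target,
                              "source": res.feature_source,
                              "video_id": vid, "pred": float(val)})

    for target in RATING_COLUMNS:
        y = ratings[target].to_numpy(float)
        for name in ("joints", "pose3d", "pose2d"):
            X = feats[name].to_numpy(float)
            res = encode_feature_set(
                X, y, tr, te, target=target, feature_source=name,
                alphas=alphas, folds=config.folds, repeats=config.repeats,
                seed=int(rng.integers(2 ** 31)))
            keep(res, fit_predict(X[tr], y[tr], X[te], res.chosen_alpha))

    decode_rows = []
    if config.with_embeddings and p["embeddings"].exists():
        models = _load_models(p, vids, config)
        for target in RATING_COLUMNS:
            y = ratings[target].to_numpy(float)
            for mname, layers in sorted(models.items()):
                res = encode_with_layer_selection(
                    layers, y, tr, te, target=target, feature_source=mname,
                    alphas=alphas, folds=config.folds,
                    repeats=config.repeats,
                    seed=int(rng.integers(2 ** 31)))
                X = layers[res.chosen_layer]
                keep(res, fit_predict(X[tr], y[tr], X[te], res.chosen_alpha))
                # decode social pose features from the selected layer
                d3 = decode_features(X, feats["pose3d"].to_numpy(float),
                                     tr, te, alphas=alphas,
                                     folds=config.folds,
                                     repeats=config.repeats,
                                     seed=int(rng.integers(2 ** 31)))
                d2 = decode_features(X, feats["pose2d"].to_numpy(float),
                                     tr, te, alphas=alphas,
                                     folds=config.folds,
                                     repeats=config.repeats,
                                     seed=int(rng.integers(2 ** 31)))
                decode_rows.append({"model": mname, "target": target,
                                    "layer": res.chosen_layer,
                                    "rating_r": res.test_r,
                                    "decode3d_r": d3, "decode2d_r": d2})
    elif config.with_embeddings:
        log.info("encode: no embeddings file; model stages skipped")

    pd.DataFrame(records).to_csv(p["encoding"], index=False)
    pd.DataFrame(pred_rows).to_csv(p["predictions"], index=False)
    pd.DataFrame(decode_rows).to_csv(p["decoding"], index=False)
    log.info("encode: %d fits written", len(records))


def stage_grouped(config: RunConfig, run_dir: Path, seed: int) -> None:
    p = _paths(run_dir)
    if not (config.with_embeddings and p["embeddings"].exists()):
        log.info("grouped: no embeddings; stage skipped")
        pd.DataFrame().to_csv(p["grouped"], index=False)
        return
    ratings, feats, vids, tr, te = _load_analysis_set(p)
    enc = pd.read_csv(p["encoding"])
    models = _load_models(p, vids, config)
    pose = feats["pose3d"].to_numpy(float)
    rng = np.random.default_rng(seed)
    rows = []
    for target in RATING_COLUMNS:
        y = ratings[target].to_numpy(float)
        for mname in sorted(models):
            sel = enc.query("target == @target and feature_source == @mname")
            layer = sel["layer"].iloc[0]
            alone_r = float(sel["test_r"].iloc[0])
            X = models[mname][layer]
            res = grouped_ridge_search(
                {"embedding": X[tr], "pose3d": pose[tr]},
                {"embedding": X[te], "pose3d": pose[te]},
                y[tr], y[te], n_gamma=config.n_gamma,
                concentrations=config.concentrations,
                alphas=config.alphas(), folds=config.folds,
                seed=int(rng.integers(2 ** 31)))
            rows.append({"target": target, "model": mname, "layer": layer,
                         "alone_r": alone_r, "combined_r": res.test_r,
                         **res.to_record()})
    pd.DataFrame(rows).to_csv(p["grouped"], index=False)
    log.info("grouped: %d fits written", len(rows))


def stage_semipartial(config: RunConfig, run_dir: Path, seed: int) -> None:
    p = _paths(run_dir)
    ratings, feats, vids, tr, te = _load_analysis_set(p)
    J = feats["joints"].to_numpy(float)
    predictor_sets = {
        "positions": feats["pose3d"][POSITION_COLUMNS].to_numpy(float),
        "directions": feats["pose3d"][DIRECTION_COLUMNS].to_numpy(float),
        "pose3d": feats["pose3d"].to_numpy(float),
    }
    rng = np.random.default_rng(seed)
    rows = []
    for pname, P in predictor_sets.items():
        resid = semipartial_residualize(
            J[tr], J[te], P[tr], P[te], predictor_name=pname,
            alphas=config.alphas(), folds=config.folds,
            seed=int(rng.integers(2 ** 31)))
        for target in RATING_COLUMNS:
            y = ratings[target].to_numpy(float)
            res = semipartial_encode(
                resid, y[tr], y[te], target=target, alphas=config.alphas(),
                folds=config.folds, repeats=config.repeats,
                seed=int(rng.integers(2 ** 31)))
            rows.append({"predictor": pname, "target": target,
                         "residual_alpha": resid.alpha,
                         "test_r": res.test_r})
    pd.DataFrame(rows).to_csv(p["semipartial"], index=False)
    log.info("semipartial: %d fits written", len(rows))


def stage_permtest(config: RunConfig, run_dir: Path, seed: int) -> None:
    p = _paths(run_dir)
    ratings, feats, vids, tr, te = _load_analysis_set(p)
    preds = pd.read_csv(p["predictions"])
    enc = pd.read_csv(p["encoding"])
    rng = np.random.default_rng(seed)
    rows = []

    def add(test_name, target, result):
        rows.append({"test": test_name, "target": target,
                     "observed": result.observed, "p": result.p_value,
                     "tails": result.tails, "n_perm": result.n_perm,
                     "seed": result.seed})

    have_models = (enc["feature_source"]
                   .str.startswith("model_").any()) if len(enc) else False
    have_grouped = p["grouped"].exists() and p["grouped"].stat().st_size > 2
    grouped = pd.read_csv(p["grouped"]) if have_grouped else pd.DataFrame()
    decoding = (pd.read_csv(p["decoding"])
                if p["decoding"].exists() and p["decoding"].stat().st_size > 2
                else pd.DataFrame())

    test_vids = np.array(vids)[te]
    for target in RATING_COLUMNS:
        y_test = ratings[target].loc[test_vids].to_numpy(float)
        tp = preds.query("target == @target").pivot(
            index="source", columns="video_id", values="pred")[test_vids]
        if have_models:
            model_rows = tp.index[tp.index.str.startswith("model_")]
            add("models_vs_pose3d", target, perm_group_vs_single(
                tp.loc[model_rows].to_numpy(), tp.loc["pose3d"].to_numpy(),
                y_test, n_perm=config.n_perm,
                seed=int(rng.integers(2 ** 31))))
        if len(decoding) and decoding["model"].nunique() >= 3:
            d = decoding.query("target == @target").sort_values("model")
            add("decode3d_vs_rating_corr", target, perm_correlation(
                d["decode3d_r"].to_numpy(), d["rating_r"].to_numpy(),
                n_perm=config.n_perm, tails="two",
                seed=int(rng.integers(2 ** 31))))
            add("decode3d_minus_decode2d_corr", target, perm_corr_difference(
                d["decode3d_r"].to_numpy(), d["decode2d_r"].to_numpy(),
                d["rating_r"].to_numpy(), n_perm=config.n_perm,
                seed=int(rng.integers(2 ** 31))))
        if len(grouped):
            g = grouped.query("target == @target").sort_values("model")
            add("pose3d_augmentation", target, perm_paired_improvement(
                g["alone_r"].to_numpy(), g["combined_r"].to_numpy(),
                n_perm=config.n_perm, seed=int(rng.integers(2 ** 31))))
    pd.DataFrame(rows).to_csv(p["permtests"], index=False)
    log.info("permtest: %d tests written", len(rows))


def stage_report(config: RunConfig, run_dir: Path, seed: int = 0) -> None:
    p = _paths(run_dir)
    p["report"].mkdir(parents=True, exist_ok=True)
    enc = pd.read_csv(p["encoding"])
    perms = (pd.read_csv(p["permtests"])
             if p["permtests"].exists() and p["permtests"].stat().st_size > 2
             else pd.DataFrame())

    fig3 = enc[enc["feature_source"].isin(["joints", "pose3d", "pose2d"])][
        ["target", "feature_source", "test_r"]]
    fig3.to_csv(p["report"] / "fig3_table.csv", index=False)

    model_enc = enc[enc["feature_source"].str.startswith("model_")]
    if len(model_enc):
        pose_r = enc.query("feature_source == 'pose3d'").set_index("target")
        fig2 = model_enc[["target", "feature_source", "layer", "test_r"]].copy()
        fig2["pose3d_r"] = fig2["target"].map(pose_r["test_r"])
        if len(perms):
            pmap = perms.query("test == 'models_vs_pose3d'").set_index("target")
            fig2["perm_p"] = fig2["target"].map(pmap["p"])
        fig2.to_csv(p["report"] / "fig2_table.csv", index=False)

    if p["decoding"].exists() and p["decoding"].stat().st_size > 2:
        fig4 = pd.read_csv(p["decoding"])
        if len(perms):
            pmap = perms.query("test == 'decode3d_vs_rating_corr'") \
                        .set_index("target")
            fig4["perm_p"] = fig4["target"].map(pmap["p"])
        fig4.to_csv(p["report"] / "fig4_table.csv", index=False)

    if p["grouped"].exists() and p["grouped"].stat().st_size > 2:
        fig5 = pd.read_csv(p["grouped"])
        if len(fig5):
            fig5["improvement"] = fig5["combined_r"] - fig5["alone_r"]
            frac = fig5.groupby("target")["improvement"] \
                       .apply(lambda s: float((s > 0).mean()))
            fig5["fraction_models_improved"] = fig5["target"].map(frac)
            if len(perms):
                pmap = perms.query("test == 'pose3d_augmentation'") \
                            .set_index("target")
                fig5["perm_p"] = fig5["target"].map(pmap["p"])
            fig5.to_csv(p["report"] / "fig5_table.csv", index=False)
    log.info("report: tables written to %s", p["report"])


_STAGE_FUNCS = {
    "simulate": stage_simulate, "features": stage_features,
    "encode": stage_encode, "grouped": stage_grouped,
    "semipartial": stage_semipartial, "permtest": stage_permtest,
    "report": stage_report,
}


def run_full_pipeline(config: RunConfig, run_dir: str | Path) -> Path:
    """Execute every stage in order and write a run manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    from . import __version__
    manifest = {"config": config.to_dict(), "stage_seeds": seeds,
                "package_version": __version__}
    with open(run_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=float)
    for name in _STAGES:
        log.info("stage %s (seed %d)", name, seeds[name])
        _STAGE_FUNCS[name](config, run_dir, seeds[name])
    return run_dir
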