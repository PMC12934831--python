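"""Permutation tests and the semi-partial (residualization) analysis.

Four nonparametric tests, each with 5,000 permutations by default and a
p-value floor of 1/n_perm (so the smallest reportable p is 0.0002):

* group-vs-single: is the mean test correlation of a population of models
  different from a single reference model?  Null built by shuffling the
  held-out ratings against the fixed predictions (two-tailed).
* paired improvement: does adding a feature group improve each model's
  score?  Null by randomly swapping each (alone, combined) pair
  (one-tailed).
* score correlation: is the correlation between two per-model score
  vectors nonzero?  Null by shuffling one vector (two-tailed).
* correlation difference: is r(scores_3d, human) larger than
  r(scores_2d, human)?  Null by independently shuffling both score
  vectors (one-tailed).

The semi-partial analysis regresses the 270-dim joint features on a
smaller predictor set (ridge, one CV-chosen alpha shared across outputs),
subtracts the prediction, and re-encodes the ratings from the residuals:
the residual test r measures joint information beyond the predictor set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .encoding import (
    Standardizer, _cv_folds, _pearson_paired_columns,
    _ridge_path_predictions, alpha_grid, encode_feature_set, EncodingResult,
    pearson_r,
)

__all__ = [
    "PermutationResult", "perm_group_vs_single", "perm_paired_improvement",
    "perm_correlation", "perm_corr_difference", "semipartial_residualize",
    "semipartial_encode", "ResidualJointFeatures",
]


@dataclass
class PermutationResult:
    """A permutation test outcome: observed statistic, null draws, and the
    floored Monte-Carlo p-value max(count, 1) / n_perm."""

    statistic_name: str
    observed: float
    null_draws: np.ndarray = field(repr=False)
    p_value: float
    tails: str  # "one" | "two"
    n_perm: int
    seed: int


def _mc_p(null: np.ndarray, observed: float, tails: str) -> float:
    if tails == "two":
        count = int(np.sum(np.abs(null) >= abs(observed)))
    elif tails == "one":
        count = int(np.sum(null >= observed))
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return max(count, 1) / len(null)


def _row_zscore(M: np.ndarray) -> np.ndarray:
    c = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    return c / np.where(norms == 0, 1.0, norms)


def perm_group_vs_single(
    model_preds: np.ndarray, single_pred: np.ndarray, y_test: np.ndarray,
    n_perm: int = 5000, seed: int = 0,
) -> PermutationResult:
    """Two-tailed test of mean model-population r minus single-model r.

    ``model_preds`` is (n_models, n_test); predictions stay fixed while the
    ratings are shuffled ``n_perm`` times and every correlation recomputed.
    """
    model_preds = np.atleast_2d(np.asarray(model_preds, float))
    single_pred = np.asarray(single_pred, float).ravel()
    y_test = np.asarray(y_test, float).ravel()
    if model_preds.shape[1] != y_test.size or single_pred.size != y_test.size:
        raise ValueError("prediction vectors must align with y_test")

    P = _row_zscore(np.vstack([model_preds, single_pred[None, :]]))
    yz = _row_zscore(y_test[None, :])[0]
    r_obs = P @ yz
    observed = float(r_obs[:-1].mean() - r_obs[-1])

    rng = np.random.default_rng(seed)
    Y = rng.permuted(np.broadcast_to(y_test, (n_perm, y_test.size)).copy(),
                     axis=1)
    R = P @ _row_zscore(Y).T                       # (models+1, n_perm)
    null = R[:-1].mean(axis=0) - R[-1]
    return PermutationResult(
        statistic_name="mean_model_r_minus_single_r", observed=observed,
        null_draws=null, p_value=_mc_p(null, observed, "two"),
        tails="two", n_perm=n_perm, seed=seed,
    )


def perm_paired_improvement(
    r_alone: np.ndarray, r_combined: np.ndarray,
    n_perm: int = 5000, seed: int = 0, exact: bool = False,
) -> PermutationResult:
    """One-tailed paired test of mean(r_combined - r_alone) > 0.

    The null randomly swaps each pair (equivalently, flips the sign of each
    difference) independently with probability one half.  ``exact=True``
    enumerates all 2^m sign patterns instead (m <= 20).
    """
    d = np.asarray(r_combined, float) - np.asarray(r_alone, float)
    if d.ndim != 1:
        raise ValueError("scores must be equal-length vectors")
    observed = float(d.mean())
    rng = np.random.default_rng(seed)
    if exact:
        if d.size > 20:
            raise ValueError("exact enumeration limited to <= 20 pairs")
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=d.size)))
        null = signs @ d / d.size
        count = int(np.sum(null >= observed - 1e-12))
        p = count / len(null)
        n_eff = len(null)
    else:
        signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
        null = signs @ d / d.size
        p = _mc_p(null, observed, "one")
        n_eff = n_perm
    return PermutationResult(
        statistic_name="mean_paired_improvement", observed=observed,
        null_draws=null, p_value=p, tails="one", n_perm=n_eff, seed=seed,
    )


def perm_correlation(
    scores_x: np.ndarray, scores_y: np.ndarray,
    n_perm: int = 5000, tails: str = "two", seed: int = 0,
    exact: bool = False,
) -> PermutationResult:
    """Permutation test of the Pearson correlation between two per-model
    score vectors; null by shuffling ``scores_x``.  ``exact=True``
    enumerates all permutations (n <= 8)."""
    x = np.asarray(scores_x, float).ravel()
    y = np.asarray(scores_y, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length score vectors, n >= 3")
    observed = pearson_r(x, y)
    rng = np.random.default_rng(seed)
    yz = _row_zscore(y[None, :])[0]
    if exact:
        if x.size > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(x.size))))
        null = _row_zscore(x[perms]) @ yz
        if tails == "two":
            count = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
        else:
            count = int(np.sum(null >= observed - 1e-12))
        p = count / len(null)
        n_eff = len(null)
    else:
        X = rng.permuted(np.broadcast_to(x, (n_perm, x.size)).copy(), axis=1)
        null = _row_zscore(X) @ yz
        p = _mc_p(null, observed, tails)
        n_eff = n_perm
    return PermutationResult(
        statistic_name="score_correlation", observed=observed,
        null_draws=null, p_value=p, tails=tails, n_perm=n_eff, seed=seed,
    )


def perm_corr_difference(
    scores_3d: np.ndarray, scores_2d: np.ndarray, scores_human: np.ndarray,
    n_perm: int = 5000, seed: int = 0,
) -> PermutationResult:
    """One-tailed test of delta_r = r(scores_3d, human) - r(scores_2d, human).

    Each permutation independently shuffles the 3D and the 2D score vectors
    across models, breaking both relationships with the human scores.
    """
    s3 = np.asarray(scores_3d, float).ravel()
    s2 = np.asarray(scores_2d, float).ravel()
    h = np.asarray(scores_human, float).ravel()
    if not (s3.size == s2.size == h.size):
        raise ValueError("score vectors must have equal length")
    observed = pearson_r(s3, h) - pearson_r(s2, h)
    rng = np.random.default_rng(seed)
    hz = _row_zscore(h[None, :])[0]
    S3 = rng.permuted(np.broadcast_to(s3, (n_perm, s3.size)).copy(), axis=1)
    S2 = rng.permuted(np.broadcast_to(s2, (n_perm, s2.size)).copy(), axis=1)
    null = _row_zscore(S3) @ hz - _row_zscore(S2) @ hz
    return PermutationResult(
        statistic_name="r3d_minus_r2d", observed=float(observed),
        null_draws=null, p_value=_mc_p(null, observed, "one"),
        tails="one", n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# semi-partial (residualization) analysis

@dataclass
class ResidualJointFeatures:
    """Joint features minus their ridge prediction from a predictor set.

    Residuals are in the original joint units, aligned row-wise with the
    input; ``alpha`` is the single CV-chosen penalty shared across the 270
    outputs, ``predictor_name`` records provenance.
    """

    residual_train: np.ndarray
    residual_test: np.ndarray
    predictor_name: str
    alpha: float


def semipartial_residualize(
    joints_train: np.ndarray, joints_test: np.ndarray,
    pred_train: np.ndarray, pred_test: np.ndarray,
    predictor_name: str = "predictors",
    alphas: np.ndarray | None = None,
    folds: int = 5, seed: int = 0,
) -> ResidualJointFeatures:
    """Residualize joint features on a predictor feature set.

    A multi-output ridge maps the (standardized) predictors to the
    (centered) joints; the penalty is chosen by K-fold validation on the
    training rows, maximizing the mean validation r across outputs, and is
    shared by all outputs so the residualizer stays a single linear map.
    Residuals for train and test both use the train-fitted map.
    """
    J_tr = np.asarray(joints_train, float)
    J_te = np.asarray(joints_test, float)
    X_tr = np.asarray(pred_train, float)
    X_te = np.asarray(pred_test, float)
    if J_tr.shape[0] != X_tr.shape[0] or J_te.shape[0] != X_te.shape[0]:
        raise ValueError("joint and predictor rows misaligned")
    alphas = alpha_grid() if alphas is None else np.asarray(alphas, float)

    sums = np.zeros(len(alphas))
    n_folds = 0
    for tr, va in _cv_folds(J_tr.shape[0], folds, repeats=1, seed=seed):
        x_std = Standardizer.fit(X_tr[tr])
        j_mean = J_tr[tr].mean(axis=0)
        preds = _ridge_path_predictions(
            x_std.transform(X_tr[tr]), J_tr[tr] - j_mean,
            x_std.transform(X_tr[va]), alphas)       # (A, m, 270)
        for ai in range(len(alphas)):
            sums[ai] += float(np.mean(
                _pearson_paired_columns(preds[ai], J_tr[va])))
        n_folds += 1
    # prefer the least regularization whose validation score is within a
    # small tolerance of the best: ridge shrinkage bias leaves a residual
    # component proportional (and perfectly correlated) to the predictor
    # signal, which would defeat the purpose of removing it
    scores = sums / n_folds
    good = np.flatnonzero(scores >= scores.max() - 1e-3)
    alpha = float(alphas[int(good[0])])

    x_std = Standardizer.fit(X_tr)
    j_mean = J_tr.mean(axis=0)
    Xs_tr = x_std.transform(X_tr)
    U, s, Vt = np.linalg.svd(Xs_tr, full_matrices=False)
    d = s / (s ** 2 + alpha)
    W = Vt.T @ (d[:, None] * (U.T @ (J_tr - j_mean)))
    fit_tr = Xs_tr @ W + j_mean
    fit_te = x_std.transform(X_te) @ W + j_mean
    res_tr = J_tr - fit_tr
    res_te = J_te - fit_te
    # residual columns at the numerical-noise floor of the fit carry no
    # information (only regularization-bias rounding); zero them so they
    # cannot masquerade as signal after downstream standardization
    floor = 1e-8 * np.maximum(J_tr.std(axis=0), np.finfo(float).tiny)
    dead = res_tr.std(axis=0) <= floor
    res_tr[:, dead] = 0.0
    res_te[:, dead] = 0.0
    return ResidualJointFeatures(
        residual_train=res_tr, residual_test=res_te,
        predictor_name=predictor_name, alpha=alpha,
    )


def semipartial_encode(
    residuals: ResidualJointFeatures,
    y_train: np.ndarray, y_test: np.ndarray,
    target: str = "target",
    alphas: np.ndarray | None = None,
    folds: int = 5, repeats: int = 2, seed: int = 0,
) -> EncodingResult:
    """Encode ratings from residualized joint features; the test r measures
    unique joint information beyond the predictor set."""
    X = np.vstack([residuals.residual_train, residuals.residual_test])
    y = np.concatenate([np.asarray(y_train, float).ravel(),
                        np.asarray(y_test, float).ravel()])
    n_tr = residuals.residual_train.shape[0]
    res = encode_feature_set(
        X, y, np.arange(n_tr), np.arange(n_tr, len(y)),
        target=target,
        feature_source=f"joints_residualized_on_{residuals.predictor_name}",
        alphas=alphas, folds=folds, repeats=repeats, seed=seed,
    )
    return res
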