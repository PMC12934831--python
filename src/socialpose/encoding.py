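"""Ridge-regression encoding framework.

The pipeline that scores how well a feature set predicts behavioral
ratings: z-score normalization fit on training rows only, ridge regression
with the regularization strength chosen from a log-spaced grid
(1e-10..1e10) by five-fold cross-validation repeated twice, sparse random
projection to the Johnson-Lindenstrauss dimension for very wide embedding
matrices, Pearson-r scoring on a held-out test split, and a grouped
(banded) ridge that learns a per-group weighting of two feature spaces via
Dirichlet random search.

All selection (layer, alpha, gamma) depends only on training rows; the
test split enters exactly once, in the final evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.random_projection import SparseRandomProjection

__all__ = [
    "Standardizer", "zscore_fit_apply", "alpha_grid", "jl_min_dim",
    "sparse_random_projection", "ridge_solve", "pearson_r", "cv_select",
    "fit_evaluate", "encode_feature_set", "grouped_ridge_search",
    "EncodingResult", "GroupedRidgeResult",
]


# ---------------------------------------------------------------------------
# normalization

@dataclass
class Standardizer:
    """Column z-scoring fit on the training split (population SD, ddof=0).

    Zero-variance columns are mapped to zeros rather than raising."""

    mean_: np.ndarray
    scale_: np.ndarray  # 0 where the training column was constant

    @classmethod
    def fit(cls, train: np.ndarray) -> "Standardizer":
        train = np.atleast_2d(np.asarray(train, float))
        if train.shape[0] < 1:
            raise ValueError("empty training matrix")
        return cls(mean_=train.mean(axis=0), scale_=train.std(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        safe = np.where(self.scale_ == 0, 1.0, self.scale_)
        out = (X - self.mean_) / safe
        out[:, self.scale_ == 0] = 0.0
        return out


def zscore_fit_apply(train: np.ndarray, *others: np.ndarray):
    """Standardize ``train`` per column and apply the same map to ``others``.

    Returns ``(train_std, *others_std, standardizer)``.
    """
    std = Standardizer.fit(train)
    if np.atleast_2d(train).shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    return (std.transform(train), *(std.transform(o) for o in others), std)


# ---------------------------------------------------------------------------
# grids and projections

def alpha_grid(n_points: int = 21) -> np.ndarray:
    """Log10-equispaced regularization grid from 1e-10 to 1e10 inclusive."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    return np.logspace(-10, 10, n_points)


def jl_min_dim(n_samples: int, eps: float) -> int:
    """Johnson-Lindenstrauss minimum embedding dimension.

    floor(4 ln(n) / (eps^2/2 - eps^3/3)); e.g. 4732 for n=250, eps=0.1.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not 0 < eps < 1:
        raise ValueError("eps must be in (0, 1)")
    return int(4.0 * np.log(n_samples) / (eps ** 2 / 2 - eps ** 3 / 3))


def sparse_random_projection(
    X: np.ndarray, n_components: int, seed: int = 0
) -> np.ndarray:
    """Achlioptas-style sparse random projection to ``n_components``.

    Entries are {-1, 0, +1} * sqrt(1 / (density * n_components)) with
    nonzero density 1/sqrt(d).  Applied only when the input is wider than
    ``n_components``; otherwise the input is returned unchanged.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = np.asarray(X, float)
    if X.shape[1] <= n_components:
        return X
    srp = SparseRandomProjection(
        n_components=n_components, density="auto", random_state=seed)
    return srp.fit_transform(X)


# ---------------------------------------------------------------------------
# ridge primitives

def ridge_solve(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form ridge weights: the minimizer of ||y - Xw||^2 + a||w||^2.

    No intercept; callers standardize first.  At alpha=0 this is the
    minimum-norm least-squares solution.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs to ridge_solve")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    uty = U.T @ y
    if alpha == 0:
        tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
        d = np.divide(1.0, s, out=np.zeros_like(s), where=s > tol)
    else:
        d = s / (s ** 2 + alpha)
    return Vt.T @ (d * uty)


def _ridge_path_predictions(
    X_tr: np.ndarray, Y_tr: np.ndarray, X_out: np.ndarray, alphas: np.ndarray
) -> np.ndarray:
    """Predictions of ridge fits at every alpha, via one SVD of X_tr.

    Y_tr may be (n,) or (n, m) multi-output.  Returns an array of shape
    (len(alphas), n_out_rows[, m]).
    """
    U, s, Vt = np.linalg.svd(X_tr, full_matrices=False)
    uty = U.T @ Y_tr                      # (k,[ m])
    xov = X_out @ Vt.T                    # (n_out, k)
    d = s[None, :] / (s[None, :] ** 2 + np.asarray(alphas)[:, None])  # (A, k)
    if uty.ndim == 1:
        return np.einsum("ok,ak,k->ao", xov, d, uty)
    return np.einsum("ok,ak,km->aom", xov, d, uty)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation; zero-variance input warns and returns 0."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 2")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        warnings.warn("zero-variance input to pearson_r; returning r = 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(np.clip(da @ db / (na * nb), -1.0, 1.0))


def _pearson_columns(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each column of ``pred`` (n, k) and ``y`` (n,).
    Zero-variance columns score 0."""
    pc = pred - pred.mean(axis=0)
    yc = y - y.mean()
    denom = np.linalg.norm(pc, axis=0) * np.linalg.norm(yc)
    num = pc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom == 0, 1, denom), 0.0)
    return np.clip(r, -1.0, 1.0)


def _pearson_paired_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n, k) matrices;
    zero-variance pairs score 0."""
    ac = A - A.mean(axis=0)
    bc = B - B.mean(axis=0)
    denom = np.linalg.norm(ac, axis=0) * np.linalg.norm(bc, axis=0)
    num = np.einsum("nk,nk->k", ac, bc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom == 0, 1, denom), 0.0)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# cross-validated selection and evaluation

def _cv_folds(n: int, folds: int, repeats: int, seed: int):
    """Seeded shuffled K-fold indices, ``repeats`` distinct shuffles."""
    if folds > n:
        raise ValueError("more folds than training rows")
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        order = rng.permutation(n)
        for chunk in np.array_split(order, folds):
            val = np.sort(chunk)
            tr = np.setdiff1d(order, val)
            yield tr, val


def cv_select(
    candidates: dict[str, np.ndarray],
    y: np.ndarray,
    folds: int = 5,
    repeats: int = 2,
    alphas: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[str, float, pd.DataFrame]:
    """Choose the best (candidate, alpha) by repeated K-fold validation r.

    Within each fold, features and target are z-scored with statistics from
    the fold's training rows.  The score is the unweighted mean validation
    Pearson r over all fold-fits.  Ties break toward the smaller alpha,
    then the lexicographically smaller candidate name.
    """
    if not candidates:
        raise ValueError("no candidates")
    alphas = alpha_grid() if alphas is None else np.asarray(alphas, float)
    y = np.asarray(y, float).ravel()
    names = sorted(candidates)
    sums = {name: np.zeros(len(alphas)) for name in names}
    n_fits = 0
    for tr, va in _cv_folds(len(y), folds, repeats, seed):
        y_std = Standardizer.fit(y[tr, None])
        y_tr = y_std.transform(y[tr, None]).ravel()
        n_fits += 1
        for name in names:
            X = np.asarray(candidates[name], float)
            x_std = Standardizer.fit(X[tr])
            preds = _ridge_path_predictions(
                x_std.transform(X[tr]), y_tr, x_std.transform(X[va]), alphas)
            sums[name] += np.array(
                [_safe_r(p, y[va]) for p in preds])
    table = pd.DataFrame(
        [(name, float(a), sums[name][i] / n_fits)
         for name in names for i, a in enumerate(alphas)],
        columns=["candidate", "alpha", "mean_val_r"],
    )
    # argmax with deterministic tie-breaking: score desc, alpha asc, name asc
    best = table.sort_values(
        ["mean_val_r", "alpha", "candidate"],
        ascending=[False, True, True], kind="stable",
    ).iloc[0]
    return str(best["candidate"]), float(best["alpha"]), table


def _safe_r(pred: np.ndarray, y: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pearson_r(pred, y)


@dataclass
class EncodingResult:
    """Outcome of one encoding fit: provenance plus the held-out test r."""

    target: str
    feature_source: str
    chosen_layer: str | None
    chosen_alpha: float
    test_r: float
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_record(self) -> dict:
        return {
            "target": self.target, "feature_source": self.feature_source,
            "layer": self.chosen_layer, "alpha": self.chosen_alpha,
            "test_r": self.test_r,
        }


def fit_predict(
    X_train: np.ndarray, y_train: np.ndarray,
    X_test: np.ndarray, alpha: float,
) -> np.ndarray:
    """Standardize on the full training split, fit ridge at ``alpha``, and
    return test predictions (in standardized target units)."""
    X_train, X_test = np.asarray(X_train, float), np.asarray(X_test, float)
    y_train = np.asarray(y_train, float).ravel()
    x_std = Standardizer.fit(X_train)
    y_std = Standardizer.fit(y_train[:, None])
    w = ridge_solve(x_std.transform(X_train),
                    y_std.transform(y_train[:, None]).ravel(), alpha)
    return x_std.transform(X_test) @ w


def fit_evaluate(
    X_train: np.ndarray, y_train: np.ndarray,
    X_test: np.ndarray, y_test: np.ndarray, alpha: float,
) -> float:
    """Standardize on the full training split, fit ridge at ``alpha``,
    and return the Pearson r between test predictions and test targets."""
    pred = fit_predict(X_train, y_train, X_test, alpha)
    return pearson_r(pred, np.asarray(y_test, float).ravel())


def encode_feature_set(
    X: np.ndarray, y: np.ndarray,
    train_idx: np.ndarray, test_idx: np.ndarray,
    target: str = "target", feature_source: str = "features",
    alphas: np.ndarray | None = None,
    folds: int = 5, repeats: int = 2, seed: int = 0,
) -> EncodingResult:
    """Full single-feature-set pipeline: CV alpha selection on the training
    rows, refit on the full training split, score on the test split."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    _, alpha, table = cv_select({feature_source: X[train_idx]}, y[train_idx],
                                folds=folds, repeats=repeats, alphas=alphas,
                                seed=seed)
    r = fit_evaluate(X[train_idx], y[train_idx], X[test_idx], y[test_idx],
                     alpha)
    return EncodingResult(target=target, feature_source=feature_source,
                          chosen_layer=None, chosen_alpha=alpha, test_r=r,
                          cv_table=table)


def encode_with_layer_selection(
    layers: dict[str, np.ndarray], y: np.ndarray,
    train_idx: np.ndarray, test_idx: np.ndarray,
    target: str = "target", feature_source: str = "model",
    alphas: np.ndarray | None = None,
    folds: int = 5, repeats: int = 2, seed: int = 0,
) -> EncodingResult:
    """Layer-selection pipeline for multi-layer embedding models.

    The best (layer, alpha) pair is chosen by repeated K-fold validation on
    the training split; the chosen layer is refit on the full training
    split at its best alpha and scored on the test split.
    """
    y = np.asarray(y, float).ravel()
    layer, alpha, table = cv_select(
        {k: np.asarray(v, float)[train_idx] for k, v in layers.items()},
        y[train_idx], folds=folds, repeats=repeats, alphas=alphas, seed=seed)
    X = np.asarray(layers[layer], float)
    r = fit_evaluate(X[train_idx], y[train_idx], X[test_idx], y[test_idx],
                     alpha)
    return EncodingResult(target=target, feature_source=feature_source,
                          chosen_layer=layer, chosen_alpha=alpha, test_r=r,
                          cv_table=table)


# ---------------------------------------------------------------------------
# grouped (banded) ridge with Dirichlet random search

@dataclass
class GroupedRidgeResult:
    """Grouped-ridge fit: selected group weights (on the simplex), shared
    alpha, and held-out test r."""

    gamma: dict[str, float]
    alpha: float
    test_r: float
    mean_val_r: float

    def to_record(self) -> dict:
        rec = {"alpha": self.alpha, "test_r": self.test_r,
               "mean_val_r": self.mean_val_r}
        rec.update({f"gamma_{k}": v for k, v in self.gamma.items()})
        return rec


def _draw_gammas(n_groups: int, n_gamma: int, concentrations, rng) -> np.ndarray:
    per = n_gamma // len(concentrations)
    draws = [rng.dirichlet(np.full(n_groups, c), size=per)
             for c in concentrations]
    rest = n_gamma - per * len(concentrations)
    if rest:
        draws.append(rng.dirichlet(np.full(n_groups, concentrations[-1]),
                                   size=rest))
    return np.vstack(draws)


def grouped_ridge_search(
    groups_train: dict[str, np.ndarray],
    groups_test: dict[str, np.ndarray],
    y_train: np.ndarray, y_test: np.ndarray,
    n_gamma: int = 200,
    concentrations: tuple[float, ...] = (0.1, 1.0),
    alphas: np.ndarray | None = None,
    folds: int = 5,
    repeats: int = 2,
    seed: int = 0,
) -> GroupedRidgeResult:
    """Banded ridge over feature groups via Dirichlet random search.

    Candidate group weightings gamma are sampled on the simplex (half the
    draws per concentration); each scales its group's standardized columns
    by sqrt(gamma_g) before a shared-alpha ridge.  Selection maximizes the
    mean K-fold validation r over the (gamma, alpha) grid; the winner is
    refit on the full training split and scored on the test split.

    Internally the fit uses the equivalent kernel form
    K(gamma) = sum_g gamma_g X_g X_g^T, so each candidate costs one n x n
    eigendecomposition rather than a d x d solve.
    """
    if len(groups_train) < 2:
        raise ValueError("grouped ridge needs at least two groups")
    if set(groups_train) != set(groups_test):
        raise ValueError("train/test group names differ")
    for name, X in groups_train.items():
        if X.size == 0 or groups_test[name].size == 0:
            raise ValueError(f"group {name!r} is empty")
    names = sorted(groups_train)
    alphas = alpha_grid() if alphas is None else np.asarray(alphas, float)
    y_train = np.asarray(y_train, float).ravel()
    y_test = np.asarray(y_test, float).ravel()
    rng = np.random.default_rng(seed)
    gammas = _draw_gammas(len(names), n_gamma, concentrations, rng)

    n = len(y_train)
    score_sum = np.zeros((len(gammas), len(alphas)))
    n_folds_done = 0
    for tr, va in _cv_folds(n, folds, repeats=repeats,
                            seed=int(rng.integers(2 ** 31))):
        K_tr, K_va = [], []
        for name in names:
            X = np.asarray(groups_train[name], float)
            std = Standardizer.fit(X[tr])
            Xtr, Xva = std.transform(X[tr]), std.transform(X[va])
            K_tr.append(Xtr @ Xtr.T)
            K_va.append(Xva @ Xtr.T)
        y_std = Standardizer.fit(y_train[tr, None])
        yt = y_std.transform(y_train[tr, None]).ravel()
        yv = y_train[va]
        for gi, g in enumerate(gammas):
            K = sum(w * k for w, k in zip(g, K_tr))
            Kv = sum(w * k for w, k in zip(g, K_va))
            evals, evecs = np.linalg.eigh(K)
            vty = evecs.T @ yt
            kvv = Kv @ evecs
            coef = vty[None, :] / (evals[None, :] + alphas[:, None])  # (A, n)
            preds = kvv @ coef.T                                       # (m, A)
            score_sum[gi] += _pearson_columns(preds, yv)
        n_folds_done += 1
    scores = score_sum / n_folds_done

    # deterministic argmax: score desc, then smaller alpha, then gamma index
    flat = scores.ravel()
    order = np.lexsort((np.tile(np.arange(len(alphas)), len(gammas)),
                        -flat))
    best_flat = order[0]
    gi, ai = divmod(best_flat, len(alphas))
    gamma, alpha = gammas[gi], float(alphas[ai])

    # refit on the full training split
    K_full = np.zeros((n, n))
    test_parts = []
    for w, name in zip(gamma, names):
        X = np.asarray(groups_train[name], float)
        std = Standardizer.fit(X)
        Xtr = std.transform(X)
        Xte = std.transform(np.asarray(groups_test[name], float))
        K_full += w * (Xtr @ Xtr.T)
        test_parts.append(w * (Xte @ Xtr.T))
    y_std = Standardizer.fit(y_train[:, None])
    yt = y_std.transform(y_train[:, None]).ravel()
    beta = np.linalg.solve(K_full + alpha * np.eye(n), yt)
    pred = sum(test_parts) @ beta
    r = pearson_r(pred, y_test)
    return GroupedRidgeResult(
        gamma={name: float(g) for name, g in zip(names, gamma)},
        alpha=alpha, test_r=r, mean_val_r=float(scores[gi, ai]),
    )


# ---------------------------------------------------------------------------
# multi-output decoding (embeddings -> pose features)

def decode_features(
    X: np.ndarray, F: np.ndarray,
    train_idx: np.ndarray, test_idx: np.ndarray,
    alphas: np.ndarray | None = None,
    folds: int = 5, repeats: int = 2, seed: int = 0,
) -> float:
    """Mean cross-validated decoding score of a feature table from
    embeddings: per-output alpha selected by K-fold validation r, refit on
    the full training split, mean test r over outputs."""
    alphas = alpha_grid() if alphas is None else np.asarray(alphas, float)
    X, F = np.asarray(X, float), np.asarray(F, float)
    Xtr, Xte = X[train_idx], X[test_idx]
    Ftr, Fte = F[train_idx], F[test_idx]

    sums = np.zeros((len(alphas), F.shape[1]))
    n_fits = 0
    for tr, va in _cv_folds(len(train_idx), folds, repeats, seed):
        x_std = Standardizer.fit(Xtr[tr])
        f_std = Standardizer.fit(Ftr[tr])
        preds = _ridge_path_predictions(
            x_std.transform(Xtr[tr]), f_std.transform(Ftr[tr]),
            x_std.transform(Xtr[va]), alphas)          # (A, m, k)
        for ai in range(len(alphas)):
            sums[ai] += _pearson_paired_columns(preds[ai], Ftr[va])
        n_fits += 1
    best_alpha_per_output = np.asarray(alphas)[np.argmax(sums, axis=0)]

    x_std = Standardizer.fit(Xtr)
    f_std = Standardizer.fit(Ftr)
    rs = []
    for k, a in enumerate(best_alpha_per_output):
        w = ridge_solve(x_std.transform(Xtr), f_std.transform(Ftr)[:, k],
                        float(a))
        rs.append(_safe_r(x_std.transform(Xte) @ w, Fte[:, k]))
    return float(np.mean(rs))
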