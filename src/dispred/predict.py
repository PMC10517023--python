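"""Risk models on the learned representation and the ensemble stage.

Stage 2 fits ordinary least squares of the binary phenotype on the
phenotype-specific latent z_d; stage 3 combines its scores p_z with the
scores p_x of an L1-penalised (Lasso) model on raw dosages as

    p_e = alpha * p_z + beta * p_x

with (alpha, beta) chosen either by exhaustive grid search over
{0.1, ..., 1.5}^2 maximising validation AUC, or by gradient descent on a
differentiable surrogate (mean squared error of p_e against the labels;
logistic loss available).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LassoCV

from .eval import auc

__all__ = [
    "LatentRegressor",
    "LassoModel",
    "PredictionSet",
    "EnsembleWeights",
    "fit_latent_regressor",
    "fit_lasso_raw",
    "ensemble_predict",
    "grid_search_weights",
    "gradient_search_weights",
]

GRID = np.round(np.arange(0.1, 1.51, 0.1), 10)


@dataclass
class LatentRegressor:
    """OLS fit of y on z_d; scores are the fitted linear values."""

    intercept: float
    coef: np.ndarray
    rank_deficient: bool = False

    def predict(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) @ self.coef + self.intercept


@dataclass
class LassoModel:
    """Lasso on raw dosages with the CV-selected penalty exposed."""

    intercept: float
    coef: np.ndarray
    alpha: float
    alphas: np.ndarray
    cv_mse: np.ndarray  # mean CV error per path penalty

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.coef + self.intercept


@dataclass
class PredictionSet:
    """Aligned score vectors from the three stages."""

    ids: list[str]
    p_z: np.ndarray
    p_x: np.ndarray
    p_e: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.p_z) == len(self.p_x)):
            raise ValueError("ids, p_z and p_x must be aligned")


@dataclass
class EnsembleWeights:
    alpha: float
    beta: float
    search_method: str
    achieved_validation_auc: float


def fit_latent_regressor(z_d: np.ndarray, y: np.ndarray) -> LatentRegressor:
    """Least-squares linear model of the labels on the latent coordinates.

    Rank-deficient designs are solved with the minimum-norm solution and
    flagged rather than rejected — a collapsed latent dimension should not
    abort the pipeline.
    """
    z_d = np.asarray(z_d, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), z_d])
    sol, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    return LatentRegressor(
        intercept=float(sol[0]),
        coef=sol[1:],
        rank_deficient=rank < design.shape[1],
    )


def fit_lasso_raw(
    x: np.ndarray,
    y: np.ndarray,
    n_alphas: int = 10,
    max_iter: int = 5000,
    tol: float = 1e-3,
    cv_folds: int = 5,
) -> LassoModel:
    """Lasso over an automatic regularisation path, penalty picked by CV."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any():
        raise ValueError("dosages must be imputed before fitting")
    if len(y) < cv_folds:
        raise ValueError(f"need at least {cv_folds} samples for {cv_folds}-fold CV")
    model = LassoCV(
        alphas=n_alphas, max_iter=max_iter, tol=tol, cv=cv_folds
    ).fit(x, y)
    return LassoModel(
        intercept=float(model.intercept_),
        coef=model.coef_.copy(),
        alpha=float(model.alpha_),
        alphas=model.alphas_.copy(),
        cv_mse=model.mse_path_.mean(axis=1),
    )


def ensemble_predict(
    p_z: np.ndarray, p_x: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Element-wise weighted sum of the two score vectors."""
    p_z = np.asarray(p_z, dtype=float)
    p_x = np.asarray(p_x, dtype=float)
    if p_z.shape != p_x.shape:
        raise ValueError(f"score length mismatch: {p_z.shape} vs {p_x.shape}")
    return alpha * p_z + beta * p_x


def grid_search_weights(
    p_z_val: np.ndarray, p_x_val: np.ndarray, y_val: np.ndarray
) -> EnsembleWeights:
    """Exhaustive search of the 15 x 15 weight grid by validation AUC.

    Ties are broken toward the smallest alpha, then the smallest beta, by
    iterating the grid in lexicographic order and accepting only strict
    improvements.
    """
    y_val = np.asarray(y_val)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation labels contain a single class")
    best = None
    for a, b in itertools.product(GRID, GRID):
        score = auc(ensemble_predict(p_z_val, p_x_val, a, b), y_val)
        if best is None or score > best[2]:
            best = (float(a), float(b), score)
    return EnsembleWeights(
        alpha=best[0],
        beta=best[1],
        search_method="grid",
        achieved_validation_auc=best[2],
    )


def gradient_search_weights(
    p_z: np.ndarray,
    p_x: np.ndarray,
    y: np.ndarray,
    init: tuple[float, float] = (1.1, 0.9),
    epochs: int = 5000,
    learning_rate: float = 0.01,
    loss: str = "mse",
) -> EnsembleWeights:
    """Gradient descent on the two ensemble weights.

    AUC itself is not differentiable, so the search minimises a surrogate:
    by default the mean squared error between p_e and the binary labels
    (matching the least-squares choice of the latent stage); ``loss="logistic"``
    minimises log-loss on a sigmoid of p_e instead.  The two-parameter MSE
    objective is convex, so plain full-batch descent suffices.
    """
    p_z = np.asarray(p_z, dtype=float)
    p_x = np.asarray(p_x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (p_z.shape == p_x.shape == y.shape):
        raise ValueError("p_z, p_x and y must be aligned")
    a, b = float(init[0]), float(init[1])
    n = len(y)
    for _ in range(epochs):
        p_e = a * p_z + b * p_x
        if loss == "mse":
            resid = p_e - y
            ga = 2.0 * float(resid @ p_z) / n
            gb = 2.0 * float(resid @ p_x) / n
        elif loss == "logistic":
            s = 1.0 / (1.0 + np.exp(-p_e))
            ga = float((s - y) @ p_z) / n
            gb = float((s - y) @ p_x) / n
        else:
            raise ValueError(f"unknown loss {loss!r}")
        if not (np.isfinite(ga) and np.isfinite(gb)):
            raise FloatingPointError(
                f"non-finite gradient at (alpha={a}, beta={b}): ({ga}, {gb})"
            )
        a -= learning_rate * ga
        b -= learning_rate * gb
    final_auc = (
        auc(a * p_z + b * p_x, y.astype(int))
        if len(np.unique(y)) > 1
        else float("nan")
    )
    return EnsembleWeights(
        alpha=a, beta=b, search_method="gradient", achieved_validation_auc=final_auc
    )
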