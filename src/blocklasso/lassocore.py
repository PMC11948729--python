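"""L1-penalized least squares over a penalty path, with model selection.

The objective, per block or globally, is

    O(lambda) = (1/2N) ||y* - X·beta||²  +  lambda ||beta||₁

solved by coordinate descent (scikit-learn's ``lasso_path``, whose
``alpha`` is exactly this ``lambda``) on column-standardized features,
warm-starting down a log-spaced grid from lambda_max — the smallest
penalty at which the solution is identically zero (KKT condition:
lambda_max = max_j |x_jᵀ y| / N). Model selection picks the penalty
maximizing a validation-set metric, with ties resolved toward the
larger penalty (sparser model).

Per-block fits are independent by construction: results do not depend
on block order or concurrency, which is what licenses the
block-diagonal approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path as _sk_lasso_path

logger = logging.getLogger(__name__)

__all__ = [
    "LambdaGrid",
    "LassoPathResult",
    "BlockModel",
    "make_lambda_grid",
    "fit_lasso_path",
    "select_model",
    "fit_blocks",
    "lasso_objective",
]


@dataclass(frozen=True)
class LambdaGrid:
    """Strictly decreasing, strictly positive penalty sequence."""

    lambdas: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, float)
        if lam.ndim != 1 or len(lam) < 1:
            raise ValueError("lambda grid must be a non-empty 1-D array")
        if np.any(lam <= 0):
            raise ValueError("penalties must be strictly positive")
        if np.any(np.diff(lam) >= 0):
            raise ValueError("penalties must be strictly decreasing")
        object.__setattr__(self, "lambdas", lam)

    def __len__(self) -> int:
        return len(self.lambdas)


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize with training statistics; drop zero-SD columns."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance feature(s)", int((~keep).sum()))
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, mean, sd, keep


def make_lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_points: int = 100,
    ratio: float = 1e-3,
) -> LambdaGrid:
    """Log-spaced grid from lambda_max down to ratio·lambda_max.

    lambda_max = max_j |x_jᵀ (y - ȳ)| / N on standardized columns: at or
    above it the all-zero coefficient vector satisfies the KKT
    conditions exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ValueError("y is constant: no signal to fit")
    Xs, *_ = _standardize_train(np.asarray(X, float))
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / len(y))
    if lam_max == 0:
        raise ValueError("all features orthogonal to y: lambda_max is 0")
    return LambdaGrid(np.geomspace(lam_max, ratio * lam_max, n_points))


@dataclass
class LassoPathResult:
    """Coordinate-descent solutions along a penalty grid.

    Coefficients are on the standardized-feature scale; ``feature_idx``
    maps kept columns back to the input matrix (zero-variance columns
    are dropped before fitting). The intercept is ȳ at every path point
    because standardized columns have zero mean.
    """

    lambdas: np.ndarray
    coefs: np.ndarray        # (n_kept_features, n_lambdas)
    intercept: float
    feature_idx: np.ndarray  # kept columns of the input X
    mean: np.ndarray         # per-kept-feature training mean
    sd: np.ndarray           # per-kept-feature training SD

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scores for every path point: (n_samples, n_lambdas)."""
        Xs = (np.asarray(X, float)[:, self.feature_idx] - self.mean) / self.sd
        return Xs @ self.coefs + self.intercept


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    grid: LambdaGrid,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> LassoPathResult:
    """Solve the penalized objective at each grid point with warm starts."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in X or y")
    Xs, mean, sd, keep = _standardize_train(X)
    yc = y - y.mean()
    _, coefs, _ = _sk_lasso_path(
        Xs, yc, alphas=grid.lambdas, tol=tol, max_iter=max_iter
    )
    return LassoPathResult(
        lambdas=grid.lambdas,
        coefs=coefs,
        intercept=float(y.mean()),
        feature_idx=np.where(keep)[0],
        mean=mean[keep],
        sd=sd[keep],
    )


def lasso_objective(X_std: np.ndarray, y_centered: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """(1/2N)||y - X·beta||² + lambda·||beta||₁ on the standardized scale."""
    n = len(y_centered)
    resid = y_centered - X_std @ beta
    return float(resid @ resid / (2 * n) + lam * np.abs(beta).sum())


@dataclass
class BlockModel:
    """Selected per-block model: sparse SNV weights at one penalty.

    Weights live on the standardized scale together with the training
    mean/SD of each feature, so original-dosage-scale weights
    (beta_std / sd) reproduce standardized-scale predictions exactly.
    A null model (no predictive fit) carries zero features.
    """

    block_id: str
    lambda_sel: float
    beta_std: np.ndarray
    features: pd.DataFrame  # snv_id, chrom, pos_bp, a1 for each weight
    mean: np.ndarray
    sd: np.ndarray
    intercept: float
    is_null: bool = False

    @property
    def beta_raw(self) -> np.ndarray:
        """Weights on the original dosage scale."""
        return self.beta_std / self.sd if len(self.beta_std) else self.beta_std

    @property
    def n_nonzero(self) -> int:
        return int((self.beta_std != 0).sum())

    def score(self, dosages: np.ndarray) -> np.ndarray:
        """Linear block score Σ_j beta_raw_j · X_ij (no intercept)."""
        if self.is_null or len(self.beta_std) == 0:
            return np.zeros(len(dosages))
        return dosages @ self.beta_raw

    @staticmethod
    def null(block_id: str) -> "BlockModel":
        return BlockModel(
            block_id=block_id,
            lambda_sel=np.nan,
            beta_std=np.zeros(0),
            features=pd.DataFrame(columns=["snv_id", "chrom", "pos_bp", "a1"]),
            mean=np.zeros(0),
            sd=np.zeros(0),
            intercept=0.0,
            is_null=True,
        )


def _validation_metric(scores: np.ndarray, y: np.ndarray, metric: str) -> np.ndarray:
    """Column-wise validation metric; degenerate columns score -inf."""
    out = np.full(scores.shape[1], -np.inf)
    sy = y.std()
    if metric == "correlation":
        sc = scores.std(axis=0)
        ok = (sc > 0) & (sy > 0)
        if ok.any():
            yc = y - y.mean()
            cc = (scores[:, ok] - scores[:, ok].mean(axis=0)).T @ yc
            out[ok] = cc / (len(y) * sc[ok] * sy)
    elif metric == "auc":
        from .evalstats import auc
        for j in range(scores.shape[1]):
            if scores[:, j].std() > 0:
                out[j] = auc(scores[:, j], y)
    else:
        raise ValueError("metric must be 'correlation' or 'auc'")
    return out


def select_model(
    path: LassoPathResult,
    X_val: np.ndarray,
    y_val: np.ndarray,
    metric: str = "correlation",
    block_id: str = "block",
    features: pd.DataFrame | None = None,
) -> BlockModel:
    """Pick the path point maximizing the validation metric.

    Ties go to the larger penalty (sparser model); if no path point
    produces a non-degenerate score the null model is returned, flagged.
    """
    scores = path.predict(X_val)
    vals = _validation_metric(scores, np.asarray(y_val, float), metric)
    if not np.isfinite(vals).any():
        return BlockModel.null(block_id)
    best = int(np.argmax(vals))  # grid is descending, argmax takes first => larger lambda
    beta = path.coefs[:, best]
    nz = beta != 0
    kept = path.feature_idx[nz]
    if features is not None:
        meta = features.iloc[kept].reset_index(drop=True)
    else:
        meta = pd.DataFrame({
            "snv_id": [f"f{j}" for j in kept],
            "chrom": 0, "pos_bp": kept, "a1": "NA",
        })
    return BlockModel(
        block_id=block_id,
        lambda_sel=float(path.lambdas[best]),
        beta_std=beta[nz],
        features=meta,
        mean=path.mean[nz],
        sd=path.sd[nz],
        intercept=path.intercept,
        is_null=not nz.any(),
    )


def fit_blocks(
    genotypes,
    features: dict[str, np.ndarray],
    residual: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    metric: str = "correlation",
    n_points: int = 100,
    ratio: float = 1e-3,
) -> list["BlockModel"]:
    """Fit one independent LASSO per block and select its penalty.

    ``features`` maps block_id to the selected SNV column indices of
    that block. A block whose fit fails yields a null model and the run
    continues (the failure is logged); block order cannot influence any
    other block's result.
    """
    y = np.asarray(residual, float)
    models: list[BlockModel] = []
    for block in genotypes.blocks:
        sel = np.asarray(features.get(block.block_id, np.zeros(0, int)), int)
        if sel.size == 0:
            models.append(BlockModel.null(block.block_id))
            continue
        try:
            Xb = block.dosages[:, sel]
            grid = make_lambda_grid(Xb[train_idx], y[train_idx], n_points, ratio)
            path = fit_lasso_path(Xb[train_idx], y[train_idx], grid)
            meta = block.snvs.iloc[sel][["snv_id", "chrom", "pos_bp", "a1"]].reset_index(drop=True)
            models.append(
                select_model(path, Xb[val_idx], y[val_idx], metric, block.block_id, meta)
            )
        except Exception:  # noqa: BLE001 - a failed block must not kill the run
            logger.exception("block %s failed; substituting null model", block.block_id)
            models.append(BlockModel.null(block.block_id))
    return models
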