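"""Ordinary least squares multiple linear regression for QSAR models.

Fits descriptor-subset models with coefficient standard errors and computes
the standard fitting statistics used to judge them: R2, adjusted R2,
standard error of the estimate, the Fisher F ratio with its p-value,
training RMSE/MAE and Lin's concordance correlation coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MLRModel",
    "FitStatistics",
    "fit_mlr",
    "predict",
    "adjusted_r2",
    "fisher_f",
    "concordance_cc",
    "fit_statistics",
]


@dataclass
class MLRModel:
    """A fitted linear TEAC model: named coefficients with standard errors."""

    descriptor_names: list[str]
    coefficients: np.ndarray
    coefficient_ses: np.ndarray
    intercept: float
    intercept_se: float
    n_train: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.coefficient_ses = np.asarray(self.coefficient_ses, dtype=float)
        p = len(self.descriptor_names)
        if not (len(self.coefficients) == len(self.coefficient_ses) == p) or p < 1:
            raise ValueError("inconsistent model arrays")
        if self.n_train <= p + 1:
            raise ValueError(f"n_train={self.n_train} too small for p={p}")

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def to_json(self, path) -> None:
        payload = {
            "descriptor_names": self.descriptor_names,
            "coefficients": self.coefficients.tolist(),
            "coefficient_ses": self.coefficient_ses.tolist(),
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "n_train": self.n_train,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MLRModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class FitStatistics:
    """Training-set ("fitting criteria") statistics of an MLR model."""

    r2: float
    r2_adj: float
    s: float
    f_ratio: float
    p_value: float
    rmse_tr: float
    mae_tr: float
    ccc_tr: float


def _design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i + 1}" for i in range(arr.shape[1])]


def fit_mlr(X, y) -> MLRModel:
    """Fit an OLS model with intercept; X is a compounds x descriptors block.

    The solve goes through a QR decomposition of the intercept-augmented
    design for stability with near-collinear descriptors; standard errors
    come from the unbiased residual variance and (X'X)^-1 obtained from the
    R factor.
    """
    values, names = _design(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = values.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    A = np.column_stack([np.ones(n), values])
    q, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    if diag.min() <= max(n, p + 1) * np.finfo(float).eps * max(diag.max(), 1.0):
        raise np.linalg.LinAlgError("rank-deficient design (collinear descriptors)")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - A @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p - 1)
    r_inv = np.linalg.solve(r, np.eye(p + 1))
    xtx_inv = r_inv @ r_inv.T
    ses = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    return MLRModel(
        descriptor_names=names,
        coefficients=beta[1:],
        coefficient_ses=ses[1:],
        intercept=float(beta[0]),
        intercept_se=float(ses[0]),
        n_train=n,
    )


def predict(model: MLRModel, X) -> np.ndarray:
    """Evaluate a fitted model on rows of descriptor values (mM output)."""
    if isinstance(X, pd.DataFrame):
        missing = [d for d in model.descriptor_names if d not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor columns: {missing}")
        values = X[model.descriptor_names].to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.shape[1] != model.p:
            raise ValueError("wrong number of descriptor columns")
    return model.intercept + values @ model.coefficients


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R2: 1 - (1 - R2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fisher_f(r2: float, n: int, p: int) -> tuple[float, float]:
    """Fisher F ratio of a p-variable fit from its R2, with its p-value."""
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1); r2=1 gives an infinite F")
    f = (r2 / p) / ((1.0 - r2) / (n - p - 1))
    p_value = float(stats.f.sf(f, p, n - p - 1))
    return f, p_value


def concordance_cc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2*Sxy / (Sxx + Syy + n*(xbar - ybar)^2) with S the centred
    cross/sum-of-squares; penalizes both dispersion and location shifts.
    """
    x = np.asarray(observed, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(xc @ xc + yc @ yc + len(x) * (x.mean() - y.mean()) ** 2)
    if denom == 0:
        raise ValueError("zero total variance in both vectors")
    return float(2.0 * (xc @ yc) / denom)


def fit_statistics(model: MLRModel, X, y) -> FitStatistics:
    """All training-set statistics of a fitted model on its own data."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = predict(model, X)
    resid = y - yhat
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("zero variance in the response")
    n, p = model.n_train, model.p
    r2 = 1.0 - rss / tss
    if r2 < 1.0:
        f_ratio, p_value = fisher_f(r2, n, p)
    else:
        f_ratio, p_value = np.inf, 0.0
    return FitStatistics(
        r2=r2,
        r2_adj=adjusted_r2(r2, n, p),
        s=float(np.sqrt(rss / (n - p - 1))),
        f_ratio=f_ratio,
        p_value=p_value,
        rmse_tr=float(np.sqrt(rss / n)),
        mae_tr=float(np.abs(resid).mean()),
        ccc_tr=concordance_cc(y, yhat),
    )
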