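"""Leverage-based applicability domain and Williams-plot data.

Computes hat (leverage) values against the training design, the warning
leverage h* = 3(p+1)/n, and standardized cross-validated residuals, and
flags structurally influential compounds (X-outliers, leverage > h*) and
response outliers (Y-outliers, |standardized residual| > 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlr import MLRModel, predict
from .validation import external_validation, loo_cv

__all__ = ["ADReport", "leverages", "warning_leverage", "williams_report",
           "plot_williams"]


@dataclass
class ADReport:
    """Williams-plot table: leverage and standardized residual per compound."""

    table: pd.DataFrame  # columns: set, leverage, std_residual, x_outlier, y_outlier
    h_star: float

    @property
    def x_outliers(self) -> list:
        return list(self.table.index[self.table["x_outlier"]])

    @property
    def y_outliers(self) -> list:
        return list(self.table.index[self.table["y_outlier"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="compound_id")

    def summary(self) -> dict:
        return {
            "h_star": self.h_star,
            "n_compounds": int(len(self.table)),
            "x_outliers": self.x_outliers,
            "y_outliers": self.y_outliers,
        }


def leverages(X_train, X_query=None) -> np.ndarray:
    """Hat values h = x (X'X)^-1 x' of query rows against the training
    design (intercept-augmented).  With no query, returns the training
    hat diagonal."""
    train = _matrix(X_train)
    n, p = train.shape
    A = np.column_stack([np.ones(n), train])
    q, r = np.linalg.qr(A)
    if np.abs(np.diag(r)).min() <= max(n, p + 1) * np.finfo(float).eps * \
            max(np.abs(np.diag(r)).max(), 1.0):
        raise np.linalg.LinAlgError("rank-deficient training design")
    if X_query is None:
        return (q ** 2).sum(axis=1)
    query = _matrix(X_query)
    B = np.column_stack([np.ones(len(query)), query])
    # h = || R^-T b ||^2 since (A'A)^-1 = R^-1 R^-T
    w = np.linalg.solve(r.T, B.T)
    return (w ** 2).sum(axis=0)


def warning_leverage(n_train: int, p: int) -> float:
    """Warning leverage h* = 3(p+1)/n for a p-descriptor model."""
    if n_train <= p + 1:
        raise ValueError(f"need n > p+1 (n={n_train}, p={p})")
    return 3.0 * (p + 1) / n_train


def williams_report(model: MLRModel, X_train, y_train,
                    X_test=None, y_test=None) -> ADReport:
    """Williams-plot data for training (and optionally test) compounds.

    Training residuals are leave-one-out residuals standardized by RMSE_cv;
    test residuals are external residuals standardized by RMSE_ext.
    """
    internal = loo_cv(_frame(X_train, model), y_train)
    y_tr = np.asarray(y_train, dtype=float).ravel()
    loo_resid = y_tr - internal.loo_predictions
    h_tr = leverages(_frame(X_train, model))
    h_star = warning_leverage(len(y_tr), model.p)
    rows = {
        "set": ["train"] * len(y_tr),
        "leverage": list(h_tr),
        "std_residual": list(loo_resid / internal.rmse_cv),
    }
    index = list(X_train.index) if isinstance(X_train, pd.DataFrame) \
        else list(range(len(y_tr)))

    if X_test is not None:
        y_te = np.asarray(y_test, dtype=float).ravel()
        ext = external_validation(
            model, _frame(X_test, model), y_te,
            train_mean=float(y_tr.mean()),
            train_tss_per_n=float(((y_tr - y_tr.mean()) ** 2).sum() / len(y_tr)),
        )
        resid_te = y_te - predict(model, _frame(X_test, model))
        h_te = leverages(_frame(X_train, model), _frame(X_test, model))
        rows["set"] += ["test"] * len(y_te)
        rows["leverage"] += list(h_te)
        rows["std_residual"] += list(resid_te / ext.rmse_ext)
        index += list(X_test.index) if isinstance(X_test, pd.DataFrame) \
            else list(range(len(y_tr), len(y_tr) + len(y_te)))

    table = pd.DataFrame(rows, index=index)
    table["x_outlier"] = table["leverage"] > h_star
    table["y_outlier"] = table["std_residual"].abs() > 3.0
    return ADReport(table=table, h_star=h_star)


def plot_williams(report: ADReport, path) -> None:
    """Write a Williams plot (leverage vs standardized residual) to disk."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for subset, marker in (("train", "o"), ("test", "s")):
        part = report.table[report.table["set"] == subset]
        if len(part):
            ax.scatter(part["leverage"], part["std_residual"],
                       marker=marker, label=subset, alpha=0.8)
    ax.axvline(report.h_star, linestyle="--", color="gray")
    for guide in (-3, 3):
        ax.axhline(guide, linestyle=":", color="gray")
    ax.set_xlabel("leverage (hat value)")
    ax.set_ylabel("standardized cross-validated residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


def _frame(X, model: MLRModel):
    if isinstance(X, pd.DataFrame):
        return X[model.descriptor_names]
    return X
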