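"""Internal, external and response-permutation validation of MLR models.

Implements leave-one-out and leave-many-out cross-validation, the external
predictivity family Q2_F1 / Q2_F2 / Q2_F3 with external RMSE / MAE / PRESS /
R2 / CCC, the Y-scrambling randomization test, and the acceptability rule
set used to keep or reject a model (R2 >= 0.6, R2_ext >= 0.6, CCC >= 0.85,
RMSE_tr < RMSE_cv, scrambled statistics well below the real ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mlr import FitStatistics, MLRModel, concordance_cc, fit_mlr, predict

__all__ = [
    "InternalValidation",
    "LMOResult",
    "ExternalValidation",
    "YScrambleResult",
    "AcceptabilityFlags",
    "loo_cv",
    "lmo_cv",
    "external_validation",
    "y_scramble",
    "acceptability_check",
    "validation_report",
]

# Default acceptability thresholds.
R2_MIN = 0.6
R2_EXT_MIN = 0.6
CCC_MIN = 0.85


@dataclass
class InternalValidation:
    """Leave-one-out statistics: Q2_LOO, PRESS and CV error summaries."""

    q2_loo: float
    press_cv: float
    rmse_cv: float
    mae_cv: float
    ccc_cv: float
    loo_predictions: np.ndarray = field(repr=False, default=None)


@dataclass
class LMOResult:
    """Leave-many-out result: pooled Q2 plus the per-iteration values."""

    q2_lmo: float
    per_iteration: np.ndarray
    leave_fraction: float
    n_iter: int
    seed: int

    @property
    def mean_per_iteration(self) -> float:
        return float(np.mean(self.per_iteration))


@dataclass
class ExternalValidation:
    """Prediction-set statistics: the Q2_F family, R2_ext and CCC_ext."""

    rmse_ext: float
    mae_ext: float
    press_ext: float
    r2_ext: float
    q2_f1: float
    q2_f2: float
    q2_f3: float
    ccc_ext: float


@dataclass
class YScrambleResult:
    """R2 / Q2_LOO distribution after randomly permuting the response."""

    n_permutations: int
    r2_scrambled: np.ndarray
    q2_scrambled: np.ndarray
    seed: int

    @property
    def mean_r2(self) -> float:
        return float(self.r2_scrambled.mean())

    @property
    def mean_q2(self) -> float:
        return float(self.q2_scrambled.mean())


@dataclass
class AcceptabilityFlags:
    """Boolean verdicts of the model-acceptability rules."""

    r2_ok: bool
    r2_ext_ok: bool
    ccc_ok: bool
    rmse_order_ok: bool
    yscr_ok: bool

    @property
    def all_ok(self) -> bool:
        return all([self.r2_ok, self.r2_ext_ok, self.ccc_ok,
                    self.rmse_order_ok, self.yscr_ok])


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


def loo_cv(X, y) -> InternalValidation:
    """Leave-one-out cross-validation of an OLS fit.

    Uses the hat-diagonal identity e_(-i) = e_i / (1 - h_ii), which equals
    refitting without each point; PRESS is the sum of squared deleted
    residuals and Q2_LOO = 1 - PRESS/TSS.
    """
    values = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = values.shape
    if n <= p + 2:
        raise ValueError(f"need n > p+2 for LOO (n={n}, p={p})")
    A = np.column_stack([np.ones(n), values])
    q, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    if diag.min() <= max(n, p + 1) * np.finfo(float).eps * max(diag.max(), 1.0):
        raise np.linalg.LinAlgError("rank-deficient design")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - A @ beta
    leverage = (q ** 2).sum(axis=1)
    if np.any(leverage >= 1.0 - 1e-12):
        raise ValueError("a leverage equals 1; LOO residual undefined")
    loo_resid = resid / (1.0 - leverage)
    loo_pred = y - loo_resid
    press = float(loo_resid @ loo_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("zero variance in the response")
    return InternalValidation(
        q2_loo=1.0 - press / tss,
        press_cv=press,
        rmse_cv=float(np.sqrt(press / n)),
        mae_cv=float(np.abs(loo_resid).mean()),
        ccc_cv=concordance_cc(y, loo_pred),
        loo_predictions=loo_pred,
    )


def lmo_cv(X, y, leave_fraction: float = 0.3, n_iter: int = 100,
           seed: int = 0) -> LMOResult:
    """Leave-many-out cross-validation.

    Each iteration removes a random ceil(fraction * n) subset, refits, and
    predicts the held-out compounds against the retained-subset mean
    baseline.  The headline ``q2_lmo`` pools squared errors and baseline
    deviations over all iterations (stable even for tiny hold-out groups);
    the per-iteration Q2 values are also returned.
    """
    if not 0 < leave_fraction <= 0.5:
        raise ValueError("leave_fraction must lie in (0, 0.5]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    values = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = values.shape
    n_out = int(np.ceil(leave_fraction * n))
    if n - n_out < p + 2:
        raise ValueError("retained set too small to refit")
    rng = np.random.default_rng(seed)
    per_iter = np.empty(n_iter)
    press_pool = 0.0
    base_pool = 0.0
    for i in range(n_iter):
        out = rng.choice(n, size=n_out, replace=False)
        keep = np.setdiff1d(np.arange(n), out)
        model = fit_mlr(values[keep], y[keep])
        pred = predict(model, values[out])
        err2 = float(((y[out] - pred) ** 2).sum())
        base2 = float(((y[out] - y[keep].mean()) ** 2).sum())
        press_pool += err2
        base_pool += base2
        per_iter[i] = 1.0 - err2 / base2 if base2 > 0 else np.nan
    return LMOResult(
        q2_lmo=1.0 - press_pool / base_pool,
        per_iteration=per_iter,
        leave_fraction=leave_fraction,
        n_iter=n_iter,
        seed=seed,
    )


def external_validation(model: MLRModel, X_ext, y_ext, train_mean: float,
                        train_tss_per_n: float) -> ExternalValidation:
    """External (prediction set) statistics of a fitted model.

    ``train_mean`` is the training-response mean and ``train_tss_per_n`` the
    training total sum of squares divided by n_train; they anchor Q2_F1 and
    Q2_F3 to the training distribution.
    """
    y_ext = np.asarray(y_ext, dtype=float).ravel()
    n_ext = len(y_ext)
    if n_ext < 3:
        raise ValueError("need at least 3 external compounds")
    pred = predict(model, X_ext)
    err = y_ext - pred
    press_ext = float(err @ err)
    ext_tss = float(((y_ext - y_ext.mean()) ** 2).sum())
    if ext_tss == 0:
        raise ValueError("zero external variance: Q2_F2 undefined")
    r = np.corrcoef(y_ext, pred)[0, 1]
    return ExternalValidation(
        rmse_ext=float(np.sqrt(press_ext / n_ext)),
        mae_ext=float(np.abs(err).mean()),
        press_ext=press_ext,
        r2_ext=float(r ** 2),
        q2_f1=1.0 - press_ext / float(((y_ext - train_mean) ** 2).sum()),
        q2_f2=1.0 - press_ext / ext_tss,
        q2_f3=1.0 - (press_ext / n_ext) / train_tss_per_n,
        ccc_ext=concordance_cc(y_ext, pred),
    )


def y_scramble(X, y, n_permutations: int = 100, seed: int = 0) -> YScrambleResult:
    """Response-permutation (Y-scrambling) test.

    Refits the model on randomly permuted responses, keeping descriptors
    fixed, and records R2 and Q2_LOO per permutation.  A real model must
    beat these chance levels, and mean R2 must exceed mean Q2.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    values = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: all values equal")
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_permutations)
    q2s = np.empty(n_permutations)
    tss = float(((y - y.mean()) ** 2).sum())
    n = len(y)
    A = np.column_stack([np.ones(n), values])
    q, _ = np.linalg.qr(A)
    leverage = (q ** 2).sum(axis=1)
    for i in range(n_permutations):
        perm = rng.permutation(y)
        # same design each time: project permuted response once
        fitted = q @ (q.T @ perm)
        resid = perm - fitted
        r2s[i] = 1.0 - float(resid @ resid) / tss
        loo_resid = resid / (1.0 - leverage)
        q2s[i] = 1.0 - float(loo_resid @ loo_resid) / tss
    return YScrambleResult(n_permutations=n_permutations, r2_scrambled=r2s,
                           q2_scrambled=q2s, seed=seed)


def acceptability_check(fit: FitStatistics, internal: InternalValidation,
                        external: ExternalValidation,
                        yscr: YScrambleResult) -> AcceptabilityFlags:
    """Apply the model-acceptability rule set to a full validation report."""
    return AcceptabilityFlags(
        r2_ok=fit.r2 >= R2_MIN,
        r2_ext_ok=external.r2_ext >= R2_EXT_MIN,
        ccc_ok=fit.ccc_tr >= CCC_MIN,
        rmse_order_ok=fit.rmse_tr < internal.rmse_cv,
        yscr_ok=(yscr.mean_r2 > yscr.mean_q2
                 and yscr.mean_r2 < fit.r2
                 and yscr.mean_q2 < internal.q2_loo),
    )


def validation_report(fit: FitStatistics,
                      internal: InternalValidation | None = None,
                      external: ExternalValidation | None = None,
                      kxx: float | None = None,
                      delta_k: float | None = None) -> dict:
    """Assemble a flat statistics dict keyed by the conventional row labels."""
    report = {
        "R2": fit.r2, "R2_adj": fit.r2_adj, "s": fit.s, "F": fit.f_ratio,
        "p": fit.p_value, "RMSE_tr": fit.rmse_tr, "MAE_tr": fit.mae_tr,
        "CCC_tr": fit.ccc_tr,
    }
    if kxx is not None:
        report["Kxx"] = kxx
    if delta_k is not None:
        report["DK"] = delta_k
    if internal is not None:
        report.update({
            "Q2_LOO": internal.q2_loo, "RMSE_cv": internal.rmse_cv,
            "MAE_cv": internal.mae_cv, "PRESS_cv": internal.press_cv,
            "CCC_cv": internal.ccc_cv,
        })
    if external is not None:
        report.update({
            "RMSE_ext": external.rmse_ext, "MAE_ext": external.mae_ext,
            "PRESS_ext": external.press_ext, "R2_ext": external.r2_ext,
            "Q2_F1": external.q2_f1, "Q2_F2": external.q2_f2,
            "Q2_F3": external.q2_f3, "CCC_ext": external.ccc_ext,
        })
    return report
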