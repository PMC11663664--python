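"""NIPALS PLS1 regression with cross-validated latent-variable selection.

The model regresses one chemical component at a time on the (preprocessed)
spectra. NIPALS extracts latent variables by iterating
``w = X'y / ||X'y||; t = Xw; p = X't/t't; q = y't/t't`` and deflating both
blocks; the regression vector is assembled as ``b = W (P'W)^-1 q``. The
latent count is chosen by seeded k-fold cross-validation with a parsimony
rule (smallest count whose SECV is within 2% of the minimum).

Evaluation produces the standard multivariate-calibration bundle: R2 and
RMSE on calibration and validation, RPD (reference sd / RMSE),
bias-corrected standard errors (SEC, SEP) and validation bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Finite stand-in for RPD when RMSE underflows to ~0 (perfect fit).
RPD_SENTINEL = 1e6

DEFAULT_MAX_LATENT = 15


@dataclass
class PLSRModel:
    """Fitted NIPALS PLS1 model."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # W, (p, a)
    x_loadings: np.ndarray  # P, (p, a)
    y_loadings: np.ndarray  # q, (a,)
    n_latent: int
    coef: np.ndarray  # regression vector b, (p,)
    scores: np.ndarray | None = None  # T, (n, a); mutually orthogonal columns


@dataclass
class ModelMetrics:
    """Calibration/validation performance bundle."""

    r2_c: float
    rmsec: float
    rpd_c: float
    sec: float
    secv: float
    r2_p: float
    rmsep: float
    rpd_p: float
    sep: float
    bias: float

    def as_dict(self) -> dict[str, float]:
        return {
            "r2_c": self.r2_c,
            "rmsec": self.rmsec,
            "rpd_c": self.rpd_c,
            "sec": self.sec,
            "secv": self.secv,
            "r2_p": self.r2_p,
            "rmsep": self.rmsep,
            "rpd_p": self.rpd_p,
            "sep": self.sep,
            "bias": self.bias,
        }


def fit_plsr(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSRModel:
    """Fit PLS1 by NIPALS with ``n_latent`` latent variables."""
    x = np.atleast_2d(np.asarray(X, dtype=float))
    yv = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if yv.size != n:
        raise ValueError("y length does not match X rows")
    if np.std(yv) == 0:
        raise ValueError("y has zero variance")
    if not 1 <= n_latent <= min(n - 1, p):
        raise ValueError(
            f"n_latent must be in [1, {min(n - 1, p)}], got {n_latent}"
        )
    x_mean = x.mean(axis=0)
    y_mean = float(yv.mean())
    xc = x - x_mean
    yc = yv - y_mean

    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    T = np.zeros((n, n_latent))
    q = np.zeros(n_latent)
    a_used = 0
    for a in range(n_latent):
        w = xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break  # y residual fully explained; stop extracting
        w /= nw
        t = xc @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        P[:, a] = xc.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a] = w
        T[:, a] = t
        xc = xc - np.outer(t, P[:, a])
        yc = yc - q[a] * t
        a_used = a + 1
    if a_used == 0:
        raise ValueError("could not extract any latent variable")
    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        n_latent=a_used,
        coef=coef,
        scores=T,
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """``y_hat = (X_new - x_mean) b + y_mean`` on the training grid."""
    x = np.atleast_2d(np.asarray(X_new, dtype=float))
    if x.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {x.shape[1]} channels; model expects {model.x_mean.size}"
        )
    return (x - model.x_mean) @ model.coef + model.y_mean


def _prefix_coefs(model: PLSRModel) -> np.ndarray:
    """Regression vectors for every latent-count prefix, shape (p, a)."""
    out = np.zeros((model.x_mean.size, model.n_latent))
    for a in range(1, model.n_latent + 1):
        Wa = model.weights[:, :a]
        Pa = model.x_loadings[:, :a]
        out[:, a - 1] = Wa @ np.linalg.solve(Pa.T @ Wa, model.y_loadings[:a])
    return out


def select_n_latent(
    X: np.ndarray,
    y: np.ndarray,
    max_latent: int = DEFAULT_MAX_LATENT,
    cv_folds: int = 10,
    seed: int = 0,
    return_press: bool = False,
):
    """Choose the latent count by seeded k-fold cross-validation.

    Computes SECV (bias-corrected sd of CV residuals) per candidate count
    and picks the smallest count whose SECV is within 2% of the minimum.
    Returns ``(n_latent, secv_curve)`` (plus the PRESS curve when
    ``return_press``); the curves have one entry per candidate count.
    """
    x = np.atleast_2d(np.asarray(X, dtype=float))
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.size
    if max_latent < 1:
        raise ValueError("max_latent must be >= 1")
    if cv_folds > n:
        raise ValueError("more folds than samples")
    if cv_folds < 2:
        raise ValueError("need at least 2 folds")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % cv_folds

    a_max = min(max_latent, x.shape[1])
    for f in range(cv_folds):
        a_max = min(a_max, int(np.sum(fold_of != f)) - 1)
    if a_max < 1:
        raise ValueError("too few samples per fold to fit any latent variable")

    resid = np.empty((n, a_max))
    for f in range(cv_folds):
        tr = fold_of != f
        te = ~tr
        model = fit_plsr(x[tr], yv[tr], a_max)
        coefs = _prefix_coefs(model)  # (p, a_fit)
        pred = (x[te] - model.x_mean) @ coefs + model.y_mean
        if model.n_latent < a_max:  # early exhaustion: pad with last column
            pad = np.repeat(pred[:, -1:], a_max - model.n_latent, axis=1)
            pred = np.hstack([pred, pad])
        resid[te, :] = pred - yv[te, None]

    press = np.sum(resid**2, axis=0)
    secv = np.sqrt(
        np.sum((resid - resid.mean(axis=0)) ** 2, axis=0) / (n - 1)
    )
    best = secv.min()
    n_latent = int(np.argmax(secv <= 1.02 * best) + 1)
    if return_press:
        return n_latent, secv, press
    return n_latent, secv


def evaluate(
    model: PLSRModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    secv: float = float("nan"),
) -> ModelMetrics:
    """Compute the calibration/validation metric bundle.

    RMSE uses a plain 1/n mean square; R2 is the coefficient of
    determination against each set's own mean; RPD = reference sd (n-1) /
    RMSE; SEC/SEP are bias-corrected standard errors (n-1); bias is the
    mean validation residual.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if y_val.size < 3:
        raise ValueError("need at least 3 validation samples")

    e_cal = predict(model, X_cal) - y_cal
    e_val = predict(model, X_val) - y_val

    rmsec = float(np.sqrt(np.mean(e_cal**2)))
    rmsep = float(np.sqrt(np.mean(e_val**2)))
    sst_cal = float(np.sum((y_cal - y_cal.mean()) ** 2))
    sst_val = float(np.sum((y_val - y_val.mean()) ** 2))
    r2_c = float(1 - np.sum(e_cal**2) / sst_cal) if sst_cal > 0 else float("nan")
    r2_p = float(1 - np.sum(e_val**2) / sst_val) if sst_val > 0 else float("nan")

    def _rpd(y: np.ndarray, rmse: float) -> float:
        sd = float(np.std(y, ddof=1))
        return float(sd / rmse) if rmse > 1e-12 else RPD_SENTINEL

    bias_c = float(e_cal.mean())
    bias_p = float(e_val.mean())
    sec = float(np.sqrt(np.sum((e_cal - bias_c) ** 2) / (y_cal.size - 1)))
    sep = float(np.sqrt(np.sum((e_val - bias_p) ** 2) / (y_val.size - 1)))

    return ModelMetrics(
        r2_c=r2_c,
        rmsec=rmsec,
        rpd_c=_rpd(y_cal, rmsec),
        sec=sec,
        secv=float(secv),
        r2_p=r2_p,
        rmsep=rmsep,
        rpd_p=_rpd(y_val, rmsep),
        sep=sep,
        bias=bias_p,
    )
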