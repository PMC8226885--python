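"""PLS1 regression and Monte-Carlo cross-validation (MCCV) evaluation.

The calibration model is single-response partial least squares (PLS1) on
mean-centered data — centering only, no autoscaling, the default in NIR
calibration where preprocessing already handles scale.  The core fit is a
vectorized NIPALS-with-deflation loop returning the regression vector
``beta`` for every component count up to a cap in one pass; wavelength
selectors fit tens of thousands of small PLS models, so this path is kept
free of per-call overhead.

Model assessment follows the MCCV design used for NIR calibration
transfer: one external hold-out set is fixed up front (never seen by
selection or latent-variable choice), and RMSECV is pooled over N random
re-splits of the calibration portion,

    RMSECV = sqrt( sum over repeats of squared validation errors
                   / (N * n_v) ).

Rc and Rp are Pearson correlations between predicted and measured values
(calibration-side pooled over MCCV validation predictions; prediction-side
on the external set), and RPD = sd(y_external) / RMSEP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .dataset import SpectraSet

__all__ = [
    "PLS1Regression",
    "PLSModel",
    "MccvConfig",
    "EvaluationReport",
    "fit_pls",
    "predict",
    "mccv_evaluate",
    "mccv_rmsecv",
    "MccvScorer",
    "rpd_band",
    "pls1_beta",
    "pls1_beta_path",
]

_TINY = 1e-14


def pls1_beta_path(X, y, n_components):
    """PLS1 regression vectors for every component count 1..n_components.

    Returns ``(betas, x_mean, y_mean)`` where ``betas`` has shape
    ``(k_eff, p)`` and row ``a`` is beta for ``a+1`` components, mapping raw
    X to y via ``yhat = (X - x_mean) @ beta + y_mean``.  The path may stop
    early (``k_eff < n_components``) if the residual collapses.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    k = int(n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    k = min(k, n - 1, p)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    if np.abs(yc).max() < _TINY:
        raise ValueError("constant y: regression undefined")

    W = np.empty((p, k))
    P = np.empty((p, k))
    q = np.empty(k)
    betas = []
    n_eff = 0
    for a in range(k):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < _TINY:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt < _TINY:
            break
        pl = Xc.T @ t / tt
        qa = (yc @ t) / tt
        Xc -= np.outer(t, pl)
        yc -= qa * t
        W[:, a] = w
        P[:, a] = pl
        q[a] = qa
        n_eff = a + 1
        # beta_a = W_a (P_a^T W_a)^{-1} q_a
        Wa = W[:, :n_eff]
        beta = Wa @ np.linalg.solve(P[:, :n_eff].T @ Wa, q[:n_eff])
        betas.append(beta)
    if n_eff == 0:
        raise ValueError("degenerate input: no PLS component extractable")
    return np.array(betas), x_mean, y_mean


def pls1_beta(X, y, n_components):
    """Regression vector for exactly ``n_components`` latent variables."""
    betas, x_mean, y_mean = pls1_beta_path(X, y, n_components)
    return betas[-1], x_mean, y_mean


class PLS1Regression(BaseEstimator, RegressorMixin):
    """Single-response PLS regression (centering only).

    Parameters
    ----------
    n_components : int
        Number of latent variables.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Regression vector beta on centered data.
    x_mean_, y_mean_ : centering offsets.
    n_components_ : effective number of components extracted.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        betas, x_mean, y_mean = pls1_beta_path(X, y, self.n_components)
        self.coef_ = betas[-1]
        self.n_components_ = betas.shape[0]
        self.x_mean_ = x_mean
        self.y_mean_ = y_mean
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"channel mismatch: model expects p={self.n_features_in_}, "
                f"got p={X.shape[1]}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


@dataclass
class PLSModel:
    """Fitted PLS1 model: ``yhat = (X - x_mean) @ beta + y_mean``."""

    n_components: int
    beta: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    training_meta: dict = field(default_factory=dict)


def fit_pls(spectra: SpectraSet, n_components: int) -> PLSModel:
    """Fit PLS1 on a SpectraSet carrying reference values."""
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    cap = min(spectra.n_samples - 1, spectra.n_channels)
    if n_components > cap:
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)={cap}")
    beta, x_mean, y_mean = pls1_beta(spectra.X, spectra.y, n_components)
    return PLSModel(
        n_components=n_components,
        beta=beta,
        x_mean=x_mean,
        y_mean=float(y_mean),
        training_meta={
            "n": spectra.n_samples,
            "p": spectra.n_channels,
            "wavelengths_nm": spectra.wavelengths.tolist(),
        },
    )


def predict(model: PLSModel, spectra: SpectraSet) -> np.ndarray:
    if spectra.n_channels != model.beta.shape[0]:
        raise ValueError(
            f"channel mismatch: model expects p={model.beta.shape[0]}, "
            f"got p={spectra.n_channels}"
        )
    return (spectra.X - model.x_mean) @ model.beta + model.y_mean


# ----------------------------------------------------------------------
# Monte-Carlo cross-validation


@dataclass
class MccvConfig:
    """MCCV design: repeats, calibration share, seed, LV cap.

    ``calibration_size`` may be an absolute count or a fraction of n; the
    default 145/195 mirrors the common 3:1 calibration/external split used
    for fruit-quality NIR calibrations.
    """

    n_repeats: int = 100
    calibration_size: float = 145 / 195
    seed: int = 0
    max_components: int = 20

    def resolve_calibration(self, n: int) -> int:
        cs = self.calibration_size
        nc = int(round(cs * n)) if 0 < cs < 1 else int(cs)
        if not 2 <= nc < n:
            raise ValueError(f"calibration size {nc} invalid for n={n}")
        return nc


RPD_BANDS = (
    (2.5, "excellent"),
    (2.0, "very good"),
    (1.8, "good"),
    (1.4, "fair"),
    (1.0, "poor"),
)


def rpd_band(rpd: float) -> str:
    """Qualitative rating of an RPD value.

    > 2.5 excellent; [2, 2.5] very good; [1.8, 2) good; [1.4, 1.8) fair;
    [1, 1.4) poor; < 1 very poor.  Note 2.5 itself rates "very good".
    """
    if rpd < 0:
        raise ValueError("RPD must be non-negative")
    if rpd > 2.5:
        return "excellent"
    for lo, label in RPD_BANDS[1:]:
        if rpd >= lo:
            return label
    return "very poor"


@dataclass
class EvaluationReport:
    """Calibration/prediction statistics of one evaluated model."""

    Rc: float
    RMSECV: float
    Rp: float
    RMSEP: float
    RPD: float
    n_components: int
    rpd_band: str
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "Rc": self.Rc,
            "RMSECV": self.RMSECV,
            "Rp": self.Rp,
            "RMSEP": self.RMSEP,
            "RPD": self.RPD,
            "n_components": self.n_components,
            "rpd_band": self.rpd_band,
        }
        d["meta"] = {
            k: v for k, v in self.meta.items() if k != "per_split"
        }
        return d

    def summary_row(self, method: str = "", n_vars: Optional[int] = None) -> str:
        nv = "" if n_vars is None else f"{n_vars:>6d}"
        return (
            f"{method:<16s} {self.n_components:>3d} {nv:>6s} "
            f"{self.Rc:7.3f} {self.RMSECV:9.4f} {self.Rp:7.3f} "
            f"{self.RMSEP:9.4f} {self.RPD:7.3f}  {self.rpd_band}"
        )


def _pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa = a.std()
    sb = b.std()
    if sa < _TINY or sb < _TINY:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def mccv_rmsecv(
    X,
    y,
    n_components: int,
    n_repeats: int = 10,
    calibration_fraction: float = 145 / 195,
    rng=None,
) -> float:
    """Pooled MCCV RMSE at a fixed component count (selector workhorse)."""
    rng = np.random.default_rng(rng)
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    nc = max(2, min(n - 1, int(round(calibration_fraction * n))))
    sq = 0.0
    cnt = 0
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        cal, val = perm[:nc], perm[nc:]
        k = min(n_components, nc - 1, X.shape[1])
        beta, xm, ym = pls1_beta(X[cal], y[cal], k)
        err = (X[val] - xm) @ beta + ym - y[val]
        sq += float(err @ err)
        cnt += val.size
    return float(np.sqrt(sq / cnt))


class MccvScorer:
    """Pooled MCCV RMSE on a fixed set of calibration/validation splits.

    Selector search loops evaluate thousands of candidate channel subsets;
    holding the splits fixed makes their RMSEs directly comparable
    (common random numbers) instead of confounding subset quality with
    split luck.  ``rmse(idx)`` optimises the LV count along the PLS path
    up to ``max_components``; ``rmse(idx, n_components=k)`` scores at a
    fixed count.
    """

    def __init__(self, X, y, n_repeats=10, max_components=10, rng=None,
                 calibration_fraction=145 / 195):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float).ravel()
        self.max_components = max_components
        rng = np.random.default_rng(rng)
        n = self.X.shape[0]
        nc = max(2, min(n - 1, int(round(calibration_fraction * n))))
        self.splits = [
            (p[:nc], p[nc:]) for p in (rng.permutation(n) for _ in range(n_repeats))
        ]

    def rmse(self, channel_idx, n_components=None) -> float:
        idx = np.asarray(channel_idx, dtype=int)
        if idx.size == 0:
            return float(np.std(self.y))
        Xs = self.X[:, idx]
        kmax = n_components or self.max_components
        preds, meas = [], []
        for cal, val in self.splits:
            k = min(kmax, cal.size - 1, idx.size)
            betas, xm, ym = pls1_beta_path(Xs[cal], self.y[cal], k)
            yh = (Xs[val] - xm) @ betas.T + ym
            if betas.shape[0] < kmax:
                yh = np.hstack(
                    [yh, np.repeat(yh[:, -1:], kmax - betas.shape[0], axis=1)]
                )
            preds.append(yh)
            meas.append(self.y[val])
        P = np.vstack(preds)
        m = np.concatenate(meas)
        per_k = np.sqrt(np.mean((P - m[:, None]) ** 2, axis=0))
        if n_components is not None:
            return float(per_k[min(n_components, per_k.size) - 1])
        return float(per_k.min())


def mccv_evaluate(
    spectra: SpectraSet,
    config: MccvConfig,
    n_components: Optional[int] = None,
    external_indices=None,
) -> EvaluationReport:
    """Evaluate a PLS calibration by MCCV with a fixed external hold-out.

    The external set (``n - calibration_size`` samples) is drawn once from
    the seed (or supplied explicitly); MCCV repeats re-split only the
    calibration portion, at the same calibration fraction.  When
    ``n_components`` is None the LV count minimising pooled RMSECV over
    ``[1, max_components]`` is chosen.  Rp/RMSEP/RPD come from a single
    fit on the full calibration set predicted onto the external set.
    """
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    n = spectra.n_samples
    nc = config.resolve_calibration(n)
    rng = np.random.default_rng(config.seed)
    if external_indices is None:
        perm = rng.permutation(n)
        cal_idx, ext_idx = perm[:nc], perm[nc:]
    else:
        ext_idx = np.asarray(external_indices, int)
        cal_idx = np.setdiff1d(np.arange(n), ext_idx)
    X_cal, y_cal = spectra.X[cal_idx], spectra.y[cal_idx]
    X_ext, y_ext = spectra.X[ext_idx], spectra.y[ext_idx]
    n_cal = cal_idx.size
    frac = nc / n
    n_inner = max(2, min(n_cal - 1, int(round(frac * n_cal))))
    kmax = min(config.max_components, n_inner - 1, spectra.n_channels)
    if n_components is not None:
        kmax = min(max(n_components, 1), n_inner - 1, spectra.n_channels)

    # Pool validation predictions for every candidate LV count in one pass.
    preds = [[] for _ in range(kmax)]
    meas = []
    splits = []
    for _ in range(config.n_repeats):
        perm = rng.permutation(n_cal)
        tr, va = perm[:n_inner], perm[n_inner:]
        betas, xm, ym = pls1_beta_path(X_cal[tr], y_cal[tr], kmax)
        Xv = X_cal[va] - xm
        yh = Xv @ betas.T + ym  # (n_va, k_eff)
        if betas.shape[0] < kmax:  # degenerate early stop: repeat last column
            pad = np.repeat(yh[:, -1:], kmax - betas.shape[0], axis=1)
            yh = np.hstack([yh, pad])
        for k in range(kmax):
            preds[k].append(yh[:, k])
        meas.append(y_cal[va])
        splits.append({"val_idx": cal_idx[va], "pred": yh})
    meas_pool = np.concatenate(meas)
    rmse_k = np.array(
        [
            np.sqrt(np.mean((np.concatenate(preds[k]) - meas_pool) ** 2))
            for k in range(kmax)
        ]
    )
    if n_components is None:
        k_best = int(np.argmin(rmse_k)) + 1
    else:
        k_best = min(n_components, kmax)
    rmsecv = float(rmse_k[k_best - 1])
    rc = _pearson(np.concatenate(preds[k_best - 1]), meas_pool)

    beta, xm, ym = pls1_beta(X_cal, y_cal, min(k_best, n_cal - 1))
    yhat_ext = (X_ext - xm) @ beta + ym
    rmsep = float(np.sqrt(np.mean((yhat_ext - y_ext) ** 2)))
    rp = _pearson(yhat_ext, y_ext)
    sd_ext = float(np.std(y_ext, ddof=1))
    rpd = sd_ext / rmsep if rmsep > 0 else np.inf
    return EvaluationReport(
        Rc=rc,
        RMSECV=rmsecv,
        Rp=rp,
        RMSEP=rmsep,
        RPD=float(rpd),
        n_components=k_best,
        rpd_band=rpd_band(max(rpd, 0.0)) if np.isfinite(rpd) else "excellent",
        meta={
            "n": n,
            "n_calibration": int(n_cal),
            "n_external": int(ext_idx.size),
            "n_repeats": config.n_repeats,
            "rmse_by_components": rmse_k.tolist(),
            "external_sd": sd_ext,
            "external_indices": ext_idx.tolist(),
            "per_split": splits,
        },
    )
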