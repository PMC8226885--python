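"""Spectral pretreatment operators.

Each operator is a scikit-learn transformer acting row-wise on an
``(n_samples, n_channels)`` absorbance matrix, plus a thin functional
wrapper taking and returning a :class:`~nirselect.dataset.SpectraSet`.

Implemented set (the one evaluated in practice for diffuse-reflectance
NIR): moving-average smoothing (MAS), maximum / mean / range
normalization, Savitzky-Golay first and second derivatives, multiplicative
scatter correction (MSC) and standard normal variate (SNV).

Conventions
-----------
* SNV uses the sample standard deviation (ddof=1), the dominant convention
  in chemometrics.
* MSC fits, per spectrum, the scalars (a, b) minimising
  ``sum((x - a - b*ref)^2)`` and returns ``(x - a)/b``.  The reference
  defaults to the column-wise mean of the *fitted* data and is stored, so
  held-out spectra are corrected against the calibration reference.
* Savitzky-Golay derivatives are scaled by the mean wavelength step so
  units are absorbance per nm (or nm^2); the operator stays linear even on
  a mildly non-uniform axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectraSet

__all__ = [
    "SNV",
    "MSC",
    "MovingAverage",
    "SavitzkyGolayDerivative",
    "RowNormalize",
    "PreprocessConfig",
    "snv",
    "msc",
    "moving_average",
    "savitzky_golay_derivative",
    "normalize",
    "apply_preprocess",
    "PREPROCESS_METHODS",
]

_EPS_SPREAD = 1e-12


class SNV(BaseEstimator, TransformerMixin):
    """Standard normal variate: centre and scale every spectrum to sd 1 (ddof=1)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        flat = np.flatnonzero(sd.ravel() < _EPS_SPREAD)
        if flat.size:
            raise ValueError(
                f"SNV undefined for constant spectra (rows {flat.tolist()})"
            )
        return (X - mean) / sd


class MSC(BaseEstimator, TransformerMixin):
    """Multiplicative scatter correction against a stored reference spectrum.

    Parameters
    ----------
    reference : array-like, optional
        Reference spectrum.  If None, the column-wise mean of the data seen
        in :meth:`fit` is used and stored as ``reference_``.
    """

    def __init__(self, reference=None):
        self.reference = reference

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (X.shape[1],):
                raise ValueError("reference length does not match channel count")
        else:
            if X.shape[0] < 2:
                raise ValueError("MSC needs >= 2 spectra to form a mean reference")
            ref = X.mean(axis=0)
        self.reference_ = ref
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        ref = self.reference_
        # Per-row least squares x ~ a + b*ref, closed form.
        rc = ref - ref.mean()
        denom = rc @ rc
        if denom < _EPS_SPREAD:
            raise ValueError("degenerate (constant) MSC reference")
        b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
        if np.any(np.abs(b) < _EPS_SPREAD):
            bad = np.flatnonzero(np.abs(b) < _EPS_SPREAD)
            raise ValueError(f"degenerate scatter fit (|b|~0) for rows {bad.tolist()}")
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]

    def fit_params(self, X):
        """Return the per-row fitted (a, b) without applying the correction."""
        check_is_fitted(self)
        X = check_array(X)
        ref = self.reference_
        rc = ref - ref.mean()
        b = (X - X.mean(axis=1, keepdims=True)) @ rc / (rc @ rc)
        a = X.mean(axis=1) - b * ref.mean()
        return a, b


class MovingAverage(BaseEstimator, TransformerMixin):
    """Centered moving-average smoothing with shrinking symmetric edge windows."""

    def __init__(self, window_points: int = 11):
        self.window_points = window_points

    def fit(self, X, y=None):
        X = check_array(X)
        w = self.window_points
        if w % 2 == 0 or w < 3:
            raise ValueError(f"window_points must be odd and >= 3, got {w}")
        if w > X.shape[1]:
            raise ValueError("window_points exceeds channel count")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        p = X.shape[1]
        half = self.window_points // 2
        out = uniform_filter1d(X, size=self.window_points, axis=1, mode="nearest")
        # Edges: truncated symmetric windows (half-width shrinks to fit).
        for j in range(half):
            out[:, j] = X[:, : 2 * j + 1].mean(axis=1)
            out[:, p - 1 - j] = X[:, p - 1 - 2 * j :].mean(axis=1)
        return out


class SavitzkyGolayDerivative(BaseEstimator, TransformerMixin):
    """Savitzky-Golay derivative filter scaled to per-nm units.

    ``deriv_order`` 1 or 2; the derivative is divided by the mean
    wavelength step (raised to the order) of the axis supplied at
    construction, so outputs are absorbance * nm^-order.  If no axis is
    given a unit step is assumed.
    """

    def __init__(self, deriv_order: int = 1, window_points: int = 11,
                 poly_order: int = 2, wavelengths=None):
        self.deriv_order = deriv_order
        self.window_points = window_points
        self.poly_order = poly_order
        self.wavelengths = wavelengths

    def fit(self, X, y=None):
        X = check_array(X)
        if self.deriv_order not in (1, 2):
            raise ValueError("deriv_order must be 1 or 2")
        if self.window_points % 2 == 0:
            raise ValueError("window_points must be odd")
        if self.poly_order < self.deriv_order:
            raise ValueError("poly_order must be >= deriv_order")
        if self.window_points <= self.poly_order:
            raise ValueError("window_points must exceed poly_order")
        if X.shape[1] < self.window_points:
            raise ValueError("fewer channels than window_points")
        self.n_features_in_ = X.shape[1]
        if self.wavelengths is not None:
            wl = np.asarray(self.wavelengths, dtype=float)
            self.step_ = float(np.mean(np.diff(wl)))
        else:
            self.step_ = 1.0
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return savgol_filter(
            X,
            window_length=self.window_points,
            polyorder=self.poly_order,
            deriv=self.deriv_order,
            delta=self.step_,
            axis=1,
            mode="interp",
        )


class RowNormalize(BaseEstimator, TransformerMixin):
    """Row-wise normalization: ``max`` (x/max), ``mean`` (x/mean) or
    ``range`` ((x-min)/(max-min))."""

    def __init__(self, mode: str = "max"):
        self.mode = mode

    def fit(self, X, y=None):
        X = check_array(X)
        if self.mode not in ("max", "mean", "range"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if self.mode == "max":
            denom = X.max(axis=1)
            shifted = X
        elif self.mode == "mean":
            denom = X.mean(axis=1)
            shifted = X
        else:
            mn = X.min(axis=1)
            denom = X.max(axis=1) - mn
            shifted = X - mn[:, None]
        bad = np.flatnonzero(np.abs(denom) < _EPS_SPREAD)
        if bad.size:
            raise ValueError(
                f"zero {self.mode} divisor for rows {bad.tolist()}"
            )
        return shifted / denom[:, None]


# ----------------------------------------------------------------------
# Functional wrappers on SpectraSet


def _wrap(spectra: SpectraSet, transformer) -> SpectraSet:
    return spectra.with_X(transformer.fit_transform(spectra.X))


def snv(spectra: SpectraSet) -> SpectraSet:
    try:
        return _wrap(spectra, SNV())
    except ValueError as exc:
        raise _name_rows(exc, spectra)


def msc(spectra: SpectraSet, reference=None) -> SpectraSet:
    return _wrap(spectra, MSC(reference=reference))


def moving_average(spectra: SpectraSet, window_points: int = 11) -> SpectraSet:
    return _wrap(spectra, MovingAverage(window_points=window_points))


def savitzky_golay_derivative(
    spectra: SpectraSet, order: int, window_points: int = 11, poly_order: int = 2
) -> SpectraSet:
    return _wrap(
        spectra,
        SavitzkyGolayDerivative(
            deriv_order=order,
            window_points=window_points,
            poly_order=poly_order,
            wavelengths=spectra.wavelengths,
        ),
    )


def normalize(spectra: SpectraSet, mode: str = "max") -> SpectraSet:
    try:
        return _wrap(spectra, RowNormalize(mode=mode))
    except ValueError as exc:
        raise _name_rows(exc, spectra)


def _name_rows(exc: ValueError, spectra: SpectraSet) -> ValueError:
    """Translate row indices in an error message into sample ids."""
    msg = str(exc)
    import re

    m = re.search(r"rows \[([\d, ]+)\]", msg)
    if m:
        rows = [int(v) for v in m.group(1).split(",")]
        ids = [spectra.sample_ids[r] for r in rows]
        msg = msg[: m.start()] + f"samples {ids}"
    return ValueError(msg)


@dataclass
class PreprocessConfig:
    """Serializable description of one pretreatment step."""

    method: str = "none"
    window_points: int = 11
    poly_order: int = 2
    msc_reference: Optional[list] = field(default=None, repr=False)

    _VALID = ("none", "mas", "max_norm", "mean_norm", "range_norm",
              "sg_d1", "sg_d2", "msc", "snv")

    def __post_init__(self):
        if self.method not in self._VALID:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {self._VALID}"
            )
        if self.window_points % 2 == 0 or self.window_points < 3:
            raise ValueError("window_points must be odd and >= 3")
        if self.poly_order >= self.window_points:
            raise ValueError("poly_order must be < window_points")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "window_points": self.window_points,
            "poly_order": self.poly_order,
        }


PREPROCESS_METHODS = PreprocessConfig._VALID


def apply_preprocess(spectra: SpectraSet, config: PreprocessConfig) -> SpectraSet:
    """Dispatch one named pretreatment over a SpectraSet."""
    m = config.method
    if m == "none":
        return spectra
    if m == "mas":
        return moving_average(spectra, config.window_points)
    if m == "max_norm":
        return normalize(spectra, "max")
    if m == "mean_norm":
        return normalize(spectra, "mean")
    if m == "range_norm":
        return normalize(spectra, "range")
    if m == "sg_d1":
        return savitzky_golay_derivative(spectra, 1, config.window_points, config.poly_order)
    if m == "sg_d2":
        return savitzky_golay_derivative(spectra, 2, config.window_points, config.poly_order)
    if m == "msc":
        return msc(spectra, reference=config.msc_reference)
    if m == "snv":
        return snv(spectra)
    raise ValueError(f"unknown method {m!r}")  # pragma: no cover
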