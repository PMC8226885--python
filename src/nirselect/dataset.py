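"""Core data model and file I/O for NIR spectra, reference values and selection results.

A :class:`SpectraSet` bundles an absorbance matrix ``X`` (n samples x p
channels) with its wavelength axis in nm, sample identifiers, and an
optional aligned vector of reference values ``y`` (e.g. soluble solid
content in °Brix, or titratable acidity in %).

Spectra are exchanged as plain CSV: the header row carries the wavelengths
in nm, the first column the sample ids.  Reference values live in a second
CSV mapping sample id to a numeric value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "WavelengthWindow",
    "SelectionResult",
    "read_spectra",
    "write_spectra",
    "crop",
]


@dataclass(frozen=True)
class WavelengthWindow:
    """Inclusive wavelength window [lo_nm, hi_nm] in nanometres."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError(
                f"invalid window: lo_nm={self.lo_nm} must be < hi_nm={self.hi_nm}"
            )


class SpectraSet:
    """Absorbance matrix with wavelength axis and optional aligned reference values.

    Parameters
    ----------
    X : array-like, shape (n_samples, n_channels)
        Absorbance values; must be finite.
    wavelengths : array-like, shape (n_channels,)
        Strictly increasing wavelength axis in nm.
    sample_ids : sequence of str, optional
        Unique sample labels; defaults to ``"s0001"...``.
    y : array-like, shape (n_samples,), optional
        Reference property values aligned to the rows of ``X``.
    y_units : str, optional
        Units carried as metadata (e.g. ``"°Brix"``).
    """

    def __init__(self, X, wavelengths, sample_ids=None, y=None, y_units=None):
        X = np.asarray(X, dtype=float)
        wavelengths = np.asarray(wavelengths, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        n, p = X.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 channels, got {X.shape}")
        if wavelengths.shape != (p,):
            raise ValueError(
                f"wavelength axis length {wavelengths.shape} does not match p={p}"
            )
        if not np.all(np.diff(wavelengths) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(
                f"non-finite absorbance at row {bad[0]}, channel {bad[1]}"
            )
        if sample_ids is None:
            sample_ids = [f"s{i + 1:04d}" for i in range(n)]
        sample_ids = [str(s) for s in sample_ids]
        if len(sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if y is not None:
            y = np.asarray(y, dtype=float)
            if y.shape != (n,):
                raise ValueError(f"y has shape {y.shape}, expected ({n},)")
        self.X = X
        self.wavelengths = wavelengths
        self.sample_ids = list(sample_ids)
        self.y = y
        self.y_units = y_units

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def with_X(self, X, wavelengths=None) -> "SpectraSet":
        """Return a copy with a replaced absorbance matrix (same samples)."""
        return SpectraSet(
            X,
            self.wavelengths if wavelengths is None else wavelengths,
            sample_ids=self.sample_ids,
            y=self.y,
            y_units=self.y_units,
        )

    def subset_channels(self, indices) -> "SpectraSet":
        """Return a copy restricted to the given channel indices (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            self.X[:, indices],
            self.wavelengths[indices],
            sample_ids=self.sample_ids,
            y=self.y,
            y_units=self.y_units,
        )

    def subset_samples(self, indices) -> "SpectraSet":
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            self.X[indices],
            self.wavelengths,
            sample_ids=[self.sample_ids[i] for i in indices],
            y=None if self.y is None else self.y[indices],
            y_units=self.y_units,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        return (
            f"SpectraSet(n={self.n_samples}, p={self.n_channels}, "
            f"axis={lo:.1f}-{hi:.1f} nm, y={'present' if self.y is not None else 'absent'})"
        )


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run.

    ``selected_indices`` always refer to the axis of the spectra the
    selector (or the first stage of a chain) was given.
    """

    selected_indices: np.ndarray
    selected_wavelengths_nm: np.ndarray
    method_name: str
    iteration_log: list = field(default_factory=list)
    rmse_trajectory: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise ValueError("selected_indices must be sorted and unique")
        self.selected_indices = idx
        self.selected_wavelengths_nm = np.asarray(
            self.selected_wavelengths_nm, dtype=float
        )

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    def to_dict(self) -> dict:
        return {
            "method_name": self.method_name,
            "n_selected": self.n_selected,
            "selected_indices": self.selected_indices.tolist(),
            "selected_wavelengths_nm": self.selected_wavelengths_nm.tolist(),
            "rmse_trajectory": [float(v) for v in self.rmse_trajectory],
            "iteration_log": _jsonable(self.iteration_log),
            "meta": _jsonable(self.meta),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ----------------------------------------------------------------------
# I/O


def read_spectra(spectra_path, reference_path=None, y_units=None) -> SpectraSet:
    """Read a spectra CSV (header = wavelengths, first column = sample id).

    When ``reference_path`` is given its values are aligned to the spectra
    rows by sample id; ids missing from the reference table are reported
    with a warning and ``y`` is set to NaN-free only if every id matched
    (otherwise ``y`` is omitted entirely).
    """
    df = pd.read_csv(spectra_path, index_col=0, float_precision="round_trip")
    try:
        wavelengths = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {spectra_path}: {exc}")
    if not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelength header must be strictly increasing")
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    X = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        r, c = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(
            f"non-numeric or non-finite value at sample {ids[r]!r}, "
            f"wavelength {df.columns[c]}"
        )

    y = None
    if reference_path is not None:
        ref = pd.read_csv(reference_path, index_col=0, float_precision="round_trip")
        ref.index = ref.index.map(str)
        if ref.index.has_duplicates:
            raise ValueError("duplicate sample ids in reference table")
        col = ref.columns[0]
        missing = [i for i in ids if i not in ref.index]
        if missing:
            warnings.warn(
                f"reference values missing for ids {missing}; y omitted",
                stacklevel=2,
            )
        else:
            y = ref.loc[ids, col].to_numpy(dtype=float)
            if y_units is None:
                y_units = col
    return SpectraSet(X, wavelengths, sample_ids=ids, y=y, y_units=y_units)


def write_spectra(spectra: SpectraSet, spectra_path, reference_path=None) -> None:
    """Write a SpectraSet back to CSV (inverse of :func:`read_spectra`)."""
    df = pd.DataFrame(
        spectra.X,
        index=pd.Index(spectra.sample_ids, name="id"),
        columns=[repr(float(w)) for w in spectra.wavelengths],
    )
    df.to_csv(spectra_path, float_format=lambda v: repr(float(v)))
    if reference_path is not None and spectra.y is not None:
        pd.DataFrame(
            {spectra.y_units or "value": spectra.y},
            index=pd.Index(spectra.sample_ids, name="id"),
        ).to_csv(reference_path, float_format=lambda v: repr(float(v)))


def crop(spectra: SpectraSet, window: WavelengthWindow) -> SpectraSet:
    """Restrict a SpectraSet to channels with lo_nm <= wavelength <= hi_nm."""
    mask = (spectra.wavelengths >= window.lo_nm) & (spectra.wavelengths <= window.hi_nm)
    if not mask.any():
        raise ValueError(
            f"window [{window.lo_nm}, {window.hi_nm}] excludes all channels"
        )
    if mask.sum() < 2:
        raise ValueError("window retains fewer than 2 channels")
    return spectra.subset_channels(np.flatnonzero(mask))
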