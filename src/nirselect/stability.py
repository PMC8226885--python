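"""Variable stability in the sample space.

A channel's stability is defined from the spread of its PLS regression
coefficient over Monte-Carlo subsamples of the calibration set: draw M
subsets of n1 samples (without replacement), fit PLS1 on each, collect the
coefficient matrix beta (p x M), and set

    S_i = mean(beta_i·) / (std(beta_i·) + eps)

with a small eps guarding the noise-free case where the coefficient does
not vary at all.  A channel whose coefficient is consistently large and of
stable sign scores high |S|; channels whose coefficients flip sign or
wander across subsamples score near zero.  Selection logic compares |S|:
a strongly negative coefficient is as informative as a positive one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraSet
from .pls import pls1_beta

__all__ = ["StabilityConfig", "StabilityProfile", "compute_stability"]

EPS_STD = 1e-12


@dataclass
class StabilityConfig:
    """Monte-Carlo design for the stability estimate.

    ``subsample_size`` may be an absolute count or a fraction of n
    (default 0.8·n).  ``n_components`` is the LV count of the per-subset
    PLS fits; the default of 1 makes each coefficient vector proportional
    to the centered covariance of the channels with y, so the ranking
    reflects each channel's own association with the property.  Deeper
    fits concentrate weight on a few channels of a collinear band and
    spread correction weight onto background channels, which blurs the
    ranking; they remain available for sensitivity checks.
    """

    n_sample_spaces: int = 100
    subsample_size: float = 0.8
    n_components: int = 1
    seed: int = 0

    def resolve_subsample(self, n: int) -> int:
        s = self.subsample_size
        n1 = int(round(s * n)) if 0 < s < 1 else int(s)
        if not 2 <= n1 < n:
            raise ValueError(f"subsample size {n1} invalid for n={n}")
        return n1


@dataclass
class StabilityProfile:
    S: np.ndarray
    beta_matrix: np.ndarray  # p x M
    beta_mean: np.ndarray
    beta_std: np.ndarray
    saturated: bool = False
    meta: dict = field(default_factory=dict)

    def abs_ranking(self) -> np.ndarray:
        """Channel indices ordered by decreasing |S|."""
        return np.argsort(-np.abs(self.S), kind="stable")

    def to_frame(self, wavelengths=None):
        import pandas as pd

        data = {"S": self.S, "beta_mean": self.beta_mean, "beta_std": self.beta_std}
        if wavelengths is not None:
            return pd.DataFrame(data, index=pd.Index(wavelengths, name="wavelength_nm"))
        return pd.DataFrame(data)


def compute_stability(
    spectra: SpectraSet, config: StabilityConfig, rng=None
) -> StabilityProfile:
    """Stability S_i of every channel from M Monte-Carlo subsample PLS fits.

    An explicit ``rng`` overrides ``config.seed`` so a caller iterating
    many rounds can keep one reproducible stream.
    """
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    n, p = spectra.n_samples, spectra.n_channels
    M = config.n_sample_spaces
    if M < 2:
        raise ValueError("n_sample_spaces must be >= 2")
    n1 = config.resolve_subsample(n)
    if n1 <= config.n_components:
        raise ValueError(
            f"subsample size {n1} must exceed n_components={config.n_components}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = min(config.n_components, n1 - 1, p)
    B = np.empty((p, M))
    X, y = spectra.X, spectra.y
    for m in range(M):
        idx = rng.choice(n, size=n1, replace=False)
        beta, _, _ = pls1_beta(X[idx], y[idx], k)
        B[:, m] = beta
    mean = B.mean(axis=1)
    std = B.std(axis=1)  # population sd over the M fits
    saturated = bool(np.any(std < EPS_STD))
    S = mean / (std + EPS_STD)
    return StabilityProfile(
        S=S,
        beta_matrix=B,
        beta_mean=mean,
        beta_std=std,
        saturated=saturated,
        meta={"M": M, "n1": n1, "n_components": k},
    )
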