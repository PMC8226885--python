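"""Seeded generator of NIR-like diffuse-reflectance spectra with planted bands.

The generator emulates the morphology of fruit diffuse-reflectance NIR
absorbance in the 1000-2300 nm region: a handful of Gaussian absorption
bands whose amplitudes scale linearly with a latent property (the
"informative" bands, standing in for overtone/combination bands such as
those near 1450 and 1940 nm), concentration-independent nuisance bands
with random amplitudes, a smooth polynomial baseline with a considerable
offset, per-sample multiplicative gain and additive offset (scatter), and
white noise.  Informative band centres additionally wander a few nm from
sample to sample (the temperature-style peak shifts familiar from NIR
water bands), which makes retaining a whole band — shoulders included —
genuinely better than cherry-picking its core channels.  It is a test bed
for wavelength selectors, not a radiative-transfer simulation of fruit
tissue.

The ground-truth informative channel set — all channels within two band
widths of an informative band centre — is available for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .dataset import SpectraSet

__all__ = ["SyntheticScenario", "generate", "informative_channels", "reference_scenario"]

Band = Tuple[float, float, float]  # (center nm, width nm, loading)


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic-spectra draw.

    ``bands`` are (center_nm, width_nm, loading) triples; a band
    contributes ``loading * c * exp(-(lambda-center)^2 / (2 width^2))`` to
    sample absorbance, where ``c`` is the latent property drawn uniformly
    from ``target_range``.  ``nuisance_bands`` are (center, width,
    max_amplitude) with per-sample amplitude uniform in [0, max].  When
    ``noise_sd`` is None it is derived from ``snr`` as
    (largest band amplitude span over the target range) / snr.
    """

    n_samples: int = 200
    axis: np.ndarray = field(
        default_factory=lambda: np.linspace(1000.0, 2300.0, 400)
    )
    bands: Sequence[Band] = (
        (1450.0, 20.0, 0.050),
        (1780.0, 20.0, 0.050),
        (2150.0, 20.0, 0.050),
    )
    band_center_jitter_nm: float = 8.0
    nuisance_bands: Sequence[Band] = (
        (1050.0, 30.0, 0.060),
        (1120.0, 30.0, 0.050),
        (1190.0, 35.0, 0.040),
        (1300.0, 30.0, 0.060),
        (1560.0, 20.0, 0.040),
        (1650.0, 25.0, 0.060),
        (1880.0, 25.0, 0.050),
        (1950.0, 40.0, 0.080),
        (2020.0, 25.0, 0.050),
        (2260.0, 20.0, 0.050),
    )
    scatter_gain_sd: float = 0.003
    scatter_offset_sd: float = 0.001
    baseline_order: int = 2
    baseline_sd: float = 0.001
    snr: float = 20.0
    noise_sd: Optional[float] = None
    edge_noise_factor: float = 7.0
    edge_noise_scale_nm: float = 60.0
    target_range: Tuple[float, float] = (8.0, 12.0)
    y_units: str = "°Brix"
    seed: int = 7

    def validate(self) -> None:
        problems = []
        axis = np.asarray(self.axis, float)
        if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
            problems.append("axis must be a strictly increasing 1-D grid")
        lo, hi = axis[0], axis[-1]
        for c, w, a in self.bands:
            if not lo <= c <= hi:
                problems.append(f"band center {c} nm outside axis [{lo}, {hi}]")
            if w <= 0:
                problems.append(f"band width {w} must be positive")
        for c, w, a in self.nuisance_bands:
            if w <= 0:
                problems.append(f"nuisance band width {w} must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if self.band_center_jitter_nm < 0:
            problems.append("band_center_jitter_nm must be >= 0")
        if self.edge_noise_factor < 0 or self.edge_noise_scale_nm <= 0:
            problems.append("edge noise factor must be >= 0 and scale positive")
        if self.snr <= 0:
            problems.append("snr must be positive")
        if self.n_samples < 2:
            problems.append("n_samples must be >= 2")
        if not self.target_range[0] < self.target_range[1]:
            problems.append("target_range must be (lo, hi) with lo < hi")
        if problems:
            raise ValueError("invalid scenario: " + "; ".join(problems))

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        lo, hi = self.target_range
        span = max((abs(a) * (hi - lo) for _, _, a in self.bands), default=0.0)
        return span / self.snr if span > 0 else 0.0


def reference_scenario(seed: int = 7, n_samples: int = 200) -> SyntheticScenario:
    """The package's standard fixture: 400 channels in 1000-2300 nm, three
    informative 20 nm bands at 1450/1780/2150 nm, SNR 20."""
    return SyntheticScenario(n_samples=n_samples, seed=seed)


def _gaussian(axis: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((axis - center) / width) ** 2)


def generate(scenario: SyntheticScenario) -> SpectraSet:
    """Draw one SpectraSet from the scenario (deterministic in the seed)."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    axis = np.asarray(scenario.axis, float)
    n, p = scenario.n_samples, axis.size
    lo, hi = scenario.target_range
    c = rng.uniform(lo, hi, size=n)

    u = (axis - axis[0]) / (axis[-1] - axis[0])
    # Shared background: rising baseline with two broad fixed humps, the
    # "considerable baseline offset" of diffuse-reflectance absorbance.
    background = (
        0.4
        + 1.2 * u
        + 0.25 * _gaussian(axis, 1950.0, 60.0)
        + 0.15 * _gaussian(axis, 1300.0, 50.0)
    )

    signal = np.tile(background, (n, 1))
    jit = scenario.band_center_jitter_nm
    for center, width, loading in scenario.bands:
        shifts = rng.normal(0.0, jit, size=n) if jit > 0 else np.zeros(n)
        signal += (c * loading)[:, None] * np.exp(
            -0.5 * ((axis[None, :] - center - shifts[:, None]) / width) ** 2
        )
    for center, width, amp in scenario.nuisance_bands:
        amps = rng.uniform(0.0, amp, size=n)
        signal += np.outer(amps, _gaussian(axis, center, width))
    if scenario.baseline_order >= 0:
        coefs = rng.normal(0.0, scenario.baseline_sd,
                           size=(n, scenario.baseline_order + 1))
        powers = np.vstack([u**d for d in range(scenario.baseline_order + 1)])
        signal += coefs @ powers

    gain = rng.normal(1.0, scenario.scatter_gain_sd, size=n)
    offset = rng.normal(0.0, scenario.scatter_offset_sd, size=n)
    noise_sd = scenario.resolved_noise_sd()
    # Channel-wise noise floor: flat mid-spectrum, rising toward both axis
    # ends where real detectors degrade (the reason edge regions are
    # trimmed or selected away in practice).
    f, w = scenario.edge_noise_factor, scenario.edge_noise_scale_nm
    ramp = f * np.exp(-(axis - axis[0]) / w) + f * np.exp(-(axis[-1] - axis) / w)
    channel_sd = noise_sd * np.sqrt(1.0 + ramp**2)
    noise = (
        rng.normal(0.0, 1.0, size=(n, p)) * channel_sd
        if noise_sd > 0
        else 0.0
    )
    X = gain[:, None] * signal + offset[:, None] + noise
    return SpectraSet(X, axis, y=c, y_units=scenario.y_units)


def informative_channels(scenario: SyntheticScenario) -> np.ndarray:
    """Ground-truth channel indices within +/- 2 widths of any informative band."""
    scenario.validate()
    axis = np.asarray(scenario.axis, float)
    mask = np.zeros(axis.size, dtype=bool)
    for center, width, _ in scenario.bands:
        mask |= np.abs(axis - center) <= 2.0 * width
    return np.flatnonzero(mask)
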