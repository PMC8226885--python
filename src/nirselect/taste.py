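"""Taste index for fruit quality and its weighted transform.

The taste index (TI) of a fruit sample is the ratio of soluble solid
content (SSC, °Brix) to titratable acidity (TA, %),

    TI = SSC / TA.

Because TI lives on a scale two orders of magnitude above TA, calibration
uses a weighted recombination that brings both onto a common scale:

    nV_TI = TA * (P_TA/100) + TI * 0.119 * (P_TI/100),

with percentage weights P_TA + P_TI = 100 (default 90/10).  The 0.119
scale factor is kept as a fixed constant (numerically close to a typical
mean TA, which makes the second term roughly SSC-scaled); it is exposed in
:class:`TasteIndexParams` for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TasteIndexParams", "taste_index", "transform_ti"]


@dataclass(frozen=True)
class TasteIndexParams:
    p_ta: float = 90.0
    p_ti: float = 10.0
    scale: float = 0.119

    def __post_init__(self):
        if not (0 <= self.p_ta <= 100 and 0 <= self.p_ti <= 100):
            raise ValueError("weights must lie in [0, 100]")
        if abs(self.p_ta + self.p_ti - 100.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 100, got {self.p_ta} + {self.p_ti}"
            )


def taste_index(ssc, ta):
    """TI = SSC / TA; element-wise on arrays.  TA must be positive."""
    ssc = np.asarray(ssc, dtype=float)
    ta = np.asarray(ta, dtype=float)
    if np.any(ta <= 0):
        raise ValueError("TA must be positive to form the SSC/TA ratio")
    out = ssc / ta
    return float(out) if out.ndim == 0 else out


def transform_ti(ta, ti, params: TasteIndexParams | None = None):
    """Weighted transform nV_TI = TA*(P_TA/100) + TI*scale*(P_TI/100)."""
    if params is None:
        params = TasteIndexParams()
    ta = np.asarray(ta, dtype=float)
    ti = np.asarray(ti, dtype=float)
    out = ta * (params.p_ta / 100.0) + ti * params.scale * (params.p_ti / 100.0)
    return float(out) if out.ndim == 0 else out
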