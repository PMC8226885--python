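"""Variable stability and cluster analysis algorithm (VSCAA).

VSCAA selects informative wavelengths by combining two views of each
channel:

* **stability** in the *sample* space — the ratio of mean to spread of the
  channel's PLS coefficient over Monte-Carlo subsamples (see
  :mod:`nirselect.stability`); and
* **frequency** in the *variable* space — how often the channel appears
  among the best-RMSE random-subset PLS submodels.

Each iteration (1) splits the surviving channels into "useful" and
"useless" sets by weighted bootstrap sampling (WBS) with weights
proportional to |S|; (2) profiles channel frequencies over W random
variable spaces, keeping the best fraction of submodels; (3) shrinks the
survivor set to a target given by an exponential decay schedule
r_i = alpha * exp(-k*i) — removing low-frequency channels from the
useless set first, and only cutting into the useful set (by low |S|) when
the target drops below its size; (4) scores the survivors by a small
internal MCCV.  After N loops the iteration with the minimum recorded
RMSE supplies the selected wavelengths.

The decay constants follow the CARS convention, alpha = (p/2)^(1/(N-1)),
k = ln(p/2)/(N-1), which retains everything at iteration 1 and exactly two
variables at iteration N.  A literal ``as_printed`` variant of the decay
rate (k divided by a further N-1) is kept for audit; it eliminates almost
nothing and is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .dataset import SpectraSet, SelectionResult
from .pls import MccvScorer
from .stability import StabilityConfig, StabilityProfile, compute_stability

__all__ = [
    "VscaaConfig",
    "DecaySchedule",
    "FrequencyProfile",
    "decay_schedule",
    "wbs_partition",
    "frequency_profile",
    "vscaa_select",
    "chain_select",
    "VSCAASelector",
]


# ----------------------------------------------------------------------
# Exponential decay schedule


@dataclass(frozen=True)
class DecaySchedule:
    """Retained-variable schedule r_i = alpha * exp(-k*i), i = 1..N."""

    alpha: float
    k: float
    r: np.ndarray          # retained fraction per iteration
    counts: np.ndarray     # retained count per iteration (non-increasing, >= 2)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "k": self.k,
            "r": self.r.tolist(),
            "counts": self.counts.tolist(),
        }


def decay_schedule(p: int, N: int, mode: str = "cars_standard") -> DecaySchedule:
    """Build the elimination schedule for ``p`` initial variables, ``N`` loops.

    ``cars_standard``: k = ln(p/2)/(N-1), so r_1 = 1 (keep all) and
    r_N * p = 2 (keep two).  ``as_printed``: k = ln((p/2)^(1/(N-1)))/(N-1).
    ``r_i`` is interpreted as a retained *fraction* of the initial count.
    """
    if p < 4:
        raise ValueError("decay schedule needs p >= 4")
    if N < 2:
        raise ValueError("decay schedule needs N >= 2")
    alpha = (p / 2.0) ** (1.0 / (N - 1))
    if mode == "cars_standard":
        k = math.log(p / 2.0) / (N - 1)
    elif mode == "as_printed":
        k = math.log((p / 2.0) ** (1.0 / (N - 1))) / (N - 1)
    else:
        raise ValueError(f"unknown decay mode {mode!r}")
    i = np.arange(1, N + 1)
    r = alpha * np.exp(-k * i)
    counts = np.clip(np.rint(r * p).astype(int), 2, p)
    counts = np.minimum.accumulate(counts)
    return DecaySchedule(alpha=alpha, k=k, r=r, counts=counts)


# ----------------------------------------------------------------------
# WBS partition and frequency profiling


def wbs_partition(stability: StabilityProfile | np.ndarray, seed=None):
    """Split channels into useful/useless by weighted bootstrap sampling.

    Draws p with-replacement samples over the p channels with probability
    proportional to |S_i|; the distinct channels drawn form the useful
    set.  With equal weights the expected useful fraction is
    1 - (1 - 1/p)^p (about 0.632 for large p).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    S = stability.S if isinstance(stability, StabilityProfile) else np.asarray(stability)
    w = np.abs(np.asarray(S, dtype=float))
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero stability weights: WBS partition undefined")
    p = w.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(p, size=p, replace=True, p=w / total)
    useful = np.unique(draws)
    mask = np.zeros(p, dtype=bool)
    mask[useful] = True
    useless = np.flatnonzero(~mask)
    return useful, useless


@dataclass
class FrequencyProfile:
    """Occurrence counts of each channel among the retained best submodels."""

    f: np.ndarray
    spaces_evaluated: int
    models_kept: int


def frequency_profile(
    spectra: SpectraSet,
    space_size: int,
    n_spaces: int = 500,
    model_retention: float = 0.1,
    n_components: int = 5,
    seed=None,
) -> FrequencyProfile:
    """Channel frequencies over random variable spaces.

    Builds ``n_spaces`` random channel subsets of size ``space_size``, fits
    PLS1 on each, ranks the submodels by validation RMSE on one shared
    random hold-out split (a fifth of the samples), keeps the best
    ``ceil(model_retention * n_spaces)``, and counts how often each channel
    occurs among the kept submodels.  Ranking on held-out rather than
    in-sample error keeps subsets full of interferent channels — which fit
    the calibration set well but predict poorly — from being rewarded.
    """
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    n, p = spectra.n_samples, spectra.n_channels
    if not 2 <= space_size <= p:
        raise ValueError(f"space_size {space_size} out of range [2, {p}]")
    if not 0 < model_retention <= 1:
        raise ValueError("model_retention must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X, y = spectra.X, spectra.y
    from .pls import pls1_beta

    perm = rng.permutation(n)
    n_tr = max(2, n - max(1, n // 5))
    tr, va = perm[:n_tr], perm[n_tr:]
    k = min(n_components, n_tr - 1, space_size)
    subsets = np.empty((n_spaces, space_size), dtype=int)
    rmse = np.empty(n_spaces)
    for w_i in range(n_spaces):
        idx = rng.choice(p, size=space_size, replace=False)
        beta, xm, ym = pls1_beta(X[np.ix_(tr, idx)], y[tr], k)
        resid = (X[np.ix_(va, idx)] - xm) @ beta + ym - y[va]
        rmse[w_i] = np.sqrt(np.mean(resid**2))
        subsets[w_i] = idx
    n_keep = max(1, math.ceil(model_retention * n_spaces))
    kept = np.argsort(rmse, kind="stable")[:n_keep]
    f = np.bincount(subsets[kept].ravel(), minlength=p)
    return FrequencyProfile(f=f, spaces_evaluated=n_spaces, models_kept=n_keep)


# ----------------------------------------------------------------------
# The selector


@dataclass
class VscaaConfig:
    """Tuning knobs of the VSCAA loop.

    ``space_size`` is a fraction of the current channel count when < 1,
    otherwise an absolute size.  ``model_retention_fraction`` is the share
    of the W submodels whose channels are counted in the frequency
    profile.
    """

    n_loops: int = 50
    variable_spaces: int = 500
    space_size: float = 0.5
    model_retention_fraction: float = 0.1
    stability_config: StabilityConfig = field(default_factory=StabilityConfig)
    decay_mode: str = "cars_standard"
    inner_cv_repeats: int = 10
    score_max_components: int = 10
    frequency_components: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.model_retention_fraction <= 1:
            raise ValueError("model_retention_fraction must be in (0, 1]")
        if self.variable_spaces < 10:
            raise ValueError("variable_spaces must be >= 10")
        if self.n_loops < 2:
            raise ValueError("n_loops must be >= 2")


def _eliminate(order_keys, pool: np.ndarray, n_remove: int) -> np.ndarray:
    """Return the ``n_remove`` members of ``pool`` first in elimination order.

    ``order_keys`` is a tuple of arrays aligned with ``pool``; earlier keys
    dominate, ascending.  The final implicit key is descending channel
    index (higher index eliminated first).
    """
    keys = tuple(reversed(order_keys)) + ()
    order = np.lexsort((-pool,) + keys)
    return pool[order[:n_remove]]


class VSCAASelector(SelectorMixin, BaseEstimator):
    """Wavelength selector implementing the VSCAA loop (scikit-learn API).

    Parameters mirror :class:`VscaaConfig`; ``fit(X, y)`` runs the full
    N-loop elimination and exposes the minimum-RMSE variable set through
    ``get_support()`` / ``transform``.

    Attributes
    ----------
    support_mask_ : boolean mask of selected channels.
    selection_result_ : :class:`~nirselect.dataset.SelectionResult`
        Full audit trail (per-iteration counts, RMSE, eliminations).
    schedule_ : the :class:`DecaySchedule` used.
    """

    def __init__(
        self,
        n_loops: int = 50,
        variable_spaces: int = 500,
        space_size: float = 0.5,
        model_retention_fraction: float = 0.1,
        n_sample_spaces: int = 100,
        subsample_size: float = 0.8,
        n_components: int = 1,
        decay_mode: str = "cars_standard",
        inner_cv_repeats: int = 10,
        score_max_components: int = 10,
        frequency_components: int = 5,
        seed: int = 0,
        wavelengths=None,
    ):
        self.n_loops = n_loops
        self.variable_spaces = variable_spaces
        self.space_size = space_size
        self.model_retention_fraction = model_retention_fraction
        self.n_sample_spaces = n_sample_spaces
        self.subsample_size = subsample_size
        self.n_components = n_components
        self.decay_mode = decay_mode
        self.inner_cv_repeats = inner_cv_repeats
        self.score_max_components = score_max_components
        self.frequency_components = frequency_components
        self.seed = seed
        self.wavelengths = wavelengths

    # -- scikit-learn plumbing -----------------------------------------
    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        wl = (
            np.asarray(self.wavelengths, float)
            if self.wavelengths is not None
            else np.arange(X.shape[1], dtype=float)
        )
        spectra = SpectraSet(X, wl, y=y)
        cfg = VscaaConfig(
            n_loops=self.n_loops,
            variable_spaces=self.variable_spaces,
            space_size=self.space_size,
            model_retention_fraction=self.model_retention_fraction,
            stability_config=StabilityConfig(
                n_sample_spaces=self.n_sample_spaces,
                subsample_size=self.subsample_size,
                n_components=self.n_components,
                seed=self.seed,
            ),
            decay_mode=self.decay_mode,
            inner_cv_repeats=self.inner_cv_repeats,
            score_max_components=self.score_max_components,
            frequency_components=self.frequency_components,
            seed=self.seed,
        )
        result = vscaa_select(spectra, cfg)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[result.selected_indices] = True
        self.support_mask_ = mask
        self.selection_result_ = result
        self.schedule_ = decay_schedule(X.shape[1], self.n_loops, self.decay_mode)
        self.n_features_in_ = X.shape[1]
        return self


def vscaa_select(spectra: SpectraSet, config: Optional[VscaaConfig] = None) -> SelectionResult:
    """Run the VSCAA elimination loop and return the minimum-RMSE variable set."""
    if config is None:
        config = VscaaConfig()
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    if np.std(spectra.y) <= 0:
        raise ValueError("degenerate y (constant)")
    p0 = spectra.n_channels
    if p0 < 4:
        raise ValueError("VSCAA needs at least 4 channels")
    N = config.n_loops
    schedule = decay_schedule(p0, N, config.decay_mode)
    rng = np.random.default_rng(config.seed)
    X, y = spectra.X, spectra.y

    current = np.arange(p0)
    log = []
    rmse_traj = []
    best = None
    # One fixed set of MCCV splits scores every iteration's survivor set,
    # so the Step-6 argmin compares models, not split luck; the LV count
    # is optimised per set along the PLS path.
    scorer = MccvScorer(
        X, y,
        n_repeats=config.inner_cv_repeats,
        max_components=config.score_max_components,
        rng=rng,
    )
    for it in range(1, N + 1):
        target = int(min(schedule.counts[it - 1], current.size))
        sub = spectra.subset_channels(current)

        # Step 1: stability + WBS partition into useful/useless.
        prof = compute_stability(sub, config.stability_config, rng=rng)
        useful_loc, useless_loc = wbs_partition(prof, seed=rng)

        # Step 2: frequency over random variable spaces.
        pc = current.size
        if config.space_size < 1:
            p1 = max(2, int(round(config.space_size * pc)))
        else:
            p1 = int(min(config.space_size, pc))
        freq = frequency_profile(
            sub,
            space_size=p1,
            n_spaces=config.variable_spaces,
            model_retention=config.model_retention_fraction,
            n_components=config.frequency_components,
            seed=rng,
        )

        # Step 3: shrink to the schedule target.
        n_remove = pc - target
        absS = np.abs(prof.S)
        removed_loc = np.empty(0, dtype=int)
        if n_remove > 0:
            if target > useful_loc.size:
                # Remove lowest-frequency useless channels only.
                removed_loc = _eliminate(
                    (freq.f[useless_loc], absS[useless_loc]), useless_loc, n_remove
                )
            else:
                # All useless go; then trim useful by lowest |S|.
                trim = _eliminate(
                    (absS[useful_loc], freq.f[useful_loc]), useful_loc,
                    max(0, useful_loc.size - target),
                )
                removed_loc = np.concatenate([useless_loc, trim])
        keep_mask = np.ones(pc, dtype=bool)
        keep_mask[removed_loc] = False
        survivors = current[keep_mask]

        # Step 4: score survivors by the shared internal MCCV.
        rmse = scorer.rmse(survivors)
        rmse_traj.append(rmse)
        log.append(
            {
                "iteration": it,
                "retained": int(survivors.size),
                "n_useful": int(useful_loc.size),
                "rmse": float(rmse),
                "eliminated_indices": np.sort(current[removed_loc]).tolist(),
            }
        )
        if best is None or rmse < best[0]:
            best = (rmse, survivors.copy(), it)
        current = survivors
        if current.size <= 2:
            break

    _, sel, best_it = best
    sel = np.sort(sel)
    return SelectionResult(
        selected_indices=sel,
        selected_wavelengths_nm=spectra.wavelengths[sel],
        method_name="VSCAA",
        iteration_log=log,
        rmse_trajectory=rmse_traj,
        meta={
            "best_iteration": best_it,
            "best_rmse": float(best[0]),
            "schedule": schedule.to_dict(),
            "config": {
                "n_loops": config.n_loops,
                "variable_spaces": config.variable_spaces,
                "space_size": config.space_size,
                "model_retention_fraction": config.model_retention_fraction,
                "decay_mode": config.decay_mode,
                "seed": config.seed,
                "score_max_components": config.score_max_components,
                "frequency_components": config.frequency_components,
                "M": config.stability_config.n_sample_spaces,
                "subsample_size": config.stability_config.subsample_size,
                "n_components": config.stability_config.n_components,
            },
        },
    )


# ----------------------------------------------------------------------
# Selector chaining


def chain_select(spectra: SpectraSet, stages: Sequence) -> SelectionResult:
    """Compose selectors; each stage sees only the previous stage's survivors.

    ``stages`` is a sequence of ``(name, selector_fn)`` pairs or bare
    callables mapping SpectraSet -> SelectionResult.  The returned indices
    refer to the original wavelength axis.  An empty chain returns the
    full channel set.
    """
    current = np.arange(spectra.n_channels)
    sub = spectra
    stage_logs = []
    names = []
    for si, stage in enumerate(stages):
        if isinstance(stage, tuple):
            name, fn = stage
        else:
            name, fn = getattr(stage, "__name__", f"stage{si}"), stage
        res = fn(sub)
        if res.n_selected < 2:
            raise ValueError(
                f"stage {si} ({name}) returned fewer than 2 variables"
            )
        current = current[res.selected_indices]
        sub = spectra.subset_channels(current)
        names.append(name)
        stage_logs.append({"stage": name, "result": res.to_dict()})
    return SelectionResult(
        selected_indices=np.sort(current),
        selected_wavelengths_nm=spectra.wavelengths[np.sort(current)],
        method_name="-".join(names) if names else "identity",
        iteration_log=stage_logs,
        rmse_trajectory=[],
        meta={"n_stages": len(stage_logs)},
    )
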