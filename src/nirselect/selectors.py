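"""Comparison wavelength selectors: SiPLS, SPA, GA and BOSS.

These are the established selectors VSCAA is benchmarked against and
chained with:

* **SiPLS** (synergy interval PLS) — exhaustive search over combinations
  of contiguous spectral subintervals, scored by MCCV RMSECV.
* **SPA** (successive projections algorithm) — greedy chains of minimally
  collinear channels built by orthogonal projections, with chain/size
  chosen by MCCV RMSECV.
* **GA** — binary-chromosome genetic algorithm (tournament selection,
  uniform crossover, per-bit mutation, elitism of 1) with fitness
  -RMSECV.
* **BOSS** (bootstrapping soft shrinkage) — iterated weighted bootstrap
  submodels; each round keeps the better-RMSE half of the submodels and
  rebuilds channel weights from their normalized |beta|, softly shrinking
  the support until it stops changing.

Every selector returns a :class:`~nirselect.dataset.SelectionResult`
whose indices refer to the channel axis it was given, and has a
scikit-learn ``SelectorMixin`` wrapper for pipeline use.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .dataset import SpectraSet, SelectionResult
from .pls import pls1_beta

__all__ = [
    "SiplsConfig",
    "SpaConfig",
    "GaConfig",
    "BossConfig",
    "sipls_intervals",
    "sipls_select",
    "spa_select",
    "ga_select",
    "boss_select",
    "SiPLSSelector",
    "SPASelector",
    "GASelector",
    "BOSSSelector",
]


# ----------------------------------------------------------------------
# Shared scoring helper: pooled MCCV RMSE on fixed splits so that every
# candidate subset is judged on the same calibration/validation draws.


class _SplitScorer:
    def __init__(self, X, y, n_repeats, n_components, rng,
                 calibration_fraction=145 / 195):
        self.X = X
        self.y = y
        self.k = n_components
        n = X.shape[0]
        nc = max(2, min(n - 1, int(round(calibration_fraction * n))))
        self.splits = []
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            self.splits.append((perm[:nc], perm[nc:]))

    def rmse(self, channel_idx) -> float:
        idx = np.asarray(channel_idx, dtype=int)
        if idx.size == 0:
            return float(np.std(self.y))  # intercept-only fallback
        Xs = self.X[:, idx]
        sq = 0.0
        cnt = 0
        for cal, val in self.splits:
            k = min(self.k, cal.size - 1, idx.size)
            beta, xm, ym = pls1_beta(Xs[cal], self.y[cal], k)
            err = (Xs[val] - xm) @ beta + ym - self.y[val]
            sq += float(err @ err)
            cnt += val.size
        return float(np.sqrt(sq / cnt))


# ----------------------------------------------------------------------
# SiPLS


@dataclass
class SiplsConfig:
    n_intervals: int = 19
    n_combine: int = 4
    n_components_cap: int = 10
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_combine > self.n_intervals:
            raise ValueError("n_combine must be <= n_intervals")


def sipls_intervals(p: int, n_intervals: int) -> list[np.ndarray]:
    """Contiguous near-equal partition; the earliest intervals take the
    extra channel when p is not divisible."""
    if n_intervals > p:
        raise ValueError("more intervals than channels")
    base, rem = divmod(p, n_intervals)
    out = []
    start = 0
    for i in range(n_intervals):
        width = base + (1 if i < rem else 0)
        out.append(np.arange(start, start + width))
        start += width
    return out


def sipls_select(spectra: SpectraSet, config: SiplsConfig | None = None) -> SelectionResult:
    """Exhaustive synergy-interval search over C(n_intervals, n_combine)."""
    if config is None:
        config = SiplsConfig()
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    p = spectra.n_channels
    n_comb = math.comb(config.n_intervals, config.n_combine)
    if n_comb > 10**6:
        raise ValueError(
            f"{n_comb} interval combinations exceed 1e6; reduce n_combine"
        )
    intervals = sipls_intervals(p, config.n_intervals)
    rng = np.random.default_rng(config.seed)
    scorer = _SplitScorer(
        spectra.X, spectra.y, config.cv_repeats, config.n_components_cap, rng
    )
    best = None
    for combo in itertools.combinations(range(config.n_intervals), config.n_combine):
        idx = np.concatenate([intervals[i] for i in combo])
        r = scorer.rmse(idx)
        if best is None or r < best[0]:
            best = (r, combo, idx)
    rmse, combo, idx = best
    return SelectionResult(
        selected_indices=np.sort(idx),
        selected_wavelengths_nm=spectra.wavelengths[np.sort(idx)],
        method_name="SiPLS",
        iteration_log=[{"intervals": list(combo), "rmse": rmse}],
        rmse_trajectory=[rmse],
        meta={
            "n_intervals": config.n_intervals,
            "n_combine": config.n_combine,
            "interval_widths": [len(iv) for iv in intervals],
            "winning_intervals": [int(i) for i in combo],
            "rmsecv": rmse,
        },
    )


# ----------------------------------------------------------------------
# SPA


@dataclass
class SpaConfig:
    min_vars: int = 2
    max_vars: int = 20
    n_components_cap: int = 10
    cv_repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.min_vars <= self.max_vars:
            raise ValueError("need 1 <= min_vars <= max_vars")


def _spa_chain(X: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Successive-projections chain from one start column.

    At each step every remaining column is projected onto the orthogonal
    complement of the span of the chosen columns; the column with the
    largest residual norm joins the chain.
    """
    P = X - X.mean(axis=0)  # work on centered columns
    n, p = P.shape
    chain = [start]
    proj = P.copy()
    for _ in range(max_vars - 1):
        xk = proj[:, chain[-1]]
        nk = xk @ xk
        if nk <= 1e-30:
            break
        proj = proj - xk[:, None] @ (xk @ proj / nk)[None, :]
        norms = np.einsum("ij,ij->j", proj, proj)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-24:
            break
        chain.append(nxt)
    return chain


def spa_select(spectra: SpectraSet, config: SpaConfig | None = None) -> SelectionResult:
    """SPA over all start channels, subset size chosen by MCCV RMSECV."""
    if config is None:
        config = SpaConfig()
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    n, p = spectra.n_samples, spectra.n_channels
    max_vars = min(config.max_vars, n - 1, p)
    rng = np.random.default_rng(config.seed)
    scorer = _SplitScorer(
        spectra.X, spectra.y, config.cv_repeats, config.n_components_cap, rng
    )
    Xc = spectra.X - spectra.X.mean(axis=0)
    col_norms = np.einsum("ij,ij->j", Xc, Xc)
    best = None
    trace = []
    for start in range(p):
        if col_norms[start] <= 1e-30:
            warnings.warn(f"skipping zero-variance start channel {start}")
            continue
        chain = _spa_chain(spectra.X, start, max_vars)
        for size in range(config.min_vars, min(max_vars, len(chain)) + 1):
            idx = np.array(chain[:size])
            r = scorer.rmse(idx)
            trace.append({"start": start, "size": size, "rmse": r})
            if best is None or r < best[0]:
                best = (r, idx)
    if best is None:
        raise ValueError("no valid SPA chain (all start channels degenerate)")
    rmse, idx = best
    order = np.argsort(idx)
    return SelectionResult(
        selected_indices=idx[order],
        selected_wavelengths_nm=spectra.wavelengths[idx[order]],
        method_name="SPA",
        iteration_log=trace[:200],
        rmse_trajectory=[rmse],
        meta={"rmsecv": rmse, "chain_unsorted": idx.tolist()},
    )


# ----------------------------------------------------------------------
# GA


@dataclass
class GaConfig:
    population_size: int = 64
    n_generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    init_inclusion: float = 0.5
    n_components_cap: int = 10
    cv_repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for r in (self.crossover_rate, self.mutation_rate, self.init_inclusion):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


def ga_select(spectra: SpectraSet, config: GaConfig | None = None) -> SelectionResult:
    """Binary-chromosome GA over channels; fitness = -MCCV RMSECV."""
    if config is None:
        config = GaConfig()
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    p = spectra.n_channels
    rng = np.random.default_rng(config.seed)
    scorer = _SplitScorer(
        spectra.X, spectra.y, config.cv_repeats, config.n_components_cap, rng
    )
    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        if key not in cache:
            idx = np.flatnonzero(chrom)
            if idx.size == 0:
                cache[key] = -np.inf
            else:
                cache[key] = -scorer.rmse(idx)
        return cache[key]

    pop = rng.random((config.population_size, p)) < config.init_inclusion
    # Ensure no empty chromosome at start.
    for c in pop:
        if not c.any():
            c[rng.integers(p)] = True
    fit = np.array([fitness(c) for c in pop])
    best_chrom = pop[np.argmax(fit)].copy()
    best_fit = fit.max()
    trace = [{"generation": 0, "best_rmse": -best_fit, "mean_vars": float(pop.sum(1).mean())}]

    for gen in range(1, config.n_generations + 1):
        new = [best_chrom.copy()]  # elitism of 1
        while len(new) < config.population_size:
            # Tournament selection (size 2) for two parents.
            cand = rng.integers(config.population_size, size=4)
            p1 = pop[cand[0]] if fit[cand[0]] >= fit[cand[1]] else pop[cand[1]]
            p2 = pop[cand[2]] if fit[cand[2]] >= fit[cand[3]] else pop[cand[3]]
            c1, c2 = p1.copy(), p2.copy()
            if rng.random() < config.crossover_rate:
                mask = rng.random(p) < 0.5
                c1[mask], c2[mask] = p2[mask], p1[mask]
            for c in (c1, c2):
                mut = rng.random(p) < config.mutation_rate
                c[mut] = ~c[mut]
                if not c.any():
                    c[rng.integers(p)] = True
                new.append(c)
        pop = np.array(new[: config.population_size])
        fit = np.array([fitness(c) for c in pop])
        gi = int(np.argmax(fit))
        if fit[gi] > best_fit:
            best_fit = fit[gi]
            best_chrom = pop[gi].copy()
        trace.append(
            {
                "generation": gen,
                "best_rmse": -best_fit,
                "mean_vars": float(pop.sum(1).mean()),
            }
        )
    idx = np.flatnonzero(best_chrom)
    return SelectionResult(
        selected_indices=idx,
        selected_wavelengths_nm=spectra.wavelengths[idx],
        method_name="GA",
        iteration_log=trace,
        rmse_trajectory=[t["best_rmse"] for t in trace],
        meta={"rmsecv": -best_fit, "n_generations": config.n_generations},
    )


# ----------------------------------------------------------------------
# BOSS


@dataclass
class BossConfig:
    n_submodels: int = 1000
    n_components_cap: int = 10
    cv_repeats: int = 3
    max_rounds: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_submodels < 10:
            raise ValueError("n_submodels must be >= 10")


def boss_select(spectra: SpectraSet, config: BossConfig | None = None) -> SelectionResult:
    """Bootstrapping soft shrinkage selection.

    Weights start uniform.  Each round draws ``n_submodels`` weighted
    bootstrap variable sets, fits PLS1 per set, keeps the better-RMSE
    half, and accumulates each kept submodel's normalized |beta| into the
    next round's weights (renormalized to sum 1).  Rounds continue while
    the nonzero-weight support shrinks; the support with minimum MCCV
    RMSECV across rounds is returned.
    """
    if config is None:
        config = BossConfig()
    if spectra.y is None:
        raise ValueError("spectra has no reference values (y)")
    n, p = spectra.n_samples, spectra.n_channels
    rng = np.random.default_rng(config.seed)
    scorer = _SplitScorer(
        spectra.X, spectra.y, config.cv_repeats, config.n_components_cap, rng
    )
    X, y = spectra.X, spectra.y
    weights = np.full(p, 1.0 / p)
    support = np.arange(p)
    rounds = []
    prev_support_size = p + 1
    while support.size < prev_support_size and support.size >= 2:
        prev_support_size = support.size
        sub_rmse = np.empty(config.n_submodels)
        subsets = []
        for m in range(config.n_submodels):
            draw = rng.choice(p, size=support.size, replace=True, p=weights)
            idx = np.unique(draw)
            if idx.size < 1:
                idx = support[:1]
            k = min(config.n_components_cap, n - 1, idx.size)
            beta, xm, ym = pls1_beta(X[:, idx], y, k)
            resid = (X[:, idx] - xm) @ beta + ym - y
            sub_rmse[m] = np.sqrt(np.mean(resid**2))
            subsets.append((idx, beta))
        keep = np.argsort(sub_rmse, kind="stable")[: config.n_submodels // 2]
        new_w = np.zeros(p)
        for m in keep:
            idx, beta = subsets[m]
            ab = np.abs(beta)
            tot = ab.sum()
            if tot > 0:
                new_w[idx] += ab / tot
        if new_w.sum() <= 0:
            raise ValueError("BOSS weights collapsed: no informative submodel")
        weights = new_w / new_w.sum()
        support = np.flatnonzero(weights > 0)
        if support.size < 2:
            raise ValueError(
                "BOSS weights collapsed to a single variable before a valid model"
            )
        rounds.append(
            {
                "round": len(rounds) + 1,
                "support_size": int(support.size),
                "rmsecv": scorer.rmse(support),
                "weight_sum": float(weights.sum()),
                "support": support.copy(),
            }
        )
        if len(rounds) >= config.max_rounds:
            break
    if not rounds:
        raise ValueError("BOSS performed no rounds")
    best = min(rounds, key=lambda r: r["rmsecv"])
    idx = np.sort(best["support"])
    log = [
        {k: v for k, v in r.items() if k != "support"} for r in rounds
    ]
    return SelectionResult(
        selected_indices=idx,
        selected_wavelengths_nm=spectra.wavelengths[idx],
        method_name="BOSS",
        iteration_log=log,
        rmse_trajectory=[r["rmsecv"] for r in rounds],
        meta={"best_round": best["round"], "rmsecv": best["rmsecv"]},
    )


# ----------------------------------------------------------------------
# scikit-learn wrappers


class _FunctionSelector(SelectorMixin, BaseEstimator):
    """Common fit plumbing for the functional selectors."""

    _select = None  # set by subclasses
    _config_cls = None

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        wl = np.arange(X.shape[1], dtype=float)
        spectra = SpectraSet(X, wl, y=y)
        cfg = self._config_cls(**self.get_params())
        result = type(self)._select(spectra, cfg)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[result.selected_indices] = True
        self.support_mask_ = mask
        self.selection_result_ = result
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_


class SiPLSSelector(_FunctionSelector):
    _select = staticmethod(sipls_select)
    _config_cls = SiplsConfig

    def __init__(self, n_intervals=19, n_combine=4, n_components_cap=10,
                 cv_repeats=10, seed=0):
        self.n_intervals = n_intervals
        self.n_combine = n_combine
        self.n_components_cap = n_components_cap
        self.cv_repeats = cv_repeats
        self.seed = seed


class SPASelector(_FunctionSelector):
    _select = staticmethod(spa_select)
    _config_cls = SpaConfig

    def __init__(self, min_vars=2, max_vars=20, n_components_cap=10,
                 cv_repeats=5, seed=0):
        self.min_vars = min_vars
        self.max_vars = max_vars
        self.n_components_cap = n_components_cap
        self.cv_repeats = cv_repeats
        self.seed = seed


class GASelector(_FunctionSelector):
    _select = staticmethod(ga_select)
    _config_cls = GaConfig

    def __init__(self, population_size=64, n_generations=100, crossover_rate=0.8,
                 mutation_rate=0.01, init_inclusion=0.5, n_components_cap=10,
                 cv_repeats=5, seed=0):
        self.population_size = population_size
        self.n_generations = n_generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.init_inclusion = init_inclusion
        self.n_components_cap = n_components_cap
        self.cv_repeats = cv_repeats
        self.seed = seed


class BOSSSelector(_FunctionSelector):
    _select = staticmethod(boss_select)
    _config_cls = BossConfig

    def __init__(self, n_submodels=1000, n_components_cap=10, cv_repeats=3,
                 max_rounds=50, seed=0):
        self.n_submodels = n_submodels
        self.n_components_cap = n_components_cap
        self.cv_repeats = cv_repeats
        self.max_rounds = max_rounds
        self.seed = seed
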