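"""Config-driven end-to-end runner: crop -> preprocess -> select -> PLSR -> report.

The pipeline mirrors the standard NIR calibration workflow: trim the axis
to the informative window, apply one pretreatment, run a (possibly
chained) wavelength selector, then evaluate a PLS1 model by MCCV.  One
external hold-out split is fixed from the master seed *before* any
selector runs; selection and latent-variable choice see calibration data
only, and the external set is touched exactly once for Rp/RMSEP/RPD.
MSC, the only pretreatment with a fitted parameter, takes its reference
spectrum from the calibration rows and applies it to all rows.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dataset import SpectraSet, SelectionResult, WavelengthWindow, crop, read_spectra
from .preprocessing import MSC, PreprocessConfig, apply_preprocess
from .pls import MccvConfig, EvaluationReport, mccv_evaluate
from .stability import StabilityConfig
from .vscaa import VscaaConfig, vscaa_select, chain_select
from .selectors import (
    SiplsConfig,
    SpaConfig,
    GaConfig,
    BossConfig,
    sipls_select,
    spa_select,
    ga_select,
    boss_select,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_selector", "SELECTOR_NAMES"]

SELECTOR_NAMES = ("identity", "vscaa", "sipls", "spa", "ga", "boss")


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n per-stage seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def make_selector(name: str, params: Optional[dict] = None, seed: int = 0):
    """Build a SpectraSet -> SelectionResult callable from a selector name."""
    params = dict(params or {})
    name = name.lower()
    if name == "identity":
        def identity(spectra: SpectraSet) -> SelectionResult:
            idx = np.arange(spectra.n_channels)
            return SelectionResult(idx, spectra.wavelengths, "identity")
        return identity
    if name == "vscaa":
        stab_keys = {"n_sample_spaces", "subsample_size", "n_components"}
        stab = {k: params.pop(k) for k in list(params) if k in stab_keys}
        cfg = VscaaConfig(
            stability_config=StabilityConfig(seed=seed, **stab), seed=seed, **params
        )
        return lambda s: vscaa_select(s, cfg)
    if name == "sipls":
        cfg = SiplsConfig(seed=seed, **params)
        return lambda s: sipls_select(s, cfg)
    if name == "spa":
        cfg = SpaConfig(seed=seed, **params)
        return lambda s: spa_select(s, cfg)
    if name == "ga":
        cfg = GaConfig(seed=seed, **params)
        return lambda s: ga_select(s, cfg)
    if name == "boss":
        cfg = BossConfig(seed=seed, **params)
        return lambda s: boss_select(s, cfg)
    raise ValueError(f"unknown selector {name!r}; expected one of {SELECTOR_NAMES}")


@dataclass
class PipelineConfig:
    spectra_path: Optional[str] = None
    reference_path: Optional[str] = None
    window: Optional[WavelengthWindow] = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selector_chain: Sequence = ()  # (name, params) pairs
    mccv: MccvConfig = field(default_factory=MccvConfig)
    output_dir: Optional[str] = None
    seed: int = 0
    selection_data: str = "calibration"

    def __post_init__(self):
        if self.selection_data != "calibration":
            raise ValueError(
                "leakage guard: selectors may only see calibration data"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "window" in d and d["window"] is not None:
            w = d["window"]
            d["window"] = WavelengthWindow(float(w[0]), float(w[1]))
        if "preprocess" in d and isinstance(d["preprocess"], (dict, str)):
            pp = d["preprocess"]
            d["preprocess"] = (
                PreprocessConfig(method=pp) if isinstance(pp, str)
                else PreprocessConfig(**pp)
            )
        if "mccv" in d and isinstance(d["mccv"], dict):
            d["mccv"] = MccvConfig(**d["mccv"])
        chain = []
        for stage in d.get("selector_chain", ()):
            if isinstance(stage, str):
                chain.append((stage, {}))
            else:
                stage = dict(stage)
                chain.append((stage.pop("method"), stage))
        d["selector_chain"] = chain
        return cls(**d)


@dataclass
class PipelineResult:
    selection: SelectionResult
    report: EvaluationReport
    baseline_report: EvaluationReport
    summary: str
    log: list

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.selection.to_json(out / "selection.json")
        with open(out / "evaluation.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "selected": self.report.to_dict(),
                    "full_spectrum": self.baseline_report.to_dict(),
                },
                fh,
                indent=2,
            )
        (out / "summary.txt").write_text(self.summary, encoding="utf-8")
        (out / "pipeline.log").write_text("\n".join(self.log) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig, spectra: Optional[SpectraSet] = None) -> PipelineResult:
    """Execute the full workflow; ``spectra`` may be passed directly in
    place of the configured input paths."""
    log: list[str] = []

    def note(msg):
        log.append(msg)
        print(msg, file=sys.stderr)

    if spectra is None:
        if config.spectra_path is None:
            raise ValueError("no spectra: set spectra_path or pass a SpectraSet")
        spectra = read_spectra(config.spectra_path, config.reference_path)
        note(f"[load] {spectra!r}")
    if spectra.y is None:
        raise ValueError("pipeline requires reference values (y)")

    if config.window is not None:
        spectra = crop(spectra, config.window)
        note(f"[crop] window [{config.window.lo_nm}, {config.window.hi_nm}] nm "
             f"-> p={spectra.n_channels}")

    seeds = derive_seeds(config.seed, 2 + len(config.selector_chain))
    note(f"[seed] master={config.seed} stage_seeds={seeds}")

    # External hold-out fixed before preprocessing/selection.
    n = spectra.n_samples
    nc = config.mccv.resolve_calibration(n)
    rng = np.random.default_rng(seeds[0])
    perm = rng.permutation(n)
    cal_idx, ext_idx = np.sort(perm[:nc]), np.sort(perm[nc:])
    note(f"[split] calibration n={nc}, external n={n - nc} (fixed before selection)")

    # Preprocess.  MSC fits its reference on calibration rows only.
    pp = config.preprocess
    if pp.method == "msc" and pp.msc_reference is None:
        est = MSC().fit(spectra.X[cal_idx])
        spectra = spectra.with_X(est.transform(spectra.X))
        note("[preprocess] msc (reference = calibration mean spectrum)")
    else:
        spectra = apply_preprocess(spectra, pp)
        note(f"[preprocess] {pp.method} (window_points={pp.window_points}, "
             f"poly_order={pp.poly_order})")

    # Selection on calibration data only.
    cal = spectra.subset_samples(cal_idx)
    stages = [
        (nm, make_selector(nm, params, seed=seeds[2 + i]))
        for i, (nm, params) in enumerate(config.selector_chain)
    ]
    if stages:
        selection = chain_select(cal, stages)
    else:
        selection = make_selector("identity")(cal)
    note(f"[select] {selection.method_name}: {selection.n_selected} / "
         f"{spectra.n_channels} channels")

    # Evaluation: MCCV inside calibration, single external prediction.
    mccv = MccvConfig(
        n_repeats=config.mccv.n_repeats,
        calibration_size=config.mccv.calibration_size,
        seed=seeds[1],
        max_components=config.mccv.max_components,
    )
    selected_set = spectra.subset_channels(selection.selected_indices)
    report = mccv_evaluate(selected_set, mccv, external_indices=ext_idx)
    baseline = mccv_evaluate(spectra, mccv, external_indices=ext_idx)
    note(f"[evaluate] selected: RMSECV={report.RMSECV:.4f} RMSEP={report.RMSEP:.4f} "
         f"RPD={report.RPD:.3f} ({report.rpd_band})")

    header = (f"{'method':<16s} {'LVs':>3s} {'nvar':>6s} {'Rc':>7s} {'RMSECV':>9s} "
              f"{'Rp':>7s} {'RMSEP':>9s} {'RPD':>7s}  band")
    summary = "\n".join(
        [
            header,
            baseline.summary_row("full-spectrum", spectra.n_channels),
            report.summary_row(selection.method_name, selection.n_selected),
        ]
    )
    result = PipelineResult(
        selection=selection,
        report=report,
        baseline_report=baseline,
        summary=summary,
        log=log,
    )
    if config.output_dir:
        result.write(config.output_dir)
    return result
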