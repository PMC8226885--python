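# nirselect

Wavelength selection and PLS calibration for near-infrared (NIR)
spectroscopy, built around **VSCAA** — the *variable stability and cluster
analysis algorithm* — together with the comparison selectors it is
benchmarked against (SiPLS, SPA, GA, BOSS), the standard spectral
pretreatments (SNV, MSC, Savitzky–Golay derivatives, smoothing,
normalizations), PLS1 regression with Monte-Carlo cross-validation
(MCCV), and a seeded generator of NIR-like diffuse-reflectance spectra
with planted informative bands.

The package is aimed at chemometricians calibrating a continuous fruit or
plant quality property (soluble solid content in °Brix, titratable acidity
in %, or their weighted taste-index combination) against absorbance
spectra on a ~400-channel grid in the 1000–2300 nm range, and at method
developers who need a controlled, ground-truthed test bed for wavelength
selectors.

## The method

A PLS1 calibration relates spectra to the property through
`y = X β + e`.  VSCAA scores every wavelength channel in two complementary
spaces and iteratively eliminates the channels weak in both:

* **Stability in the sample space.**  Fit PLS on M Monte-Carlo subsamples
  of n₁ samples each, collect the coefficient matrix β (p × M), and set
  `S_i = mean(β_i·) / std(β_i·)`.  A channel whose coefficient is large
  and of stable sign scores high |S|.
* **Frequency in the variable space.**  Fit PLS on W random channel
  subsets of size P₁, keep the best fraction α of submodels by held-out
  RMSE, and count each channel's occurrences f_i among the kept submodels.

Each iteration i of N splits the surviving channels into *useful* and
*useless* sets by **weighted bootstrap sampling** (WBS: p draws with
replacement, probability ∝ |S_i|; the distinct draws are "useful" — with
equal weights about 63.2 % of channels), then shrinks the survivor set to
the target of an **exponential decay schedule**

    r_i = α e^(−k i),   α = (p/2)^(1/(N−1)),   k = ln(p/2)/(N−1),

which retains everything at i = 1 and exactly two channels at i = N.
While the target exceeds the useful-set size, only low-frequency useless
channels are removed; below it, all useless channels go and the useful set
is trimmed by low |S|.  Survivors are scored by a small internal MCCV, and
after N loops the iteration with the minimum RMSE supplies the selected
wavelengths.

Model quality is reported the way NIR calibrations are: Rc and RMSECV
pooled over MCCV re-splits of the calibration set, Rp and RMSEP on a
single external hold-out fixed before any selection, and
RPD = sd(y_external)/RMSEP with the usual qualitative bands
(RPD > 2.5 "excellent", 2–2.5 "very good", …, < 1 "very poor").

## Worked example

```python
import nirselect as ns
from nirselect.stability import StabilityConfig

# 200 synthetic diffuse-reflectance spectra, 400 channels in 1000-2300 nm,
# three informative bands planted at 1450 / 1780 / 2150 nm
scenario = ns.reference_scenario(seed=0)
spectra = ns.generate(scenario)
truth = ns.informative_channels(scenario)

result = ns.vscaa_select(
    spectra, ns.VscaaConfig(seed=0, stability_config=StabilityConfig(seed=0))
)
recall = len(set(result.selected_indices) & set(truth)) / len(truth)
print(f"selected {result.n_selected} channels, recall {recall:.2f}")

report = ns.mccv_evaluate(
    spectra.subset_channels(result.selected_indices),
    ns.MccvConfig(n_repeats=100, seed=0),
)
print(f"Rc {report.Rc:.3f}  RMSECV {report.RMSECV:.3f}  "
      f"Rp {report.Rp:.3f}  RMSEP {report.RMSEP:.3f}  "
      f"RPD {report.RPD:.3f} ({report.rpd_band})")
```

prints

```
selected 289 channels, recall 0.89
Rc 0.988  RMSECV 0.180  Rp 0.995  RMSEP 0.121  RPD 10.232 (excellent)
```

The selector kept 289 of 400 channels covering 89 % of the planted-band
channels, and the reduced model predicts the held-out samples with an
RMSEP of 0.12 °Brix on a property spanning 8–12 °Brix — rated "excellent"
by RPD (the synthetic test bed is easier than real fruit, hence the high
value).  Selectors compose: `ns.chain_select(spectra, stages)` runs e.g.
SiPLS → VSCAA, every selector is also a scikit-learn `SelectorMixin`
(`VSCAASelector`, `SiPLSSelector`, …) usable inside a `Pipeline`, and the
`nirselect` CLI exposes `simulate`, `select`, `ti` and `pipeline`
subcommands.

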