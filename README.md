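# synchrofluor

Synchronous-scan **derivative spectrofluorometry** toolkit: simulate
excitation–emission fluorescence of strongly overlapping fluorophore
pairs, resolve them by the zero-crossing first-derivative technique,
and run a full ICH-style assay validation — all without an instrument.

The package is modelled on the quantification of the β-carboline
alkaloids **harmaline (HL)** and **harmine (HM)**. Excited at 285 nm,
the free alkaloids emit nearly coincident bands between 300 and 400 nm
and cannot be distinguished. Complexation with
hydroxypropyl-β-cyclodextrin (HP-β-CD) separates the emission maxima to
400 nm (HL) and 455 nm (HM); a synchronous scan at a fixed offset
Δλ = λem − λex = 50 nm narrows the bands; and a 9-point Savitzky–Golay
first derivative lets each analyte be read where the other's derivative
crosses zero — HL at ~419 nm and HM at ~456 nm — so the mixture signal
at each readout responds to one analyte only, linearly over
10–200 ng/mL.

## The method in brief

For a synchronous spectrum `S(λ) = EEM(λ − Δλ, λ)` and its smoothed
first derivative `D = dS/dλ` (Savitzky–Golay, 9 points), the analytical
signal for analyte A is the signed amplitude `D_mix(λ_A)` at a
wavelength where the interferent's derivative vanishes,
`D_B(λ_A) = 0`. Calibration is ordinary least squares of amplitude on
concentration `c`; detection limits follow ICH Q2:

    LOD = 3.3 σ / |S|,   LOQ = 10 σ / |S|

with σ the regression residual SD and S the slope, so LOQ/LOD = 10/3.3
always. Accuracy is percent recovery `%R = 100·found/added`; precision
is `%RSD = 100·sd/mean`.

## Worked example

```python
from synchrofluor import (
    default_complexed_models, develop_method, quantify_eem,
    simulate_eem, NoiseModel, delta_lambda_screen,
)

hl, hm = default_complexed_models()          # HP-β-CD complexed pair
setup = develop_method((hl, hm), noise=NoiseModel(), seed=0)
best, _ = delta_lambda_screen(models=(hl, hm))

# an unknown mixture: 75 ng/mL HL + 25 ng/mL HM, with measurement noise
eem = simulate_eem([(hl, 75.0), (hm, 25.0)], noise=NoiseModel(), seed=42)
found = quantify_eem(eem, setup)
```

This prints (via the obvious `print` statements):

```
optimal delta-lambda : 50 nm
harmaline readout    : 418.7 nm
harmine readout      : 456.2 nm
HL_complexed: slope -0.0110, r^2 0.99997, LOD 1.40 ng/mL, LOQ 4.25 ng/mL
HM_complexed: slope -0.0239, r^2 1.00000, LOD 0.45 ng/mL, LOQ 1.37 ng/mL
HL_complexed: 74.60 ng/mL [ok]
HM_complexed: 24.85 ng/mL [ok]
```

The Δλ screen confirms 50 nm as the best synchronous offset; the
auto-selected readouts sit at the published 419/456 nm zero-crossings;
both calibrations are linear to r² > 0.9999; and the noisy 75/25
mixture is recovered within ~0.6% despite the heavy spectral overlap —
the operational meaning of "no interference".

A command-line interface wraps the same operations:

```sh
synchrofluor screen                       # Δλ = 20–80 nm optimisation table
synchrofluor calibrate --out-dir cal/     # persist calibration JSONs
synchrofluor quantify --calibration cal/calibration_HL_complexed.json spectrum.csv
synchrofluor validate --seed 1 --out report.json --markdown report.md
```

## Layout

- `synchrofluor.spectra` — spectral types, synchronous extraction,
  Savitzky–Golay derivative, zero-crossing readout selection.
- `synchrofluor.simulate` — Gaussian-band EEM generator (free and
  complexed models, backgrounds, noise, perturbations).
- `synchrofluor.calibration` — OLS calibration, LOD/LOQ, inverse
  prediction, recovery and RSD.
- `synchrofluor.validation` — accuracy/precision, robustness,
  specificity and Δλ-screen studies; full report.
- `synchrofluor.io` / `synchrofluor.config` / `synchrofluor.cli` —
  CSV/JCAMP-DX/JSON formats, run configuration, command line.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
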