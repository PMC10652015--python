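# Methods

## The measurement model

A fluorophore in a given state (free, or complexed with
hydroxypropyl-β-cyclodextrin) is described by a separable Gaussian band
model. Its contribution to the excitation–emission matrix (EEM) at
concentration `c` (ng/mL) is

    I(λex, λem) = c · rf · G(λex; ex_center, ex_width)
                         · Σ_b a_b · G(λem; center_b, width_b)

where `G` is a unit-height Gaussian (`width` = standard deviation, nm)
and `rf` the response factor (intensity units per ng/mL). Mixtures
superpose; the noise-free model is therefore exactly linear in every
concentration, which is the property the whole calibration strategy
rests on. Measurement noise is applied per grid point as
`I → I·(1 + ε_p) + ε_a` with independent Gaussian `ε_p`
(proportional) and `ε_a` (additive). All randomness is drawn from
`numpy.random.default_rng` (PCG64) with explicit seeds; child seeds for
replicate simulations are spawned through `numpy.random.SeedSequence`,
so every study is reproducible bit for bit.

## Synchronous extraction and axis convention

The synchronous spectrum is the EEM diagonal
`S(λem) = EEM(λem − Δλ, λem)`, indexed by the **emission** wavelength
(`λem = λex + Δλ`). This convention is chosen because the harmine
readout (456 nm) then coincides with its stated emission region, which
is how the readout wavelengths are conventionally reported. Values off
the excitation grid are linearly interpolated (error O(step²)); the
result is restricted to emission wavelengths whose diagonal point lies
inside the EEM, and at least nine points (one derivative window) must
survive.

The default grids are 1 nm steps over 290–600 nm (emission) and
240–560 nm (excitation). The excitation span must reach ~500 nm: at
Δλ = 50 the readout window 419–456 nm samples λex = 369–406 nm, and the
Δλ = 20–80 nm screen widens that range further. A scan stopping at
340 nm could never produce the published readouts.

## Derivative processing

The first derivative is a Savitzky–Golay filter: a local polynomial is
least-squares fitted in a sliding 9-point window and differentiated at
the window centre; division by the grid step gives units of intensity
per nm. Edge points come from the polynomial fitted to the first/last
full window (no truncation), so derivative spectra keep the full grid.

The default polynomial order is **3**. Order 2 carries a smoothing bias
in the first derivative of roughly 0.7% (25 nm-wide band) to 5%
(9 nm band) on a 1 nm grid, which is visible against the ~0.8% assay
RSD; order 3 reduces the bias to 1.6·10⁻⁵–9·10⁻⁴ while keeping the
9-point noise suppression. Both the window and the order are
configurable.

Amplitudes are **signed** and read by linear interpolation between grid
points; calibration uses the signed value (both default slopes are
negative — the readouts sit on descending derivative flanks), never the
absolute value.

## Zero-crossing readout selection

`find_zero_crossings` locates sign changes of the derivative by linear
interpolation between the bracketing grid points; a crossing whose
flanking extrema are both below a noise guard is suppressed.

`select_analytical_wavelengths` reads analyte A at a zero-crossing of
the interferent B's derivative — the crossing where |A's derivative| is
largest — and symmetrically for B. The returned wavelength is the
crossing itself, not merely a point near it: under the shared linear
interpolation the interferent amplitude at an interpolated crossing is
exactly zero, which is what makes noise-free mixture recovery exact.
The `tolerance` parameter (default 2 nm) merges near-duplicate
crossings. Grid points where the interferent's derivative is
numerically dead (≤ 10⁻⁹ of its maximum) are equally interference-free
and join the candidate set; if the interferent has no usable crossing at
all, the selection falls back to the wavelength minimising the
interferent/analyte amplitude ratio and flags the readout.

`resolution_score` rates a readout pair as
`min over readouts of |analyte| / (|interferent| + ε)` with
`ε = 10⁻³ · max|analyte derivative|`. Tying ε to the analyte's own
amplitude scale makes the score exactly invariant under joint intensity
rescaling and caps it at 10³ when the interferent vanishes; at exact
crossings the score reduces to readout amplitude relative to the
analyte's best achievable derivative amplitude, which is what the Δλ
screen ranks — sensitivity-at-the-readout per unit of available signal,
independent of absolute intensity.

## Default band models

Free-state models (excited at 285 nm, single emission bands at 372 and
362 nm, sd ~32–34 nm) reproduce the unresolvable 300–400 nm overlap
(normalised overlap ≈ 0.98) and exist only to demonstrate why the
direct emission scan fails. All quantitative work uses the complexed
models:

| model | excitation (nm) | emission bands (center, sd, rel. amp) | rf |
|---|---|---|---|
| HL·CD | G(355, 40) | (400, 20, 1.0) + (460.89, 10, 0.25) | 0.3268 |
| HM·CD | G(370, 18.7) | (455, 11, 1.0) + (417.35, 9, 0.10) | 1.3885 |

The main emission bands pin the complexed maxima at 400/455 nm. The
small secondary bands are the residual shoulders each complex keeps on
the far side of its main band; their centres are calibrated so that,
after Δλ = 50 extraction and the 9-point derivative, harmine's
derivative crosses zero at ~419 nm (harmaline's readout) and
harmaline's at ~456 nm (harmine's readout), with each crossing landing
where the other analyte's derivative amplitude peaks. Response factors
set the calibration slope magnitudes to 0.011 (HL) and 0.024 (HM)
intensity·nm⁻¹ per ng/mL. With these shapes the Δλ screen over
{20,…,80} nm prefers 50 nm because only there do the crossings coincide
with the derivative-amplitude maxima of both analytes.

The single-Gaussian excitation band of each complexed model is the
*effective long-wave absorption envelope* that the Δλ = 50 diagonal
actually samples (λex ≈ 355–410 nm). The deep-UV 285 nm excitation band
used for conventional emission scans is deliberately not part of the
complexed models — a known limitation: these models describe the
synchronous measurement, not the full excitation spectrum.

## Noise, backgrounds, perturbations

- **Noise defaults** (`additive_sd = 0.005`, `proportional_sd = 0.0008`
  intensity units / fraction) are calibrated so the derivative-readout
  repeatability at 50 ng/mL is ≈ 0.8 %RSD for the less sensitive
  analyte (measured 0.82%; 1.7% at the 10 ng/mL level). A proportional
  component is required: purely additive noise cannot give
  near-constant %RSD across 10–100 ng/mL.
- **Backgrounds** (`plasma_blank`, `seed_extract`) are weak, broad
  separable Gaussian surfaces standing for residual matrix
  fluorescence. They are smooth and additive, so a parallel blank
  subtracts them exactly — mirroring bench practice; quantification of
  background-bearing samples always subtracts a blank simulated under
  the same conditions.
- **Robustness perturbations** map bench factors to spectral proxies:
  buffer pH ±0.5 → ±0.2 nm shift of every emission centre; buffer
  volume ±0.25 mL → ±1.5% intensity; HP-β-CD volume ±0.1 mL → ±1%
  intensity. The pH shift magnitude is calibrated so the simulated
  recovery excursion (≈ ±1.5%) matches the reported scale of the bench
  robustness data; in this narrow-band geometry a 0.5 nm shift would
  already produce ±4% excursions.

## Calibration and validation statistics

- Plain unweighted OLS (no evidence supports weighting); residual SD
  uses the n−2 denominator. Degenerate designs (a single concentration)
  raise an error rather than returning NaNs.
- LOD/LOQ multipliers are fixed at 3.3 and 10 on the regression
  residual SD (ICH Q2's σ/S formulas; σ as residual SD rather than
  blank SD, both being permitted). The multipliers are arguments for
  users who prefer other conventions; the LOQ/LOD ratio is 10/3.3 by
  construction.
- Inverse prediction returns `(amplitude − intercept)/slope` unchanged
  (negative values included) plus a flag: `below_loq`, `out_of_range`
  or `ok`.
- Accuracy/precision: both analytes are spiked together at 10, 50 and
  100 ng/mL, three replicates, three sessions (9 determinations per
  session). Accuracy is the mean %R of session 1. Precision uses the
  one-way variance decomposition: repeatability = pooled within-session
  RSD; intermediate precision = √(within + between) expressed as RSD,
  so intermediate ≥ repeatability whenever a session effect exists.
  Sessions differ by a seeded intensity jitter (sd 0.3%), a minimal
  between-day model.
- Robustness quantifies perturbed samples against the **unperturbed**
  calibration — that mismatch is the quantity a robustness study
  measures — and reports pooled and per-sign mean %R and RSD per
  factor.
- Specificity uses the published addition designs
  (75,25)/(100,100)/(25,75) ng/mL (synthetic mixtures) and
  (67,200)/(120,120)/(200,67) ng/mL (spiked plasma, with plasma blank
  background).
- Report tables round to two decimals (round-half-even) only at
  rendering time; all stored values keep full precision.

## Problem sizes and runtime

Studies run on full-resolution grids (321 × 311 EEMs). The default
validation suite is 27 accuracy + 54 robustness + 3 specificity
simulations plus 14 calibration spectra; the complete test suite and
the acceptance script each finish in a few seconds on one CPU.

## What passing tests do and do not show

The simulator reproduces the *structure* of the measurement — band
positions, overlap, linearity, noise magnitude, matrix backgrounds and
small perturbations — not digitised instrument spectra. Real spectra
are asymmetric, carry Rayleigh/Raman scatter ridges and inner-filter
curvature at high concentration, and their robustness responses emerge
from solution chemistry rather than from clean band shifts. Passing
tests therefore demonstrate that the resolution-and-validation
*pipeline* is correct and self-consistent under realistic conditions;
they do not certify performance on any particular instrument, and
instrument-bound published values (slopes, intercepts, LODs, real
seed-extract concentrations) are treated as magnitudes to emulate, not
as targets to reproduce.
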