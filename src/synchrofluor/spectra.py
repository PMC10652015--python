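"""Spectral data model and multicomponent-resolution operations.

The quantification strategy implemented here is synchronous-scan
derivative spectrofluorometry with zero-crossing readout:

1. a synchronous spectrum is extracted from an excitation-emission
   matrix (EEM) along the diagonal ``λex = λem − Δλ``;
2. the spectrum is differentiated with a smoothed (Savitzky-Golay)
   first derivative;
3. each analyte of an overlapping pair is read at a wavelength where
   the *other* analyte's derivative crosses zero, so the mixture
   derivative there is proportional to the analyte alone.

All spectra live on uniform wavelength grids (`WavelengthGrid`);
intensities are in arbitrary fluorescence units and derivative
amplitudes in units per nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DomainError

__all__ = [
    "WavelengthGrid",
    "ExcitationEmissionMatrix",
    "SynchronousSpectrum",
    "DerivativeSpectrum",
    "AnalyticalWavelengths",
    "extract_synchronous",
    "savgol_first_derivative",
    "amplitude_at",
    "find_zero_crossings",
    "select_analytical_wavelengths",
    "resolution_score",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis ``start + k·step``, inclusive of ``stop``.

    Parameters are in nm; ``step`` defaults to the 1 nm sampling used by
    the production method.
    """

    start: float
    stop: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"start ({self.start}) must be < stop ({self.stop})")
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")

    def __len__(self) -> int:
        return int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self))

    def contains(self, wavelength: float) -> bool:
        return self.start - 1e-9 <= wavelength <= self.values[-1] + 1e-9

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WavelengthGrid":
        """Build a grid from an explicit uniformly spaced, increasing axis."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("need a 1-D axis with at least two points")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("wavelength axis must be uniformly spaced")
        return cls(float(values[0]), float(values[-1]), float(steps[0]))


@dataclass
class ExcitationEmissionMatrix:
    """Fluorescence intensity over a 2-D (λex, λem) grid.

    ``intensity`` has shape ``(len(ex_grid), len(em_grid))``.
    """

    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        expected = (len(self.ex_grid), len(self.em_grid))
        if self.intensity.shape != expected:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grids {expected}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __add__(self, other: "ExcitationEmissionMatrix") -> "ExcitationEmissionMatrix":
        if self.ex_grid != other.ex_grid or self.em_grid != other.em_grid:
            raise ValueError("EEMs must share grids to be added")
        return ExcitationEmissionMatrix(
            self.ex_grid, self.em_grid, self.intensity + other.intensity
        )

    def __sub__(self, other: "ExcitationEmissionMatrix") -> "ExcitationEmissionMatrix":
        if self.ex_grid != other.ex_grid or self.em_grid != other.em_grid:
            raise ValueError("EEMs must share grids to be subtracted")
        return ExcitationEmissionMatrix(
            self.ex_grid, self.em_grid, self.intensity - other.intensity
        )


@dataclass
class SynchronousSpectrum:
    """1-D intensity vs emission wavelength at a fixed offset Δλ.

    The spectrum is indexed by the *emission* wavelength of the scan,
    ``λem = λex + Δλ``.
    """

    delta_lambda: float
    em_grid: WavelengthGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.delta_lambda <= 0:
            raise ValueError(f"delta_lambda must be positive, got {self.delta_lambda}")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.em_grid),):
            raise ValueError("intensity length does not match the grid")


@dataclass
class DerivativeSpectrum:
    """Smoothed first derivative of a synchronous spectrum, in units per nm."""

    em_grid: WavelengthGrid
    d_intensity: np.ndarray
    window_points: int = 9
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0 or self.window_points < self.poly_order + 1:
            raise ValueError(
                "window_points must be odd and at least poly_order + 1 "
                f"(got window={self.window_points}, order={self.poly_order})"
            )
        self.d_intensity = np.asarray(self.d_intensity, dtype=float)
        if self.d_intensity.shape != (len(self.em_grid),):
            raise ValueError("d_intensity length does not match the grid")


@dataclass
class AnalyticalWavelengths:
    """Interference-free readout wavelengths for a two-analyte pair.

    ``fallback_*`` flags mark readouts chosen by the interferent/analyte
    amplitude-ratio fallback because the interferent's derivative never
    crosses zero.
    """

    lambda_A: float
    lambda_B: float
    fallback_A: bool = False
    fallback_B: bool = False


def extract_synchronous(
    eem: ExcitationEmissionMatrix, delta_lambda: float
) -> SynchronousSpectrum:
    """Extract the synchronous spectrum ``S(λem) = EEM(λem − Δλ, λem)``.

    The diagonal is evaluated with linear interpolation along the
    excitation axis whenever ``λem − Δλ`` falls between excitation grid
    points, and the result is restricted to emission wavelengths whose
    diagonal point lies inside the EEM.  At least 9 emission points must
    survive (one derivative window).
    """
    if delta_lambda <= 0:
        raise ValueError(f"delta_lambda must be positive, got {delta_lambda}")
    em = eem.em_grid.values
    ex = eem.ex_grid.values
    target_ex = em - delta_lambda
    mask = (target_ex >= ex[0] - 1e-9) & (target_ex <= ex[-1] + 1e-9)
    n_valid = int(mask.sum())
    if n_valid < 9:
        raise DomainError(
            f"diagonal λex = λem − {delta_lambda} nm intersects the EEM at only "
            f"{n_valid} emission points (need ≥ 9)"
        )
    cols = np.flatnonzero(mask)
    tx = np.clip(target_ex[cols], ex[0], ex[-1])
    # linear interpolation along the excitation axis, column by column
    idx = np.clip(np.searchsorted(ex, tx, side="right") - 1, 0, ex.size - 2)
    frac = (tx - ex[idx]) / (ex[idx + 1] - ex[idx])
    vals = (1.0 - frac) * eem.intensity[idx, cols] + frac * eem.intensity[idx + 1, cols]
    grid = WavelengthGrid(float(em[cols[0]]), float(em[cols[-1]]), eem.em_grid.step)
    return SynchronousSpectrum(delta_lambda, grid, vals)


def savgol_first_derivative(
    spec: SynchronousSpectrum, window_points: int = 9, poly_order: int = 3
) -> DerivativeSpectrum:
    """Savitzky-Golay first derivative with respect to wavelength.

    A local polynomial of order ``poly_order`` is least-squares fitted in
    a sliding window of ``window_points`` samples and differentiated at
    the window centre; division by the grid step makes the units
    intensity per nm.  Edge points are taken from a polynomial fitted to
    the first/last window (scipy's ``mode="interp"``), so no points are
    lost at the ends.
    """
    n = len(spec.em_grid)
    if window_points % 2 == 0:
        raise ValueError(f"window_points must be odd, got {window_points}")
    if poly_order >= window_points:
        raise ValueError("poly_order must be smaller than window_points")
    if n < window_points:
        raise ValueError(
            f"spectrum has {n} points, shorter than the {window_points}-point window"
        )
    d = savgol_filter(
        spec.intensity,
        window_length=window_points,
        polyorder=poly_order,
        deriv=1,
        delta=spec.em_grid.step,
        mode="interp",
    )
    return DerivativeSpectrum(spec.em_grid, d, window_points, poly_order)


def amplitude_at(dspec: DerivativeSpectrum, wavelength: float) -> float:
    """Signed derivative amplitude at ``wavelength``, linearly interpolated."""
    grid = dspec.em_grid
    if not grid.contains(wavelength):
        raise DomainError(
            f"wavelength {wavelength} nm outside grid [{grid.start}, {grid.values[-1]}]"
        )
    return float(np.interp(wavelength, grid.values, dspec.d_intensity))


def find_zero_crossings(
    dspec: DerivativeSpectrum, min_flank: float = 0.0
) -> list[float]:
    """Wavelengths where the derivative changes sign.

    Crossings are located by linear interpolation between the bracketing
    grid points.  A crossing whose flanking extrema (largest |amplitude|
    between it and the neighbouring crossings, or the spectrum ends) are
    *both* below ``min_flank`` is suppressed as noise.
    """
    x = dspec.em_grid.values
    d = dspec.d_intensity
    crossings: list[float] = []
    for i in range(d.size - 1):
        a, b = d[i], d[i + 1]
        if a == 0.0:
            # an exact grid zero counts once, when the signal changes sign
            # across it
            prev_sign = np.sign(d[:i][d[:i] != 0.0][-1]) if np.any(d[:i] != 0.0) else 0.0
            if prev_sign != 0.0 and np.sign(b) == -prev_sign:
                crossings.append(float(x[i]))
        elif a * b < 0.0:
            crossings.append(float(x[i] - a * (x[i + 1] - x[i]) / (b - a)))
    if min_flank > 0.0 and crossings:
        bounds = [x[0], *crossings, x[-1]]
        kept = []
        for k, c in enumerate(crossings):
            left = _segment_max_abs(x, d, bounds[k], c)
            right = _segment_max_abs(x, d, c, bounds[k + 2])
            if left >= min_flank or right >= min_flank:
                kept.append(c)
        crossings = kept
    return crossings


def _segment_max_abs(x: np.ndarray, d: np.ndarray, lo: float, hi: float) -> float:
    sel = (x >= lo) & (x <= hi)
    if not np.any(sel):
        return 0.0
    return float(np.max(np.abs(d[sel])))


# Relative threshold under which an interferent derivative is treated as
# numerically dead (interference-free even without a sign change).
_DEAD_REL = 1e-9


def _zero_candidates(dspec: DerivativeSpectrum, tolerance: float) -> list[float]:
    """Interference-free readout candidates offered by one interferent.

    Candidates are the interferent's interpolated zero-crossings plus
    any grid points where its derivative is numerically zero relative to
    its own maximum (covering interferents with no signal in a region).
    Candidates closer than ``tolerance`` are merged.
    """
    scale = float(np.max(np.abs(dspec.d_intensity)))
    if scale == 0.0:
        return list(dspec.em_grid.values)
    guard = _DEAD_REL * scale
    cands = find_zero_crossings(dspec, min_flank=guard)
    merged: list[float] = []
    for c in cands:
        if merged and c - merged[-1] < tolerance:
            continue
        merged.append(c)
    # grid points where the interferent is numerically dead are equally
    # interference-free; they are kept as-is (no merging needed)
    dead = dspec.em_grid.values[np.abs(dspec.d_intensity) <= guard]
    return sorted(set(merged) | set(float(v) for v in dead))


def select_analytical_wavelengths(
    dspec_A: DerivativeSpectrum,
    dspec_B: DerivativeSpectrum,
    tolerance: float = 2.0,
) -> AnalyticalWavelengths:
    """Choose one interference-free readout wavelength per analyte.

    Analyte A is read at the zero-crossing of B's derivative where |A's
    derivative| is largest (and symmetrically for B), so that in a
    mixture the derivative amplitude at each readout responds to one
    analyte only.  ``tolerance`` merges near-duplicate crossings.  If an
    interferent's derivative never crosses zero, the readout falls back
    to the wavelength minimising the interferent/analyte amplitude ratio
    and is flagged.
    """
    if dspec_A.em_grid != dspec_B.em_grid:
        raise ValueError("derivative spectra must share a wavelength grid")

    def pick(analyte: DerivativeSpectrum, interferent: DerivativeSpectrum):
        cands = _zero_candidates(interferent, tolerance)
        if cands:
            amps = [abs(amplitude_at(analyte, c)) for c in cands]
            return cands[int(np.argmax(amps))], False
        # fallback: best interferent-to-analyte ratio anywhere on the grid
        a = np.abs(analyte.d_intensity)
        b = np.abs(interferent.d_intensity)
        eps = 1e-12 * max(float(a.max()), 1.0)
        ratio = b / (a + eps)
        return float(analyte.em_grid.values[int(np.argmin(ratio))]), True

    lam_a, fb_a = pick(dspec_A, dspec_B)
    lam_b, fb_b = pick(dspec_B, dspec_A)
    return AnalyticalWavelengths(lam_a, lam_b, fb_a, fb_b)


def resolution_score(
    dspec_A: DerivativeSpectrum,
    dspec_B: DerivativeSpectrum,
    wavelengths: AnalyticalWavelengths,
    eps_rel: float = 1e-3,
) -> float:
    """Quality of a readout pair: worst-case analyte-to-interferent contrast.

    For each readout the score is ``|analyte| / (|interferent| + ε)``
    with ``ε = eps_rel · max|analyte derivative|``; the overall score is
    the minimum of the two.  Tying ε to the analyte's own amplitude
    scale makes the score invariant under joint intensity rescaling and
    keeps it finite (``≤ 1/eps_rel``) when the interferent vanishes; a
    readout sitting exactly on an interferent zero-crossing then scores
    the analyte amplitude relative to the analyte's best achievable
    amplitude, which is what the Δλ screen ranks.
    """
    score = np.inf
    for analyte, interferent, lam in (
        (dspec_A, dspec_B, wavelengths.lambda_A),
        (dspec_B, dspec_A, wavelengths.lambda_B),
    ):
        amp = abs(amplitude_at(analyte, lam))
        intf = abs(amplitude_at(interferent, lam))
        eps = eps_rel * float(np.max(np.abs(analyte.d_intensity)))
        if eps == 0.0 and intf == 0.0:
            eps = 1e-300  # both spectra identically zero: score 0 anyway
        score = min(score, amp / (intf + eps))
    return float(score)
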