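"""Linear calibration, inverse prediction and detection limits.

The analytical signal is the signed first-derivative amplitude of the
synchronous spectrum at a fixed readout wavelength, which is strictly
linear in concentration.  Calibration is ordinary least squares of
amplitude on concentration; detection and quantification limits follow
the ICH Q2 residual-standard-deviation formulas

    LOD = 3.3 σ / |S|,    LOQ = 10 σ / |S|,

with σ the residual SD of the regression (n − 2 denominator) and S the
slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError

__all__ = [
    "CalibrationModel",
    "PredictionFlag",
    "fit_line",
    "lod_loq",
    "predict_concentration",
    "percent_recovery",
    "rsd",
]

#: ICH Q2 multipliers for the residual-SD-based limit estimates.
LOD_MULTIPLIER = 3.3
LOQ_MULTIPLIER = 10.0


class PredictionFlag(str, Enum):
    OK = "ok"
    BELOW_LOQ = "below_loq"
    OUT_OF_RANGE = "out_of_range"


@dataclass
class CalibrationModel:
    """Fitted calibration line for one analyte at one readout wavelength."""

    analyte: str
    wavelength: float
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    lod: float
    loq: float
    range: tuple[float, float]
    n_points: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a calibration needs at least 3 points")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")
        if not self.range[0] < self.range[1]:
            raise ValueError("calibration range must have low < high")

    def amplitude_for(self, concentration: float) -> float:
        """Forward prediction: expected amplitude at ``concentration``."""
        return self.slope * concentration + self.intercept


def fit_line(
    concentrations,
    amplitudes,
    analyte: str = "",
    wavelength: float = float("nan"),
    lod_multiplier: float = LOD_MULTIPLIER,
    loq_multiplier: float = LOQ_MULTIPLIER,
    seed: int | None = None,
) -> CalibrationModel:
    """Ordinary least-squares calibration of amplitude on concentration.

    ``residual_sd = sqrt(SSE / (n − 2))``; r² from the standard
    variance decomposition; the valid range is [min, max] of the input
    concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"concentrations and amplitudes must be equal-length 1-D "
            f"(got {x.shape} vs {y.shape})"
        )
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all concentrations identical; slope undefined")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    residual_sd = float(np.sqrt(sse / (x.size - 2)))
    r_squared = 1.0 if sst == 0.0 else max(0.0, min(1.0, 1.0 - sse / sst))
    lod, loq = lod_loq(residual_sd, res.slope, lod_multiplier, loq_multiplier)
    return CalibrationModel(
        analyte=analyte,
        wavelength=wavelength,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r_squared,
        residual_sd=residual_sd,
        lod=lod,
        loq=loq,
        range=(float(x.min()), float(x.max())),
        n_points=int(x.size),
        seed=seed,
    )


def lod_loq(
    residual_sd: float,
    slope: float,
    lod_multiplier: float = LOD_MULTIPLIER,
    loq_multiplier: float = LOQ_MULTIPLIER,
) -> tuple[float, float]:
    """ICH Q2 limits from regression residual SD and slope.

    Returns ``(3.3 σ/|S|, 10 σ/|S|)`` by default, so LOQ/LOD is always
    10/3.3 regardless of the inputs.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if residual_sd < 0:
        raise ValueError("residual_sd must be non-negative")
    return (
        lod_multiplier * residual_sd / abs(slope),
        loq_multiplier * residual_sd / abs(slope),
    )


def predict_concentration(
    model: CalibrationModel, amplitude: float
) -> tuple[float, PredictionFlag]:
    """Inverse prediction ``c = (amplitude − intercept) / slope`` with a flag.

    Flags mark results below the quantification limit or outside the
    calibrated range; negative concentrations are returned as-is (and
    flagged) rather than clipped.
    """
    c = (amplitude - model.intercept) / model.slope
    if c < model.loq:
        flag = PredictionFlag.BELOW_LOQ
    elif not model.range[0] <= c <= model.range[1]:
        flag = PredictionFlag.OUT_OF_RANGE
    else:
        flag = PredictionFlag.OK
    return float(c), flag


def percent_recovery(found: float, added: float) -> float:
    """Accuracy metric ``%R = 100 · found / added``."""
    if added <= 0:
        raise ValueError(f"added concentration must be positive, got {added}")
    return 100.0 * found / added


def rsd(values) -> float:
    """Percent relative standard deviation, sample SD (n−1) over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))
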