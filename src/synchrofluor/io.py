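"""File formats: spectrum/EEM CSV, minimal JCAMP-DX read, calibration JSON.

CSV dialect is fixed to avoid locale drift: comma separator, dot
decimal, UTF-8, mandatory header.  Spectrum files are

    wavelength_nm,intensity
    290.0,0.0134
    ...

optionally preceded by ``# key = value`` metadata comments (the writer
records ``delta_lambda_nm``).  EEM files put the emission grid in the
first row, the excitation grid in the first column and intensities in
the body.

The JCAMP-DX reader accepts single-spectrum files with an
``##XYDATA=(X++(Y..Y))`` block in plain AFFN form; compressed encodings
(SQZ/DIF/DUP) and multi-block files are rejected loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .calibration import CalibrationModel
from .errors import DataError, FormatError
from .spectra import (
    ExcitationEmissionMatrix,
    SynchronousSpectrum,
    WavelengthGrid,
)

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_eem_csv",
    "write_eem_csv",
    "read_jcamp",
    "save_calibration",
    "load_calibration",
]


def _parse_float(text: str, line: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"cannot parse {what} {text!r}", line) from None


def write_spectrum_csv(spec: SynchronousSpectrum, path: str | Path) -> None:
    """Write a spectrum with full float precision and its Δλ as metadata."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# delta_lambda_nm = {spec.delta_lambda!r}\n")
        fh.write("wavelength_nm,intensity\n")
        for w, v in zip(spec.em_grid.values, spec.intensity):
            fh.write(f"{float(w)!r},{float(v)!r}\n")


def read_spectrum_csv(
    path: str | Path, delta_lambda: float | None = None
) -> SynchronousSpectrum:
    """Read a spectrum CSV; Δλ comes from metadata unless given explicitly.

    Wavelengths must be strictly increasing and uniformly spaced (the
    derivative stage requires a uniform grid).
    """
    path = Path(path)
    meta: dict[str, float] = {}
    wavelengths: list[float] = []
    intensities: list[float] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = _parse_float(val.strip(), lineno, "metadata value")
                continue
            fields = line.split(",")
            if not header_seen:
                if [f.strip() for f in fields] != ["wavelength_nm", "intensity"]:
                    raise FormatError(
                        "header must be exactly 'wavelength_nm,intensity', "
                        f"got {line!r}",
                        lineno,
                    )
                header_seen = True
                continue
            if len(fields) != 2:
                raise FormatError(
                    f"expected 2 columns, got {len(fields)}", lineno
                )
            wavelengths.append(_parse_float(fields[0], lineno, "wavelength"))
            intensities.append(_parse_float(fields[1], lineno, "intensity"))
    if not header_seen:
        raise FormatError("missing 'wavelength_nm,intensity' header")
    w = np.asarray(wavelengths)
    if w.size < 2:
        raise DataError(f"{path.name}: need at least two data rows")
    if np.any(np.diff(w) <= 0):
        raise DataError(f"{path.name}: wavelengths must be strictly increasing")
    try:
        grid = WavelengthGrid.from_values(w)
    except ValueError as exc:
        raise DataError(f"{path.name}: {exc}") from exc
    dl = delta_lambda if delta_lambda is not None else meta.get("delta_lambda_nm")
    if dl is None:
        raise DataError(
            f"{path.name}: no delta_lambda_nm metadata; pass delta_lambda explicitly"
        )
    return SynchronousSpectrum(float(dl), grid, np.asarray(intensities))


def write_eem_csv(eem: ExcitationEmissionMatrix, path: str | Path) -> None:
    """First row: emission grid; first column: excitation grid; body: intensity."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("ex_nm\\em_nm," + ",".join(repr(float(v)) for v in eem.em_grid.values) + "\n")
        for ex_val, row in zip(eem.ex_grid.values, eem.intensity):
            fh.write(repr(float(ex_val)) + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_eem_csv(path: str | Path) -> ExcitationEmissionMatrix:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path.name}: an EEM needs a header row and ≥ 2 data rows")
    header = lines[0].split(",")
    em_vals = [
        _parse_float(tok, 1, "emission wavelength") for tok in header[1:]
    ]
    n_em = len(em_vals)
    ex_vals: list[float] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(",")
        if len(fields) != n_em + 1:
            raise FormatError(
                f"row has {len(fields) - 1} intensity values, expected {n_em}",
                lineno,
            )
        ex_vals.append(_parse_float(fields[0], lineno, "excitation wavelength"))
        rows.append([_parse_float(tok, lineno, "intensity") for tok in fields[1:]])
    try:
        ex_grid = WavelengthGrid.from_values(np.asarray(ex_vals))
        em_grid = WavelengthGrid.from_values(np.asarray(em_vals))
    except ValueError as exc:
        raise DataError(f"{path.name}: {exc}") from exc
    return ExcitationEmissionMatrix(ex_grid, em_grid, np.asarray(rows))


# ---------------------------------------------------------------------------
# JCAMP-DX (single spectrum, AFFN XYDATA)
# ---------------------------------------------------------------------------


def read_jcamp(path: str | Path, delta_lambda: float | None = None) -> SynchronousSpectrum:
    """Read a single-spectrum JCAMP-DX file with an AFFN XYDATA table.

    Supports ``##XYDATA=(X++(Y..Y))`` with optional ``##XFACTOR``,
    ``##YFACTOR``, ``##DELTAX`` and ``##NPOINTS`` records.  Compressed
    ordinate encodings and any other XYDATA variant raise FormatError.
    """
    path = Path(path)
    records: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    in_data = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.split("$$")[0].strip()
                if key == "XYDATA":
                    if value.replace(" ", "") != "(X++(Y..Y))":
                        raise FormatError(
                            f"unsupported XYDATA variant {value!r}", lineno
                        )
                    in_data = True
                    continue
                if in_data and key == "END":
                    in_data = False
                    continue
                records[key] = value
                continue
            if in_data:
                data_lines.append((lineno, line))
    if not data_lines:
        raise FormatError(f"{path.name}: no XYDATA table found")
    xfactor = float(records.get("XFACTOR", "1"))
    yfactor = float(records.get("YFACTOR", "1"))
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in data_lines:
        toks = line.replace(",", " ").split()
        for tok in toks:
            if any(ch.isalpha() or ch in "@%" for ch in tok):
                raise FormatError(
                    f"compressed ordinate token {tok!r} not supported", lineno
                )
        vals = [_parse_float(t, lineno, "XYDATA value") for t in toks]
        if len(vals) < 2:
            raise FormatError("XYDATA line needs an X value and ≥ 1 Y value", lineno)
        x0 = vals[0] * xfactor
        xs.append(x0)
        ys.append(vals[1] * yfactor)
        if len(vals) > 2:
            deltax = float(records.get("DELTAX", "0"))
            if deltax == 0:
                raise FormatError(
                    "multiple Y per line requires ##DELTAX", lineno
                )
            for k, v in enumerate(vals[2:], start=1):
                xs.append(x0 + k * deltax * 1.0)
                ys.append(v * yfactor)
    n_declared = records.get("NPOINTS")
    if n_declared is not None and int(float(n_declared)) != len(xs):
        raise DataError(
            f"{path.name}: NPOINTS={n_declared} but {len(xs)} points read"
        )
    w = np.asarray(xs)
    order = np.argsort(w)
    w, y = w[order], np.asarray(ys)[order]
    try:
        grid = WavelengthGrid.from_values(w)
    except ValueError as exc:
        raise DataError(f"{path.name}: {exc}") from exc
    if delta_lambda is None:
        raise DataError(
            f"{path.name}: JCAMP-DX carries no Δλ; pass delta_lambda explicitly"
        )
    return SynchronousSpectrum(float(delta_lambda), grid, y)


# ---------------------------------------------------------------------------
# Calibration persistence
# ---------------------------------------------------------------------------


def save_calibration(model: CalibrationModel, path: str | Path) -> None:
    doc = {
        "format": "synchrofluor-calibration-v1",
        "analyte": model.analyte,
        "wavelength_nm": model.wavelength,
        "slope": model.slope,
        "intercept": model.intercept,
        "r_squared": model.r_squared,
        "residual_sd": model.residual_sd,
        "lod_ng_ml": model.lod,
        "loq_ng_ml": model.loq,
        "range_ng_ml": list(model.range),
        "n_points": model.n_points,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_calibration(path: str | Path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "synchrofluor-calibration-v1":
        raise FormatError(f"{Path(path).name}: not a calibration document")
    return CalibrationModel(
        analyte=doc["analyte"],
        wavelength=doc["wavelength_nm"],
        slope=doc["slope"],
        intercept=doc["intercept"],
        r_squared=doc["r_squared"],
        residual_sd=doc["residual_sd"],
        lod=doc["lod_ng_ml"],
        loq=doc["loq_ng_ml"],
        range=tuple(doc["range_ng_ml"]),
        n_points=doc["n_points"],
        seed=doc.get("seed"),
    )
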