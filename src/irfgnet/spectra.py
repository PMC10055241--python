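"""Reading and preprocessing of IR spectra.

Raw spectra arrive as JCAMP-DX records or two-column CSV files in either
transmittance or absorbance. Preprocessing converts to absorbance
(Beer-Lambert, ``A = -log10 T``), resamples by linear interpolation onto a
fixed, evenly spaced 600-point wavenumber grid spanning 400-4000 cm^-1, and
min-max normalizes each spectrum to [0, 1]. The resulting vector is the
network input. No baseline correction, smoothing, or peak picking is done.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RawSpectrum",
    "SpectrumGrid",
    "ProcessedSpectrum",
    "read_spectrum",
    "to_absorbance",
    "resample",
    "SpectrumFormatError",
]

Y_UNITS = ("transmittance_fraction", "transmittance_percent", "absorbance")

# floor for transmittance before the log; bounds absorbance at 6
_T_CLIP = 1e-6


class SpectrumFormatError(ValueError):
    """Malformed spectrum file or inconsistent spectrum data."""


@dataclass
class RawSpectrum:
    """A spectrum as read from disk, prior to any preprocessing.

    ``x`` is strictly monotone (ascending or descending, as stored in the
    file); ``y`` holds intensities in the unit named by ``y_unit``.
    """

    x: np.ndarray
    y: np.ndarray
    y_unit: str = "absorbance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape or self.x.size < 2:
            raise SpectrumFormatError("x and y must be equal-length 1-D arrays (n >= 2)")
        dx = np.diff(self.x)
        if not ((dx > 0).all() or (dx < 0).all()):
            raise SpectrumFormatError("wavenumber axis must be strictly monotone")
        if self.y_unit not in Y_UNITS:
            raise SpectrumFormatError(f"unknown y_unit {self.y_unit!r}")


@dataclass(frozen=True)
class SpectrumGrid:
    """Evenly spaced wavenumber grid, endpoints inclusive.

    Defaults to 600 points over 400-4000 cm^-1 (~6.01 cm^-1 spacing), the
    network's fixed input axis.
    """

    start: float = 400.0
    end: float = 4000.0
    n_points: int = 600

    def __post_init__(self) -> None:
        if not (self.start < self.end and self.n_points >= 2):
            raise ValueError("grid requires start < end and n_points >= 2")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_points)


DEFAULT_GRID = SpectrumGrid()


@dataclass
class ProcessedSpectrum:
    """Grid-aligned, [0, 1]-normalized absorbance vector: the CNN input."""

    intensities: np.ndarray
    grid: SpectrumGrid = DEFAULT_GRID
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_points,):
            raise ValueError(
                f"expected {self.grid.n_points} intensities, got {self.intensities.shape}"
            )
        if self.intensities.min() < -1e-9 or self.intensities.max() > 1 + 1e-9:
            raise ValueError("processed intensities must lie in [0, 1]")


def read_spectrum(path: str | Path, format: str | None = None, y_unit: str | None = None) -> RawSpectrum:
    """Read a spectrum file into a :class:`RawSpectrum`.

    Parameters
    ----------
    path
        File to read.
    format
        ``"jcamp"`` or ``"csv"``; inferred from the suffix when omitted
        (``.jdx``/``.dx`` -> jcamp, otherwise csv).
    y_unit
        Intensity unit for CSV input (default ``"absorbance"``); for JCAMP
        the unit is inferred from ``##YUNITS=``.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumFormatError(f"no such file: {path}")
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcm") else "csv"
    if format == "jcamp":
        return _read_jcamp(path)
    if format == "csv":
        return _read_csv(path, y_unit or "absorbance")
    raise SpectrumFormatError(f"unknown spectrum format {format!r}")


def _read_csv(path: Path, y_unit: str) -> RawSpectrum:
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = re.split(r"[,\t;]", line)
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric value in {line!r}"
                ) from None
            xs.append(x)
            ys.append(y)
    if len(xs) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data rows")
    return RawSpectrum(np.array(xs), np.array(ys), y_unit, meta={"source": str(path)})


_JCAMP_NUM = re.compile(r"[+-]?\d*\.?\d+(?:[eE][+-]?\d+)?")


def _read_jcamp(path: Path) -> RawSpectrum:
    """Minimal JCAMP-DX reader.

    Supports the ``##XYDATA=(X++(Y..Y))`` tabular form with plain (AFFN)
    numbers and the ``##XYPOINTS=(XY..XY)`` pair form, honoring XFACTOR,
    YFACTOR, FIRSTX, LASTX, NPOINTS and DELTAX. Compressed (SQZ/DIF/DUP)
    ordinates are not supported.
    """
    header: dict[str, str] = {}
    mode = None
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("$$")[0].rstrip()
            if not line.strip():
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    mode = "xydata"
                    continue
                if key == "XYPOINTS":
                    mode = "xypoints"
                    continue
                if key == "END":
                    mode = None
                    continue
                header[key] = value
                mode = None
                continue
            if mode is None:
                continue
            nums = _JCAMP_NUM.findall(line)
            if not nums:
                raise SpectrumFormatError(f"{path}:{lineno}: unreadable data line {line!r}")
            vals = [float(v) for v in nums]
            if mode == "xydata":
                # first number is the abscissa of the line, the rest ordinates
                if len(vals) < 2:
                    raise SpectrumFormatError(f"{path}:{lineno}: XYDATA line needs X and Y")
                xs.append(vals[0])
                ys.append(vals[1:])
            else:
                if len(vals) % 2:
                    raise SpectrumFormatError(f"{path}:{lineno}: odd value count in XYPOINTS")
                xs.extend(vals[0::2])
                ys.extend(vals[1::2])
    if not xs:
        raise SpectrumFormatError(f"{path}: no spectral data found")

    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))

    if ys and isinstance(ys[0], list):  # XYDATA: reconstruct per-point x
        firstx = float(header.get("FIRSTX", xs[0] * xfactor))
        lastx = float(header.get("LASTX", xs[-1] * xfactor))
        flat_y = [v for row in ys for v in row]
        npoints = int(float(header.get("NPOINTS", len(flat_y))))
        if npoints != len(flat_y):
            raise SpectrumFormatError(
                f"{path}: NPOINTS={npoints} but {len(flat_y)} ordinates found"
            )
        x_arr = np.linspace(firstx, lastx, npoints)
        y_arr = np.array(flat_y) * yfactor
    else:
        x_arr = np.array(xs) * xfactor
        y_arr = np.array(ys) * yfactor

    yunits = header.get("YUNITS", "ABSORBANCE").upper()
    if "TRANSMIT" in yunits:
        y_unit = "transmittance_percent" if y_arr.max() > 1.5 else "transmittance_fraction"
    else:
        y_unit = "absorbance"
    meta = {"source": str(path), "title": header.get("TITLE", "")}
    return RawSpectrum(x_arr, y_arr, y_unit, meta=meta)


def to_absorbance(s: RawSpectrum) -> RawSpectrum:
    """Convert a raw spectrum to absorbance via ``A = -log10(T)``.

    Absorbance input is returned unchanged. Percent transmittance is divided
    by 100 first; transmittance is clipped below at 1e-6 before the log, so
    absorbance never exceeds 6.
    """
    if s.y_unit == "absorbance":
        return s
    t = s.y / 100.0 if s.y_unit == "transmittance_percent" else s.y.copy()
    t = np.clip(t, _T_CLIP, None)
    a = -np.log10(t)
    return RawSpectrum(s.x.copy(), a, "absorbance", meta=dict(s.meta))


def resample(s: RawSpectrum, grid: SpectrumGrid = DEFAULT_GRID) -> ProcessedSpectrum:
    """Interpolate onto the fixed grid and min-max normalize to [0, 1].

    Linear interpolation; grid points outside the observed wavenumber range
    take the nearest observed value (no fabricated absorption edges). A
    constant spectrum normalizes to all zeros, with a warning.
    """
    x, y = s.x, s.y
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    if x[-1] < grid.start or x[0] > grid.end:
        raise ValueError(
            f"spectrum range [{x[0]:g}, {x[-1]:g}] cm^-1 does not overlap grid "
            f"[{grid.start:g}, {grid.end:g}] cm^-1"
        )
    vals = np.interp(grid.wavenumbers, x, y)  # np.interp clamps to edge values
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-12:
        logger.warning("constant spectrum: normalizing to all zeros")
        vals = np.zeros_like(vals)
    else:
        vals = (vals - lo) / (hi - lo)
    return ProcessedSpectrum(vals, grid=grid, meta=dict(s.meta))


def preprocess(s: RawSpectrum, grid: SpectrumGrid = DEFAULT_GRID) -> ProcessedSpectrum:
    """Full pipeline: absorbance conversion then grid resampling."""
    return resample(to_absorbance(s), grid)


def save_dataset(
    path: str | Path,
    X: np.ndarray,
    grid: SpectrumGrid,
    ids: list[str],
    Y: np.ndarray | None = None,
    class_names: list[str] | None = None,
) -> None:
    """Write the processed-dataset container: one .npz archive holding the
    (n_samples, n_points) intensity matrix, the grid definition, sample ids
    and optionally the binary label matrix with its class names."""
    arrays = {
        "X": np.asarray(X, dtype=np.float32),
        "grid": np.array([grid.start, grid.end, grid.n_points]),
        "ids": np.array(ids, dtype=str),
    }
    if Y is not None:
        arrays["Y"] = np.asarray(Y, dtype=np.int8)
        arrays["class_names"] = np.array(class_names or [], dtype=str)
    np.savez_compressed(path, **arrays)


def load_dataset(path: str | Path) -> dict:
    """Read a container written by :func:`save_dataset`."""
    with np.load(path, allow_pickle=False) as data:
        start, end, n = data["grid"]
        out = {
            "X": data["X"].astype(float),
            "grid": SpectrumGrid(float(start), float(end), int(n)),
            "ids": data["ids"].tolist(),
        }
        if "Y" in data:
            out["Y"] = data["Y"].astype(np.int8)
            out["class_names"] = data["class_names"].tolist()
    return out
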