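"""Hyperspectral cube I/O and white-reference reflectance calibration.

A scene is a rows x cols x bands reflectance raster captured by a 16-band
snapshot-mosaic visible-range sensor. Raw sensor counts are converted to
relative reflectance by flat-field normalisation against a frame of a
calibration board of known reflectance (the "white reference"):

    R = f * (raw - dark) / (white - dark)

with ``f`` the board reflectance (default 0.98) and ``dark`` an optional
dark-current frame (zero when absent). Calibrated values are clipped to
[0, 1.10]; small excursions above 1 are expected from specular noise in
uncontrolled bedside illumination and are not an error.

Cubes are stored as ENVI header (.hdr) + flat binary raster (bil/bip/bsq,
uint16 or float32) or as multi-band TIFF. Coordinates are 0-based,
row-major; regions of interest are half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CalibrationError, DimensionError, FormatError, ParameterError

#: Band centres (nm) of the 16-band snapshot-mosaic visible-range sensor.
SENSOR_WAVELENGTHS_NM: tuple[float, ...] = (
    465.0, 474.0, 485.0, 496.0, 510.0, 522.0, 534.0, 546.0,
    548.0, 562.0, 578.0, 586.0, 600.0, 608.0, 624.0, 630.0,
)

#: Ceiling applied to calibrated reflectance (specular-noise headroom).
REFLECTANCE_CEILING = 1.10

# ENVI data-type codes <-> numpy dtypes (subset this package reads/writes)
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-centre wavelengths in nanometres."""

    wavelengths_nm: tuple[float, ...]

    def __post_init__(self):
        wl = tuple(float(w) for w in self.wavelengths_nm)
        object.__setattr__(self, "wavelengths_nm", wl)
        if len(wl) == 0:
            raise ParameterError("wavelength grid is empty")
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ParameterError("wavelengths must be strictly increasing")
        if wl[0] < 400.0 or wl[-1] > 1000.0:
            raise ParameterError("wavelengths must lie within [400, 1000] nm")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def band_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of bands whose centre lies in the closed range [lo, hi]."""
        wl = np.asarray(self.wavelengths_nm)
        return np.nonzero((wl >= lo_nm) & (wl <= hi_nm))[0]


#: Grid of the study sensor's 16 bands.
SENSOR_GRID = WavelengthGrid(SENSOR_WAVELENGTHS_NM)


@dataclass(frozen=True)
class ImagingGeometry:
    """Acquisition geometry: camera distance, board reflectance, pixel pitch."""

    working_distance_cm: float = 70.0
    white_reflectance_factor: float = 0.98
    pixel_pitch_cm: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.white_reflectance_factor <= 1.0):
            raise ParameterError("white_reflectance_factor must be in (0, 1]")
        if self.pixel_pitch_cm <= 0:
            raise ParameterError("pixel_pitch_cm must be positive")
        if self.working_distance_cm <= 0:
            raise ParameterError("working_distance_cm must be positive")


@dataclass
class SpectralCube:
    """rows x cols x bands raster with its wavelength grid and pixel pitch.

    ``values`` are raw counts when ``calibrated`` is False and unitless
    relative reflectance in [0, 1.10] when True.
    """

    values: np.ndarray
    grid: WavelengthGrid
    pixel_pitch_cm: float
    calibrated: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionError(
                f"cube must be rows x cols x bands, got ndim={self.values.ndim}"
            )
        if self.values.shape[2] != len(self.grid):
            raise DimensionError(
                f"cube has {self.values.shape[2]} bands but grid lists "
                f"{len(self.grid)} wavelengths"
            )
        if self.pixel_pitch_cm <= 0:
            raise ParameterError("pixel_pitch_cm must be positive")
        if self.calibrated:
            v = self.values
            if not np.all(np.isfinite(v)):
                raise CalibrationError("calibrated cube contains non-finite values")
            if v.size and (v.min() < 0 or v.max() > REFLECTANCE_CEILING + 1e-12):
                raise CalibrationError(
                    "calibrated reflectance outside [0, %.2f]" % REFLECTANCE_CEILING
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    def spectra(self) -> np.ndarray:
        """Flattened (rows*cols) x bands view of the pixel spectra."""
        return self.values.reshape(-1, len(self.grid))


# ---------------------------------------------------------------------------
# ENVI header + flat binary raster
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header: missing leading 'ENVI' token")
    # join brace-delimited multi-line values onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: " ".join(m.group(0).split()), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _require_int(fields: dict, key: str) -> int:
    if key not in fields:
        raise FormatError(f"ENVI header missing required field '{key}'")
    try:
        return int(fields[key])
    except ValueError:
        raise FormatError(f"ENVI header field '{key}' is not an integer: "
                          f"{fields[key]!r}") from None


def read_envi_cube(
    header_path: str | Path,
    data_path: str | Path | None = None,
    *,
    pixel_pitch_cm: float = 0.05,
    geometry: ImagingGeometry | None = None,
) -> SpectralCube:
    """Read an ENVI header + flat binary raster into an uncalibrated cube.

    Wavelengths come from the header's ``wavelength`` block when present,
    otherwise the bundled 16-band sensor grid (only when the band count is
    16). ``data_path`` defaults to the header path without its ``.hdr``
    suffix. Pixel pitch comes from ``geometry`` when given.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    samples = _require_int(fields, "samples")
    lines = _require_int(fields, "lines")
    bands = _require_int(fields, "bands")
    dtype_code = _require_int(fields, "data type")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported ENVI interleave {interleave!r}")
    byte_order = int(fields.get("byte order", "0"))

    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
        wavelengths = [float(w) for w in wl_text.replace(",", " ").split()]
        if len(wavelengths) != bands:
            raise DimensionError(
                f"ENVI header declares bands={bands} but lists "
                f"{len(wavelengths)} wavelengths"
            )
        grid = WavelengthGrid(tuple(wavelengths))
    elif bands == len(SENSOR_GRID):
        grid = SENSOR_GRID
    else:
        raise FormatError(
            f"ENVI header lists no wavelengths and bands={bands} does not "
            f"match the bundled {len(SENSOR_GRID)}-band sensor grid"
        )

    if data_path is None:
        candidates = [header_path.with_suffix(ext)
                      for ext in ("", ".raw", ".img", ".dat")]
        data_path = next((p for p in candidates if p.exists()), None)
        if data_path is None:
            raise FormatError(
                f"no raster found next to {header_path.name} "
                f"(tried {[p.name for p in candidates]})"
            )
    elif not Path(data_path).exists():
        raise FormatError(f"raster file {data_path} does not exist")
    raw = np.fromfile(data_path, dtype=_ENVI_DTYPES[dtype_code])
    if byte_order == 1:
        raw = raw.byteswap()
    expected = samples * lines * bands
    if raw.size != expected:
        raise DimensionError(
            f"raster holds {raw.size} values, header implies {expected}"
        )

    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        values = raw.reshape(lines, samples, bands)

    pitch = geometry.pixel_pitch_cm if geometry is not None else pixel_pitch_cm
    return SpectralCube(np.ascontiguousarray(values), grid, pitch, calibrated=False)


def write_envi_cube(
    cube: SpectralCube,
    header_path: str | Path,
    data_path: str | Path | None = None,
    *,
    interleave: str = "bsq",
    dtype: np.dtype | type | None = None,
) -> None:
    """Write a cube as ENVI header + flat binary raster (round-trip exact
    for integer data and for float32 values already in float32)."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix("")
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ParameterError(f"unsupported interleave {interleave!r}")

    values = cube.values
    if dtype is not None:
        values = values.astype(dtype)
    if values.dtype not in _DTYPE_CODES:
        values = values.astype(np.float32)
    rows, cols, bands = values.shape

    if interleave == "bsq":
        flat = values.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = values.transpose(0, 2, 1)
    else:
        flat = values

    wl = ", ".join(f"{w:g}" for w in cube.grid.wavelengths_nm)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        f"data type = {_DTYPE_CODES[values.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    np.ascontiguousarray(flat).tofile(data_path)


def read_tiff_cube(
    path: str | Path,
    *,
    grid: WavelengthGrid | None = None,
    pixel_pitch_cm: float = 0.05,
) -> SpectralCube:
    """Read a multi-band TIFF; accepts (bands, rows, cols) or
    (rows, cols, bands) layout, disambiguated by matching the grid length."""
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim != 3:
        raise DimensionError(f"TIFF is not a 3-D stack (ndim={arr.ndim})")
    g = grid if grid is not None else SENSOR_GRID
    if arr.shape[0] == len(g) and arr.shape[2] != len(g):
        arr = arr.transpose(1, 2, 0)
    if arr.shape[2] != len(g):
        raise DimensionError(
            f"no TIFF axis of length {len(g)} matches the wavelength grid"
        )
    return SpectralCube(np.ascontiguousarray(arr), g, pixel_pitch_cm)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _as_frame(ref: SpectralCube | np.ndarray, shape: tuple, grid_len: int,
              name: str) -> np.ndarray:
    """Coerce a reference (cube, single spectrum, or array) to broadcastable
    float array against ``shape``."""
    arr = ref.values if isinstance(ref, SpectralCube) else np.asarray(ref)
    arr = arr.astype(np.float64)
    if arr.ndim == 1:
        if arr.shape[0] != grid_len:
            raise DimensionError(f"{name} spectrum has {arr.shape[0]} bands, "
                                 f"cube has {grid_len}")
        return arr.reshape(1, 1, -1)
    if arr.ndim == 3:
        if arr.shape[2] != grid_len:
            raise DimensionError(f"{name} has {arr.shape[2]} bands, cube has "
                                 f"{grid_len}")
        if arr.shape[:2] not in ((1, 1), shape[:2]):
            raise DimensionError(
                f"{name} spatial shape {arr.shape[:2]} does not match cube "
                f"{shape[:2]}"
            )
        return arr
    raise DimensionError(f"{name} must be a spectrum or a cube (ndim 1 or 3)")


def calibrate_reflectance(
    raw: SpectralCube,
    white: SpectralCube | np.ndarray,
    dark: SpectralCube | np.ndarray | None = None,
    geometry: ImagingGeometry | None = None,
) -> SpectralCube:
    """Flat-field calibration R = f * (raw - dark) / (white - dark).

    ``white`` may be a full frame or a single spectrum broadcast spatially;
    ``dark`` defaults to zero. Output is clipped to [0, 1.10] and flagged
    calibrated. Raises :class:`CalibrationError` when any (white - dark)
    entry is non-positive, reporting how many entries are bad.
    """
    geometry = geometry or ImagingGeometry(pixel_pitch_cm=raw.pixel_pitch_cm)
    nb = len(raw.grid)
    raw_v = raw.values.astype(np.float64)
    white_v = _as_frame(white, raw.shape, nb, "white")
    dark_v = (np.zeros((1, 1, nb)) if dark is None
              else _as_frame(dark, raw.shape, nb, "dark"))

    denom = white_v - dark_v
    bad = int(np.count_nonzero(denom <= 0))
    if bad:
        raise CalibrationError(
            f"white reference not above dark level in {bad} entries"
        )
    refl = geometry.white_reflectance_factor * (raw_v - dark_v) / denom
    refl = np.clip(refl, 0.0, REFLECTANCE_CEILING)
    return SpectralCube(refl, raw.grid, raw.pixel_pitch_cm, calibrated=True)


# ---------------------------------------------------------------------------
# Snapshot-mosaic demosaicing
# ---------------------------------------------------------------------------

def demosaic_snapshot(
    mosaic: np.ndarray,
    pattern_size: int = 4,
    *,
    grid: WavelengthGrid | None = None,
    pixel_pitch_cm: float = 0.05,
) -> SpectralCube:
    """Split a single-plane snapshot-mosaic frame into a band cube.

    Band ``b`` is the sub-grid at mosaic offset (b // p, b % p) in row-major
    tile order mapped onto the sorted wavelength list; output spatial size is
    input / p and the pixel pitch grows by the same factor.
    """
    mosaic = np.asarray(mosaic)
    if mosaic.ndim != 2:
        raise DimensionError("mosaic must be a single 2-D plane")
    p = int(pattern_size)
    g = grid if grid is not None else SENSOR_GRID
    if p * p != len(g):
        raise DimensionError(
            f"pattern {p}x{p} yields {p * p} bands but grid has {len(g)}"
        )
    rows, cols = mosaic.shape
    if rows % p or cols % p:
        raise DimensionError(
            f"mosaic {rows}x{cols} not divisible by pattern size {p}"
        )
    bands = [mosaic[b // p::p, b % p::p] for b in range(p * p)]
    values = np.stack(bands, axis=-1)
    return SpectralCube(values, g, pixel_pitch_cm * p, calibrated=False)


def remosaic_snapshot(cube: SpectralCube, pattern_size: int = 4) -> np.ndarray:
    """Inverse tiling of :func:`demosaic_snapshot` (exact reconstruction)."""
    p = int(pattern_size)
    if p * p != len(cube.grid):
        raise DimensionError(
            f"pattern {p}x{p} yields {p * p} bands but cube has "
            f"{len(cube.grid)}"
        )
    rows, cols, _ = cube.shape
    mosaic = np.empty((rows * p, cols * p), dtype=cube.values.dtype)
    for b in range(p * p):
        mosaic[b // p::p, b % p::p] = cube.values[:, :, b]
    return mosaic
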