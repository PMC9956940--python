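"""Synthetic 16-band hyperspectral wound phantoms with exact ground truth.

The study's bedside images were never deposited, so every pipeline stage is
exercised on generated scenes instead: a skin-like background spectrum, a
wound region carrying an oxy-hemoglobin-style absorption dip at 534-586 nm,
an optional erythema halo blending from wound to skin spectrum, a
multiplicative illumination gradient, and additive Gaussian sensor noise.
The wound mask is drawn first as a discrete set of pixels, so the true
area — pixel count times pitch squared — is exact regardless of how
realistic the shape is.

Spectral anchors and the dip depth are fixed documented constants chosen
for clean class separability with a hemoglobin-like motif; they are not
fits to tissue optics data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .area import METHOD_NURSE_LW, AreaMeasurement, lw_area
from .cube_io import REFLECTANCE_CEILING, SENSOR_GRID, SpectralCube, WavelengthGrid
from .errors import ParameterError
from .segmentation import WoundMask

#: Piecewise-linear skin reflectance anchors (nm -> reflectance).
SKIN_ANCHORS_NM = ((465.0, 0.35), (500.0, 0.42), (560.0, 0.50),
                   (600.0, 0.56), (630.0, 0.60))
#: Hemoglobin-style absorption dip: depth, centre and half-width (nm).
DIP_DEPTH = 0.25
DIP_CENTER_NM = 560.0
DIP_HALF_WIDTH_NM = 95.0
WOUND_FLOOR = 0.05


def skin_spectrum(grid: WavelengthGrid = SENSOR_GRID) -> np.ndarray:
    """Smooth skin reflectance rising from 0.35 at 465 nm to 0.60 at 630 nm."""
    wl = np.asarray(grid.wavelengths_nm)
    if wl[0] < 400.0 or wl[-1] > 1000.0:
        raise ParameterError("grid must lie within 400-1000 nm")
    xp = [a for a, _ in SKIN_ANCHORS_NM]
    fp = [v for _, v in SKIN_ANCHORS_NM]
    return np.interp(wl, xp, fp)


def wound_spectrum(grid: WavelengthGrid = SENSOR_GRID) -> np.ndarray:
    """Skin spectrum minus a raised-cosine absorption dip over 534-586 nm.

    The dip has depth 0.25 at its 560 nm centre and vanishes 95 nm away,
    so it is exactly zero at the 465 nm anchor; values are floored at 0.05.
    """
    wl = np.asarray(grid.wavelengths_nm)
    d = np.abs(wl - DIP_CENTER_NM)
    dip = np.where(
        d < DIP_HALF_WIDTH_NM,
        DIP_DEPTH * np.cos(np.pi * d / (2.0 * DIP_HALF_WIDTH_NM)) ** 2,
        0.0,
    )
    return np.maximum(skin_spectrum(grid) - dip, WOUND_FLOOR)


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters of one phantom scene."""

    rows: int = 96
    cols: int = 96
    pixel_pitch_cm: float = 0.05
    wound_shape: str = "disk"          # disk | blob
    disk_radius_px: int = 20
    blob_smooth_px: float = 6.0
    blob_threshold: float = 0.6        # upper-tail quantile kept as wound
    erythema_halo_px: int = 0
    noise_sigma: float = 0.01
    illumination_gradient: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.erythema_halo_px < 0:
            raise ParameterError("erythema_halo_px must be >= 0")
        if not (0.0 < self.blob_threshold < 1.0):
            raise ParameterError("blob_threshold must be in (0, 1)")
        if self.wound_shape not in ("disk", "blob"):
            raise ParameterError(f"unknown wound shape {self.wound_shape!r}")


@dataclass
class PhantomScene:
    """A generated cube plus its exact ground truth."""

    cube: SpectralCube
    truth_mask: WoundMask
    true_area_cm2: float
    params: PhantomParams


def _disk_mask(rows: int, cols: int, radius: int) -> np.ndarray:
    rr, cc = np.mgrid[:rows, :cols]
    cr, cc0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    return (rr - cr) ** 2 + (cc - cc0) ** 2 <= radius**2


def _blob_mask(rows: int, cols: int, smooth_px: float, threshold: float,
               rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((rows, cols))
    smoothed = ndimage.gaussian_filter(noise, sigma=smooth_px)
    # keep the upper tail, then the component containing the field maximum
    # so the wound is a single connected blob
    mask = smoothed >= np.quantile(smoothed, threshold)
    labeled, _ = ndimage.label(mask)
    peak = np.unravel_index(np.argmax(smoothed), smoothed.shape)
    return labeled == labeled[peak]


def generate_phantom(params: PhantomParams | None = None) -> PhantomScene:
    """Generate one phantom scene, fully deterministic per seed."""
    params = params or PhantomParams()
    rows, cols = params.rows, params.cols
    rng = np.random.default_rng(params.seed)

    if params.wound_shape == "disk":
        margin = params.disk_radius_px + params.erythema_halo_px
        if 2 * margin >= min(rows, cols):
            raise ParameterError(
                f"disk radius {params.disk_radius_px} plus halo "
                f"{params.erythema_halo_px} does not fit in {rows}x{cols}"
            )
        truth = _disk_mask(rows, cols, params.disk_radius_px)
    else:
        truth = _blob_mask(rows, cols, params.blob_smooth_px,
                           params.blob_threshold, rng)
        if not truth.any():
            raise ParameterError("blob threshold produced an empty wound")

    grid = SENSOR_GRID
    skin = skin_spectrum(grid)
    wound = wound_spectrum(grid)

    # wound weight: 1 inside the wound, linear falloff across the halo ring
    weight = truth.astype(np.float64)
    if params.erythema_halo_px > 0:
        dist = ndimage.distance_transform_edt(~truth)
        ring = (dist > 0) & (dist <= params.erythema_halo_px)
        weight[ring] = 1.0 - dist[ring] / (params.erythema_halo_px + 1.0)

    values = (weight[:, :, None] * wound[None, None, :]
              + (1.0 - weight)[:, :, None] * skin[None, None, :])

    if params.illumination_gradient > 0:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rr, cc = np.mgrid[:rows, :cols]
        ramp = ((rr / max(rows - 1, 1) - 0.5) * np.cos(theta)
                + (cc / max(cols - 1, 1) - 0.5) * np.sin(theta))
        peak = np.abs(ramp).max()
        if peak > 0:
            ramp = ramp / peak      # ramp in [-1, 1]
        values = values * (1.0 + params.illumination_gradient * ramp)[:, :, None]

    if params.noise_sigma > 0:
        values = values + rng.normal(0.0, params.noise_sigma, values.shape)

    values = np.clip(values, 0.0, REFLECTANCE_CEILING)
    cube = SpectralCube(values, grid, params.pixel_pitch_cm, calibrated=True)
    mask = WoundMask(truth, params.pixel_pitch_cm)
    true_area = mask.pixel_count() * params.pixel_pitch_cm**2
    return PhantomScene(cube, mask, true_area, params)


def halo_mask(scene: PhantomScene) -> np.ndarray:
    """Wound plus erythema ring of a scene (equals the truth mask when the
    scene was generated without a halo)."""
    truth = scene.truth_mask.mask
    h = scene.params.erythema_halo_px
    if h <= 0:
        return truth.copy()
    dist = ndimage.distance_transform_edt(~truth)
    return truth | (dist <= h)


def simulate_nurse_measurement(
    scene: PhantomScene,
    include_halo: bool = False,
    jitter_cm: float = 0.0,
    seed: int | None = None,
) -> AreaMeasurement:
    """Emulate the bedside ruler measurement on a phantom.

    The nurse reads maximal length and width off the visually reddened
    region — the wound plus, when ``include_halo`` is set, its erythema
    ring — with optional uniform ruler error of +/- ``jitter_cm`` per
    dimension, and multiplies them (LW rule).
    """
    region = halo_mask(scene) if include_halo else scene.truth_mask.mask
    base = lw_area(WoundMask(region, scene.truth_mask.pixel_pitch_cm),
                   method=METHOD_NURSE_LW)
    length = base.provenance["length_cm"]
    width = base.provenance["width_cm"]
    if jitter_cm > 0:
        rng = np.random.default_rng(
            scene.params.seed + 1_000_003 if seed is None else seed
        )
        length = max(length + rng.uniform(-jitter_cm, jitter_cm),
                     scene.truth_mask.pixel_pitch_cm)
        width = max(width + rng.uniform(-jitter_cm, jitter_cm),
                    scene.truth_mask.pixel_pitch_cm)
    return AreaMeasurement(
        method=METHOD_NURSE_LW,
        area_cm2=length * width,
        provenance={
            "include_halo": include_halo,
            "jitter_cm": jitter_cm,
            "length_cm": length,
            "width_cm": width,
        },
    )
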