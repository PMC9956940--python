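"""Wound area measurement: the LW rule and morphology-based planimetry.

Two conventions are computed per case, both in cm^2:

* **LW rule** — the bedside ruler convention: maximal length times maximal
  width, i.e. the axis-aligned bounding-box area of the wound mask. This is
  what nurses record and what the machine mirrors for comparability.
* **Planimetric (morphology) area** — the wound mask is cleaned by a
  morphological opening, reduced to its largest 4-connected component, and
  hole-filled; the area is then the pixel count times the per-pixel area.

An empty mask raises :class:`~hsiwound.errors.EmptyWoundError` rather than
returning zero: every study case had a wound, so emptiness indicates a
segmentation failure upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import diamond, opening

from .cube_io import SpectralCube
from .errors import CalibrationError, EmptyWoundError
from .segmentation import RegionOfInterest, WoundMask, extract_roi, segment_cube

#: Method tags for the three measurement conventions.
METHOD_NURSE_LW = "nurse_lw"
METHOD_MACHINE_LW = "machine_lw"
METHOD_MACHINE_MORPH = "machine_morph"


@dataclass
class AreaMeasurement:
    method: str
    area_cm2: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.area_cm2 < 0:
            raise ValueError("area_cm2 must be non-negative")


def _bbox_extent_px(mask: np.ndarray) -> tuple[int, int]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1)


def lw_area(mask: WoundMask, method: str = METHOD_MACHINE_LW) -> AreaMeasurement:
    """Length x width area of the mask's axis-aligned bounding box."""
    if mask.pixel_count() == 0:
        raise EmptyWoundError("cannot apply the LW rule to an empty mask")
    h_px, w_px = _bbox_extent_px(mask.mask)
    pitch = mask.pixel_pitch_cm
    length_cm, width_cm = h_px * pitch, w_px * pitch
    return AreaMeasurement(
        method=method,
        area_cm2=length_cm * width_cm,
        provenance={
            "pixel_pitch_cm": pitch,
            "length_cm": length_cm,
            "width_cm": width_cm,
        },
    )


def clean_mask(
    mask: WoundMask,
    opening_radius: int = 1,
    min_component: int = 1,
) -> WoundMask:
    """Morphological clean-up before planimetry.

    Binary opening with a cross-shaped (diamond) structuring element of the
    given radius removes speckle; the single largest 4-connected component
    is kept (ties broken by the smallest top-left bounding-box corner,
    row-major), components below ``min_component`` pixels being ignored;
    fully enclosed holes are then filled. The result is a subset of the
    hole-filled opened input.
    """
    m = mask.mask
    if opening_radius > 0:
        m = opening(m, diamond(opening_radius)).astype(bool)
    if not m.any():
        raise EmptyWoundError("mask emptied by morphological opening",
                              stage="opening")

    labeled, n_comp = cc_label(m, connectivity=1, return_num=True)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    sizes[sizes < min_component] = 0
    if sizes.max() == 0:
        raise EmptyWoundError(
            f"no connected component reaches {min_component} pixels",
            stage="component-filter",
        )
    best = None
    for comp in np.nonzero(sizes == sizes.max())[0]:
        rows, cols = np.nonzero(labeled == comp)
        corner = (int(rows.min()), int(cols.min()))
        if best is None or corner < best[1]:
            best = (comp, corner)
    kept = labeled == best[0]

    filled = ndimage.binary_fill_holes(kept)
    return WoundMask(filled, mask.pixel_pitch_cm)


def planimetric_area(
    mask: WoundMask, method: str = METHOD_MACHINE_MORPH
) -> AreaMeasurement:
    """Pixel-count planimetry: true pixels x pitch^2."""
    count = mask.pixel_count()
    if count == 0:
        raise EmptyWoundError("cannot measure the area of an empty mask")
    pitch = mask.pixel_pitch_cm
    return AreaMeasurement(
        method=method,
        area_cm2=count * pitch * pitch,
        provenance={"pixel_pitch_cm": pitch, "pixel_count": count},
    )


@dataclass(frozen=True)
class PipelineSettings:
    """Tunable parameters of the segmentation + measurement pipeline."""

    k: int = 2
    seed: int = 0
    restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-6
    selection_rule: str = "hemoglobin-dip"
    normalize: bool = False
    opening_radius: int = 1
    min_component: int = 1


def measure_case(
    cube: SpectralCube,
    roi: RegionOfInterest | None = None,
    settings: PipelineSettings | None = None,
) -> tuple[AreaMeasurement, AreaMeasurement]:
    """End-to-end measurement of one calibrated cube.

    Crops to the ROI, clusters the spectra, labels the wound cluster, and
    returns (machine_lw, machine_morph): the LW area of the raw wound mask
    and the planimetric area of the cleaned mask, each carrying full
    provenance (seed, rule, parameters).
    """
    if not cube.calibrated:
        raise CalibrationError("measure_case requires a calibrated cube")
    settings = settings or PipelineSettings()
    sub = extract_roi(cube, roi) if roi is not None else cube

    mask, model, wound_idx = segment_cube(
        sub,
        k=settings.k,
        seed=settings.seed,
        restarts=settings.restarts,
        max_iter=settings.max_iter,
        tol=settings.tol,
        rule=settings.selection_rule,
        normalize=settings.normalize,
    )
    if mask.pixel_count() == 0:
        raise EmptyWoundError("segmentation produced an empty wound mask",
                              stage="segmentation")

    provenance = {
        "k": settings.k,
        "seed": settings.seed,
        "restarts": settings.restarts,
        "selection_rule": settings.selection_rule,
        "normalize": settings.normalize,
        "wound_cluster": wound_idx,
        "inertia": model.inertia,
        "opening_radius": settings.opening_radius,
        "min_component": settings.min_component,
        "roi": None if roi is None else (roi.r0, roi.r1, roi.c0, roi.c1),
    }
    machine_lw = lw_area(mask)
    machine_lw.provenance.update(provenance)

    cleaned = clean_mask(mask, settings.opening_radius, settings.min_component)
    machine_morph = planimetric_area(cleaned)
    machine_morph.provenance.update(provenance)
    return machine_lw, machine_morph
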