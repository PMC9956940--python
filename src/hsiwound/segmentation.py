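"""Wound segmentation: ROI framing, from-scratch k-means, cluster labelling.

The measurement pipeline frames the wound region (dropping bed sheets,
clothing and other unrelated content), then partitions the framed pixel
spectra into k clusters with Lloyd's algorithm and labels the wound cluster.
k defaults to 2 — wound versus surrounding healthy skin — because framing
removes non-skin content first.

The wound cluster is identified by the hemoglobin-dip rule: erythema and
granulation tissue absorb strongly in the oxy-hemoglobin bands around
534-586 nm while healthy skin reflectance keeps rising toward the red end,
so the cluster whose centroid has the smallest mean(534-586 nm) /
mean(600-630 nm) ratio is taken as wound. A "darkest" fallback (minimum
overall mean reflectance) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube_io import SpectralCube, WavelengthGrid
from .errors import DimensionError, ParameterError, SegmentationError

HEMOGLOBIN_BAND_NM = (534.0, 586.0)
REFERENCE_BAND_NM = (600.0, 630.0)


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pixel rectangle [r0, r1) x [c0, c1), 0-based row-major."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self):
        if not (0 <= self.r0 < self.r1 and 0 <= self.c0 < self.c1):
            raise ParameterError(
                f"ROI must satisfy 0 <= r0 < r1 and 0 <= c0 < c1, got "
                f"[{self.r0},{self.r1}) x [{self.c0},{self.c1})"
            )

    def check_within(self, rows: int, cols: int) -> None:
        if self.r1 > rows or self.c1 > cols:
            raise ParameterError(
                f"ROI [{self.r0},{self.r1}) x [{self.c0},{self.c1}) exceeds "
                f"raster {rows} x {cols}"
            )


@dataclass
class ClusterModel:
    """A fitted k-means model over pixel spectra."""

    k: int
    centroids: np.ndarray          # k x bands
    labels: np.ndarray             # n, values in [0, k)
    inertia: float                 # total within-cluster sum of squares
    seed: int
    n_iter: int
    inertia_history: np.ndarray    # recorded per assignment step


@dataclass
class WoundMask:
    """Binary wound raster sharing its source cube's geometry."""

    mask: np.ndarray
    pixel_pitch_cm: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DimensionError("mask must be 2-D")
        if self.pixel_pitch_cm <= 0:
            raise ParameterError("pixel_pitch_cm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def pixel_count(self) -> int:
        return int(self.mask.sum())


def extract_roi(cube: SpectralCube, roi: RegionOfInterest) -> SpectralCube:
    """Crop the cube to the ROI; pitch and grid are unchanged."""
    roi.check_within(cube.rows, cube.cols)
    sub = cube.values[roi.r0:roi.r1, roi.c0:roi.c1, :].copy()
    return SpectralCube(sub, cube.grid, cube.pixel_pitch_cm, cube.calibrated)


# ---------------------------------------------------------------------------
# k-means (Lloyd's algorithm with k-means++ seeding and restarts)
# ---------------------------------------------------------------------------

def _squared_distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; clip tiny negatives from
    # cancellation so argmin/sqrt stay safe
    d2 = (
        np.einsum("ij,ij->i", points, points)[:, None]
        - 2.0 * points @ centroids.T
        + np.einsum("ij,ij->i", centroids, centroids)[None, :]
    )
    return np.maximum(d2, 0.0)


def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first centre uniform, then proportional to D^2."""
    n = points.shape[0]
    centroids = np.empty((k, points.shape[1]))
    idx = int(rng.integers(n))
    centroids[0] = points[idx]
    d2 = _squared_distances(points, centroids[:1])[:, 0]
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))  # all remaining points coincide
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centroids[j] = points[idx]
        d2 = np.minimum(d2, _squared_distances(points, centroids[j:j + 1])[:, 0])
    return centroids


def _lloyd(points: np.ndarray, init: np.ndarray, max_iter: int,
           tol: float) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    k = init.shape[0]
    centroids = init.copy()
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = _squared_distances(points, centroids)
        labels = np.argmin(d2, axis=1)
        # empty-cluster rule: re-seed at the point currently farthest from
        # its own centroid (never silently drop a cluster)
        counts = np.bincount(labels, minlength=k)
        if np.any(counts == 0):
            assigned = d2[np.arange(points.shape[0]), labels]
            order = np.argsort(assigned)[::-1]
            cursor = 0
            for j in np.nonzero(counts == 0)[0]:
                idx = int(order[cursor])
                cursor += 1
                centroids[j] = points[idx]
                labels[idx] = j
            d2 = _squared_distances(points, centroids)
            labels = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(points.shape[0]), labels].sum()))
        new_centroids = np.empty_like(centroids)
        for j in range(k):
            new_centroids[j] = points[labels == j].mean(axis=0)
        shift = float(np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max())
        centroids = new_centroids
        if shift < tol:
            break
    # final consistent state: labels under final centroids, then centroids
    # as the exact means of those labels (both steps are non-increasing)
    d2 = _squared_distances(points, centroids)
    labels = np.argmin(d2, axis=1)
    for j in range(k):
        members = points[labels == j]
        if members.shape[0]:
            centroids[j] = members.mean(axis=0)
    d2 = _squared_distances(points, centroids)
    inertia = float(d2[np.arange(points.shape[0]), labels].sum())
    history.append(inertia)
    return centroids, labels, inertia, n_iter, history


def kmeans_fit(
    spectra: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    normalize: bool = False,
) -> ClusterModel:
    """Fit k-means to pixel spectra: Lloyd iterations from k-means++ starts,
    best of ``restarts`` runs by inertia; fully deterministic given ``seed``.

    ``normalize`` divides each spectrum by its own mean first (brightness
    removal), which makes the partition invariant to global positive scaling.
    """
    points = np.asarray(spectra, dtype=np.float64)
    if points.ndim != 2:
        raise DimensionError("spectra must be n x bands")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if restarts < 1:
        raise ParameterError("restarts must be >= 1")
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise SegmentationError(
            f"k={k} exceeds the {n_distinct} distinct spectra available"
        )
    if normalize:
        means = points.mean(axis=1, keepdims=True)
        if np.any(means <= 0):
            raise SegmentationError(
                "mean normalization undefined for non-positive spectra"
            )
        points = points / means

    root = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(restarts):
        rng = np.random.default_rng(root.integers(2**31))
        init = _kmeans_pp_init(points, k, rng)
        centroids, labels, inertia, n_iter, history = _lloyd(
            points, init, max_iter, tol
        )
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia, n_iter, history)
    centroids, labels, inertia, n_iter, history = best
    return ClusterModel(
        k=k,
        centroids=centroids,
        labels=labels,
        inertia=inertia,
        seed=seed,
        n_iter=n_iter,
        inertia_history=np.asarray(history),
    )


# ---------------------------------------------------------------------------
# Wound-cluster selection and mask construction
# ---------------------------------------------------------------------------

def hemoglobin_dip_ratio(spectrum: np.ndarray, grid: WavelengthGrid) -> float:
    """mean reflectance over 534-586 nm divided by mean over 600-630 nm.

    Low values mean strong oxy-hemoglobin absorption relative to the red
    end — the spectral signature of wound tissue.
    """
    num_idx = grid.band_indices(*HEMOGLOBIN_BAND_NM)
    den_idx = grid.band_indices(*REFERENCE_BAND_NM)
    if num_idx.size == 0 or den_idx.size == 0:
        raise SegmentationError(
            "grid has no bands inside the hemoglobin/reference windows"
        )
    num = float(np.mean(np.asarray(spectrum)[num_idx]))
    den = float(np.mean(np.asarray(spectrum)[den_idx]))
    return num / max(den, 1e-12)


def select_wound_cluster(
    model: ClusterModel,
    grid: WavelengthGrid,
    rule: str = "hemoglobin-dip",
) -> int:
    """Pick the wound cluster from a fitted model.

    ``hemoglobin-dip`` (default): minimal 534-586/600-630 nm centroid ratio.
    ``darkest``: minimal overall mean centroid reflectance.
    """
    if model.k < 2:
        raise SegmentationError("wound selection needs k >= 2 clusters")
    if rule == "hemoglobin-dip":
        scores = [hemoglobin_dip_ratio(c, grid) for c in model.centroids]
    elif rule == "darkest":
        scores = [float(np.mean(c)) for c in model.centroids]
    else:
        raise ParameterError(f"unknown selection rule {rule!r}")
    return int(np.argmin(scores))


def labels_to_mask(
    labels: np.ndarray,
    shape: tuple[int, int],
    wound_index: int,
    pitch_cm: float,
) -> WoundMask:
    """Binary mask true where the pixel label equals the wound cluster."""
    labels = np.asarray(labels)
    rows, cols = shape
    if labels.size != rows * cols:
        raise DimensionError(
            f"{labels.size} labels cannot fill a {rows} x {cols} raster"
        )
    k = int(labels.max()) + 1 if labels.size else 0
    if not (0 <= wound_index < max(k, 1)):
        raise ParameterError(f"wound_index {wound_index} outside [0, {k})")
    return WoundMask(labels.reshape(rows, cols) == wound_index, pitch_cm)


def segment_cube(
    cube: SpectralCube,
    k: int = 2,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    rule: str = "hemoglobin-dip",
    normalize: bool = False,
) -> tuple[WoundMask, ClusterModel, int]:
    """Cluster a (typically ROI-cropped) cube and return the wound mask."""
    model = kmeans_fit(
        cube.spectra(), k, seed=seed, restarts=restarts,
        max_iter=max_iter, tol=tol, normalize=normalize,
    )
    wound_idx = select_wound_cluster(model, cube.grid, rule)
    mask = labels_to_mask(
        model.labels, (cube.rows, cube.cols), wound_idx, cube.pixel_pitch_cm
    )
    return mask, model, wound_idx
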