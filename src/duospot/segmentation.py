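"""Nucleus and cell segmentation.

ROIs are detected on the binned nuclear image; nuclei are segmented at full
resolution in two intensity passes (bright nuclei first, dim nuclei on the
remaining area); cells are obtained by expanding each nucleus by a budget
that depends on its area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk
from skimage.segmentation import watershed

__all__ = [
    "RoiBox",
    "NucleusParams",
    "CellLabelMap",
    "li_threshold",
    "adaptive_mask",
    "detect_rois",
    "segment_nuclei",
    "expand_cells",
    "AREA_CUTOFF",
    "EXPAND_SMALL",
    "EXPAND_LARGE",
]

log = logging.getLogger(__name__)

#: Nucleus-area cutoff (px^2) selecting the expansion budget.  Areas >= cutoff
#: take the large budget (ties go to the larger cell).
AREA_CUTOFF = 2800
EXPAND_SMALL = 12
EXPAND_LARGE = 32


@dataclass
class RoiBox:
    """A full-resolution bounding box around one nucleus region.

    ``roi_mask`` marks this ROI's own nuclei inside the box, so that nuclei of
    neighboring ROIs falling into an overlapping box can be masked out.
    """

    bounds: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    roi_mask: np.ndarray
    roi_id: int = 0

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bounds
        if self.roi_mask.shape != (r1 - r0, c1 - c0):
            raise ValueError("roi_mask shape must equal the bounds extent")

    def crop(self, image: np.ndarray) -> np.ndarray:
        r0, c0, r1, c1 = self.bounds
        return image[r0:r1, c0:c1]


@dataclass
class CellLabelMap:
    labels: np.ndarray  # per-pixel cell id; 0 = background
    expansion_px: dict[int, int] = field(default_factory=dict)


def li_threshold(image: np.ndarray) -> float:
    """Minimum cross-entropy (Li) threshold by exhaustive candidate search.

    Every distinct intensity value is tested as a threshold; foreground is
    ``image > t``.  The selected threshold minimizes

        eta(t) = -[ S_b(t) * log(mu_b(t)) + S_f(t) * log(mu_f(t)) ]

    where ``S`` and ``mu`` are the intensity sum and mean on either side
    (terms with zero intensity mass contribute nothing).  The returned value
    is the midpoint between the optimal candidate and the next intensity
    level (same partition, threshold strictly between the classes).  A
    constant image returns that constant, which leaves the foreground empty.
    """
    values = np.asarray(image, float).ravel()
    if values.size == 0:
        raise ValueError("empty image")
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size == 1:
        return float(uniq[0])

    weighted = uniq * counts
    csum_n = np.cumsum(counts)
    csum_s = np.cumsum(weighted)
    total_n, total_s = csum_n[-1], csum_s[-1]

    # candidate thresholds: every unique value except the maximum (which
    # would empty the foreground)
    nb, sb = csum_n[:-1], csum_s[:-1]
    nf, sf = total_n - nb, total_s - sb

    with np.errstate(divide="ignore", invalid="ignore"):
        term_b = np.where(sb > 0, sb * np.log(sb / nb), 0.0)
        term_f = np.where(sf > 0, sf * np.log(sf / nf), 0.0)
    eta = -(term_b + term_f)
    best = int(np.argmin(eta))
    return float((uniq[best] + uniq[best + 1]) / 2)


def adaptive_mask(
    image: np.ndarray,
    window: int = 64,
    correction: float = 1.0,
    lower_bound: float = 0.0,
) -> np.ndarray:
    """Adaptive minimum cross-entropy mask.

    Li thresholds are computed on a grid of ``window``-sized tiles, bilinearly
    interpolated to a per-pixel threshold surface, multiplied by
    ``correction`` and floored at ``lower_bound``.  Mask = image > threshold.
    """
    img = np.asarray(image, float)
    if window < 8:
        raise ValueError("adaptive window must be >= 8 px")
    h, w = img.shape
    if window >= h or window >= w:
        log.info("adaptive window %d exceeds image %s; using global threshold", window, img.shape)
        thr = max(li_threshold(img) * correction, lower_bound)
        return img > thr

    ny, nx = int(np.ceil(h / window)), int(np.ceil(w / window))
    tile_thr = np.empty((ny, nx))
    centers_y = np.empty(ny)
    centers_x = np.empty(nx)
    for i in range(ny):
        r0, r1 = i * window, min((i + 1) * window, h)
        centers_y[i] = (r0 + r1 - 1) / 2
        for j in range(nx):
            c0, c1 = j * window, min((j + 1) * window, w)
            centers_x[j] = (c0 + c1 - 1) / 2
            tile_thr[i, j] = li_threshold(img[r0:r1, c0:c1])

    # bilinear interpolation of tile thresholds to pixel resolution, with
    # edge clamping outside the outermost tile centers
    yy = np.interp(np.arange(h), centers_y, np.arange(ny))
    xx = np.interp(np.arange(w), centers_x, np.arange(nx))
    coords = np.meshgrid(yy, xx, indexing="ij")
    surface = ndi.map_coordinates(tile_thr, coords, order=1, mode="nearest")
    surface = np.maximum(surface * correction, lower_bound)
    return img > surface


def detect_rois(
    binned_dapi: np.ndarray,
    bin_factor: int = 8,
    margin: int = 40,
    min_area_binned: int = 4,
    full_shape: tuple[int, int] | None = None,
) -> list[RoiBox]:
    """Detect nucleus-occupied ROIs on the binned nuclear image.

    Bounding boxes are scaled to full resolution and padded by ``margin`` px;
    boxes may overlap, but each ROI's mask covers only its own nuclei.
    """
    binned = np.asarray(binned_dapi, float)
    if full_shape is None:
        full_shape = (binned.shape[0] * bin_factor, binned.shape[1] * bin_factor)
    if np.ptp(binned) == 0:
        return []
    thr = li_threshold(binned)
    mask = binned > thr
    if not mask.any():
        return []
    labels, n = ndi.label(mask)
    rois: list[RoiBox] = []
    for region_id, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        region = labels[sl] == region_id
        if region.sum() < min_area_binned:
            continue
        r0 = max(sl[0].start * bin_factor - margin, 0)
        c0 = max(sl[1].start * bin_factor - margin, 0)
        r1 = min(sl[0].stop * bin_factor + margin, full_shape[0])
        c1 = min(sl[1].stop * bin_factor + margin, full_shape[1])

        own = ndi.binary_dilation(labels == region_id, structure=np.ones((3, 3)))
        full_mask = np.zeros(full_shape, bool)
        fr1 = min(own.shape[0] * bin_factor, full_shape[0])
        fc1 = min(own.shape[1] * bin_factor, full_shape[1])
        full_mask[:fr1, :fc1] = np.kron(own, np.ones((bin_factor, bin_factor), bool))[
            :fr1, :fc1
        ]
        rois.append(
            RoiBox(bounds=(r0, c0, r1, c1), roi_mask=full_mask[r0:r1, c0:c1], roi_id=len(rois) + 1)
        )
    return rois


@dataclass
class NucleusParams:
    """Tunable nucleus-detection parameters (mirrors per-sample manual tuning)."""

    min_diameter: float = 8.0
    max_diameter: float = 100.0
    lower_bound_high: float = 0.0
    lower_bound_low: float = 0.0
    correction_high: float = 1.0
    correction_low: float = 1.0
    smoothing_sigma: float = 2.0
    declump_min_distance: int = 10


def _label_pass(
    smoothed: np.ndarray, mask: np.ndarray, params: NucleusParams
) -> np.ndarray:
    """Label a binary nucleus mask with intensity-seeded watershed declumping."""
    if not mask.any():
        return np.zeros(mask.shape, np.int32)
    mask = ndi.binary_fill_holes(mask)
    coords = peak_local_max(
        np.where(mask, smoothed, 0.0),
        min_distance=params.declump_min_distance,
        labels=ndi.label(mask)[0],
        num_peaks_per_label=4,
    )
    if len(coords) == 0:
        return ndi.label(mask)[0].astype(np.int32)
    seeds = np.zeros(mask.shape, np.int32)
    seeds[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    dist = ndi.distance_transform_edt(mask)
    labels = watershed(-dist, seeds, mask=mask)

    min_area = np.pi * (params.min_diameter / 2) ** 2
    max_area = np.pi * (params.max_diameter / 2) ** 2
    out = np.zeros_like(labels, np.int32)
    next_id = 1
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        area = region.sum()
        if min_area <= area <= max_area:
            out[region] = next_id
            next_id += 1
    return out


def segment_nuclei(dapi: np.ndarray, params: NucleusParams | None = None) -> np.ndarray:
    """Two-pass nucleus segmentation on a (ROI-masked) nuclear image.

    Pass 1 picks up high-intensity nuclei; pass 2 re-thresholds the remaining
    area to recover dim nuclei.  Pass-2 objects overlapping pass-1 objects are
    discarded; the union is relabeled consecutively.
    """
    params = params or NucleusParams()
    img = np.asarray(dapi, float)
    smoothed = ndi.gaussian_filter(img, params.smoothing_sigma)

    thr1 = max(li_threshold(smoothed) * params.correction_high, params.lower_bound_high)
    labels1 = _label_pass(smoothed, smoothed > thr1, params)

    taken = ndi.binary_dilation(labels1 > 0, structure=disk(3))
    remaining = np.where(taken, 0.0, smoothed)
    if np.ptp(remaining) > 0:
        thr2 = max(li_threshold(remaining) * params.correction_low, params.lower_bound_low)
        mask2 = (remaining > thr2) & ~taken
        labels2 = _label_pass(smoothed, mask2, params)
        # drop pass-2 objects touching pass-1 objects
        overlap_ids = np.unique(labels2[taken & (labels2 > 0)])
        for lab in overlap_ids:
            labels2[labels2 == lab] = 0
    else:
        labels2 = np.zeros_like(labels1)

    combined = labels1.copy()
    offset = labels1.max()
    nz = labels2 > 0
    combined[nz] = labels2[nz] + offset
    # relabel consecutively, ordered by (row, col) of first pixel
    out = np.zeros_like(combined)
    for new_id, lab in enumerate(np.unique(combined[combined > 0]), start=1):
        out[combined == lab] = new_id
    return out


def expand_cells(
    nuclei: np.ndarray,
    area_cutoff: int = AREA_CUTOFF,
    expand_small: int = EXPAND_SMALL,
    expand_large: int = EXPAND_LARGE,
) -> CellLabelMap:
    """Expand each nucleus into a cell region by an area-conditional budget.

    Nuclei with area < ``area_cutoff`` px^2 expand by ``expand_small`` px,
    others by ``expand_large`` px.  Contested pixels go to the nucleus with
    the nearest boundary; cell regions stay disjoint and contain their nuclei.
    """
    labels = np.asarray(nuclei)
    if labels.max() == 0:
        return CellLabelMap(labels=labels.astype(np.int32), expansion_px={})

    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, labels.max() + 1))
    budget = {
        lab + 1: (expand_small if area < area_cutoff else expand_large)
        for lab, area in enumerate(areas)
        if area > 0
    }

    dist, (iy, ix) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    nearest = labels[iy, ix]
    budget_arr = np.zeros(labels.max() + 1)
    for lab, b in budget.items():
        budget_arr[lab] = b
    cells = np.where((labels > 0) | (dist <= budget_arr[nearest]), nearest, 0)
    return CellLabelMap(labels=cells.astype(np.int32), expansion_px=budget)
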