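"""Morphology-based segmentation of the time-averaged image into ROIs.

Two labeling regimes are supported. With nucleus-localized reporters
(``labeled_nuclei``) cells appear as uniformly filled bright disks and are
found by thresholding the locally normalized image and splitting touching
cells with a distance-transform watershed. With cytosolic, nucleus-excluded
reporters (``unlabeled_nuclei``) cells appear as bright rings around a dark
nucleus; somata are seeded from dark regional centers enclosed by bright
cytosol and grown to the surrounding ring.

A hexagonal-grid fallback covers datasets without single-neuron resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import perimeter as _perimeter
from skimage.segmentation import watershed

from capop.core_model import ROIMap


@dataclass
class SegmentationParams:
    """Parameters of the two-threshold morphological segmentation.

    ``thr_soma`` is the cell-center threshold and ``thr_neuropil`` the
    neuropil-border threshold, both on the normalized [0, 1] image. In
    ``labeled_nuclei`` mode bright regions above ``thr_soma`` seed cells and
    pixels below ``thr_neuropil`` are excluded from the final ROIs; in
    ``unlabeled_nuclei`` mode dark regions below ``thr_soma`` seed nuclei
    and the ROI is the surrounding cytosol above ``thr_neuropil``.

    ``roi_size_opt`` selects the morphological seeding scale: the expected
    cell radius is 6 μm for ``"bigger"`` and 3 μm for ``"smaller"``.
    """

    mode: str = "labeled_nuclei"
    roi_size_opt: str = "bigger"
    local_contrast: float = 20.0
    thr_soma: float = 0.1
    thr_neuropil: float = 0.45
    area_min: float = 0.0
    area_max: float = np.inf
    intensity_min: float = 0.0
    circ_min: float = 0.0
    circ_max: float = np.inf

    def __post_init__(self) -> None:
        if self.mode not in ("labeled_nuclei", "unlabeled_nuclei"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.roi_size_opt not in ("bigger", "smaller"):
            raise ValueError(f"unknown roi_size_opt {self.roi_size_opt!r}")
        if not (0 <= self.thr_soma <= 1 and 0 <= self.thr_neuropil <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.area_min > self.area_max:
            raise ValueError("area_min must not exceed area_max")
        if self.circ_min > self.circ_max:
            raise ValueError("circ_min must not exceed circ_max")

    @property
    def cell_radius_um(self) -> float:
        return 6.0 if self.roi_size_opt == "bigger" else 3.0


def normalize_contrast(image: np.ndarray, local_contrast: float = 20.0) -> np.ndarray:
    """Spatially normalize an image to [0, 1] by local background and range.

    Output is ``(image − local min) / (local range + ε)`` over a moving
    window of ``local_contrast`` pixels, clipped to [0, 1]. The regularizer
    ε = 0.05·(global 99th−1st percentile range) keeps structure-free noise
    regions dark while preserving invariance to global affine intensity
    changes (``a·image + b`` normalizes identically for a > 0).
    """
    image = np.asarray(image, dtype=float)
    if local_contrast < 3:
        raise ValueError("local_contrast must be >= 3 pixels")
    p1, p99 = np.percentile(image, [1, 99])
    if np.ptp(image) == 0:
        warnings.warn("constant image: normalized output is all 0.5")
        return np.full_like(image, 0.5)
    size = int(round(local_contrast))
    lmin = ndimage.minimum_filter(image, size=size, mode="nearest")
    lmax = ndimage.maximum_filter(image, size=size, mode="nearest")
    eps = 0.05 * (p99 - p1)
    if eps == 0:
        eps = 0.05 * np.ptp(image)
    return np.clip((image - lmin) / (lmax - lmin + eps), 0.0, 1.0)


def _rois_from_labels(labels: np.ndarray, keep: np.ndarray | None = None) -> list:
    out = []
    for lab in range(1, labels.max() + 1):
        px = np.argwhere(labels == lab if keep is None else (labels == lab) & keep)
        if len(px):
            out.append(px)
    return out


def detect_rois(norm: np.ndarray, p: SegmentationParams,
                pixel_size: float = 1.0) -> ROIMap:
    """Detect single-cell ROIs on a normalized image.

    Returns an :class:`ROIMap` with pairwise-disjoint ROIs; an empty map
    (with a warning) when nothing is found.
    """
    norm = np.asarray(norm, dtype=float)
    scale = max(p.cell_radius_um / pixel_size, 1.0)
    smooth = ndimage.gaussian_filter(norm, sigma=1.0)

    if p.mode == "labeled_nuclei":
        rois = _detect_disks(smooth, p, scale)
    else:
        rois = _detect_rings(smooth, p, scale)
    if not rois:
        warnings.warn("no ROIs detected")
        return _empty_roimap()
    return ROIMap(rois=rois)


def _empty_roimap() -> ROIMap:
    rm = ROIMap.__new__(ROIMap)
    rm.rois = []
    rm.planes = np.empty(0, dtype=np.intp)
    rm.labels = []
    return rm


def _detect_disks(smooth: np.ndarray, p: SegmentationParams, scale: float) -> list:
    mask = smooth > p.thr_soma
    if not mask.any():
        return []
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=max(int(round(scale)), 1),
                           labels=mask, exclude_border=False)
    if len(peaks) == 0:
        return []
    markers = np.zeros_like(smooth, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask)
    bright = smooth >= p.thr_neuropil
    return _rois_from_labels(labels, keep=bright)


def _detect_rings(smooth: np.ndarray, p: SegmentationParams, scale: float) -> list:
    dark = smooth <= p.thr_soma
    lab, n_lab = ndimage.label(dark)
    if n_lab == 0:
        return []
    bright = smooth > p.thr_neuropil
    max_nucleus_area = np.pi * (1.2 * scale) ** 2
    w = max(int(round(scale)), 1)
    struct = _disk_structure(w)
    claimed = np.zeros_like(dark, dtype=bool)
    rois = []
    objects = ndimage.find_objects(lab)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp_area = int((lab[sl] == i).sum())
        if comp_area < 3 or comp_area > max_nucleus_area:
            continue
        # pad the bounding box so dilation has room
        r0 = max(sl[0].start - w - 1, 0)
        r1 = min(sl[0].stop + w + 1, dark.shape[0])
        c0 = max(sl[1].start - w - 1, 0)
        c1 = min(sl[1].stop + w + 1, dark.shape[1])
        sub = lab[r0:r1, c0:c1] == i
        dil = ndimage.binary_dilation(sub, structure=struct)
        ring = dil & ~sub
        n_ring = ring.sum()
        if n_ring == 0:
            continue
        frac_bright = bright[r0:r1, c0:c1][ring].mean()
        if frac_bright < 0.4:  # dark region not enclosed by cytosol
            continue
        roi_mask = dil & bright[r0:r1, c0:c1] & ~claimed[r0:r1, c0:c1]
        px = np.argwhere(roi_mask)
        if len(px) == 0:
            continue
        px = px + np.array([r0, c0])
        claimed[px[:, 0], px[:, 1]] = True
        rois.append(px)
    return rois


def _disk_structure(radius: int) -> np.ndarray:
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return rr ** 2 + cc ** 2 <= radius ** 2


def roi_circularity(roi: np.ndarray) -> float:
    """Perimeter circularity P²/(4πA): 1 for a circle, larger when irregular."""
    r0, c0 = roi.min(axis=0)
    r1, c1 = roi.max(axis=0)
    mask = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=bool)
    mask[roi[:, 0] - r0 + 1, roi[:, 1] - c0 + 1] = True
    per = _perimeter(mask)
    area = len(roi)
    return float(per ** 2 / (4 * np.pi * area)) if area else np.inf


def filter_rois(rois: ROIMap, norm: np.ndarray, p: SegmentationParams) -> ROIMap:
    """Keep ROIs passing the area, mean-intensity, and circularity criteria."""
    kept, planes, labels = [], [], []
    for i in range(len(rois)):
        px = rois.rois[i]
        area = len(px)
        if not (p.area_min <= area <= p.area_max):
            continue
        if norm[px[:, 0], px[:, 1]].mean() < p.intensity_min:
            continue
        circ = roi_circularity(px)
        if not (p.circ_min <= circ <= p.circ_max):
            continue
        kept.append(px)
        planes.append(rois.planes[i])
        labels.append(rois.labels[i])
    if not kept:
        return _empty_roimap()
    return ROIMap(rois=kept, planes=np.array(planes, dtype=np.intp), labels=labels)


def hexagonal_grid(shape: tuple, diameter: float, pixel_size: float,
                   mask: np.ndarray | None = None) -> ROIMap:
    """Tile the field with pointy-top hexagonal ROIs of the given diameter.

    ``diameter`` (μm) is the vertex-to-vertex width; every pixel belongs to
    exactly one hexagonal cell of the plane tiling. Hexagons clipped by the
    mask (or field border) are retained only if they keep at least 50% of
    the nominal hexagon area.
    """
    s = (diameter / pixel_size) / 2.0  # circumradius in pixels
    if 2 * s < 2:
        raise ValueError("hexagon diameter must span at least 2 pixels")
    rows, cols = shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(shape):
            raise ValueError("mask shape must match field shape")
        if not mask.any():
            return _empty_roimap()
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    # axial coordinates of the hexagonal lattice (pointy-top)
    q = (np.sqrt(3) / 3 * xx - 1.0 / 3 * yy) / s
    r = (2.0 / 3 * yy) / s
    qi, ri = _cube_round(q, r)
    nominal_area = 3 * np.sqrt(3) / 2 * s ** 2
    key = qi * 100000 + ri  # unique integer per hexagon (qi, ri bounded)
    if mask is not None:
        key = np.where(mask, key, np.iinfo(np.int64).min)
    flat = key.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_keys = flat[order]
    uniq, starts = np.unique(sorted_keys, return_index=True)
    rois = []
    hex_ids = []
    for u, st, en in zip(uniq, starts, np.r_[starts[1:], len(flat)]):
        if u == np.iinfo(np.int64).min:
            continue
        idx = order[st:en]
        if len(idx) < 0.5 * nominal_area:
            continue
        px = np.column_stack(np.unravel_index(idx, (rows, cols))).astype(np.intp)
        rois.append(px)
        hex_ids.append(u)
    if not rois:
        return _empty_roimap()
    # stable order: top-to-bottom, left-to-right by centroid
    cent = np.array([p.mean(axis=0) for p in rois])
    order2 = np.lexsort((cent[:, 1], cent[:, 0]))
    return ROIMap(rois=[rois[i] for i in order2])


def _cube_round(q: np.ndarray, r: np.ndarray) -> tuple:
    """Round fractional axial hex coordinates to the containing hexagon."""
    x, z = q, r
    y = -x - z
    rx, ry, rz = np.round(x), np.round(y), np.round(z)
    dx, dy, dz = np.abs(rx - x), np.abs(ry - y), np.abs(rz - z)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(np.int64), rz.astype(np.int64)


def modify_rois(rois: ROIMap, add: list | None = None,
                remove: list | None = None) -> ROIMap:
    """Programmatic ROI curation: apply removals, then additions.

    Added pixel sets must be disjoint from every kept ROI (in plane 0 /
    their declared plane); violations raise ``ValueError`` naming the
    overlapped ROI.
    """
    remove = set(remove or [])
    add = add or []
    kept_idx = [i for i in range(len(rois)) if i not in remove]
    kept = [rois.rois[i] for i in kept_idx]
    planes = [rois.planes[i] for i in kept_idx]
    labels = [rois.labels[i] for i in kept_idx]
    occupied = {}
    for j, (px, pl) in enumerate(zip(kept, planes)):
        for t in map(tuple, px):
            occupied[(pl, t)] = j
    for new in add:
        new = np.atleast_2d(np.asarray(new, dtype=np.intp))
        for t in map(tuple, new):
            hit = occupied.get((0, t))
            if hit is not None:
                raise ValueError(
                    f"added ROI overlaps existing ROI {kept_idx[hit]} at pixel {t}")
        kept.append(new)
        planes.append(0)
        labels.append("")
        kept_idx.append(-1)
        for t in map(tuple, new):
            occupied[(0, t)] = len(kept) - 1
    if not kept:
        return _empty_roimap()
    return ROIMap(rois=kept, planes=np.array(planes, dtype=np.intp), labels=labels)
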