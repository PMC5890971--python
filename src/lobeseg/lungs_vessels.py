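"""Left/right lung masks and vessel segmentation with iterative lobar assignment.

Lungs are thresholded (fixed -400 HU on inspiration; Otsu on expiration,
where parenchyma density approaches soft tissue), the airway lumen is
removed, and the two largest components become the lung halves (split by
repeated erosion if fused).  Vessels are thresholded per CT at the 96th
HU percentile within the lung (floored at -500 HU) and grouped into
26-connected objects which are then assigned to lobes by distance to the
lobar bronchial structures, splitting ambiguous objects by erosion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .airways import AirwayGraph
from .core_io import ALL_CODES, BinaryMask, CTVolume, assert_same_grid
from .errors import EmptyInputError, SegmentationFailureError

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VesselObjects:
    """26-connected vessel components with per-component lobar assignments."""

    labels: np.ndarray  # int32 component label volume, 0 = background
    spacing: tuple[float, float, float]
    assignment: dict[int, int] = field(default_factory=dict)  # component -> lobe code
    erosion_loss_voxels: int = 0

    @property
    def shape(self):
        return self.labels.shape

    def component_ids(self) -> list[int]:
        return [int(i) for i in np.unique(self.labels) if i != 0]

    def assigned_mask(self, code: int) -> np.ndarray:
        comps = [c for c, k in self.assignment.items() if k == code]
        return np.isin(self.labels, comps)

    def vessel_mask(self) -> np.ndarray:
        return self.labels > 0


def segment_lungs(ct: CTVolume, airway: BinaryMask,
                  min_component_frac: float = 0.02) -> tuple[BinaryMask, BinaryMask]:
    """Segment the left and right lung fields.

    Returns ``(left, right)`` masks (left = larger x centroid).  Fused
    lungs are split by repeated erosion followed by seeded dilation inside
    the original mask; vessel-sized holes are closed morphologically.
    """
    assert_same_grid(ct, airway)
    arr = ct.voxels
    if ct.phase == "insp":
        thr = -400.0
    else:
        # expiratory parenchyma can approach soft tissue; adapt per scan
        thr = float(threshold_otsu(arr.astype(np.float32)))
    cand = arr < thr
    cand &= ~ndimage.binary_dilation(airway.mask, structure=_STRUCT26)

    lab, n = ndimage.label(cand, structure=_STRUCT26)
    if n == 0:
        raise SegmentationFailureError("no candidate lung voxels below threshold")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    min_vox = int(min_component_frac * arr.size)
    big = [i for i in np.argsort(counts)[::-1] if counts[i] >= min_vox][:2]
    if not big:
        raise SegmentationFailureError(
            f"no lung-sized component (>= {min_component_frac:.0%} of grid)"
        )

    if len(big) == 2:
        halves = [lab == big[0], lab == big[1]]
    else:
        halves = _split_fused(lab == big[0])

    halves = [_tidy(h) & ~airway.mask for h in halves]  # closing must not re-add lumen
    if len(halves) == 1:  # could not split: lateral halves of the single mask
        m = halves[0]
        xs = np.nonzero(m.any(axis=(0, 1)))[0]
        xmid = (xs.min() + xs.max()) // 2
        a = m.copy(); a[:, :, xmid:] = False
        b = m.copy(); b[:, :, :xmid] = False
        halves = [a, b]

    cx = [np.argwhere(h)[:, 2].mean() for h in halves]
    left = halves[int(np.argmax(cx))]
    right = halves[int(np.argmin(cx))]
    overlap = left & right
    if overlap.any():  # closing may re-fuse along the mediastinum; keep disjoint
        left &= ~overlap
        right &= ~overlap
    return (BinaryMask(left, ct.spacing, ct.origin),
            BinaryMask(right, ct.spacing, ct.origin))


def _split_fused(mask: np.ndarray, max_iter: int = 10) -> list[np.ndarray]:
    """Split a fused lung mask by erosion until two large pieces emerge,
    then recover each by seeded dilation within the original mask."""
    xs = np.nonzero(mask.any(axis=(0, 1)))[0]
    spans_both = xs.min() < mask.shape[2] // 2 < xs.max()
    if not spans_both:
        return [mask]
    eroded = mask
    for _ in range(max_iter):
        eroded = ndimage.binary_erosion(eroded, structure=_STRUCT26)
        lab, n = ndimage.label(eroded, structure=_STRUCT26)
        if n < 2 or not eroded.any():
            continue
        counts = np.bincount(lab.ravel()); counts[0] = 0
        order = np.argsort(counts)[::-1][:2]
        if counts[order[1]] < 0.1 * counts[order[0]]:
            continue
        seeds = np.where(lab == order[0], 1, 0) + np.where(lab == order[1], 2, 0)
        # watershed-like recovery: nearest seed within the original mask
        _, idx = ndimage.distance_transform_edt(seeds == 0, return_indices=True)
        recovered = seeds[idx[0], idx[1], idx[2]]
        recovered[~mask] = 0
        return [recovered == 1, recovered == 2]
    log.warning("erosion-split failed to separate fused lungs")
    return [mask]


def _tidy(mask: np.ndarray) -> np.ndarray:
    """Close vessel-sized holes (radius-2 closing + 3-D hole filling).

    Closing additions are kept only inside the filled silhouette so the
    partial-volume rim at the pleural surface (whose HU mimics vessels)
    is never padded onto the mask."""
    closed = ndimage.binary_closing(mask, structure=ball(2), iterations=1)
    filled = ndimage.binary_fill_holes(closed)
    cube = ndimage.generate_binary_structure(3, 3)
    outer_band = filled & ~ndimage.binary_erosion(filled, structure=cube,
                                                  iterations=1, border_value=0)
    return mask | (filled & ~outer_band)


def segment_vessels(ct: CTVolume, lung: BinaryMask, percentile: float = 96.0,
                    floor_hu: float = -500.0, min_voxels: int = 5) -> VesselObjects:
    """Threshold-based vessel segmentation with a per-CT adjusted threshold.

    The threshold is the ``percentile`` of HU within the lung mask, floored
    at ``floor_hu``; components smaller than ``min_voxels`` are dropped.
    All components start unassigned.
    """
    assert_same_grid(ct, lung)
    if not lung.mask.any():
        raise EmptyInputError("empty lung mask")
    inside = ct.voxels[lung.mask]
    thr = max(float(np.percentile(inside, percentile)), floor_hu)
    vess = lung.mask & (ct.voxels > thr)
    lab, n = ndimage.label(vess, structure=_STRUCT26)
    if n:
        counts = np.bincount(lab.ravel())
        small = np.nonzero(counts < min_voxels)[0]
        lab[np.isin(lab, small)] = 0
        # relabel compactly
        lab, _ = ndimage.label(lab > 0, structure=_STRUCT26)
    return VesselObjects(lab.astype(np.int32), ct.spacing)


def assign_vessels_to_lobes(vessels: VesselObjects, graph: AirwayGraph,
                            hulls: dict[int, BinaryMask], max_rounds: int = 5,
                            ambiguity_ratio: float = 0.5) -> VesselObjects:
    """Iteratively assign vessel objects to lobes by distance rules.

    Per round, each unassigned component measures its minimum distance (mm)
    to every lobe's hull and labeled bronchial voxels; it is assigned to
    the nearest lobe when ``d_min / d_second <= ambiguity_ratio``,
    otherwise it is eroded by one voxel and split for the next round.
    Components that erode away or stay ambiguous remain unassigned.
    """
    spacing = np.asarray(vessels.spacing, float)
    centerlines = graph.labeled_centerline_voxels()
    trees: dict[int, cKDTree] = {}
    for code in ALL_CODES:
        pts = []
        if code in hulls and hulls[code].mask.any():
            pts.append(np.argwhere(hulls[code].mask))
        if code in centerlines:
            pts.append(centerlines[code])
        if pts:
            trees[code] = cKDTree(np.concatenate(pts, axis=0) * spacing)
    if not trees:
        return vessels

    labels = vessels.labels.copy()
    assignment: dict[int, int] = {}
    next_id = int(labels.max()) + 1
    loss = 0
    active = [int(i) for i in np.unique(labels) if i != 0]
    for _ in range(max_rounds):
        if not active:
            break
        pending: list[int] = []
        for comp in active:
            where = labels == comp
            pts = np.argwhere(where) * spacing
            dists = sorted(
                (float(trees[c].query(pts)[0].min()), c) for c in trees
            )
            d_min, best = dists[0]
            d_second = dists[1][0] if len(dists) > 1 else np.inf
            if d_second > 0 and d_min / d_second <= ambiguity_ratio:
                assignment[comp] = best
            else:
                eroded = ndimage.binary_erosion(where)
                loss += int(where.sum() - eroded.sum())
                labels[where] = 0
                if eroded.any():
                    sub, n = ndimage.label(eroded, structure=_STRUCT26)
                    for i in range(1, n + 1):
                        labels[sub == i] = next_id
                        pending.append(next_id)
                        next_id += 1
        active = pending
    if loss:
        log.info("vessel assignment eroded away %d voxels", loss)
    return VesselObjects(labels, vessels.spacing, assignment, loss)
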