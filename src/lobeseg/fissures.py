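"""Bronchial convex hulls, Hessian fissure enhancement, and watershed lobes.

The final lobe maps are produced in three steps: (1) every lung voxel is
assigned the code of the nearest labeled structure (bronchial convex
hulls, labeled centerlines, assigned vessels) to form initial masks; (2)
the fissures are enhanced with a multi-scale Hessian eigenvalue plate
filter; (3) the initial masks are eroded into watershed markers and the
watershed of the fissure score image, restricted to each lung half,
yields the final partition with fissures acting as barriers.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage.segmentation import watershed

from .airways import AirwayGraph
from .core_io import (ALL_CODES, LEFT_CODES, RIGHT_CODES, BinaryMask, CTVolume,
                      LobeMap, assert_same_grid)
from .errors import EmptyInputError, LabelingError, ValidationError
from .lungs_vessels import VesselObjects

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# convex hulls of labeled bronchi
# ---------------------------------------------------------------------------

def lobar_hulls(graph: AirwayGraph, shape) -> dict[int, BinaryMask]:
    """Voxelized 3-D convex hull of the labeled centerline voxels per lobe.

    Degenerate point sets (a single straight bronchus) are joggled into a
    sliver hull, which voxelizes to the segment itself.  Absent codes give
    empty masks.
    """
    centerlines = graph.labeled_centerline_voxels()
    if not centerlines:
        raise LabelingError("graph carries no lobar labels; run label_lobar_bronchi first")
    out: dict[int, BinaryMask] = {}
    for code in ALL_CODES:
        mask = np.zeros(shape, dtype=bool)
        pts = centerlines.get(code)
        if pts is not None and len(pts) > 0:
            mask = _voxelized_hull(pts.astype(float), shape)
        out[code] = BinaryMask(mask, graph.spacing)
    return out


def _voxelized_hull(pts: np.ndarray, shape) -> np.ndarray:
    """Voxelize the convex hull of a point set, degenerate sets included.

    Collinear points give the 1-voxel-wide segment between the extremes;
    coplanar points give the filled 2-D hull within the plane."""
    mask = np.zeros(shape, dtype=bool)
    shape = np.asarray(shape)

    def _mark(v):
        v = np.rint(v).astype(int)
        if np.all(v >= 0) and np.all(v < shape):
            mask[tuple(v)] = True

    if len(pts) == 1:
        _mark(pts[0])
        return mask
    center = pts.mean(axis=0)
    centered = pts - center
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > 1e-8).sum())
    if rank <= 1:
        axis = vt[0]
        t = centered @ axis
        p0, p1 = pts[t.argmin()], pts[t.argmax()]
        n = max(int(np.ceil(np.linalg.norm(p1 - p0) * 2)), 2)
        for step in np.linspace(0.0, 1.0, n):
            _mark(p0 * (1 - step) + p1 * step)
        return mask

    lo = np.maximum(np.floor(pts.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(pts.max(axis=0)).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return mask
    grid = np.stack(np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    if rank == 2:
        basis, normal = vt[:2], vt[2]
        tri2 = Delaunay(centered @ basis.T)
        rel = grid.astype(float) - center
        inside = (np.abs(rel @ normal) <= 0.5) & (tri2.find_simplex(rel @ basis.T) >= 0)
    else:
        try:
            tri = Delaunay(pts)
        except QhullError:
            tri = Delaunay(pts, qhull_options="QJ")
        inside = tri.find_simplex(grid.astype(float)) >= 0
    sel = grid[inside]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask


# ---------------------------------------------------------------------------
# Hessian plate enhancement
# ---------------------------------------------------------------------------

def enhance_fissures(ct: CTVolume, lung: BinaryMask,
                     scales_mm=(1.0, 2.0), eps: float = 1e-6) -> np.ndarray:
    """Multi-scale Hessian eigenvalue fissure (bright plate) enhancement.

    Per scale s, Gaussian second derivatives (in mm) give the Hessian
    eigenvalues ordered |l1| >= |l2| >= |l3|.  The plate score
    ``(|l1| - |l2|) / (|l1| + |l2| + eps)`` is kept only where l1 < 0: a
    fissure is a thin sheet *denser* than its surroundings, i.e. an
    intensity ridge whose second derivative across the plate is strongly
    negative.  Scores are maximized over scales and min-max normalized to
    [0, 1] within the lung; everything outside the lung is 0.
    """
    if not lung.mask.any():
        raise EmptyInputError("empty lung mask")
    if len(scales_mm) == 0:
        raise ValidationError("scales_mm must be non-empty")
    assert_same_grid(ct, lung)
    img = ct.voxels.astype(np.float32)
    spacing = np.asarray(ct.spacing, float)
    where = lung.mask
    score = np.zeros(ct.shape, dtype=np.float32)
    orders = {(0, 0): (2, 0, 0), (1, 1): (0, 2, 0), (2, 2): (0, 0, 2),
              (0, 1): (1, 1, 0), (0, 2): (1, 0, 1), (1, 2): (0, 1, 1)}
    for s in scales_mm:
        sigma_vox = s / spacing
        n = int(where.sum())
        H = np.empty((n, 3, 3), dtype=np.float32)
        for (i, j), order in orders.items():
            # gamma-normalized second derivative in physical units
            d = ndimage.gaussian_filter(img, sigma=sigma_vox, order=order)
            d *= (s * s) / (spacing[i] * spacing[j])
            H[:, i, j] = d[where]
            H[:, j, i] = H[:, i, j]
        ev = np.linalg.eigvalsh(H)  # ascending
        order_abs = np.argsort(np.abs(ev), axis=1)[:, ::-1]
        ev = np.take_along_axis(ev, order_abs, axis=1)
        l1, l2 = ev[:, 0], ev[:, 1]
        plate = (np.abs(l1) - np.abs(l2)) / (np.abs(l1) + np.abs(l2) + eps)
        plate[l1 >= 0] = 0.0  # only bright plates (ridge: l1 strongly negative)
        score[where] = np.maximum(score[where], plate.astype(np.float32))
    inside = score[where]
    rng_ = inside.max() - inside.min()
    if rng_ <= 0:
        score[where] = 0.0
    else:
        score[where] = (inside - inside.min()) / rng_
    return score


# ---------------------------------------------------------------------------
# initial lobe masks and final watershed
# ---------------------------------------------------------------------------

def initial_lobe_masks(left: BinaryMask, right: BinaryMask, graph: AirwayGraph,
                       hulls: dict[int, BinaryMask], vessels: VesselObjects,
                       hull_weight: float = 0.5) -> LobeMap:
    """Assign every lung voxel the code of its nearest labeled structure.

    Candidate structures per lobe are the hull voxels, the labeled
    bronchial centerlines, and the vessels assigned to that lobe; the
    distance to hull voxels is multiplied by ``hull_weight`` so hulls
    dominate near the hilum.  Right-lung voxels may only take codes 1-3,
    left-lung voxels only 4-6.
    """
    assert_same_grid(left, right)
    spacing = left.spacing
    shape = left.shape
    centerlines = graph.labeled_centerline_voxels()

    dist: dict[int, np.ndarray] = {}
    for code in ALL_CODES:
        parts = []
        hull = hulls.get(code)
        d_code = None
        if hull is not None and hull.mask.any():
            d_hull = ndimage.distance_transform_edt(~hull.mask, sampling=spacing)
            d_code = hull_weight * d_hull
        struct = np.zeros(shape, dtype=bool)
        if code in centerlines:
            c = centerlines[code]
            struct[c[:, 0], c[:, 1], c[:, 2]] = True
        struct |= vessels.assigned_mask(code)
        if struct.any():
            d_s = ndimage.distance_transform_edt(~struct, sampling=spacing)
            d_code = d_s if d_code is None else np.minimum(d_code, d_s)
        if d_code is not None:
            dist[code] = d_code.astype(np.float32)

    labels = np.zeros(shape, dtype=np.uint8)
    for side_mask, codes, name in ((right.mask, RIGHT_CODES, "right"),
                                   (left.mask, LEFT_CODES, "left")):
        avail = [c for c in codes if c in dist]
        if side_mask.any() and not avail:
            raise LabelingError(f"no labeled structures for the {name} lung")
        if not avail:
            continue
        stack = np.stack([dist[c] for c in avail], axis=0)
        nearest = np.argmin(stack, axis=0)
        side_codes = np.asarray(avail, dtype=np.uint8)[nearest]
        labels[side_mask] = side_codes[side_mask]
    return LobeMap(labels, spacing, left.origin, "six_lobe")


def finalize_lobes(initial: LobeMap, fissure_score: np.ndarray,
                   left: BinaryMask, right: BinaryMask,
                   erosion_layers: int = 3) -> LobeMap:
    """Erode the initial masks into markers and watershed the fissure image.

    The watershed floods the fissure score (high score = barrier) within
    each lung half separately, so right codes stay in the right lung.  A
    lobe eroded to extinction falls back to the largest component of its
    uneroded mask.  The output exactly partitions ``left | right``; marker
    voxels keep their label.  With a flat (all-zero) fissure image the
    result is the nearest-marker partition.
    """
    if erosion_layers < 1:
        raise ValidationError("erosion_layers must be >= 1")
    assert_same_grid(left, right)
    labels_in = initial.labels
    spacing = initial.spacing
    out = np.zeros_like(labels_in, dtype=np.uint8)
    for side_mask, codes in ((right.mask, RIGHT_CODES), (left.mask, LEFT_CODES)):
        if not side_mask.any():
            continue
        markers = np.zeros(labels_in.shape, dtype=np.int32)
        for code in codes:
            m = (labels_in == code) & side_mask
            if not m.any():
                continue
            er = ndimage.binary_erosion(m, iterations=erosion_layers, border_value=0)
            if not er.any():
                log.warning("lobe %d eroded to extinction; using its largest component", code)
                lab, n = ndimage.label(m, structure=np.ones((3, 3, 3), bool))
                if n:
                    counts = np.bincount(lab.ravel()); counts[0] = 0
                    er = lab == np.argmax(counts)
                else:
                    er = m
            markers[er] = code
        if not markers.any():
            continue
        if np.ptp(fissure_score[side_mask]) > 0:
            ws = watershed(fissure_score, markers=markers, mask=side_mask)
        else:
            ws = _nearest_marker(markers, side_mask, spacing)
        # voxels in pockets unreachable by flooding still need a label
        missing = side_mask & (ws == 0)
        if missing.any():
            fill = _nearest_marker(markers, side_mask, spacing)
            ws[missing] = fill[missing]
        out[side_mask] = ws[side_mask]
    return LobeMap(out, spacing, initial.origin, "six_lobe")


def _nearest_marker(markers: np.ndarray, mask: np.ndarray, spacing) -> np.ndarray:
    _, idx = ndimage.distance_transform_edt(markers == 0, sampling=spacing,
                                            return_indices=True)
    near = markers[idx[0], idx[1], idx[2]]
    near = near.astype(np.int32)
    near[~mask] = 0
    return near


def merge_lingula(lobemap: LobeMap) -> LobeMap:
    """Relabel the lingula (5) into the LUL (4), switching to five_lobe mode."""
    if lobemap.mode == "five_lobe":
        log.warning("merge_lingula: map already in five_lobe mode; no-op")
        return lobemap
    labels = lobemap.labels.copy()
    labels[labels == 5] = 4
    return LobeMap(labels, lobemap.spacing, lobemap.origin, "five_lobe")
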