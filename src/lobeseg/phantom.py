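"""Synthetic paired inspiratory/expiratory thorax CT phantoms with exact truth.

The phantom emulates the features of a pediatric chest CT that the
segmentation pipeline relies on: two lung fields (the left one smaller,
with a cardiac notch), a branching airway tree with anatomically directed
lobar bronchi, per-lobe vessel trees, thin bright fissure plates
(optionally incomplete), denser low-contrast expiratory parenchyma,
planted air-trapping regions that keep near-inspiratory density on the
expiratory scan, and a soft/sharp reconstruction-kernel difference
(blur vs. added high-frequency noise).

Geometry is expressed in fractional grid coordinates so the same anatomy
can be generated at different matrix sizes.  All densities are in HU and
configurable through :class:`PhantomSpec`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, CTVolume, LobeMap, ALL_CODES, LOBE_NAMES
from .errors import ValidationError

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Branch",
    "generate_phantom",
    "degrade_expiratory_contrast",
]

# Airway tree topology: (name, parent, lobe code, generation, fractional endpoint).
# 0 = central (unlobed) airway.  Direction vectors mimic anatomy: RUL runs
# superolateral, RML anterior, RLL/LLL inferior, LUL superior, LLi
# anteroinferior off the LUL bronchus.  The trachea starts at _TRACHEA_TOP.
_TRACHEA_TOP = (0.04, 0.45, 0.53)
_BRANCH_TABLE = (
    ("trachea", None, 0, 0, (0.31, 0.45, 0.53)),
    ("main_R", "trachea", 0, 1, (0.44, 0.45, 0.36)),
    ("main_L", "trachea", 0, 1, (0.46, 0.45, 0.69)),
    ("RUL", "main_R", 1, 2, (0.31, 0.44, 0.23)),
    ("RUL_a", "RUL", 1, 3, (0.26, 0.38, 0.22)),
    ("RUL_b", "RUL", 1, 3, (0.27, 0.52, 0.20)),
    ("intermedius", "main_R", 0, 2, (0.49, 0.48, 0.34)),
    ("RML", "intermedius", 2, 3, (0.53, 0.66, 0.30)),
    ("RML_a", "RML", 2, 4, (0.55, 0.70, 0.25)),
    ("RML_b", "RML", 2, 4, (0.58, 0.76, 0.36)),
    ("RML_c", "RML", 2, 4, (0.50, 0.74, 0.30)),
    ("RML_d", "RML", 2, 4, (0.47, 0.62, 0.26)),
    ("RLL", "intermedius", 3, 3, (0.69, 0.44, 0.33)),
    ("RLL_a", "RLL", 3, 4, (0.79, 0.34, 0.27)),
    ("RLL_b", "RLL", 3, 4, (0.81, 0.58, 0.31)),
    ("RLL_c", "RLL", 3, 4, (0.72, 0.64, 0.30)),
    ("RLL_d", "RLL", 3, 4, (0.78, 0.70, 0.33)),
    ("LUL", "main_L", 4, 2, (0.37, 0.48, 0.73)),
    ("LUL2", "LUL", 4, 3, (0.27, 0.44, 0.77)),
    ("LUL_a", "LUL2", 4, 4, (0.19, 0.39, 0.72)),
    ("LUL_b", "LUL2", 4, 4, (0.23, 0.52, 0.79)),
    ("LLi", "LUL", 5, 3, (0.52, 0.69, 0.78)),
    ("LLi_a", "LLi", 5, 4, (0.56, 0.77, 0.75)),
    ("LLL", "main_L", 6, 2, (0.65, 0.42, 0.72)),
    ("LLL_a", "LLL", 6, 3, (0.77, 0.34, 0.67)),
    ("LLL_b", "LLL", 6, 3, (0.79, 0.53, 0.75)),
)


@dataclass(frozen=True)
class PhantomSpec:
    """All tunable phantom parameters (geometry, densities, noise, seed)."""

    shape: tuple[int, int, int] = (96, 128, 128)
    spacing: tuple[float, float, float] = (1.5, 1.0, 1.0)

    # Lung geometry: quasi-ellipsoids in fractional (z, y, x) coordinates.
    right_lung_center: tuple[float, float, float] = (0.54, 0.50, 0.31)
    right_lung_semi: tuple[float, float, float] = (0.42, 0.345, 0.19)
    left_lung_center: tuple[float, float, float] = (0.54, 0.50, 0.72)
    left_lung_semi: tuple[float, float, float] = (0.42, 0.315, 0.17)
    cardiac_notch_center: tuple[float, float, float] = (0.69, 0.72, 0.55)
    cardiac_notch_semi: tuple[float, float, float] = (0.21, 0.19, 0.11)

    # Fissure planes: oblique fissures are z_frac = a + b * y_frac, the right
    # horizontal fissure is an axial plane.  The LUL/LLi boundary has no
    # fissure: as in real lungs the lingula is the territory of the lingular
    # bronchus, so that boundary is the Voronoi split between the LLi and
    # LUL bronchial centerlines.
    # The lingular territory is smaller than the plain bisector (real
    # segmental boundaries are irregular); weight < 1 shrinks it.
    lingula_weight: float = 0.80
    right_oblique: tuple[float, float] = (0.27, 0.50)
    left_oblique: tuple[float, float] = (0.25, 0.55)
    right_horizontal: tuple[float, float] = (0.52, -0.20)
    fissure_thickness_vox: float = 1.0
    fissure_completeness: float = 0.85

    # Airway tree: lumen radii in mm by generation; wall thickness in mm.
    airway_radii_mm: tuple[float, ...] = (4.0, 3.0, 2.0, 1.5, 1.5)
    airway_wall_mm: float = 1.5

    # Vessel trees, one per lobe, rooted near the lobar bronchus tip.
    # vessels_per_lobe is the branch count of an average-sized lobe; actual
    # counts scale with lobe volume so peripheral sampling density is even.
    vessels_per_lobe: int = 3
    vessel_radius_mm: float = 1.3

    # Density model (HU).
    hu_air: float = -1000.0
    hu_parenchyma_insp: float = -820.0
    sd_parenchyma_insp: float = 30.0
    hu_parenchyma_exp: float = -560.0
    sd_parenchyma_exp: float = 40.0
    fissure_hu_offset: float = 150.0
    hu_vessel: float = 40.0
    hu_soft_tissue: float = 40.0
    hu_airway_wall: float = -200.0

    # Planted air trapping: (lobe code, fraction of lobe volume, HU on the
    # expiratory scan).  Trapped tissue keeps near-inspiratory density.
    air_trap_regions: tuple[tuple[int, float, float], ...] = (
        (3, 0.18, -820.0),
        (6, 0.12, -820.0),
    )

    exp_caliber_scale: float = 0.80  # airway/vessel caliber reduction on expiration
    noise_sigma: float = 15.0
    blur_sigma_vox: float = 0.7
    kernel: str = "soft"
    seed: int = 0

    def validate(self) -> None:
        if any(n < 32 for n in self.shape):
            raise ValidationError(f"phantom shape too small: {self.shape}")
        if not 0.0 <= self.fissure_completeness <= 1.0:
            raise ValidationError("fissure_completeness must lie in [0, 1]")
        if self.hu_parenchyma_exp <= self.hu_parenchyma_insp:
            raise ValidationError("expiratory parenchyma must be denser (higher HU) than inspiratory")
        per_lobe: dict[int, float] = {}
        for lobe, frac, _hu in self.air_trap_regions:
            if lobe not in ALL_CODES:
                raise ValidationError(f"air-trap lobe code {lobe} invalid")
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("air-trap fraction must lie in [0, 1]")
            per_lobe[lobe] = per_lobe.get(lobe, 0.0) + frac
        for lobe, total in per_lobe.items():
            if total > 1.0:
                raise ValidationError(
                    f"air-trap fractions for lobe {lobe} sum to {total:.2f} > 1"
                )
        if self.kernel not in ("soft", "sharp"):
            raise ValidationError(f"kernel must be 'soft' or 'sharp', got {self.kernel!r}")

    # -- JSON config round-trip -------------------------------------------
    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown PhantomSpec keys: {sorted(unknown)}")
        def _tup(v):
            return tuple(_tup(x) for x in v) if isinstance(v, (list, tuple)) else v
        return cls(**{k: _tup(v) for k, v in data.items()})

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls.from_dict(json.loads(text))


@dataclass
class Branch:
    """One airway branch: centerline polyline with lobar code and radius."""

    name: str
    parent: str | None
    code: int  # 0 = central airway (trachea / main bronchi / intermedius)
    generation: int
    points: np.ndarray  # (N, 3) float voxel coordinates along the centerline
    voxels: np.ndarray  # (M, 3) int unique voxel indices of the centerline
    radius_mm: float


@dataclass
class PhantomTruth:
    """Exact ground truth for one generated phantom."""

    lobe_map: LobeMap
    lung_mask_left: BinaryMask
    lung_mask_right: BinaryMask
    centerline_tree: list[Branch]
    designed_mla: dict[int, dict[str, float]]  # lobe code (0 = whole lung) -> phase -> mean HU
    air_trap_masks: dict[int, np.ndarray]
    vessel_mask: np.ndarray
    vessel_truth_codes: np.ndarray  # uint8 volume: lobe code of each truth vessel voxel
    airway_lumen: np.ndarray

    def centerline_voxels(self, labeled_only: bool = False) -> np.ndarray:
        parts = [b.voxels for b in self.centerline_tree if b.code or not labeled_only]
        return np.concatenate(parts, axis=0)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _frac_grids(shape):
    axes = [np.linspace(0.0, 1.0, n, dtype=np.float32) for n in shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(shape, center, semi) -> np.ndarray:
    zf, yf, xf = _frac_grids(shape)
    r = ((zf - center[0]) / semi[0]) ** 2
    r = r + ((yf - center[1]) / semi[1]) ** 2
    r = r + ((xf - center[2]) / semi[2]) ** 2
    return r <= 1.0


def _sample_line(p0: np.ndarray, p1: np.ndarray, step: float = 0.4) -> np.ndarray:
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / step)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


def _ball_offsets(radius_mm, spacing) -> np.ndarray:
    """Offsets of an (optionally per-axis anisotropic) ball in voxel units."""
    radii = np.broadcast_to(np.asarray(radius_mm, float), (3,))
    rz, ry, rx = [max(int(np.floor(r / s)), 0) for r, s in zip(radii, spacing)]
    dz, dy, dx = np.mgrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    d2 = ((dz * spacing[0] / radii[0]) ** 2 + (dy * spacing[1] / radii[1]) ** 2
          + (dx * spacing[2] / radii[2]) ** 2)
    keep = d2 <= 1.0
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def _paint_tube(mask: np.ndarray, points: np.ndarray, radius_mm: float, spacing) -> None:
    idx = np.unique(np.rint(points).astype(np.int64), axis=0)
    offs = _ball_offsets(radius_mm, spacing)
    coords = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    shape = np.asarray(mask.shape)
    ok = np.all((coords >= 0) & (coords < shape), axis=1)
    coords = coords[ok]
    mask[coords[:, 0], coords[:, 1], coords[:, 2]] = True


def _build_branches(spec: PhantomSpec) -> list[Branch]:
    dims = np.asarray(spec.shape, dtype=float) - 1.0
    ends: dict[str, np.ndarray] = {}
    branches: list[Branch] = []
    for name, parent, code, gen, end_frac in _BRANCH_TABLE:
        start = np.asarray(_TRACHEA_TOP) * dims if parent is None else ends[parent]
        end = np.asarray(end_frac) * dims
        ends[name] = end
        pts = _sample_line(start, end)
        vox = np.unique(np.rint(pts).astype(np.int64), axis=0)
        radius = spec.airway_radii_mm[min(gen, len(spec.airway_radii_mm) - 1)]
        branches.append(Branch(name, parent, code, gen, pts, vox, radius))
    return branches


def _truth_lobes(spec: PhantomSpec, right: np.ndarray, left: np.ndarray,
                 branches: list[Branch]) -> np.ndarray:
    zf, yf, xf = _frac_grids(right.shape)
    z = np.broadcast_to(zf, right.shape)
    y = np.broadcast_to(yf, right.shape)
    labels = np.zeros(right.shape, dtype=np.uint8)

    a, b = spec.right_oblique
    f_r = a + b * y
    ah, bh = spec.right_horizontal
    f_h = ah + bh * y
    labels[right & (z > f_r)] = 3
    labels[right & (z <= f_r) & (z > f_h)] = 2
    labels[right & (z <= f_r) & (z <= f_h)] = 1

    a, b = spec.left_oblique
    f_l = a + b * y
    labels[left & (z > f_l)] = 6
    upper = left & (z <= f_l)
    labels[upper] = 4
    # lingula: bronchial-supply territory of the LLi bronchus within the
    # left upper region (there is no fissure between LUL and LLi)
    d_code: dict[int, np.ndarray] = {}
    for code in (4, 5):
        seed_mask = np.zeros(right.shape, dtype=bool)
        for br in branches:
            if br.code == code:
                vox = br.voxels
                ok = np.all((vox >= 0) & (vox < np.asarray(right.shape)), axis=1)
                vox = vox[ok]
                seed_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        d_code[code] = ndimage.distance_transform_edt(~seed_mask, sampling=spec.spacing)
    labels[upper & (d_code[5] < spec.lingula_weight * d_code[4])] = 5
    return labels


def _fissure_mask(spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Voxels carrying the bright fissure offset (thin plates, maybe incomplete)."""
    shape = labels.shape
    zf, yf, xf = _frac_grids(shape)
    z = np.broadcast_to(zf, shape)
    y = np.broadcast_to(yf, shape)
    lungs = labels > 0
    nz = shape[0] - 1
    half = 0.5 * spec.fissure_thickness_vox
    out = np.zeros(shape, dtype=bool)
    planes = []
    a, b = spec.right_oblique
    planes.append(((z - (a + b * y)) * nz / np.hypot(1.0, b), lungs & np.isin(labels, (1, 2, 3))))
    a, b = spec.left_oblique
    planes.append(((z - (a + b * y)) * nz / np.hypot(1.0, b), lungs & np.isin(labels, (4, 5, 6))))
    # horizontal fissure exists only on the RUL/RML boundary (above the oblique)
    a, b = spec.right_oblique
    ah, bh = spec.right_horizontal
    horiz_zone = lungs & np.isin(labels, (1, 2)) & (z <= a + b * y)
    planes.append(((z - (ah + bh * y)) * nz / np.hypot(1.0, bh), horiz_zone))
    for dist_vox, zone in planes:
        plate = zone & (np.abs(dist_vox) <= half)
        if spec.fissure_completeness < 1.0:
            # drop a smooth random patch of the plate so the watershed must
            # bridge fissure gaps, as real (incomplete) fissures demand
            f2d = ndimage.gaussian_filter(
                rng.standard_normal(shape[1:]).astype(np.float32), sigma=4.0
            )
            thr = np.quantile(f2d, 1.0 - spec.fissure_completeness)
            keep2d = f2d >= thr
            plate = plate & keep2d[None, :, :]
        out |= plate
    return out


def _air_trap_blob(lobe_mask: np.ndarray, fraction: float, spacing,
                   rng: np.random.Generator) -> np.ndarray:
    """The ``fraction`` of lobe voxels nearest a random interior center."""
    n_target = int(round(fraction * np.count_nonzero(lobe_mask)))
    blob = np.zeros(lobe_mask.shape, dtype=bool)
    if n_target == 0:
        return blob
    interior = ndimage.distance_transform_edt(lobe_mask, sampling=spacing) >= 5.0
    cand = np.argwhere(interior if interior.any() else lobe_mask)
    center = cand[rng.integers(len(cand))]
    pts = np.argwhere(lobe_mask)
    d2 = (((pts - center) * np.asarray(spacing)) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")[:n_target]
    sel = pts[order]
    blob[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return blob


def _stratified_points(cand: np.ndarray, min_dist_vox: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Greedy Poisson-disk-like subset: shuffled candidates kept when at
    least ``min_dist_vox`` (index units) from every accepted point."""
    order = rng.permutation(len(cand))
    kept: list[np.ndarray] = []
    for i in order:
        p = cand[i]
        if all(np.linalg.norm(p - q) >= min_dist_vox for q in kept):
            kept.append(p)
    return np.asarray(kept)


def _nn_tour(pts: np.ndarray, start: np.ndarray) -> np.ndarray:
    """Order points as a greedy nearest-neighbor tour from ``start`` so the
    connecting polyline stays short."""
    if len(pts) == 0:
        return pts
    remaining = list(range(len(pts)))
    cur = start
    order = []
    while remaining:
        i = min(remaining, key=lambda j: np.linalg.norm(pts[j] - cur))
        order.append(i)
        cur = pts[i]
        remaining.remove(i)
    return pts[order]


def _vessel_geometry(spec: PhantomSpec, labels: np.ndarray, branches: list[Branch],
                     rng: np.random.Generator) -> dict[int, list[tuple[np.ndarray, tuple]]]:
    """Per-lobe vessel tube segments as (polyline points, radii) lists.

    Each lobe's tree is a star of tubes from a root near a distal
    single-lobe bronchus tip to random interior points, plus a
    juxta-fissural vein web along the lobe's interlobar faces.  Geometry is
    phase-independent; calibers are applied at painting time (vessels are
    narrower on the expiratory scan).
    """
    segments: dict[int, list[tuple[np.ndarray, tuple]]] = {}
    if spec.vessels_per_lobe <= 0:
        return segments
    # vessel roots sit at a distal single-lobe bronchus tip: the LUL
    # bronchus tip itself is the lingular branching point, i.e. a central
    # airway whose neighborhood the vessel search excludes
    tips = {b.code: (b.points[-1], b.points[-1] - b.points[0]) for b in branches
            if b.code and b.name in ("RUL", "RML", "RLL", "LUL2", "LLi", "LLL")}
    spacing = np.asarray(spec.spacing)
    lungs_all = labels > 0
    # veins keep their distance from bronchi that supply several lobes (the
    # hilar corridor); near the hilum the lobar boundaries are carried by
    # the bronchi themselves
    codes_below: dict[str, set] = {}
    for name, parent, code, gen, _end in reversed(_BRANCH_TABLE):
        codes_below.setdefault(name, set())
        if code:
            codes_below[name].add(code)
        if parent is not None:
            codes_below.setdefault(parent, set())
            codes_below[parent] |= codes_below[name]
    hilar = np.zeros(labels.shape, dtype=bool)
    for b in branches:
        if len(codes_below.get(b.name, set())) != 1:
            vox = b.voxels
            ok = np.all((vox >= 0) & (vox < np.asarray(labels.shape)), axis=1)
            vox = vox[ok]
            hilar[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    d_hilar = ndimage.distance_transform_edt(~hilar, sampling=spec.spacing)
    lobe_counts = {c: int(np.count_nonzero(labels == c)) for c in ALL_CODES}
    mean_count = np.mean([v for v in lobe_counts.values() if v]) if any(lobe_counts.values()) else 1
    for code in ALL_CODES:
        lobe = labels == code
        if not lobe.any():
            continue
        edt = ndimage.distance_transform_edt(lobe, sampling=spec.spacing)
        interior = edt >= 3.5
        cand = np.argwhere(interior if interior.any() else lobe)
        n_branches = max(3, round(spec.vessels_per_lobe * lobe_counts[code] / mean_count))
        k = min(n_branches, len(cand))
        targets = cand[rng.choice(len(cand), size=k, replace=False)]
        centroid = np.argwhere(lobe).mean(axis=0)
        tip, axis = tips.get(code, (centroid, np.zeros(3)))
        direction = centroid - tip
        # root clears the peri-bronchial band so the tree is not severed
        # from its hilar origin when airway-adjacent voxels are excluded;
        # the offset is perpendicular to the bronchus axis so the root
        # never lands back inside the bronchial wall corridor
        a_norm = np.linalg.norm(axis)
        if a_norm > 1e-6:
            u = axis / a_norm
            direction = direction - np.dot(direction, u) * u
        norm = np.linalg.norm(direction)
        root = tip + (direction / norm * 7.0 if norm > 1e-6 else 0.0)
        segs: list[tuple[np.ndarray, tuple]] = []
        # z-elongated cross-section: near-axial tubes stay >= 2 slices thick
        # after blurring, so threshold detection cannot fragment them
        trunk_r = (max(spec.vessel_radius_mm, 2.2),
                   spec.vessel_radius_mm * 0.85, spec.vessel_radius_mm * 0.85)
        for t in targets:
            # route via a centroid-pulled midpoint so the tube stays inside
            # the lobe even where the lobe is a thin or notched wedge
            r0 = np.asarray(root, float)
            t1 = t.astype(float)
            mid = 0.5 * (r0 + t1)
            mid += 0.3 * (centroid - mid)
            pts = np.concatenate([_sample_line(r0, mid), _sample_line(mid, t1)[1:]])
            segs.append((pts, trunk_r))
        # Juxta-fissural veins: pulmonary veins run along the interlobar
        # planes, so each lobe gets a vein web hugging its interlobar faces;
        # these anchor the lobar boundaries for the distance assignment.
        # Along the fissureless LUL|LLi boundary the veins are distinctly
        # finer (small segmental branches): still visible on inspiration,
        # but they drop below the detection threshold on the low-contrast
        # expiratory scan, which is why the lingula is the hardest lobe
        # there.
        partner = {4: 5, 5: 4}.get(code)
        band = (edt >= 3.0) & (edt <= 6.0) & (d_hilar > 10.0)
        other_f = lungs_all & ~lobe
        if partner is not None:
            other_f &= labels != partner
        d_f = ndimage.distance_transform_edt(~other_f, sampling=spec.spacing)
        webs = [(band & (d_f <= 10.0), (1.7, 1.1, 1.1))]
        if partner is not None:
            d_p = ndimage.distance_transform_edt(labels != partner,
                                                 sampling=spec.spacing)
            webs.append((band & (d_p <= 10.0) & (d_f > 10.0), (1.6, 1.05, 1.05)))
        for fmask, web_r in webs:
            fpts = np.argwhere(fmask)
            if not len(fpts):
                continue
            # the fissureless partner face needs denser venous pinning
            spacing_vox = 11.0 if web_r[0] >= 1.7 else 8.0
            sel = _stratified_points(fpts, min_dist_vox=spacing_vox, rng=rng)
            sel = _nn_tour(sel, np.asarray(root, float))
            chain_pts = [np.asarray(root, float)] + [p.astype(float) for p in sel]
            for a, b in zip(chain_pts[:-1], chain_pts[1:]):
                segs.append((_sample_line(a, b), web_r))
            # redundant anchors: strand breaks (or exclusion corridors in
            # the detection stage) must not orphan the web from its hilar
            # root - an orphaned juxta-fissural web is distance-ambiguous
            # and can be confidently assigned to the wrong lobe.  Anchors
            # detour via a centroid-pulled midpoint, keeping them clear of
            # the peri-bronchial corridor excluded from the vessel search
            for i in range(0, len(sel), 4):
                r0 = np.asarray(root, float)
                t1 = sel[i].astype(float)
                mid = 0.5 * (r0 + t1)
                mid += 0.3 * (centroid - mid)
                pts = np.concatenate([_sample_line(r0, mid),
                                      _sample_line(mid, t1)[1:]])
                segs.append((pts, trunk_r))
        segments[code] = segs
    return segments


def _paint_vessel_codes(segments: dict[int, list[tuple[np.ndarray, tuple]]],
                        labels: np.ndarray, spacing, scale: float = 1.0,
                        shrink_mm: float = 0.0) -> np.ndarray:
    """Rasterize vessel segments at a caliber ``scale`` into a code volume.

    ``shrink_mm`` reduces each radius; the ground-truth vessel map uses the
    tube core (radius minus half a voxel) because only voxels whose center
    lies well inside the tube are majority-vessel after partial-volume
    averaging."""
    codes_vol = np.zeros(labels.shape, dtype=np.uint8)
    cube = np.ones((3, 3, 3), bool)
    for code, segs in segments.items():
        lobe = labels == code
        if not lobe.any() or not segs:
            continue
        tree = np.zeros(labels.shape, dtype=bool)
        for pts, radii in segs:
            _paint_tube(tree, pts, tuple(max(r * scale - shrink_mm, 0.3) for r in radii),
                        spacing)
        # vessels stay strictly inside their lobe; the one-voxel margin keeps
        # trees of adjacent lobes from touching diagonally across a fissure
        tree &= ndimage.binary_erosion(lobe, structure=cube)
        codes_vol[tree] = code
    return codes_vol


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, CTVolume, PhantomTruth]:
    """Generate a paired insp/exp phantom and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  Returns ``(insp, exp, truth)``
    where both volumes share one grid and the truth lobe map exactly
    partitions the union of the left/right lung masks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    spacing = spec.spacing

    right = _ellipsoid(shape, spec.right_lung_center, spec.right_lung_semi)
    left = _ellipsoid(shape, spec.left_lung_center, spec.left_lung_semi)
    left &= ~_ellipsoid(shape, spec.cardiac_notch_center, spec.cardiac_notch_semi)

    branches = _build_branches(spec)
    labels = _truth_lobes(spec, right, left, branches)
    # vessels shrink on expiration (reduced calibers), one reason the
    # expiratory scan is harder; airway calibers are kept phase-constant so
    # the airway tree, which anchors the whole pipeline, stays segmentable
    scale = {"insp": 1.0, "exp": spec.exp_caliber_scale}
    lumen = np.zeros(shape, dtype=bool)
    wall = np.zeros(shape, dtype=bool)
    central_tube = np.zeros(shape, dtype=bool)
    for b in branches:
        _paint_tube(wall, b.points, b.radius_mm + spec.airway_wall_mm, spacing)
        _paint_tube(lumen, b.points, b.radius_mm, spacing)
        if b.code == 0:
            # hilar bronchial wall is not parenchyma of any lobe
            _paint_tube(central_tube, b.points, b.radius_mm + spec.airway_wall_mm,
                        spacing)

    fissures = _fissure_mask(spec, labels, rng)
    vessel_segments = _vessel_geometry(spec, labels, branches, rng)
    vessel_codes_ph = {ph: _paint_vessel_codes(vessel_segments, labels, spacing, scale[ph])
                       for ph in ("insp", "exp")}
    # ground truth counts tube cores only (majority-vessel voxels)
    vessel_codes = _paint_vessel_codes(vessel_segments, labels, spacing, 1.0,
                                       shrink_mm=0.55)
    vessel_mask = vessel_codes > 0

    trap_masks: dict[int, np.ndarray] = {}
    trap_hu: dict[int, float] = {}
    for lobe, frac, hu in spec.air_trap_regions:
        blob = _air_trap_blob(labels == lobe, frac, spacing, rng)
        if lobe in trap_masks:
            trap_masks[lobe] |= blob
        else:
            trap_masks[lobe] = blob
        trap_hu[lobe] = hu

    lungs = labels > 0

    def _assemble(phase: str) -> np.ndarray:
        par = np.full(shape, spec.hu_soft_tissue, dtype=np.float32)
        if phase == "insp":
            par[lungs] = spec.hu_parenchyma_insp
        else:
            par[lungs] = spec.hu_parenchyma_exp
            for lobe, blob in trap_masks.items():
                par[blob] = trap_hu[lobe]
        par[fissures] += spec.fissure_hu_offset
        par[vessel_codes_ph[phase] > 0] = spec.hu_vessel
        par[wall] = spec.hu_airway_wall
        par[lumen] = spec.hu_air
        return ndimage.gaussian_filter(par, sigma=spec.blur_sigma_vox)

    clean = {ph: _assemble(ph) for ph in ("insp", "exp")}

    # truth lung masks / lobe map exclude the airway lumen so the automatic
    # masks (which remove segmented lumen) are compared like for like
    labels = labels.copy()
    excluded = lumen | central_tube
    labels[excluded] = 0
    right &= ~excluded
    left &= ~excluded
    lungs = labels > 0

    designed: dict[int, dict[str, float]] = {}
    for code in ALL_CODES:
        m = labels == code
        if m.any():
            designed[code] = {ph: float(clean[ph][m].mean()) for ph in ("insp", "exp")}
    designed[0] = {ph: float(clean[ph][lungs].mean()) for ph in ("insp", "exp")}

    sd_lung = {"insp": spec.sd_parenchyma_insp, "exp": spec.sd_parenchyma_exp}
    factor = 1.5 if spec.kernel == "sharp" else 1.0
    vols: dict[str, CTVolume] = {}
    for ph in ("insp", "exp"):
        noise = rng.standard_normal(shape).astype(np.float32) * (factor * spec.noise_sigma)
        if sd_lung[ph] > 0:
            lung_noise = rng.standard_normal(shape).astype(np.float32)
            noise[lungs] = lung_noise[lungs] * (factor * sd_lung[ph])
        vols[ph] = CTVolume.from_hu(clean[ph] + noise, spacing, (0.0, 0.0, 0.0),
                                    phase=ph, kernel=spec.kernel)

    truth = PhantomTruth(
        lobe_map=LobeMap(labels, spacing, (0.0, 0.0, 0.0), "six_lobe"),
        lung_mask_left=BinaryMask(left, spacing),
        lung_mask_right=BinaryMask(right, spacing),
        centerline_tree=branches,
        designed_mla=designed,
        air_trap_masks=trap_masks,
        vessel_mask=vessel_mask,
        vessel_truth_codes=vessel_codes,
        airway_lumen=lumen,
    )
    return vols["insp"], vols["exp"], truth


def degrade_expiratory_contrast(spec: PhantomSpec, level: float) -> PhantomSpec:
    """Move the expiratory scan toward the hard low-contrast regime.

    ``level`` in [0, 1] linearly pulls the expiratory parenchyma mean toward
    a floor of (soft-tissue HU - 150) and shrinks the fissure HU offset by
    the same factor; level 0 returns the spec unchanged.  This reproduces
    the qualitative ordering that deep-expiration scans are harder to
    segment than inspiratory ones.
    """
    if not 0.0 <= level <= 1.0:
        raise ValidationError(f"degrade level must lie in [0, 1], got {level}")
    if level == 0.0:
        return spec
    floor = spec.hu_soft_tissue - 150.0
    new_mean = spec.hu_parenchyma_exp + level * (floor - spec.hu_parenchyma_exp)
    return dataclasses.replace(
        spec,
        hu_parenchyma_exp=float(new_mean),
        fissure_hu_offset=float(spec.fissure_hu_offset * (1.0 - level)),
    )


def truth_to_json(truth: PhantomTruth) -> str:
    """Serialize the centerline tree and designed constants (not the volumes)."""
    data = {
        "designed_mla": {str(k): v for k, v in truth.designed_mla.items()},
        "branches": [
            {
                "name": b.name,
                "parent": b.parent,
                "code": b.code,
                "lobe": LOBE_NAMES.get(b.code, "central"),
                "generation": b.generation,
                "radius_mm": b.radius_mm,
                "voxels": b.voxels.tolist(),
            }
            for b in truth.centerline_tree
        ],
    }
    return json.dumps(data, indent=1)
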