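"""Segmentation agreement statistics: overlap, surface distance, Bland-Altman.

Implements the validation toolbox for comparing an automatically
generated lobe map against a reference: Dice and Jaccard overlap (per
lobe and pooled over lobes), the mean absolute (symmetric average)
surface distance in mm, Bland-Altman mean difference with limits of
agreement, and the Pearson correlation coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import LOBE_NAMES, BinaryMask, CTVolume, LobeMap, assert_same_grid
from .errors import InsufficientDataError, UndefinedMetricError, ValidationError

__all__ = [
    "dice", "jaccard", "multi_region_dice", "avg_surface_distance",
    "bland_altman", "pearson", "validation_report", "AgreementReport",
]


def _counts(a: BinaryMask, m: BinaryMask) -> tuple[int, int, int]:
    assert_same_grid(a, m)
    na, nm = a.count(), m.count()
    if na == 0 and nm == 0:
        raise UndefinedMetricError("both masks are empty")
    inter = int(np.count_nonzero(a.mask & m.mask))
    return na, nm, inter


def dice(a: BinaryMask, m: BinaryMask) -> float:
    """Dice overlap 2|A n M| / (|A| + |M|), exact on voxel counts."""
    na, nm, inter = _counts(a, m)
    return float(Fraction(2 * inter, na + nm))


def jaccard(a: BinaryMask, m: BinaryMask) -> float:
    """Jaccard overlap |A n M| / |A u M|; satisfies J = D / (2 - D)."""
    na, nm, inter = _counts(a, m)
    return float(Fraction(inter, na + nm - inter))


def multi_region_dice(auto: LobeMap, ref: LobeMap) -> float:
    """Pooled Dice over the lobe codes present in either map:
    2 * sum_i |A_i n M_i| / sum_i (|A_i| + |M_i|)."""
    assert_same_grid(auto, ref)
    if auto.mode != ref.mode:
        raise ValidationError(f"mode mismatch: {auto.mode} vs {ref.mode}")
    codes = sorted(set(auto.present_codes()) | set(ref.present_codes()))
    if not codes:
        raise UndefinedMetricError("no lobes present in either map")
    num = den = 0
    for c in codes:
        a = auto.labels == c
        m = ref.labels == c
        num += 2 * int(np.count_nonzero(a & m))
        den += int(np.count_nonzero(a)) + int(np.count_nonzero(m))
    return float(Fraction(num, den))


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-adjacent background neighbor
    (the array border counts as background)."""
    core = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1),
                                  border_value=0)
    return np.argwhere(mask & ~core)


def avg_surface_distance(a: BinaryMask, m: BinaryMask, spacing=None) -> float:
    """Symmetric mean nearest-neighbor surface distance in mm
    (mean absolute surface distance / average Hausdorff distance)."""
    assert_same_grid(a, m)
    if not a.mask.any() or not m.mask.any():
        raise UndefinedMetricError("surface distance undefined for an empty mask")
    sp = np.asarray(spacing if spacing is not None else a.spacing, float)
    sa = surface_voxels(a.mask) * sp
    sm = surface_voxels(m.mask) * sp
    d_am = cKDTree(sm).query(sa)[0]
    d_ma = cKDTree(sa).query(sm)[0]
    return float((d_am.sum() + d_ma.sum()) / (len(d_am) + len(d_ma)))


def bland_altman(auto_values, ref_values) -> tuple[float, float, float]:
    """Mean difference and 1.96-SD limits of agreement for paired values.

    Returns ``(mean_delta, loa_low, loa_high)`` with the sample (n-1)
    standard deviation of the differences auto - ref.
    """
    x = np.asarray(auto_values, float)
    y = np.asarray(ref_values, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("auto and ref value lists must be 1-D and equal length")
    if len(x) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InsufficientDataError("Pearson needs two equal-length lists of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("Pearson undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


@dataclass
class AgreementReport:
    """Per-lobe and pooled agreement between an auto and a reference map."""

    per_lobe: pd.DataFrame  # one row per present lobe code + a pooled row
    pooled_dice: float
    bland_altman_volume: tuple[float, float, float] | None = None
    pearson_volume: float | None = None

    def to_json(self) -> str:
        data = {
            "pooled_dice": self.pooled_dice,
            "rows": self.per_lobe.to_dict(orient="records"),
        }
        if self.bland_altman_volume is not None:
            md, lo, hi = self.bland_altman_volume
            data["bland_altman_volume_cm3"] = {"mean_delta": md, "loa_low": lo, "loa_high": hi}
        if self.pearson_volume is not None:
            data["pearson_volume"] = self.pearson_volume
        return json.dumps(data, indent=1)

    def to_csv(self, path) -> None:
        self.per_lobe.to_csv(path, index=False)


def validation_report(auto: LobeMap, ref: LobeMap,
                      ct_pair: tuple[CTVolume, CTVolume] | None = None) -> AgreementReport:
    """Build the per-lobe validation table comparing auto vs reference maps.

    Rows: one per lobe code present in either map (dice, jaccard, surface
    distance, volumes and volume delta) plus one pooled row.  When a
    paired (inspiratory, expiratory) CT is supplied, per-lobe E/I MLA is
    computed on both maps and the air-trapping delta is included.
    """
    from .quant import ei_mla, lobe_volumes  # local import to avoid a cycle

    assert_same_grid(auto, ref)
    if auto.mode != ref.mode:
        raise ValidationError(f"mode mismatch: {auto.mode} vs {ref.mode}")
    codes = sorted(set(auto.present_codes()) | set(ref.present_codes()))
    vols_a = lobe_volumes(auto)
    vols_r = lobe_volumes(ref)
    ei_a = ei_r = None
    if ct_pair is not None:
        insp, exp = ct_pair
        ei_a = ei_mla(insp, auto, exp, auto)
        ei_r = ei_mla(insp, ref, exp, ref)

    rows = []
    for c in codes:
        am, rm = auto.lobe_mask(c), ref.lobe_mask(c)
        row = {
            "lobe": LOBE_NAMES[c],
            "code": c,
            "dice": dice(am, rm) if (am.count() or rm.count()) else np.nan,
            "jaccard": jaccard(am, rm),
            "assd_mm": (avg_surface_distance(am, rm)
                        if am.count() and rm.count() else np.nan),
            "vol_auto_cm3": vols_a.get(c, 0.0),
            "vol_ref_cm3": vols_r.get(c, 0.0),
            "dvol_cm3": vols_a.get(c, 0.0) - vols_r.get(c, 0.0),
        }
        if ei_a is not None:
            row["ei_auto"] = ei_a.get(c, np.nan)
            row["ei_ref"] = ei_r.get(c, np.nan)
            row["dei"] = row["ei_auto"] - row["ei_ref"]
        rows.append(row)

    pooled = multi_region_dice(auto, ref)
    pooled_row = {
        "lobe": "pooled", "code": 0, "dice": pooled,
        "jaccard": pooled / (2 - pooled), "assd_mm": np.nan,
        "vol_auto_cm3": sum(vols_a.values()), "vol_ref_cm3": sum(vols_r.values()),
        "dvol_cm3": sum(vols_a.values()) - sum(vols_r.values()),
    }
    if ei_a is not None:
        pooled_row["ei_auto"] = ei_a.get(0, np.nan)
        pooled_row["ei_ref"] = ei_r.get(0, np.nan)
        pooled_row["dei"] = pooled_row["ei_auto"] - pooled_row["ei_ref"]
    rows.append(pooled_row)
    df = pd.DataFrame(rows)

    ba = pr = None
    if len(codes) >= 2:
        va = [vols_a.get(c, 0.0) for c in codes]
        vr = [vols_r.get(c, 0.0) for c in codes]
        ba = bland_altman(va, vr)
        if len(codes) >= 3 and np.ptp(va) > 0 and np.ptp(vr) > 0:
            pr = pearson(va, vr)
    return AgreementReport(df, pooled, ba, pr)
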