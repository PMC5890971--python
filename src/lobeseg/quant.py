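"""Lobe-based quantification: volumes, mean lung attenuation, and E/I MLA.

Air trapping is quantified by the expiratory-to-inspiratory ratio of the
mean lung attenuation (E/I MLA) per lobe: trapped regions stay
air-filled (low HU) on expiration, so their ratio moves toward 1.  Each
phase uses its own lobe map (no registration between phases); the
whole-lung row (code 0) pools all lobe voxels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ALL_CODES, LOBE_NAMES, BinaryMask, CTVolume, LobeMap, assert_same_grid
from .errors import UndefinedMetricError

__all__ = ["lobe_volumes", "mean_lung_attenuation", "ei_mla", "lobe_quant_table"]


def lobe_volumes(lobemap: LobeMap, spacing=None) -> dict[int, float]:
    """Per-lobe volume in cm^3 (voxel count x voxel volume)."""
    sp = np.asarray(spacing if spacing is not None else lobemap.spacing, float)
    voxel_cm3 = float(np.prod(sp)) / 1000.0
    counts = np.bincount(lobemap.labels.ravel(), minlength=7)
    return {c: float(counts[c]) * voxel_cm3 for c in ALL_CODES}


def mean_lung_attenuation(ct: CTVolume, mask: BinaryMask | np.ndarray) -> float:
    """Arithmetic mean HU over the mask voxels."""
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if isinstance(mask, BinaryMask):
        assert_same_grid(ct, mask)
    if not m.any():
        raise UndefinedMetricError("MLA undefined for an empty mask")
    return float(ct.voxels[m].mean())


def ei_mla(ct_insp: CTVolume, map_insp: LobeMap, ct_exp: CTVolume, map_exp: LobeMap,
           airway_insp: BinaryMask | None = None,
           airway_exp: BinaryMask | None = None) -> dict[int, float]:
    """Per-lobe E/I MLA; key 0 is the whole lung.

    Each phase's MLA is computed on that phase's own lobe mask.  When an
    airway mask is supplied for a phase, segmented airway lumen voxels are
    excluded from the means.  Lobes absent from either map are skipped.
    """
    assert_same_grid(ct_insp, map_insp)
    assert_same_grid(ct_exp, map_exp)
    li = map_insp.labels.copy()
    le = map_exp.labels.copy()
    if airway_insp is not None:
        li[airway_insp.mask] = 0
    if airway_exp is not None:
        le[airway_exp.mask] = 0

    out: dict[int, float] = {}
    codes = sorted(set(np.unique(li)) & set(np.unique(le)) - {0})
    for c in [0] + [int(c) for c in codes]:
        mi = (li > 0) if c == 0 else (li == c)
        me = (le > 0) if c == 0 else (le == c)
        mla_i = float(ct_insp.voxels[mi].mean())
        mla_e = float(ct_exp.voxels[me].mean())
        if mla_i >= 0:
            raise UndefinedMetricError(
                f"inspiratory MLA {mla_i:.1f} HU >= 0 for lobe {c}: non-physical parenchyma"
            )
        out[c] = mla_e / mla_i
    return out


def lobe_quant_table(ct_insp: CTVolume, map_insp: LobeMap,
                     ct_exp: CTVolume, map_exp: LobeMap,
                     airway_insp: BinaryMask | None = None,
                     airway_exp: BinaryMask | None = None) -> pd.DataFrame:
    """Volumes, per-phase MLA and E/I MLA for each lobe and the whole lung."""
    vols_i = lobe_volumes(map_insp)
    vols_e = lobe_volumes(map_exp)
    ratios = ei_mla(ct_insp, map_insp, ct_exp, map_exp, airway_insp, airway_exp)
    rows = []
    for c in sorted(ratios):
        name = "lung" if c == 0 else LOBE_NAMES[c]
        mi = map_insp.labels > 0 if c == 0 else map_insp.labels == c
        me = map_exp.labels > 0 if c == 0 else map_exp.labels == c
        rows.append({
            "lobe": name, "code": c,
            "vol_insp_cm3": sum(vols_i.values()) if c == 0 else vols_i[c],
            "vol_exp_cm3": sum(vols_e.values()) if c == 0 else vols_e[c],
            "mla_insp_hu": float(ct_insp.voxels[mi].mean()),
            "mla_exp_hu": float(ct_exp.voxels[me].mean()),
            "ei_mla": ratios[c],
        })
    return pd.DataFrame(rows)
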