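"""End-to-end lobe segmentation: airways -> graph -> lungs/vessels -> lobes."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from . import airways as aw
from . import fissures as fz
from . import lungs_vessels as lv
from .core_io import BinaryMask, CTVolume, LobeMap

log = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    """Final lobe map plus the intermediate artifacts of every stage."""

    lobe_map: LobeMap
    airway_mask: BinaryMask
    graph: "aw.AirwayGraph"
    lung_left: BinaryMask
    lung_right: BinaryMask
    vessels: "lv.VesselObjects"
    fissure_score: "object"
    initial_map: LobeMap
    timings_s: dict[str, float] = field(default_factory=dict)


def segment_lobes(ct: CTVolume, erosion_layers: int = 3,
                  scales_mm=(1.0, 2.0), lobes: int = 6) -> SegmentationResult:
    """Run the full automatic lobe segmentation pipeline on one CT volume.

    ``lobes=5`` merges the lingula into the left upper lobe in the output.
    """
    timings: dict[str, float] = {}

    def _tic(name, fn):
        t0 = time.perf_counter()
        out = fn()
        timings[name] = time.perf_counter() - t0
        log.info("stage %-16s %.2f s", name, timings[name])
        return out

    mask = _tic("airways", lambda: aw.segment_airway_tree(ct))
    skel = _tic("skeleton", lambda: aw.skeletonize(mask))
    graph = _tic("graph", lambda: aw.build_airway_graph(skel, mask))
    graph = _tic("labeling", lambda: aw.label_lobar_bronchi(graph))
    left, right = _tic("lungs", lambda: lv.segment_lungs(ct, mask))
    lung_union = BinaryMask(left.mask | right.mask, ct.spacing, ct.origin)
    # Exclude the neighborhood of the *central* airways (trachea, main
    # bronchi, any bronchus supplying several lobes) from the vessel search:
    # their bright walls span lobe boundaries at the hilum and would bridge
    # vessel trees across lobes.  Walls of intralobar bronchi stay - they
    # are legitimate structures of their own lobe.
    from scipy import ndimage as _ndi
    import numpy as _np
    central = _np.zeros(ct.shape, dtype=bool)
    for e in graph.g.edges:
        sub_codes = {graph.g.edges[se]["label"] for se in graph.subtree_edges(e)}
        sub_codes = {c for c in sub_codes if isinstance(c, int)}
        if len(sub_codes) != 1:
            chain = graph.g.edges[e]["chain"]
            central[chain[:, 0], chain[:, 1], chain[:, 2]] = True
    d_central = _ndi.distance_transform_edt(~central, sampling=ct.spacing)
    vessel_lung = BinaryMask(lung_union.mask & (d_central > 6.5), ct.spacing, ct.origin)
    vessels = _tic("vessels", lambda: lv.segment_vessels(ct, vessel_lung))
    hulls = _tic("hulls", lambda: fz.lobar_hulls(graph, ct.shape))
    vessels = _tic("assign", lambda: lv.assign_vessels_to_lobes(vessels, graph, hulls))
    fiss = _tic("fissures", lambda: fz.enhance_fissures(ct, lung_union, scales_mm))
    initial = _tic("initial", lambda: fz.initial_lobe_masks(left, right, graph, hulls, vessels))
    final = _tic("watershed", lambda: fz.finalize_lobes(initial, fiss, left, right,
                                                        erosion_layers))
    if lobes == 5:
        final = fz.merge_lingula(final)
    return SegmentationResult(final, mask, graph, left, right, vessels, fiss,
                              initial, timings)
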