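"""Bronchial hulls, Hessian fissure enhancement, initial masks, watershed."""

import numpy as np
import pytest

from lobeseg import airways as aw
from lobeseg import fissures as fz
from lobeseg.core_io import BinaryMask, CTVolume, LobeMap
from lobeseg.errors import EmptyInputError, LabelingError, ValidationError
from lobeseg.lungs_vessels import VesselObjects


def _graph_with_chains(chains_by_code, spacing=(1.0, 1.0, 1.0)):
    import networkx as nx
    g = nx.DiGraph()
    g.add_node(0, pos=tuple(chains_by_code[next(iter(chains_by_code))][0]), kind="root")
    nid = 1
    for code, chain in chains_by_code.items():
        g.add_node(nid, pos=tuple(chain[-1]), kind="endpoint")
        g.add_edge(0, nid, chain=np.asarray(chain), label=code, generation=0,
                   radius_mm=2.0)
        nid += 1
    return aw.AirwayGraph(g, 0, spacing)


class TestLobarHulls:
    def test_collinear_chain_gives_one_voxel_segment(self):
        chain = [(5, 5, x) for x in range(5, 15)]
        graph = _graph_with_chains({1: chain})
        hulls = fz.lobar_hulls(graph, (16, 16, 24))
        h = hulls[1].mask
        assert h.sum() == len(chain)
        assert set(map(tuple, np.argwhere(h))) == set(chain)

    def test_l_shape_fills_triangle_against_brute_force(self):
        chain = [(5, 5, x) for x in range(5, 20)] + [(5, y, 19) for y in range(6, 20)]
        graph = _graph_with_chains({2: chain})
        hulls = fz.lobar_hulls(graph, (32, 32, 32))
        pts = np.asarray(chain, float)
        # brute-force point-in-hull: a voxel center is inside the hull iff
        # it is a convex combination of the chain points (linear program)
        from scipy.optimize import linprog
        grid = np.argwhere(np.ones((32, 32, 32), bool))
        sel = grid[(grid[:, 0] == 5)]
        expected = np.zeros((32, 32, 32), bool)
        a_eq = np.vstack([pts.T, np.ones(len(pts))])
        for v in sel[::7]:  # sparse check for speed
            b_eq = np.append(v.astype(float), 1.0)
            res = linprog(np.zeros(len(pts)), A_eq=a_eq, b_eq=b_eq,
                          bounds=(0, 1), method="highs")
            expected[tuple(v)] = res.status == 0
        checked = sel[::7]
        got = hulls[2].mask[checked[:, 0], checked[:, 1], checked[:, 2]]
        want = expected[checked[:, 0], checked[:, 1], checked[:, 2]]
        assert (got == want).mean() > 0.95  # voxelization tolerance at edges

    def test_absent_code_is_empty_and_unlabeled_graph_rejected(self):
        graph = _graph_with_chains({1: [(5, 5, 5), (5, 5, 6)]})
        hulls = fz.lobar_hulls(graph, (8, 8, 8))
        assert hulls[4].mask.sum() == 0
        for e in graph.g.edges:
            graph.g.edges[e]["label"] = None
        with pytest.raises(LabelingError):
            fz.lobar_hulls(graph, (8, 8, 8))


class TestEnhanceFissures:
    shape = (32, 48, 48)

    def _ct(self, hu):
        return CTVolume.from_hu(hu, (1.0, 1.0, 1.0))

    def test_bright_plane_scores_over_background(self):
        hu = np.full(self.shape, -800.0)
        hu[16, :, :] = -650.0  # one-voxel bright plate
        lung = BinaryMask(np.ones(self.shape, bool), (1, 1, 1))
        score = fz.enhance_fissures(self._ct(hu), lung)
        on = score[16, 8:40, 8:40].mean()
        off = score[[8, 24], 8:40, 8:40].mean()
        assert on >= 5 * max(off, 1e-6)

    def test_uniform_volume_scores_zero(self):
        hu = np.full(self.shape, -800.0)
        lung = BinaryMask(np.ones(self.shape, bool), (1, 1, 1))
        score = fz.enhance_fissures(self._ct(hu), lung)
        assert np.all(score == 0)

    def test_blob_scores_below_plane(self):
        hu_plane = np.full(self.shape, -800.0)
        hu_plane[16, :, :] = -650.0
        hu_blob = np.full(self.shape, -800.0)
        zz, yy, xx = np.mgrid[:self.shape[0], :self.shape[1], :self.shape[2]]
        blob = (zz - 16) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2 <= 25
        hu_blob[blob] = -650.0
        lung = BinaryMask(np.ones(self.shape, bool), (1, 1, 1))
        s_plane = fz.enhance_fissures(self._ct(hu_plane), lung)
        s_blob = fz.enhance_fissures(self._ct(hu_blob), lung)
        assert s_blob[blob].mean() < s_plane[16, 8:40, 8:40].mean()

    def test_contract_violations(self):
        hu = self._ct(np.full(self.shape, -800.0))
        with pytest.raises(EmptyInputError):
            fz.enhance_fissures(hu, BinaryMask(np.zeros(self.shape, bool), (1, 1, 1)))
        with pytest.raises(ValidationError):
            fz.enhance_fissures(hu, BinaryMask(np.ones(self.shape, bool), (1, 1, 1)),
                                scales_mm=())


class TestInitialMasks:
    def test_side_constraint_overrides_raw_distance(self):
        shape = (16, 16, 32)
        left = np.zeros(shape, bool); left[:, :, 16:] = True
        right = np.zeros(shape, bool); right[:, :, :16] = True
        # only structure on the right side is an RLL (code 3) bronchus right
        # next to the midline; left lung has an LUL bronchus far away
        graph = _graph_with_chains({
            3: [(8, 8, 14), (8, 8, 15)],
            4: [(8, 8, 30), (8, 8, 31)],
        })
        vessels = VesselObjects(np.zeros(shape, np.int32), (1, 1, 1))
        hulls = {}
        lm = fz.initial_lobe_masks(BinaryMask(left, (1, 1, 1)),
                                   BinaryMask(right, (1, 1, 1)),
                                   graph, hulls, vessels)
        # the left-lung voxel at x=17 is nearest (raw) to the RLL chain but
        # must still take a left-side code
        assert lm.labels[8, 8, 17] == 4
        assert set(np.unique(lm.labels[:, :, 16:])) <= {0, 4, 5, 6}
        assert set(np.unique(lm.labels[:, :, :16])) <= {0, 1, 2, 3}

    def test_hull_voxel_keeps_hull_code(self, paired_runs):
        _, _, _, _, res, _ = paired_runs[1]
        # initial map on the phantom is already a reasonable partition
        from lobeseg.metrics import dice
        truth = paired_runs[1][3]
        for code in range(1, 7):
            d = dice(res.initial_map.lobe_mask(code), truth.lobe_map.lobe_mask(code))
            assert d >= 0.6

    def test_side_without_structures_is_an_error(self):
        shape = (8, 8, 16)
        left = np.zeros(shape, bool); left[:, :, 8:] = True
        right = np.zeros(shape, bool); right[:, :, :8] = True
        graph = _graph_with_chains({3: [(4, 4, 4), (4, 4, 5)]})
        vessels = VesselObjects(np.zeros(shape, np.int32), (1, 1, 1))
        with pytest.raises(LabelingError):
            fz.initial_lobe_masks(BinaryMask(left, (1, 1, 1)),
                                  BinaryMask(right, (1, 1, 1)),
                                  graph, {}, vessels)


class TestFinalize:
    def _simple_setup(self):
        shape = (16, 32, 32)
        right = np.zeros(shape, bool); right[2:14, 4:28, 2:15] = True
        left = np.zeros(shape, bool); left[2:14, 4:28, 17:30] = True
        labels = np.zeros(shape, np.uint8)
        labels[right & (np.arange(shape[1])[None, :, None] < 16)] = 1
        labels[right & (np.arange(shape[1])[None, :, None] >= 16)] = 3
        labels[left] = 4
        initial = LobeMap(labels, (1, 1, 1))
        return shape, right, left, initial

    def test_flat_fissure_map_gives_nearest_marker_partition(self):
        shape, right, left, initial = self._simple_setup()
        out = fz.finalize_lobes(initial, np.zeros(shape, np.float32),
                                BinaryMask(left, (1, 1, 1)),
                                BinaryMask(right, (1, 1, 1)), erosion_layers=2)
        # exact partition
        assert np.array_equal(out.labels > 0, right | left)
        # nearest-marker limit: the boundary between 1 and 3 stays at y=16+-2
        boundary_y = [y for y in range(4, 28)
                      if len(set(out.labels[8, y, 2:15][out.labels[8, y, 2:15] > 0])) > 0
                      and (out.labels[8, y, 2:15] == 3).any()
                      and (out.labels[8, y, 2:15] == 1).any()]
        ys = np.argwhere((out.labels == 1))[:, 1]
        assert ys.max() <= 18

    def test_markers_keep_their_labels(self, paired_runs):
        from scipy import ndimage
        _, _, _, _, res, _ = paired_runs[1]
        final = res.lobe_map.labels
        initial = res.initial_map.labels
        sides = (res.lung_right.mask, res.lung_left.mask)
        codes = ((1, 2, 3), (4, 5, 6))
        for side, side_codes in zip(sides, codes):
            for code in side_codes:
                marker = ndimage.binary_erosion((initial == code) & side,
                                                iterations=3, border_value=0)
                if marker.any():
                    assert (final[marker] == code).all()

    def test_partition_and_determinism(self, paired_runs):
        _, insp, _, _, res, _ = paired_runs[1]
        lungs = res.lung_left.mask | res.lung_right.mask
        assert np.array_equal(res.lobe_map.labels > 0, lungs)
        from lobeseg.pipeline import segment_lobes
        res2 = segment_lobes(insp)
        assert np.array_equal(res.lobe_map.labels, res2.lobe_map.labels)

    def test_erosion_layer_contract(self):
        shape, right, left, initial = self._simple_setup()
        with pytest.raises(ValidationError):
            fz.finalize_lobes(initial, np.zeros(shape, np.float32),
                              BinaryMask(left, (1, 1, 1)),
                              BinaryMask(right, (1, 1, 1)), erosion_layers=0)


class TestMergeLingula:
    def test_relabel_conserves_voxels(self):
        labels = np.zeros((8, 8, 8), np.uint8)
        labels[:2] = 4
        labels[2:4] = 5
        labels[4:6] = 6
        lm = LobeMap(labels, (1, 1, 1))
        merged = fz.merge_lingula(lm)
        assert merged.mode == "five_lobe"
        assert (merged.labels == 5).sum() == 0
        assert (merged.labels == 4).sum() == (labels == 4).sum() + (labels == 5).sum()
        assert (merged.labels > 0).sum() == (labels > 0).sum()

    def test_map_without_lingula_unchanged(self):
        labels = np.zeros((4, 4, 4), np.uint8)
        labels[0] = 4
        lm = LobeMap(labels, (1, 1, 1))
        merged = fz.merge_lingula(lm)
        assert np.array_equal(merged.labels, labels)

    def test_already_merged_is_noop_with_warning(self):
        labels = np.zeros((4, 4, 4), np.uint8)
        labels[0] = 4
        lm = LobeMap(labels, (1, 1, 1), mode="five_lobe")
        assert fz.merge_lingula(lm) is lm
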