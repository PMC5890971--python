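"""Airway tree segmentation, skeletonization, graph building and lobar labeling.

The airway tree is grown from a tracheal seed with a self-adapting
iterative region-growing scheme: the HU threshold starts low and is
escalated in small steps, re-growing at each step, until the grown volume
explodes (leak into parenchyma), at which point the last accepted mask is
returned.  The mask is then thinned to a one-voxel centerline, condensed
into an acyclic rooted graph, and the lobar bronchi are labeled by
anatomical direction rules (RUL superolateral, RML anterior, RLL/LLL
inferior, LUL superior, LLi anteroinferior off the LUL bronchus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .core_io import BinaryMask, CTVolume
from .errors import EmptyInputError, LabelingError, SeedNotFoundError

log = logging.getLogger(__name__)

TRACHEA = "trachea"
MAIN_L = "main_L"
MAIN_R = "main_R"
INTERMEDIUS = "bronchus_intermedius"

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_OFFS26 = np.array([(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)])


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def segment_airway_tree(ct: CTVolume, start_hu: int = -950, step_hu: int = 10,
                        max_hu: int = -500, explosion_factor: float = 1.5) -> BinaryMask:
    """Segment the airway lumen by self-adapting iterative region growing.

    The seed is the darkest voxel in the most cranial 10% of slices (the
    trachea).  Starting at ``start_hu`` the threshold is raised in
    ``step_hu`` steps; the 26-connected component containing the seed is
    re-grown at each step and the escalation stops before the step whose
    volume exceeds ``explosion_factor`` times the previous accepted volume.
    """
    arr = ct.voxels
    n_top = max(1, arr.shape[0] // 10)
    top = arr[:n_top]
    if int(top.min()) > start_hu:
        raise SeedNotFoundError(
            f"no air voxel (<= {start_hu} HU) in the top {n_top} slices"
        )
    seed = np.unravel_index(int(np.argmin(top)), top.shape)

    accepted = None
    accepted_vol = None
    for thr in range(start_hu, max_hu + step_hu, step_hu):
        comp_lab, _ = ndimage.label(arr <= thr, structure=_STRUCT26)
        comp = comp_lab == comp_lab[seed]
        vol = int(comp.sum())
        if accepted_vol is not None and vol > explosion_factor * accepted_vol:
            log.info("airway growth stopped at %d HU (volume %d > %.1fx%d)",
                     thr, vol, explosion_factor, accepted_vol)
            break
        accepted, accepted_vol = comp, vol
    return BinaryMask(accepted, ct.spacing, ct.origin)


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Thin a tubular mask to a one-voxel-wide, topology-preserving centerline.

    Sequential topology-preserving thinning (simple-point deletion,
    26-connected foreground); applied to a fixed point so the operation is
    idempotent.
    """
    m = mask.mask
    if not m.any():
        raise EmptyInputError("cannot skeletonize an empty mask")
    sk = _sk_skeletonize(m)
    for _ in range(4):
        nxt = _sk_skeletonize(sk)
        if np.array_equal(nxt, sk):
            break
        sk = nxt
    return BinaryMask(sk & m, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

@dataclass
class AirwayGraph:
    """Rooted acyclic graph of airway centerlines.

    Nodes carry ``pos`` (voxel index tuple) and ``kind`` (root /
    bifurcation / endpoint); edges carry ``chain`` (ordered voxel array,
    proximal to distal), ``radius_mm``, ``generation`` (root edge = 0) and
    ``label`` (None, a named central airway, or a lobar code 1-6).
    """

    g: nx.DiGraph
    root: int
    spacing: tuple[float, float, float]

    def node_pos_mm(self, n: int) -> np.ndarray:
        return np.asarray(self.g.nodes[n]["pos"], float) * np.asarray(self.spacing)

    def children_edges(self, node: int) -> list[tuple[int, int]]:
        return [(node, c) for c in self.g.successors(node)]

    def edge_direction(self, e: tuple[int, int]) -> np.ndarray:
        """Unit direction (mm) of the edge chain, proximal to distal."""
        chain = self.g.edges[e]["chain"]
        v = (chain[-1] - chain[0]).astype(float) * np.asarray(self.spacing)
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    def subtree_edges(self, e: tuple[int, int]) -> list[tuple[int, int]]:
        """The edge ``e`` plus all edges distal to it."""
        out = [e]
        stack = [e[1]]
        while stack:
            n = stack.pop()
            for c in self.g.successors(n):
                out.append((n, c))
                stack.append(c)
        return out

    def edges_with_label(self, label) -> list[tuple[int, int]]:
        return [e for e in self.g.edges if self.g.edges[e]["label"] == label]

    def labeled_centerline_voxels(self) -> dict[int, np.ndarray]:
        """Lobar code -> stacked chain voxels of all edges carrying it."""
        out: dict[int, list[np.ndarray]] = {}
        for e in self.g.edges:
            lab = self.g.edges[e]["label"]
            if isinstance(lab, int):
                out.setdefault(lab, []).append(self.g.edges[e]["chain"])
        return {k: np.unique(np.concatenate(v, axis=0), axis=0) for k, v in out.items()}

    def present_codes(self) -> tuple[int, ...]:
        return tuple(sorted({self.g.edges[e]["label"] for e in self.g.edges
                             if isinstance(self.g.edges[e]["label"], int)}))

    def validate(self) -> None:
        und = self.g.to_undirected()
        if self.g.number_of_nodes() and not nx.is_connected(und):
            raise LabelingError("airway graph is not connected")
        if self.g.number_of_edges() != self.g.number_of_nodes() - 1:
            raise LabelingError("airway graph is not a tree (|E| != |V| - 1)")

    def summary(self) -> str:
        kinds = [self.g.nodes[n]["kind"] for n in self.g.nodes]
        return (f"AirwayGraph({self.g.number_of_nodes()} nodes, "
                f"{self.g.number_of_edges()} edges, "
                f"{kinds.count('endpoint')} endpoints, "
                f"{kinds.count('bifurcation')} bifurcations)")


def _skeleton_adjacency(vox: np.ndarray) -> dict[int, list[int]]:
    index = {tuple(v): i for i, v in enumerate(vox)}
    adj: dict[int, list[int]] = {i: [] for i in range(len(vox))}
    for i, v in enumerate(vox):
        for off in _OFFS26:
            j = index.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
            if j is not None and j > i:
                adj[i].append(j)
                adj[j].append(i)
    return adj


def _condense(vox: np.ndarray, adj: dict[int, list[int]]) -> nx.Graph:
    """Condense a skeleton voxel graph into a junction/endpoint graph.

    Nodes are voxels with degree != 2 (plus one voxel of any pure cycle);
    edges carry the ordered voxel chains between them.
    """
    deg = {i: len(a) for i, a in adj.items()}
    nodes = [i for i in adj if deg[i] != 2]
    g = nx.MultiGraph()
    visited_half = set()
    for s in nodes:
        g.add_node(s, pos=tuple(int(c) for c in vox[s]))
        for nb in adj[s]:
            if (s, nb) in visited_half:
                continue
            chain = [s, nb]
            prev, cur = s, nb
            while deg[cur] == 2:
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                chain.append(nxt)
                prev, cur = cur, nxt
            visited_half.add((s, nb))
            visited_half.add((cur, prev))
            g.add_node(cur, pos=tuple(int(c) for c in vox[cur]))
            g.add_edge(s, cur, chain=np.asarray([vox[i] for i in chain]))
    # voxels in pure cycles (all degree 2) are untouched tubes with no
    # junction; attach one representative node so they are not lost
    covered = set()
    for _, _, d in g.edges(data=True):
        covered.update(map(tuple, d["chain"]))
    for i in adj:
        if deg[i] == 2 and tuple(vox[i]) not in covered:
            g.add_node(i, pos=tuple(int(c) for c in vox[i]))
            covered.add(tuple(vox[i]))
    return g


def build_airway_graph(skeleton: BinaryMask, mask: BinaryMask, spacing=None) -> AirwayGraph:
    """Build the rooted acyclic airway graph from a skeleton.

    Nodes sit at skeleton voxels with != 2 neighbors (26-connectivity);
    edges are maximal degree-2 chains.  Endpoint spurs shorter than 3 mm
    are pruned, residual cycles are broken by dropping their longest edge,
    and the root is the endpoint with the largest mean radius among the
    most-cranial 10% of nodes.  Edge radii come from the distance
    transform of ``mask`` sampled along the chain.
    """
    if spacing is None:
        spacing = skeleton.spacing
    sk = skeleton.mask
    if not sk.any():
        raise EmptyInputError("cannot build a graph from an empty skeleton")
    vox = np.argwhere(sk)
    adj = _skeleton_adjacency(vox)
    g = _condense(vox, adj)

    sp = np.asarray(spacing, float)

    def chain_len_mm(chain: np.ndarray) -> float:
        if len(chain) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(chain, axis=0) * sp, axis=1).sum())

    # prune short endpoint spurs, then re-merge chains through the
    # degree-2 nodes this leaves behind; repeat until stable
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if chain_len_mm(d["chain"]) >= 3.0:
                continue
            if g.degree(u) == 1 and g.degree(v) > 1:
                g.remove_node(u)
                changed = True
            elif g.degree(v) == 1 and g.degree(u) > 1:
                g.remove_node(v)
                changed = True
        # merge through degree-2 nodes (two distinct neighbors)
        for n in list(g.nodes):
            if g.degree(n) != 2:
                continue
            nbrs = list(g.edges(n, keys=True))
            if len(nbrs) != 2:
                continue
            (u1, v1, k1), (u2, v2, k2) = nbrs
            c1 = g.edges[u1, v1, k1]["chain"]
            c2 = g.edges[u2, v2, k2]["chain"]
            a = v1 if u1 == n else u1
            b = v2 if u2 == n else u2
            if a == n or b == n or a == b:
                continue
            if tuple(c1[0]) != g.nodes[n]["pos"]:
                c1 = c1[::-1]
            if tuple(c2[0]) != g.nodes[n]["pos"]:
                c2 = c2[::-1]
            merged = np.concatenate([c1[::-1], c2[1:]], axis=0)  # a ... n ... b
            g.remove_node(n)
            g.add_edge(a, b, chain=merged)
            changed = True

    # break residual cycles (incl. parallel edges) by dropping longest edges
    simple = nx.Graph()
    for n, d in g.nodes(data=True):
        simple.add_node(n, **d)
    for u, v, d in sorted(g.edges(data=True), key=lambda e: chain_len_mm(e[2]["chain"])):
        if u == v:
            continue
        if not simple.has_edge(u, v):
            simple.add_edge(u, v, **d)
    while True:
        try:
            cyc = nx.find_cycle(simple)
        except nx.NetworkXNoCycle:
            break
        longest = max(cyc, key=lambda e: chain_len_mm(simple.edges[e]["chain"]))
        simple.remove_edge(*longest)
    # keep the component that will contain the root (largest component)
    comps = sorted(nx.connected_components(simple), key=len, reverse=True)
    simple = simple.subgraph(comps[0]).copy()

    # collapsing parallel edges can leave degree-2 pass-through nodes and
    # short spurs; merge/prune them, then contract sub-3mm edges between
    # junction clusters so each anatomical bifurcation is one node
    def _pos(n):
        return np.asarray(simple.nodes[n]["pos"], float)

    changed = True
    while changed:
        changed = False
        for n in list(simple.nodes):
            if simple.degree(n) != 2:
                continue
            (a, b) = [v for v in simple.neighbors(n)]
            if a == b:
                continue
            c1 = simple.edges[a, n]["chain"]
            c2 = simple.edges[n, b]["chain"]
            if np.linalg.norm(c1[0] - _pos(n)) < np.linalg.norm(c1[-1] - _pos(n)):
                c1 = c1[::-1]  # orient a ... n
            if np.linalg.norm(c2[0] - _pos(n)) > np.linalg.norm(c2[-1] - _pos(n)):
                c2 = c2[::-1]  # orient n ... b
            simple.remove_node(n)
            if not simple.has_edge(a, b):
                simple.add_edge(a, b, chain=np.concatenate([c1, c2[1:]], axis=0))
            changed = True
        for u, v, d in list(simple.edges(data=True)):
            if not simple.has_edge(u, v):
                continue
            if chain_len_mm(d["chain"]) >= 3.0:
                continue
            du, dv = simple.degree(u), simple.degree(v)
            if du == 1 and dv > 1:
                simple.remove_node(u)
                changed = True
            elif dv == 1 and du > 1:
                simple.remove_node(v)
                changed = True
            elif du >= 3 and dv >= 3:
                simple = nx.contracted_nodes(simple, u, v, self_loops=False)
                changed = True

    # radii from the distance transform of the airway mask
    edt = ndimage.distance_transform_edt(mask.mask, sampling=spacing)
    for u, v, d in simple.edges(data=True):
        c = d["chain"]
        d["radius_mm"] = float(edt[c[:, 0], c[:, 1], c[:, 2]].mean())

    # root: endpoint with largest incident radius among the most-cranial 10%
    zs = np.array([simple.nodes[n]["pos"][0] for n in simple.nodes])
    z_cut = np.quantile(zs, 0.1)
    endpoints = [n for n in simple.nodes if simple.degree(n) <= 1]
    cranial = [n for n in endpoints if simple.nodes[n]["pos"][0] <= z_cut]
    if not cranial:
        cranial = sorted(endpoints, key=lambda n: simple.nodes[n]["pos"][0])[:1]
    def incident_radius(n):
        rs = [simple.edges[e]["radius_mm"] for e in simple.edges(n)]
        return max(rs) if rs else 0.0
    root = max(cranial, key=incident_radius)

    # orient from the root, set generations, orient chains proximal->distal
    dg = nx.DiGraph()
    for n, d in simple.nodes(data=True):
        dg.add_node(n, **d)
    gen_of: dict[int, int] = {root: 0}
    for u, v in nx.bfs_edges(simple, root):
        d = dict(simple.edges[u, v])
        chain = d["chain"]
        pos_u = np.asarray(simple.nodes[u]["pos"], float)
        if (np.linalg.norm(chain[0] - pos_u) > np.linalg.norm(chain[-1] - pos_u)):
            chain = chain[::-1]
        d["chain"] = chain
        d["generation"] = gen_of[u]
        d["label"] = None
        gen_of[v] = gen_of[u] + 1
        dg.add_edge(u, v, **d)
    for n in dg.nodes:
        if n == root:
            dg.nodes[n]["kind"] = "root"
        elif dg.out_degree(n) == 0:
            dg.nodes[n]["kind"] = "endpoint"
        else:
            dg.nodes[n]["kind"] = "bifurcation"
    return AirwayGraph(dg, root, tuple(spacing))


# ---------------------------------------------------------------------------
# lobar labeling
# ---------------------------------------------------------------------------

def _pick(graph: AirwayGraph, edges, score_fn):
    """Edge maximizing score; ties broken by larger radius, then node id."""
    return max(edges, key=lambda e: (score_fn(e), graph.g.edges[e]["radius_mm"], -e[1]))


def label_lobar_bronchi(graph: AirwayGraph) -> AirwayGraph:
    """Label trachea, main bronchi and the six lobar bronchi by direction rules.

    Axis meaning of unit directions (mm): +z inferior, +y anterior, +x
    toward the patient's left.  Rules: the two children of the trachea
    split into main_R/main_L by the sign of their lateral component; RUL is
    the child of main_R with the largest superior+lateral component, the
    continuation is the bronchus intermedius whose children split into RML
    (most anterior) and RLL (inferior); LUL is the superior child of
    main_L, LLL the inferior one, and LLi is the most anteroinferior branch
    within the LUL subtree.  Distal edges inherit their lobar code.  When a
    rule cannot fire (missing branches), remaining unlabeled endpoint
    subtrees are assigned by position quantiles within the airway bounding
    box; codes that still cannot be placed are simply absent.
    """
    graph.validate()
    g = graph.g.copy()
    out = AirwayGraph(g, graph.root, graph.spacing)

    root_edges = out.children_edges(graph.root)
    if len(root_edges) != 1:
        raise LabelingError(f"expected a single trachea edge at the root; {out.summary()}")
    trachea = root_edges[0]
    g.edges[trachea]["label"] = TRACHEA

    carina_kids = out.children_edges(trachea[1])
    if len(carina_kids) < 2:
        raise LabelingError(f"fewer than 2 children at the carina; {out.summary()}")
    mains = sorted(carina_kids, key=lambda e: g.edges[e]["radius_mm"], reverse=True)[:2]
    mains = sorted(mains, key=lambda e: out.edge_direction(e)[2])
    main_r, main_l = mains[0], mains[1]
    g.edges[main_r]["label"] = MAIN_R
    g.edges[main_l]["label"] = MAIN_L

    def assign(e, code):
        if g.edges[e]["label"] is None:
            g.edges[e]["label"] = code

    # ---- right side -----------------------------------------------------
    r_kids = out.children_edges(main_r[1])
    intermedius = None
    if len(r_kids) >= 2:
        rul = _pick(out, r_kids, lambda e: -out.edge_direction(e)[0] - out.edge_direction(e)[2])
        assign(rul, 1)
        rest = [e for e in r_kids if e != rul]
        intermedius = max(rest, key=lambda e: g.edges[e]["radius_mm"])
    elif len(r_kids) == 1:
        intermedius = r_kids[0]
    if intermedius is not None:
        g.edges[intermedius]["label"] = INTERMEDIUS
        i_kids = out.children_edges(intermedius[1])
        if len(i_kids) >= 2:
            rml = _pick(out, i_kids, lambda e: out.edge_direction(e)[1])
            assign(rml, 2)
            for e in i_kids:
                if e != rml:
                    assign(e, 3)
        elif len(i_kids) == 1:
            d = out.edge_direction(i_kids[0])
            assign(i_kids[0], 2 if d[1] > d[0] else 3)

    # ---- left side ------------------------------------------------------
    l_kids = out.children_edges(main_l[1])
    lul = None
    if len(l_kids) >= 2:
        lul = _pick(out, l_kids, lambda e: -out.edge_direction(e)[0])
        assign(lul, 4)
        lll = _pick(out, [e for e in l_kids if e != lul], lambda e: out.edge_direction(e)[0])
        assign(lll, 6)
        for e in l_kids:
            if e not in (lul, lll):
                assign(e, 4 if out.edge_direction(e)[0] < 0 else 6)
    elif len(l_kids) == 1:
        d = out.edge_direction(l_kids[0])
        code = 4 if d[0] < 0 else 6
        assign(l_kids[0], code)
        if code == 4:
            lul = l_kids[0]

    # lingula: most anteroinferior branch within two bifurcations of the
    # LUL bronchus (there is usually no fissure to find it by)
    if lul is not None:
        candidates = []
        level1 = out.children_edges(lul[1])
        candidates.extend(level1)
        for e in level1:
            candidates.extend(out.children_edges(e[1]))
        if candidates:
            def anteroinf(e):
                d = out.edge_direction(e)
                return d[0] + d[1]
            best = _pick(out, candidates, anteroinf)
            if anteroinf(best) > 0.3:
                for e in out.subtree_edges(best):
                    g.edges[e]["label"] = 5

    # ---- inheritance ----------------------------------------------------
    order = list(nx.bfs_edges(g, graph.root))
    for u, v in order:
        lab = g.edges[u, v]["label"]
        if not isinstance(lab, int):
            continue
        for e in out.children_edges(v):
            if g.edges[e]["label"] is None:
                g.edges[e]["label"] = lab

    # ---- positional fallback for unlabeled distal subtrees ---------------
    unlabeled = [e for e in g.edges if g.edges[e]["label"] is None]
    if unlabeled:
        pos = np.array([g.nodes[n]["pos"] for n in g.nodes], float)
        zmin, zmax = pos[:, 0].min(), pos[:, 0].max()
        xmid = np.median(pos[:, 2])
        for e in unlabeled:
            if g.edges[e]["label"] is not None:
                continue
            tip = np.asarray(g.nodes[e[1]]["pos"], float)
            zq = (tip[0] - zmin) / max(zmax - zmin, 1.0)
            if tip[2] <= xmid:  # right side
                code = 1 if zq < 0.33 else (2 if zq < 0.55 else 3)
            else:
                code = 4 if zq < 0.45 else 6
            for se in out.subtree_edges(e):
                if g.edges[se]["label"] is None:
                    g.edges[se]["label"] = code
            log.info("fallback-labeled subtree at %s as code %d", e, code)

    return out


def graph_to_json(graph: AirwayGraph) -> dict:
    """JSON-serializable dump of nodes, edges and labels."""
    return {
        "root": int(graph.root),
        "spacing": list(graph.spacing),
        "nodes": [
            {"id": int(n), "pos": list(map(int, d["pos"])), "kind": d["kind"]}
            for n, d in graph.g.nodes(data=True)
        ],
        "edges": [
            {
                "from": int(u),
                "to": int(v),
                "label": d["label"],
                "generation": int(d["generation"]),
                "radius_mm": round(float(d["radius_mm"]), 3),
                "n_voxels": int(len(d["chain"])),
            }
            for u, v, d in graph.g.edges(data=True)
        ],
    }
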