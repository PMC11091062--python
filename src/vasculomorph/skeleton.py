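"""Centerline extraction and organization of the vessel mask as a graph.

The segmented vascular mask is reduced to a one-voxel-thick, 26-connected,
topology-preserving skeleton, preceded by an anisotropy-aware Euclidean
distance transform that supplies a local vessel radius at every centerline
voxel.  The skeleton is then organized as a graph: voxels with one
26-neighbor (endpoints) or three and more (junctions) become node
candidates, adjacent candidates are merged into single nodes at their
centroid, and the runs of two-neighbor voxels between nodes become segments
carrying ordered 3D point lists with per-point local radii.  Nodes are
*terminal* (one incident segment) or *branching* (three or more); voxels of
degree 2 are interior segment points, so any degree-2 node arising during
construction is dissolved by merging its two incident segments.  Isolated
26-connected cycles without any junction are kept as loop-flagged segments
(their tortuosity is undefined downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "DistanceMap",
    "SkeletonNode",
    "VesselSegment",
    "VesselGraph",
    "distance_map",
    "skeletonize",
    "build_graph",
    "prune_spurs",
]

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=int)
_NEIGHBOR_KERNEL = np.ones((3, 3, 3), dtype=np.uint8)
_NEIGHBOR_KERNEL[1, 1, 1] = 0
_OFFSETS26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


@dataclass
class DistanceMap:
    """Per-voxel Euclidean distance (um) to the nearest background voxel."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]


@dataclass
class SkeletonNode:
    id: int
    position_um: np.ndarray          # (3,) in (z, y, x) um
    degree: int = 0
    kind: str = "terminal"           # "terminal" | "branching"
    component: int = -1


@dataclass
class VesselSegment:
    id: int
    node_a: int | None
    node_b: int | None
    points_um: np.ndarray            # (M, 3)
    radii_um: np.ndarray             # (M,)
    is_loop: bool = False
    component: int = -1

    @property
    def curved_length_um(self) -> float:
        if len(self.points_um) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1).sum())

    @property
    def chord_um(self) -> float:
        return float(np.linalg.norm(self.points_um[-1] - self.points_um[0]))


@dataclass
class VesselGraph:
    """Nodes and segments of a skeletonized vascular network."""

    nodes: list[SkeletonNode]
    segments: list[VesselSegment]
    voxel_size_um: tuple[float, float, float]
    shape: tuple[int, int, int]

    @property
    def n_terminal(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "terminal")

    @property
    def n_branching(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "branching")

    @property
    def n_components(self) -> int:
        comps = {n.component for n in self.nodes} | {s.component for s in self.segments}
        return len(comps)

    def node_by_id(self, node_id: int) -> SkeletonNode:
        return next(n for n in self.nodes if n.id == node_id)

    def to_networkx(self):
        """Export as a networkx.MultiGraph (loop segments become self-loops on
        a synthetic anchor node id -1-seg_id)."""
        import networkx as nx

        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, z=n.position_um[0], y=n.position_um[1], x=n.position_um[2],
                       degree=n.degree, kind=n.kind, component=n.component)
        for s in self.segments:
            a = s.node_a if s.node_a is not None else -1 - s.id
            b = s.node_b if s.node_b is not None else -1 - s.id
            if s.node_a is None and a not in g:
                p = s.points_um[0]
                g.add_node(a, z=p[0], y=p[1], x=p[2], degree=0, kind="loop-anchor",
                           component=s.component)
            g.add_edge(a, b, key=s.id, segment_id=s.id, length_um=s.curved_length_um,
                       is_loop=s.is_loop, n_points=len(s.points_um),
                       mean_radius_um=float(np.mean(s.radii_um)))
        return g


# ---------------------------------------------------------------------------
# distance map and thinning


def distance_map(mask: np.ndarray, voxel_size_um) -> DistanceMap:
    """Exact Euclidean distance transform in physical units (anisotropy-aware)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    vs = tuple(float(v) for v in np.broadcast_to(np.atleast_1d(voxel_size_um), (3,)))
    d = ndi.distance_transform_edt(mask, sampling=vs)
    return DistanceMap(d, vs)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving 3D thinning to a one-voxel-thick centerline."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    return _sk_skeletonize(mask).astype(bool)


# ---------------------------------------------------------------------------
# graph construction


def _has_solid_2cube(skel: np.ndarray) -> bool:
    s = skel
    return bool(
        (s[:-1, :-1, :-1] & s[:-1, :-1, 1:] & s[:-1, 1:, :-1] & s[:-1, 1:, 1:]
         & s[1:, :-1, :-1] & s[1:, :-1, 1:] & s[1:, 1:, :-1] & s[1:, 1:, 1:]).any()
    )


def _neighbors_of(vox, skel_set):
    z, y, x = vox
    return [
        (z + dz, y + dy, x + dx)
        for dz, dy, dx in _OFFSETS26
        if (z + dz, y + dy, x + dx) in skel_set
    ]


def _smooth_polyline(pts: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing of interior points; endpoints stay fixed.

    Counteracts the voxel staircase, which otherwise inflates curved length
    (and hence tortuosity) of oblique and curved vessels by several percent.
    """
    if window < 3 or len(pts) <= 2:
        return pts
    half = window // 2
    out = pts.copy()
    for i in range(1, len(pts) - 1):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def build_graph(skeleton: np.ndarray, dmap: DistanceMap,
                smooth_window: int = 3) -> VesselGraph:
    """Organize a thin skeleton into nodes and segments with local radii.

    ``smooth_window`` (odd, default 3) applies light moving-average smoothing
    to segment interior points; 0 or 1 keeps the raw voxel chain.  Raises if
    the input is not one voxel thick (contains a solid 2x2x2 block):
    skeletonize first.
    """
    skel = np.asarray(skeleton, bool)
    if not skel.any():
        raise ValueError("empty skeleton")
    if _has_solid_2cube(skel):
        raise ValueError("input is not one voxel thick: skeletonize first")
    vs = np.asarray(dmap.voxel_size_um, float)
    radius = dmap.data

    nb_count = ndi.correlate(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    cand = skel & (nb_count != 2)
    chain = skel & (nb_count == 2)

    # merge adjacent junction/terminal voxels into single nodes
    cluster_lab, n_clusters = ndi.label(cand, structure=_STRUCT26)

    skel_set = set(map(tuple, np.argwhere(skel)))
    lab_of = lambda v: int(cluster_lab[v])

    # node positions (centroid, um) and radii (mean of member voxels)
    nodes: list[SkeletonNode] = []
    node_radius: dict[int, float] = {}
    if n_clusters:
        idx = np.argwhere(cand)
        labs = cluster_lab[cand]
        for cid in range(1, n_clusters + 1):
            members = idx[labs == cid]
            centroid = members.mean(axis=0) * vs
            nodes.append(SkeletonNode(id=cid - 1, position_um=centroid))
            node_radius[cid - 1] = float(radius[tuple(members.T)].mean())

    segments: list[VesselSegment] = []
    visited: set[tuple[int, int, int]] = set()

    def _emit(node_a, node_b, chain_path):
        pts, rads = [], []
        if node_a is not None:
            pts.append(nodes[node_a].position_um)
            rads.append(node_radius[node_a])
        for v in chain_path:
            pts.append(np.asarray(v, float) * vs)
            rads.append(float(radius[v]))
        if node_b is not None:
            pts.append(nodes[node_b].position_um)
            rads.append(node_radius[node_b])
        segments.append(
            VesselSegment(
                id=len(segments), node_a=node_a, node_b=node_b,
                points_um=np.asarray(pts, float), radii_um=np.asarray(rads, float),
            )
        )

    # 1) segments that contain at least one chain voxel, traced from clusters
    chain_coords = sorted(map(tuple, np.argwhere(chain)))
    for start in chain_coords:
        if start in visited:
            continue
        nbrs = _neighbors_of(start, skel_set)
        cluster_nbrs = [v for v in nbrs if cluster_lab[v]]
        if not cluster_nbrs:
            continue  # pure-cycle voxel, handled below
        visited.add(start)
        node_a = lab_of(cluster_nbrs[0]) - 1
        path = [start]
        if len(cluster_nbrs) == 2:
            node_b = lab_of(cluster_nbrs[1]) - 1
        else:
            prev, cur = start, [v for v in nbrs if not cluster_lab[v]][0]
            node_b = None
            while True:
                if cluster_lab[cur]:
                    node_b = lab_of(cur) - 1
                    break
                visited.add(cur)
                path.append(cur)
                nxt = [v for v in _neighbors_of(cur, skel_set) if v != prev]
                if not nxt:
                    break  # dead end without candidate: cannot happen for nb==2
                prev, cur = cur, nxt[0]
        _emit(node_a, node_b, path)

    # 2) pure cycles: chain voxels never reached from any cluster
    # (adjacent junction voxels always share one cluster, so clusters never
    # touch each other directly and every remaining chain voxel is on a ring)
    for start in chain_coords:
        if start in visited:
            continue
        visited.add(start)
        path = [start]
        prev, cur = start, _neighbors_of(start, skel_set)[0]
        while cur != start:
            visited.add(cur)
            path.append(cur)
            nxt = [v for v in _neighbors_of(cur, skel_set) if v != prev]
            prev, cur = cur, nxt[0]
        pts = np.asarray(path, float) * vs
        pts = np.vstack([pts, pts[:1]])  # close the ring
        rads = np.append(radius[tuple(np.asarray(path).T)], radius[start])
        segments.append(
            VesselSegment(id=len(segments), node_a=None, node_b=None,
                          points_um=pts, radii_um=np.asarray(rads, float), is_loop=True)
        )

    graph = VesselGraph(nodes=nodes, segments=segments,
                        voxel_size_um=tuple(vs), shape=skel.shape)
    _recompute_degrees(graph)
    _dissolve_degree2(graph)
    _relabel(graph)
    if smooth_window and smooth_window >= 3:
        for s in graph.segments:
            s.points_um = _smooth_polyline(s.points_um, smooth_window)
    return graph


# ---------------------------------------------------------------------------
# graph maintenance


def _recompute_degrees(graph: VesselGraph) -> None:
    deg = {n.id: 0 for n in graph.nodes}
    for s in graph.segments:
        if s.node_a is not None:
            deg[s.node_a] += 1
        if s.node_b is not None:
            deg[s.node_b] += 1
    for n in graph.nodes:
        n.degree = deg[n.id]
        n.kind = "branching" if n.degree >= 3 else "terminal"


def _dissolve_degree2(graph: VesselGraph) -> None:
    """Merge the two segments incident to every degree-2 node.

    A degree-2 node whose both incident endpoints belong to the *same*
    segment is a junction-free cycle: the segment becomes a loop.
    """
    changed = True
    while changed:
        changed = False
        _recompute_degrees(graph)
        for node in list(graph.nodes):
            if node.degree != 2:
                continue
            incident = [
                (s, end)
                for s in graph.segments
                for end in ("a", "b")
                if getattr(s, f"node_{end}") == node.id
            ]
            if len(incident) != 2:
                continue
            (s1, e1), (s2, e2) = incident
            if s1 is s2:
                # cycle through a single degree-2 node -> pure loop
                s1.is_loop = True
                s1.node_a = s1.node_b = None
                if np.linalg.norm(s1.points_um[0] - s1.points_um[-1]) > 0:
                    s1.points_um = np.vstack([s1.points_um, s1.points_um[:1]])
                    s1.radii_um = np.append(s1.radii_um, s1.radii_um[0])
            else:
                p1 = s1.points_um if e1 == "b" else s1.points_um[::-1]
                r1 = s1.radii_um if e1 == "b" else s1.radii_um[::-1]
                p2 = s2.points_um if e2 == "a" else s2.points_um[::-1]
                r2 = s2.radii_um if e2 == "a" else s2.radii_um[::-1]
                far1 = s1.node_a if e1 == "b" else s1.node_b
                far2 = s2.node_b if e2 == "a" else s2.node_a
                s1.points_um = np.vstack([p1, p2[1:]])
                s1.radii_um = np.concatenate([r1, r2[1:]])
                s1.node_a, s1.node_b = far1, far2
                graph.segments.remove(s2)
            graph.nodes.remove(node)
            changed = True
            break


def _relabel(graph: VesselGraph) -> None:
    """Renumber ids densely and assign connected-component labels."""
    id_map = {n.id: i for i, n in enumerate(graph.nodes)}
    for n in graph.nodes:
        n.id = id_map[n.id]
    for i, s in enumerate(graph.segments):
        s.id = i
        s.node_a = id_map[s.node_a] if s.node_a is not None else None
        s.node_b = id_map[s.node_b] if s.node_b is not None else None
    # union-find over nodes and loop segments
    n_items = len(graph.nodes) + len(graph.segments)
    parent = list(range(n_items))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        parent[find(a)] = find(b)

    offs = len(graph.nodes)
    for s in graph.segments:
        if s.node_a is not None:
            union(offs + s.id, s.node_a)
        if s.node_b is not None:
            union(offs + s.id, s.node_b)
    roots: dict[int, int] = {}
    for n in graph.nodes:
        r = find(n.id)
        n.component = roots.setdefault(r, len(roots))
    for s in graph.segments:
        r = find(offs + s.id)
        s.component = roots.setdefault(r, len(roots))


def prune_spurs(graph: VesselGraph, min_length_um: float = 0.0) -> VesselGraph:
    """Remove terminal spur segments shorter than ``min_length_um``.

    A spur is a segment with exactly one terminal (degree-1) endpoint.
    Degree-2 nodes created by a removal are dissolved by merging their two
    incident segments; the procedure repeats to a fixed point, so pruning is
    idempotent at a fixed threshold.  ``min_length_um = 0`` (the default)
    leaves the graph unchanged.
    """
    if min_length_um < 0:
        raise ValueError("min_length_um must be >= 0")
    out = VesselGraph(
        nodes=[replace(n, position_um=n.position_um.copy()) for n in graph.nodes],
        segments=[
            replace(s, points_um=s.points_um.copy(), radii_um=s.radii_um.copy())
            for s in graph.segments
        ],
        voxel_size_um=graph.voxel_size_um,
        shape=graph.shape,
    )
    if min_length_um == 0:
        return out
    changed = True
    while changed:
        changed = False
        _recompute_degrees(out)
        deg = {n.id: n.degree for n in out.nodes}
        for s in list(out.segments):
            if s.is_loop or s.node_a is None or s.node_b is None:
                continue
            ends_terminal = (deg.get(s.node_a, 0) == 1, deg.get(s.node_b, 0) == 1)
            if sum(ends_terminal) != 1:
                continue
            if s.curved_length_um < min_length_um:
                term = s.node_a if ends_terminal[0] else s.node_b
                out.segments.remove(s)
                out.nodes = [n for n in out.nodes if n.id != term]
                changed = True
                break
        if changed:
            _dissolve_degree2(out)
    _recompute_degrees(out)
    _relabel(out)
    return out


# ---------------------------------------------------------------------------
# persistence


def save_graph(graph: VesselGraph, out_dir) -> dict:
    """Write the graph as nodes.csv + segments.csv (points JSON-encoded) and
    a GraphML export for network viewers."""
    import json
    from pathlib import Path

    import networkx as nx
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [
            {
                "id": n.id, "z_um": n.position_um[0], "y_um": n.position_um[1],
                "x_um": n.position_um[2], "degree": n.degree, "kind": n.kind,
                "component": n.component,
            }
            for n in graph.nodes
        ],
        columns=["id", "z_um", "y_um", "x_um", "degree", "kind", "component"],
    )
    segments = pd.DataFrame(
        [
            {
                "id": s.id,
                "node_a": -1 if s.node_a is None else s.node_a,
                "node_b": -1 if s.node_b is None else s.node_b,
                "is_loop": s.is_loop,
                "component": s.component,
                "points_um": json.dumps(np.round(s.points_um, 6).tolist()),
                "radii_um": json.dumps(np.round(s.radii_um, 6).tolist()),
            }
            for s in graph.segments
        ],
        columns=["id", "node_a", "node_b", "is_loop", "component", "points_um", "radii_um"],
    )
    meta = {"voxel_size_um": list(graph.voxel_size_um), "shape": list(graph.shape)}
    paths = {
        "nodes": out_dir / "nodes.csv",
        "segments": out_dir / "segments.csv",
        "graphml": out_dir / "graph.graphml",
        "meta": out_dir / "graph.json",
    }
    nodes.to_csv(paths["nodes"], index=False)
    segments.to_csv(paths["segments"], index=False)
    nx.write_graphml(graph.to_networkx(), paths["graphml"])
    paths["meta"].write_text(json.dumps(meta, sort_keys=True))
    return paths


def load_graph(in_dir) -> VesselGraph:
    """Read a graph written by :func:`save_graph` (CSV files are the source)."""
    import json
    from pathlib import Path

    import pandas as pd

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "graph.json").read_text())
    nodes_df = pd.read_csv(in_dir / "nodes.csv")
    segs_df = pd.read_csv(in_dir / "segments.csv")
    nodes = [
        SkeletonNode(
            id=int(r.id), position_um=np.array([r.z_um, r.y_um, r.x_um]),
            degree=int(r.degree), kind=str(r.kind), component=int(r.component),
        )
        for r in nodes_df.itertuples()
    ]
    segments = [
        VesselSegment(
            id=int(r.id),
            node_a=None if r.node_a < 0 else int(r.node_a),
            node_b=None if r.node_b < 0 else int(r.node_b),
            points_um=np.asarray(json.loads(r.points_um), float),
            radii_um=np.asarray(json.loads(r.radii_um), float),
            is_loop=bool(r.is_loop),
            component=int(r.component),
        )
        for r in segs_df.itertuples()
    ]
    return VesselGraph(nodes=nodes, segments=segments,
                       voxel_size_um=tuple(meta["voxel_size_um"]),
                       shape=tuple(meta["shape"]))
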