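"""Medial-axis structure of the root mask.

The root silhouette is reduced to a 1-pixel-wide, 8-connected skeleton whose
pixels carry a medial radius (Euclidean distance to the background).  The
skeleton is abstracted into a graph of tips and junctions joined by pixel
chains, short spurs are pruned, the collar (stem entry point) is located, and
a root-tip path (RTP) is traced from the collar to every tip.  RTPs carry
per-point depth, radius and tangent angle, and underlie the angle, diameter
and length traits.

Conventions: row increases downward, so "depth" is the row coordinate; a
single foreground pixel has distance 1 to the background (pixel-center
metric); tangent angles are absolute degrees from horizontal in [0, 90].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import InvalidInputError

_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance (px) from each foreground pixel to the
    nearest background pixel center; zero on background."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("distance transform of an empty mask")
    return ndimage.distance_transform_edt(mask)


@dataclass
class Skeleton:
    """1-px-wide 8-connected skeleton with per-pixel medial radii."""

    mask: np.ndarray  # boolean, same shape as the source mask
    radii: np.ndarray  # float, medial radius on skeleton pixels, 0 elsewhere

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, np.argwhere(self.mask)))


def skeletonize(mask: np.ndarray, field_: Optional[np.ndarray] = None) -> Skeleton:
    """Topology-preserving thinning of the root mask, with medial radii
    attached from the distance field."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("cannot skeletonize an empty mask")
    if field_ is None:
        field_ = distance_transform(mask)
    skel = _sk_skeletonize(mask)
    radii = np.where(skel, field_, 0.0)
    return Skeleton(mask=skel, radii=radii)


@dataclass
class SkeletonGraph:
    """Graph abstraction of a skeleton.

    Nodes are tips (1 skeleton neighbor), junction clusters (>= 3 neighbors;
    8-adjacent junction pixels are merged into one node) and isolated pixels.
    Edges are maximal degree-2 pixel chains with polyline geometry, length
    (unit and sqrt(2) steps) and per-point medial radii.
    """

    graph: nx.MultiGraph
    skeleton: Skeleton

    def tips(self) -> list[int]:
        return [n for n in self.graph.nodes if self.graph.degree(n) <= 1]

    def junctions(self) -> list[int]:
        return [n for n in self.graph.nodes if self.graph.degree(n) >= 3]

    def node_pos(self, node: int) -> tuple[int, int]:
        return self.graph.nodes[node]["pos"]

    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))


def _polyline_length(poly: np.ndarray) -> float:
    if len(poly) < 2:
        return 0.0
    steps = np.diff(np.asarray(poly, dtype=float), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def build_skeleton_graph(skeleton: Skeleton) -> SkeletonGraph:
    """Abstract the skeleton pixel set into a tip/junction graph."""
    pts = skeleton.pixel_set()
    if not pts:
        raise InvalidInputError("cannot build a graph from an empty skeleton")
    deg = {}
    nbrs = {}
    for p in pts:
        nb = [(p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS8]
        nb = [q for q in nb if q in pts]
        nbrs[p] = nb
        deg[p] = len(nb)

    node_pixels = {p for p in pts if deg[p] != 2}
    # cluster 8-adjacent junction/tip pixels of degree != 2 into single nodes;
    # tips are degree-1 so they only merge when directly touching another node
    # pixel (thick junction cores produced by thinning).
    cluster_of: dict[tuple[int, int], int] = {}
    clusters: list[list[tuple[int, int]]] = []
    for p in sorted(node_pixels):
        if p in cluster_of:
            continue
        cid = len(clusters)
        stack = [p]
        members = []
        cluster_of[p] = cid
        while stack:
            q = stack.pop()
            members.append(q)
            for r in nbrs[q]:
                if r in node_pixels and r not in cluster_of:
                    cluster_of[r] = cid
                    stack.append(r)
        clusters.append(members)

    g = nx.MultiGraph()
    for cid, members in enumerate(clusters):
        mean = np.mean(members, axis=0)
        rep = min(members, key=lambda q: ((q[0] - mean[0]) ** 2 + (q[1] - mean[1]) ** 2, q))
        max_deg = max(deg[q] for q in members)
        kind = "tip" if max_deg == 1 else ("isolated" if max_deg == 0 else "junction")
        g.add_node(cid, pos=rep, pixels=members, kind=kind)

    visited_chain: set[tuple[int, int]] = set()
    direct_seen: set[frozenset] = set()

    def add_edge(cid_a, cid_b, poly):
        poly = np.asarray(poly, dtype=int)
        g.add_edge(
            cid_a,
            cid_b,
            polyline=poly,
            length=_polyline_length(poly),
            radii=skeleton.radii[poly[:, 0], poly[:, 1]],
        )

    for cid, members in enumerate(clusters):
        for p in members:
            for q in nbrs[p]:
                if q in node_pixels:
                    if cluster_of[q] != cid:
                        key = frozenset((p, q))
                        if key not in direct_seen:
                            direct_seen.add(key)
                            add_edge(cid, cluster_of[q], [p, q])
                    continue
                if q in visited_chain:
                    continue
                poly = [p, q]
                visited_chain.add(q)
                prev, cur = p, q
                while cur not in node_pixels:
                    nxt = [r for r in nbrs[cur] if r != prev]
                    if not nxt:
                        break  # dangling chain end (cannot occur for deg-2)
                    prev, cur = cur, nxt[0]
                    poly.append(cur)
                    if cur not in node_pixels:
                        visited_chain.add(cur)
                if poly[-1] in node_pixels:
                    add_edge(cid, cluster_of[poly[-1]], poly)
                else:
                    add_edge(cid, cid, poly)

    # pure cycles: degree-2 pixels not reachable from any node pixel
    leftovers = {p for p in pts if deg[p] == 2} - visited_chain
    # chain interiors adjacent to nodes were visited; anything left belongs to
    # node-free rings
    while leftovers:
        start = min(leftovers)
        cid = g.number_of_nodes()
        g.add_node(cid, pos=start, pixels=[start], kind="cycle")
        poly = [start]
        prev, cur = start, nbrs[start][0]
        while cur != start:
            poly.append(cur)
            leftovers.discard(cur)
            nxt = [r for r in nbrs[cur] if r != prev]
            prev, cur = cur, nxt[0]
        poly.append(start)
        leftovers.discard(start)
        add_edge(cid, cid, poly)

    return SkeletonGraph(graph=g, skeleton=skeleton)


def prune_spurs(sgraph: SkeletonGraph, min_len_px: float = 10.0) -> SkeletonGraph:
    """Iteratively remove tip-terminated edges shorter than
    max(min_len_px, 1.5 * medial radius at their junction), dissolving
    junctions that degrade to degree 2, until a fixpoint is reached.

    The last remaining edge of a component is never removed.
    """
    if min_len_px < 0:
        raise InvalidInputError("min_len_px must be >= 0")
    skel_mask = sgraph.skeleton.mask.copy()
    radii = sgraph.skeleton.radii
    current = sgraph
    while True:
        g = current.graph
        to_remove: list[np.ndarray] = []
        junction_px: set[tuple[int, int]] = set()
        for u, v, data in g.edges(data=True):
            du, dv = g.degree(u), g.degree(v)
            if du == 1 and dv == 1:
                continue  # whole component: keep
            if du != 1 and dv != 1:
                continue  # interior edge
            tip, junc = (u, v) if du == 1 else (v, u)
            jr, jc = current.node_pos(junc)
            threshold = max(min_len_px, 1.5 * float(radii[jr, jc]))
            if data["length"] < threshold:
                to_remove.append(data["polyline"])
                junction_px.update(map(tuple, g.nodes[junc]["pixels"]))
        if not to_remove:
            return current
        for poly in to_remove:
            for r, c in poly:
                if (int(r), int(c)) not in junction_px:
                    skel_mask[int(r), int(c)] = False
        new_skel = Skeleton(mask=skel_mask, radii=np.where(skel_mask, radii, 0.0))
        current = build_skeleton_graph(new_skel)


def find_collar(sgraph: SkeletonGraph, scene=None) -> int:
    """The collar is the topmost skeleton tip (smallest row); ties are broken
    by proximity to the root component's centroid column."""
    g = sgraph.graph
    tips = [n for n in g.nodes if g.degree(n) <= 1]
    if not tips:
        tips = list(g.nodes)
    if not tips:
        raise InvalidInputError("empty skeleton graph")
    if scene is not None and getattr(scene, "root", None) is not None:
        centroid_col = scene.root.centroid[1]
    else:
        px = np.argwhere(sgraph.skeleton.mask)
        centroid_col = float(px[:, 1].mean())
    return min(
        tips,
        key=lambda n: (
            sgraph.node_pos(n)[0],
            abs(sgraph.node_pos(n)[1] - centroid_col),
            sgraph.node_pos(n)[1],
        ),
    )


@dataclass
class RootTipPath:
    """Ordered pixel polyline from the collar to one root tip."""

    points: np.ndarray  # (N, 2) of (row, col)
    radii: np.ndarray  # (N,) medial radii
    tangents: np.ndarray  # (N,) absolute degrees from horizontal in [0, 90]
    arclength_px: float
    node_seq: list[int] = field(default_factory=list)
    node_point_idx: list[int] = field(default_factory=list)
    collar_col: float = 0.0

    @property
    def tip(self) -> tuple[int, int]:
        return tuple(self.points[-1])

    def cumlength(self) -> np.ndarray:
        steps = np.diff(self.points.astype(float), axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(steps[:, 0], steps[:, 1]))])


def _tangent_angles(points: np.ndarray, window: int = 9) -> np.ndarray:
    """Absolute secant angle from horizontal over a centered window of
    ``window`` polyline points (clipped at the ends)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    half = max(1, window // 2)
    angles = np.empty(n)
    for i in range(n):
        a = max(0, i - half)
        b = min(n - 1, i + half)
        dr = abs(pts[b, 0] - pts[a, 0])
        dc = abs(pts[b, 1] - pts[a, 1])
        angles[i] = math.degrees(math.atan2(dr, dc)) if (dr or dc) else 0.0
    return angles


def root_tip_paths(
    sgraph: SkeletonGraph, collar: int, tangent_window: int = 9
) -> list[RootTipPath]:
    """Minimum-arclength path from the collar to every tip, with per-point
    depth (row), medial radius and tangent angle attached."""
    g = sgraph.graph
    if collar not in g:
        raise InvalidInputError("collar is not a node of the graph")
    lengths, node_paths = nx.single_source_dijkstra(g, collar, weight="length")
    collar_col = float(sgraph.node_pos(collar)[1])
    tips = [n for n in g.nodes if g.degree(n) == 1 and n != collar and n in node_paths]
    tips.sort(key=lambda n: sgraph.node_pos(n))
    paths = []
    for tip in tips:
        seq = node_paths[tip]
        points: list[tuple[int, int]] = [sgraph.node_pos(collar)]
        node_point_idx = [0]
        for a, b in zip(seq[:-1], seq[1:]):
            best = min(g[a][b].values(), key=lambda d: d["length"])
            poly = best["polyline"]
            a_pixels = set(map(tuple, g.nodes[a]["pixels"]))
            if tuple(poly[0]) not in a_pixels:
                poly = poly[::-1]
            for pt in map(tuple, poly):
                if points and pt == points[-1]:
                    continue
                points.append(pt)
            node_point_idx.append(len(points) - 1)
        pts = np.asarray(points, dtype=int)
        radii = sgraph.skeleton.radii[pts[:, 0], pts[:, 1]]
        paths.append(
            RootTipPath(
                points=pts,
                radii=radii,
                tangents=_tangent_angles(pts, tangent_window),
                arclength_px=_polyline_length(pts),
                node_seq=list(seq),
                node_point_idx=node_point_idx,
                collar_col=collar_col,
            )
        )
    return paths
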