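"""Skeleton graphs: thinning, pruning, elongation and branch features.

Filament masks are reduced to 1-pixel-wide 8-connected skeletons, turned
into graphs (nodes = endpoints and merged junction clusters, edges =
branches with their pixel paths), cleaned of short terminal spurs, and
extended at their endpoints so the skeleton spans the full filament.
Feature extraction follows the Analyze-Skeleton conventions: junctions are
pixels with >= 3 skeleton neighbours merged when adjacent, endpoints have
exactly one neighbour, and branch lengths count axial steps as 1 px and
diagonal steps as sqrt(2) px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "SkeletonGraph",
    "SkeletonFeatures",
    "skeletonize_mask",
    "prune_skeleton",
    "elongate_skeleton",
    "skeleton_features",
]

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_SQRT2 = math.sqrt(2.0)


def _step_length(a: tuple, b: tuple) -> float:
    return _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _path_length(path: list) -> float:
    return float(sum(_step_length(a, b) for a, b in zip(path, path[1:])))


@dataclass(frozen=True)
class SkeletonFeatures:
    """Analyze-Skeleton-style summary of one skeleton image."""

    n_components: int
    n_branches: int
    n_junctions: int
    n_endpoints: int
    branch_lengths: tuple
    total_length: float
    longest_path: float


@dataclass(frozen=True)
class _Edge:
    node_a: int
    node_b: int
    path: tuple       # ordered pixel path incl. terminal node pixels
    length: float
    terminal: bool    # at least one end is an endpoint node


class _Analysis:
    """Pixel-level graph of a skeleton image."""

    def __init__(self, image: np.ndarray):
        self.image = image
        pixels = set(map(tuple, np.argwhere(image)))
        self.pixels = pixels
        self.neighbors = {
            p: [q for q in ((p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS) if q in pixels]
            for p in pixels
        }
        self.degree = {p: len(nb) for p, nb in self.neighbors.items()}
        self.endpoint_px = {p for p, d in self.degree.items() if d == 1}
        junction_px = {p for p, d in self.degree.items() if d >= 3}
        self.isolated_px = {p for p, d in self.degree.items() if d == 0}

        # merge adjacent junction pixels into junction nodes
        self.node_of: dict = {}
        self.junction_nodes: list[set] = []
        next_id = 0
        seen = set()
        for p in junction_px:
            if p in seen:
                continue
            cluster, stack = set(), [p]
            while stack:
                q = stack.pop()
                if q in cluster:
                    continue
                cluster.add(q)
                stack.extend(r for r in self.neighbors[q] if r in junction_px)
            seen |= cluster
            for q in cluster:
                self.node_of[q] = next_id
            self.junction_nodes.append(cluster)
            next_id += 1
        self.n_junction_nodes = next_id
        self.endpoint_node_ids = set()
        for p in sorted(self.endpoint_px) + sorted(self.isolated_px):
            self.node_of[p] = next_id
            self.endpoint_node_ids.add(next_id)
            next_id += 1
        self.n_nodes = next_id
        self.edges = self._trace_edges()
        self.component_labels, self.n_components = ndimage.label(
            image, structure=np.ones((3, 3), dtype=int))

    def _trace_edges(self) -> list:
        slab = {p for p, d in self.degree.items() if d == 2}
        visited: set = set()
        edges: list[_Edge] = []
        seen_adjacent: set = set()

        def is_node(p: tuple) -> bool:
            return p in self.node_of

        def add_edge(a: tuple, b: tuple, path: list) -> None:
            na, nb = self.node_of[a], self.node_of[b]
            terminal = na in self.endpoint_node_ids or nb in self.endpoint_node_ids
            edges.append(_Edge(na, nb, tuple(path), _path_length(path), terminal))

        for p in sorted(self.node_of):
            for q in self.neighbors[p]:
                if q in slab and q not in visited:
                    path = [p, q]
                    visited.add(q)
                    prev, cur = p, q
                    while cur in slab:
                        nxts = [r for r in self.neighbors[cur] if r != prev]
                        if not nxts:
                            break  # dangling slab (cannot happen for deg 2)
                        nxt = nxts[0]
                        path.append(nxt)
                        if nxt in slab:
                            if nxt in visited:
                                break  # closed walk back into the path
                            visited.add(nxt)
                        prev, cur = cur, nxt
                    if is_node(path[-1]):
                        add_edge(p, path[-1], path)
                    else:  # cycle re-entering itself; anchor both ends at p
                        add_edge(p, p, path)
                elif is_node(q) and self.node_of[q] != self.node_of[p]:
                    key = frozenset((p, q))
                    if key not in seen_adjacent:
                        seen_adjacent.add(key)
                        add_edge(p, q, [p, q])
        # pure cycles: every pixel deg 2, no node pixels
        remaining = slab - visited
        while remaining:
            start = min(remaining)
            path = [start]
            visited.add(start)
            remaining.discard(start)
            prev, cur = None, start
            while True:
                nxts = [r for r in self.neighbors[cur] if r != prev]
                nxt = nxts[0]
                if nxt == start:
                    path.append(start)
                    break
                path.append(nxt)
                visited.add(nxt)
                remaining.discard(nxt)
                prev, cur = cur, nxt
            edges.append(_Edge(-1, -1, tuple(path), _path_length(path), False))
        # isolated pixels: one degenerate zero-length branch each
        for p in self.isolated_px:
            edges.append(_Edge(self.node_of[p], self.node_of[p], (p,), 0.0, True))
        return edges

    def component_of_edge(self, edge: _Edge) -> int:
        p = edge.path[0]
        return int(self.component_labels[p])

    def longest_paths(self) -> dict:
        """Geodesic diameter per component label; also returns, per
        component, the set of edges on one realizing path."""
        graph = nx.Graph()
        edge_lookup: dict = {}
        for e in self.edges:
            if e.node_a < 0:  # pure cycle: farthest geodesic = half the loop
                continue
            if graph.has_edge(e.node_a, e.node_b):
                if e.length < graph[e.node_a][e.node_b]["weight"]:
                    graph[e.node_a][e.node_b]["weight"] = e.length
                    edge_lookup[(e.node_a, e.node_b)] = e
            else:
                graph.add_edge(e.node_a, e.node_b, weight=e.length)
                edge_lookup[(e.node_a, e.node_b)] = e
        diameters: dict = {}
        diameter_edges: dict = {}
        for comp_nodes in nx.connected_components(graph):
            sub = graph.subgraph(comp_nodes)
            best = (0.0, None, None)
            lengths = dict(nx.all_pairs_dijkstra_path_length(sub))
            for a, targets in lengths.items():
                for b, dist in targets.items():
                    if dist > best[0]:
                        best = (dist, a, b)
            any_pixel = next(iter(comp_nodes))
            pixel = self._node_pixel(any_pixel)
            label = int(self.component_labels[pixel])
            diameters[label] = best[0]
            path_edges: set = set()
            if best[1] is not None and best[1] != best[2]:
                node_path = nx.dijkstra_path(sub, best[1], best[2])
                for a, b in zip(node_path, node_path[1:]):
                    e = edge_lookup.get((a, b)) or edge_lookup.get((b, a))
                    if e is not None:
                        path_edges.add(id(e))
            diameter_edges[label] = path_edges
        for e in self.edges:  # components that are pure cycles
            if e.node_a < 0:
                label = self.component_of_edge(e)
                diameters[label] = e.length / 2.0
                diameter_edges[label] = {id(e)}
        return {"diameter": diameters, "edges": diameter_edges}

    def _node_pixel(self, node_id: int) -> tuple:
        for p, nid in self.node_of.items():
            if nid == node_id:
                return p
        raise KeyError(node_id)


@dataclass
class SkeletonGraph:
    """An 8-connected 2D skeleton (1-px wide voxel set) with graph access.

    Lengths are in pixels (axial step 1, diagonal step sqrt(2)); convert to
    nanometres by multiplying with the lateral pixel size.
    """

    image: np.ndarray
    _analysis: _Analysis | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=bool)
        if self.image.ndim != 2:
            raise ValueError("skeleton image must be 2D")

    @property
    def analysis(self) -> _Analysis:
        if self._analysis is None:
            self._analysis = _Analysis(self.image)
        return self._analysis

    @property
    def n_pixels(self) -> int:
        return int(self.image.sum())

    def pixel_set(self) -> set:
        return set(self.analysis.pixels)


def _principal_chord(component: np.ndarray) -> np.ndarray:
    """1-px geodesic path between the component's principal-axis extremes."""
    coords = np.argwhere(component)
    out = np.zeros_like(component)
    centroid = coords.mean(axis=0)
    cov = np.cov(coords.T.astype(float)) + np.eye(2) * 1e-9
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, np.argmax(eigvals)]
    proj = (coords - centroid) @ direction
    start = tuple(coords[int(np.argmin(proj))])
    goal = tuple(coords[int(np.argmax(proj))])
    inside = set(map(tuple, coords))
    # BFS shortest 8-connected path through the component
    frontier = [start]
    parent = {start: None}
    while frontier and goal not in parent:
        nxt = []
        for p in frontier:
            for dr, dc in _OFFSETS:
                q = (p[0] + dr, p[1] + dc)
                if q in inside and q not in parent:
                    parent[q] = p
                    nxt.append(q)
        frontier = nxt
    node = goal if goal in parent else start
    while node is not None:
        out[node] = True
        node = parent[node]
    return out


def skeletonize_mask(mask: np.ndarray) -> SkeletonGraph:
    """Thin a boolean mask to a topology-preserving 1-px skeleton.

    Small compact components can collapse to a single pixel under
    thinning; such components are instead represented by their
    principal-axis chord so that downstream length measures stay defined.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    if not mask.any():
        return SkeletonGraph(np.zeros_like(mask, dtype=bool))
    skel = _sk_skeletonize(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() > 1 and (skel & comp).sum() <= 1:
            skel &= ~comp
            skel |= _principal_chord(comp)
    return SkeletonGraph(skel)


def prune_skeleton(skel: SkeletonGraph, min_branch_px: float) -> SkeletonGraph:
    """Iteratively remove terminal branches shorter than ``min_branch_px``.

    The longest (geodesic diameter) path of each component is never
    removed, so an unbranched skeleton is returned unchanged and pruning
    never deletes or splits a component.  Junction pixels are retained;
    the operation runs to a fixed point and is therefore idempotent.
    """
    if min_branch_px < 0:
        raise ValueError("min_branch_px must be >= 0")
    image = skel.image.copy()
    while True:
        analysis = _Analysis(image)
        keep = analysis.longest_paths()["edges"]
        junction_pixels = set().union(*analysis.junction_nodes) if analysis.junction_nodes else set()
        removed = False
        for e in analysis.edges:
            if not e.terminal or len(e.path) < 2:
                continue
            if e.length >= min_branch_px:
                continue
            if id(e) in keep.get(analysis.component_of_edge(e), set()):
                continue
            for p in e.path:
                if p not in junction_pixels:
                    image[p] = False
            removed = True
        if removed:
            continue
        # junction pixels left behind by removed spurs can be redundant
        # bumps on an otherwise straight path; a thinning pass removes
        # them without changing topology (part of the fixed point, so
        # pruning stays idempotent)
        if image.any():
            thinned = _sk_skeletonize(image)
            if not np.array_equal(thinned, image):
                image = thinned
                continue
        return SkeletonGraph(image)


def elongate_skeleton(skel: SkeletonGraph, mask: np.ndarray) -> SkeletonGraph:
    """Extend each endpoint along its local tangent while inside ``mask``.

    The tangent is a straight line estimated from the last (up to) 5
    skeleton pixels of the terminal branch.  Extension stops at the mask
    boundary or as soon as the next pixel would touch another skeleton
    pixel (so elongation can never create junctions or merge components).
    """
    mask = np.asarray(mask, dtype=bool)
    analysis = skel.analysis
    if not analysis.pixels <= set(map(tuple, np.argwhere(mask))):
        raise ValueError("skeleton must be contained in the mask")
    pixels = set(analysis.pixels)
    shape = skel.image.shape
    unit_offsets = {off: np.array(off) / np.linalg.norm(off) for off in _OFFSETS}

    for endpoint in sorted(analysis.endpoint_px):
        edge = next((e for e in analysis.edges
                     if e.path[0] == endpoint or e.path[-1] == endpoint), None)
        if edge is None:
            continue
        path = list(edge.path if edge.path[0] == endpoint else edge.path[::-1])
        window = path[: min(5, len(path))]
        if len(window) < 2:
            continue
        tangent = np.array(endpoint, dtype=float) - np.array(window[-1], dtype=float)
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent /= norm
        cur, prev = endpoint, window[1]
        for _ in range(10 * max(shape)):
            best, best_dot, best_cuts = None, 0.5, False  # forward steps only
            for off, unit in unit_offsets.items():
                dot = float(unit @ tangent)
                if dot <= best_dot:
                    continue
                cand = (cur[0] + off[0], cur[1] + off[1])
                if not (0 <= cand[0] < shape[0] and 0 <= cand[1] < shape[1]):
                    continue
                if not mask[cand] or cand in pixels:
                    continue
                touching = {(cand[0] + dr, cand[1] + dc) for dr, dc in _OFFSETS}
                others = {t for t in touching if t in pixels and t != cur}
                if not others:
                    best, best_dot, best_cuts = cand, dot, False
                elif others == {prev}:
                    # staircase corner: cand reconnects directly to prev, so
                    # cur is a redundant corner pixel — cut it to stay thin,
                    # provided cur carries nothing else
                    cur_neighbors = {(cur[0] + dr, cur[1] + dc) for dr, dc in _OFFSETS}
                    if {t for t in cur_neighbors if t in pixels} <= {prev, cand}:
                        best, best_dot, best_cuts = cand, dot, True
            if best is None:
                break
            if best_cuts:
                pixels.discard(cur)
            else:
                prev = cur
            pixels.add(best)
            cur = best

    out = np.zeros(shape, dtype=bool)
    for p in pixels:
        out[p] = True
    return SkeletonGraph(out)


def skeleton_features(skel: SkeletonGraph) -> SkeletonFeatures:
    """Count components, branches, junctions and endpoints; sum lengths."""
    analysis = skel.analysis
    branch_lengths = tuple(e.length for e in analysis.edges)
    diameters = analysis.longest_paths()["diameter"] if analysis.pixels else {}
    return SkeletonFeatures(
        n_components=int(analysis.n_components),
        n_branches=len(analysis.edges),
        n_junctions=analysis.n_junction_nodes,
        n_endpoints=len(analysis.endpoint_px),
        branch_lengths=branch_lengths,
        total_length=float(sum(branch_lengths)),
        longest_path=float(max(diameters.values(), default=0.0)),
    )
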