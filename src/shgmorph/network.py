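"""Fiber-network extraction from a binary collagen mask.

The collagen class of a segmented SHG image is reduced to a one-pixel-wide
8-connected skeleton, the skeleton is decomposed into branches between
endpoints and junctions, and branches are re-joined across junctions when
their local tangents continue smoothly — modelling a fiber that *crosses*
another fiber rather than terminating at it.  Each resulting fiber is an
ordered list of skeleton vertices; any vertex shared by two or more fibers
is a cross-link point.

Junctions in digital skeletons are messy: two thick ribbons crossing at an
angle usually skeletonize into two nearby degree-3 pixels joined by a short
bridge instead of one degree-4 pixel.  Bridges shorter than
``merge_junction_px`` are therefore absorbed into a single junction
cluster, so that both fibers can continue through the crossing and share
the cluster pixels (making the cross-link detectable).

Vertex chains traced on a pixel grid overestimate arclength (steps are
quantised to 1 and √2), so by default each fiber's chain is simplified with
a small-tolerance Douglas–Peucker pass that removes pixel-quantisation
zig-zag while pinning endpoints and cross-link vertices.  Pass
``simplify_tol_px=0`` to keep the raw chains, whose consecutive vertices
are exact 8-neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .segmentation import BinaryMask, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "Fiber",
    "FiberNetwork",
    "skeletonize",
    "extract_fibers",
    "detect_crosslinks",
]

Coord = tuple[int, int]

DEFAULT_MIN_LEN_PX = 5.0
DEFAULT_MAX_TURN_DEG = 60.0
DEFAULT_MERGE_JUNCTION_PX = 4.0
DEFAULT_SIMPLIFY_TOL_PX = 0.75


@dataclass(frozen=True)
class Fiber:
    """One extracted collagen fiber: an ordered vertex polyline in pixel
    (row, col) coordinates."""

    vertices: np.ndarray
    id: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("Fiber requires an (N>=2, 2) vertex array")
        object.__setattr__(self, "vertices", v)

    @property
    def length_px(self) -> float:
        """Polyline arclength in pixel units."""
        return float(np.sqrt((np.diff(self.vertices, axis=0) ** 2).sum(axis=1)).sum())

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])


@dataclass(frozen=True)
class FiberNetwork:
    """All fibers extracted from one region plus their cross-link points."""

    fibers: tuple[Fiber, ...]
    crosslinks: frozenset[Coord] = field(default_factory=frozenset)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    @property
    def total_length_px(self) -> float:
        return float(sum(f.length_px for f in self.fibers))


def skeletonize(mask: BinaryMask) -> np.ndarray:
    """One-pixel-wide 8-connected medial skeleton of the collagen class."""
    return _sk_skeletonize(mask.labels)


# ---------------------------------------------------------------------------
# skeleton graph

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _adjacency(skel: np.ndarray) -> dict[Coord, list[Coord]]:
    """8-neighbour adjacency over skeleton pixels, with diagonal edges
    dropped whenever the two pixels already share a cardinal neighbour
    (avoids spurious triangles that inflate junction degrees)."""
    pts = set(map(tuple, np.argwhere(skel)))
    adj: dict[Coord, list[Coord]] = {p: [] for p in pts}
    for (r, c) in pts:
        for dr, dc in _N8:
            q = (r + dr, c + dc)
            if q not in pts:
                continue
            if dr != 0 and dc != 0:
                # diagonal: skip if a cardinal stepping stone exists
                if (r, c + dc) in pts or (r + dr, c) in pts:
                    continue
            adj[(r, c)].append(q)
    return adj


def _arclength(path: Sequence[Coord]) -> float:
    a = np.asarray(path, dtype=float)
    if len(a) < 2:
        return 0.0
    return float(np.sqrt((np.diff(a, axis=0) ** 2).sum(axis=1)).sum())


def _trace_branches(
    adj: dict[Coord, list[Coord]]
) -> tuple[list[list[Coord]], list[list[Coord]]]:
    """Decompose the skeleton graph into branches between node pixels
    (degree != 2) and pure cycles (closed chains of degree-2 pixels)."""
    deg = {p: len(nbs) for p, nbs in adj.items()}
    nodes = {p for p, d in deg.items() if d != 2}
    seen: set[tuple[Coord, Coord]] = set()
    branches: list[list[Coord]] = []

    def walk(start: Coord, first: Coord) -> list[Coord]:
        path = [start, first]
        seen.add((start, first))
        seen.add((first, start))
        while path[-1] not in nodes:
            cur, prev = path[-1], path[-2]
            nxt = [q for q in adj[cur] if q != prev]
            if not nxt:  # safety: dead end that slipped classification
                break
            q = nxt[0]
            if (cur, q) in seen:
                break
            seen.add((cur, q))
            seen.add((q, cur))
            path.append(q)
        return path

    for p in sorted(nodes):
        for q in sorted(adj[p]):
            if (p, q) not in seen:
                branches.append(walk(p, q))

    # cycles: any remaining untraversed edges live on closed deg-2 chains
    cycles: list[list[Coord]] = []
    for p in sorted(adj):
        if p in nodes:
            continue
        for q in adj[p]:
            if (p, q) not in seen:
                path = walk(p, q)
                if len(path) > 2 and path[-1] in adj[path[0]]:
                    path.append(path[0])
                cycles.append(path)
    return branches, cycles


# ---------------------------------------------------------------------------
# junction clusters


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _junction_clusters(
    adj: dict[Coord, list[Coord]],
    branches: list[list[Coord]],
    merge_junction_px: float,
) -> tuple[dict[Coord, Coord], dict[Coord, set[Coord]], list[list[Coord]]]:
    """Group junction pixels into clusters; absorb short junction-junction
    bridges into their clusters.  Returns (pixel -> cluster root,
    cluster root -> pixel set, surviving branches)."""
    deg = {p: len(nbs) for p, nbs in adj.items()}
    jpx = {p for p, d in deg.items() if d >= 3}
    uf = _UnionFind()
    for p in jpx:
        uf.find(p)
        for q in adj[p]:
            if q in jpx:
                uf.union(p, q)

    extra: dict[Coord, set[Coord]] = {}
    kept: list[list[Coord]] = []
    for path in branches:
        a, b = path[0], path[-1]
        if (
            a in jpx
            and b in jpx
            and _arclength(path) <= merge_junction_px
        ):
            uf.union(a, b)
            for p in path[1:-1]:
                extra.setdefault(uf.find(a), set()).add(p)
        else:
            kept.append(path)

    cluster_of: dict[Coord, Coord] = {p: uf.find(p) for p in jpx}
    members: dict[Coord, set[Coord]] = {}
    for p, root in cluster_of.items():
        members.setdefault(root, set()).add(p)
    for root, pts in extra.items():
        final = uf.find(root)
        members.setdefault(final, set()).update(pts)
        for p in pts:
            cluster_of[p] = final
    # re-root membership after late unions
    final_members: dict[Coord, set[Coord]] = {}
    for root, pts in members.items():
        final_members.setdefault(uf.find(root), set()).update(pts)
    cluster_of = {p: uf.find(r) for p, r in cluster_of.items()}
    return cluster_of, final_members, kept


# ---------------------------------------------------------------------------
# tangents and junction pairing

_TANGENT_PTS = 5  # vertices used in the least-squares tangent fit


def _end_tangent(path: list[Coord], end: int) -> np.ndarray:
    """Unit tangent at one branch end, pointing *away* from that end into
    the branch, from a least-squares line over the nearest vertices."""
    pts = np.asarray(path[: _TANGENT_PTS] if end == 0 else path[-_TANGENT_PTS:][::-1],
                     dtype=float)
    if len(pts) == 2:
        d = pts[1] - pts[0]
    else:
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        d = vt[0]
        if np.dot(d, pts[-1] - pts[0]) < 0:
            d = -d
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.array([1.0, 0.0])


def _pair_ends(
    ends: list[tuple[int, int, Coord, np.ndarray]], max_turn_deg: float
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Greedy smallest-turn pairing of branch ends at one junction.

    ``ends`` holds (branch id, end index, terminal pixel, outward tangent);
    two ends continue into each other when their outward tangents are
    nearly opposite.  Ties broken by terminal-coordinate lexicographic
    order, so the result is independent of input order.
    """
    cands = []
    for i in range(len(ends)):
        for j in range(i + 1, len(ends)):
            bi, ei, pi, ti = ends[i]
            bj, ej, pj, tj = ends[j]
            if bi == bj:
                continue  # a branch does not continue into itself
            cosang = float(np.clip(-np.dot(ti, tj), -1.0, 1.0))
            turn = float(np.degrees(np.arccos(cosang)))
            # strict: three branches at mutual 120 deg (turn exactly 60)
            # must not join under the conventional 60-degree limit; the
            # epsilon absorbs arccos rounding at the boundary
            if turn < max_turn_deg - 1e-6:
                key = (turn, min(pi, pj), max(pi, pj))
                cands.append((key, (bi, ei), (bj, ej)))
    cands.sort(key=lambda t: t[0])
    used: set[tuple[int, int]] = set()
    pairs = []
    for _, a, b in cands:
        if a in used or b in used:
            continue
        used.add(a)
        used.add(b)
        pairs.append((a, b))
    return pairs


def _cluster_path(
    adj: dict[Coord, list[Coord]], cluster: set[Coord], a: Coord, b: Coord
) -> list[Coord]:
    """Shortest pixel path from a to b staying inside the junction cluster
    (BFS; a and b are cluster pixels)."""
    if a == b:
        return [a]
    from collections import deque

    prev: dict[Coord, Coord] = {a: a}
    dq = deque([a])
    while dq:
        cur = dq.popleft()
        for q in adj[cur]:
            if q in cluster and q not in prev:
                prev[q] = cur
                if q == b:
                    dq.clear()
                    break
                dq.append(q)
    if b not in prev:
        return [a, b]  # disconnected cluster (should not happen)
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    return path[::-1]


# ---------------------------------------------------------------------------
# Douglas–Peucker simplification


def _dp_simplify(pts: np.ndarray, tol: float) -> np.ndarray:
    """Classic Douglas–Peucker on an open polyline; keeps first/last."""
    if len(pts) <= 2 or tol <= 0:
        return pts
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        a, b = pts[i], pts[j]
        ab = b - a
        nab = np.linalg.norm(ab)
        seg = pts[i + 1 : j]
        if nab == 0:
            d = np.linalg.norm(seg - a, axis=1)
        else:
            u = ab / nab
            rel = seg - a
            d = np.abs(u[0] * rel[:, 1] - u[1] * rel[:, 0])
        k = int(np.argmax(d))
        if d[k] > tol:
            keep[i + 1 + k] = True
            stack.append((i, i + 1 + k))
            stack.append((i + 1 + k, j))
    return pts[keep]


def _simplify_chain(
    path: list[Coord], anchors: set[Coord], tol: float
) -> np.ndarray:
    """Simplify a vertex chain while pinning anchor vertices (fiber ends
    and cross-link points)."""
    pts = np.asarray(path, dtype=float)
    if tol <= 0 or len(path) <= 2:
        return pts
    anchor_idx = [0] + [
        i for i in range(1, len(path) - 1) if path[i] in anchors
    ] + [len(path) - 1]
    pieces: list[np.ndarray] = []
    for a, b in zip(anchor_idx[:-1], anchor_idx[1:]):
        simp = _dp_simplify(pts[a : b + 1], tol)
        pieces.append(simp if not pieces else simp[1:])
    return np.vstack(pieces)


# ---------------------------------------------------------------------------
# main extraction


def extract_fibers(
    skeleton: np.ndarray,
    min_len_px: float = DEFAULT_MIN_LEN_PX,
    max_turn_deg: float = DEFAULT_MAX_TURN_DEG,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    merge_junction_px: float = DEFAULT_MERGE_JUNCTION_PX,
    simplify_tol_px: float = DEFAULT_SIMPLIFY_TOL_PX,
) -> FiberNetwork:
    """Decompose a 1-px skeleton into individual fibers and cross-links.

    At every junction, branch ends whose tangents continue within
    ``max_turn_deg`` are greedily joined (smallest turn first) so a fiber
    tracks straight through a crossing; unjoined branches become separate
    fibers.  Fibers shorter than ``min_len_px`` (arclength, pixels) are
    discarded.  Cross-links are detected on the full-resolution chains
    before any simplification.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if skeleton.sum() == 0:
        return FiberNetwork(fibers=(), crosslinks=frozenset(),
                            pixel_size_um=pixel_size_um)
    adj = _adjacency(skeleton)
    branches, cycles = _trace_branches(adj)
    cluster_of, members, branches = _junction_clusters(
        adj, branches, merge_junction_px
    )

    # ends per junction cluster
    ends_at: dict[Coord, list[tuple[int, int, Coord, np.ndarray]]] = {}
    end_cluster: dict[tuple[int, int], Coord] = {}
    for bid, path in enumerate(branches):
        for end, term in ((0, path[0]), (1, path[-1])):
            root = cluster_of.get(term)
            if root is not None:
                ends_at.setdefault(root, []).append(
                    (bid, end, term, _end_tangent(path, end))
                )
                end_cluster[(bid, end)] = root

    partner: dict[tuple[int, int], tuple[int, int]] = {}
    for root in sorted(ends_at):
        for a, b in _pair_ends(ends_at[root], max_turn_deg):
            partner[a] = b
            partner[b] = a

    # assemble chains of branches
    assembled: list[list[Coord]] = []
    visited: set[int] = set()

    def branch_path(bid: int, start_end: int) -> list[Coord]:
        p = branches[bid]
        return list(p) if start_end == 0 else list(p[::-1])

    def glue(chain: list[Coord], nxt: list[Coord], root: Coord) -> list[Coord]:
        a, b = chain[-1], nxt[0]
        if a == b:
            return chain + nxt[1:]
        cpath = _cluster_path(adj, members.get(root, {a, b}) | {a, b}, a, b)
        return chain + cpath[1:] + nxt[1:]

    for bid in range(len(branches)):
        if bid in visited:
            continue
        # find an unpaired starting end, else it is a closed chain
        start_end = 0
        if (bid, 0) in partner and (bid, 1) not in partner:
            start_end = 1
        visited.add(bid)
        chain = branch_path(bid, start_end)
        cur = (bid, 1 - start_end)
        while cur in partner:
            nb, ne = partner[cur]
            if nb in visited:
                break  # closed loop of branches
            visited.add(nb)
            chain = glue(chain, branch_path(nb, ne), end_cluster[cur])
            cur = (nb, 1 - ne)
        assembled.append(chain)

    assembled.extend(cycles)

    # drop short fibers; orient from the lexicographically smaller endpoint
    paths: list[list[Coord]] = []
    for path in assembled:
        if len(path) < 2 or _arclength(path) < min_len_px:
            continue
        if tuple(path[-1]) < tuple(path[0]):
            path = path[::-1]
        paths.append(path)

    # cross-links on full-resolution chains
    owner: dict[Coord, set[int]] = {}
    for fid, path in enumerate(paths):
        for p in set(path):
            owner.setdefault(p, set()).add(fid)
    crosslinks = frozenset(p for p, fids in owner.items() if len(fids) >= 2)

    fibers = []
    for fid, path in enumerate(paths):
        verts = _simplify_chain(path, crosslinks, simplify_tol_px)
        fibers.append(Fiber(vertices=verts, id=fid))
    return FiberNetwork(
        fibers=tuple(fibers), crosslinks=crosslinks, pixel_size_um=pixel_size_um
    )


def detect_crosslinks(network: FiberNetwork) -> FiberNetwork:
    """Recompute cross-links as the unique vertex coordinates shared by at
    least two distinct fibers (each coordinate counted once)."""
    owner: dict[Coord, set[int]] = {}
    for f in network.fibers:
        for v in {(int(round(r)), int(round(c))) for r, c in f.vertices}:
            owner.setdefault(v, set()).add(f.id)
    links = frozenset(p for p, fids in owner.items() if len(fids) >= 2)
    return FiberNetwork(
        fibers=network.fibers, crosslinks=links, pixel_size_um=network.pixel_size_um
    )
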