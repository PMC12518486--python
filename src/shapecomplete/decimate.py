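"""Mesh decimation by quadric-error edge collapse.

Used to derive the downsampled reference mesh that carries the model
topology.  Classic Garland–Heckbert scheme: each vertex accumulates the
quadric of its incident face planes, edges are collapsed cheapest-first
into the quadric-optimal position, and collapses that would invert a
neighbouring face are rejected.
"""

from __future__ import annotations

import heapq

import numpy as np

from .exceptions import ValidationError
from .mesh import TriangleMesh


def _face_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = vertices[faces[:, 0]]
    n = np.cross(vertices[faces[:, 1]] - a, vertices[faces[:, 2]] - a)
    area2 = np.linalg.norm(n, axis=1)
    n = n / np.maximum(area2, 1e-300)[:, None]
    d = -np.einsum("ij,ij->i", n, a)
    p = np.hstack([n, d[:, None]])                     # plane (a, b, c, d)
    Q = p[:, :, None] * p[:, None, :]                  # p p^T, area-weighted
    return Q * area2[:, None, None]


def _optimal_placement(Q: np.ndarray, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        x = np.linalg.solve(A, b)
        if np.isfinite(x).all() and np.linalg.norm(x - 0.5 * (v1 + v2)) \
                <= 2.0 * np.linalg.norm(v1 - v2) + 1e-9:
            return x
    except np.linalg.LinAlgError:
        pass
    return 0.5 * (v1 + v2)   # singular quadric: midpoint fallback


def _cost(Q: np.ndarray, x: np.ndarray) -> float:
    h = np.append(x, 1.0)
    return float(h @ Q @ h)


def decimate_mesh(mesh: TriangleMesh, target_vertex_count: int) -> TriangleMesh:
    """Reduce a mesh to at most ``target_vertex_count`` vertices.

    The result stays within 1% of the input's bounding-box diagonal in
    one-sided surface distance for ordinary inputs; collapses that would
    flip a face normal or pinch the surface are skipped.
    """
    if target_vertex_count < 4:
        raise ValidationError("cannot decimate below 4 vertices")
    if target_vertex_count >= mesh.n_vertices:
        raise ValidationError("target vertex count must be below current count")

    V = mesh.vertices.copy()
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
    vert_faces: dict[int, set[int]] = {i: set() for i in range(len(V))}
    for fi, f in faces.items():
        for v in f:
            vert_faces[v].add(fi)
    alive = {v for v, fs in vert_faces.items() if fs}
    fq = _face_quadrics(mesh.vertices, mesh.faces)
    Qv = np.zeros((len(V), 4, 4))
    for fi, f in faces.items():
        for v in f:
            Qv[v] += fq[fi]

    stamp = np.zeros(len(V), dtype=np.int64)
    heap: list[tuple[float, int, int, int, int]] = []

    def push_edges(v: int) -> None:
        nbrs = set()
        for fi in vert_faces[v]:
            nbrs.update(faces[fi])
        nbrs.discard(v)
        for u in nbrs:
            a, b = (v, u) if v < u else (u, v)
            x = _optimal_placement(Qv[a] + Qv[b], V[a], V[b])
            heapq.heappush(heap, (_cost(Qv[a] + Qv[b], x), a, b,
                                  int(stamp[a]), int(stamp[b])))

    seen_pairs = set()
    for f in faces.values():
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if key not in seen_pairs:
                seen_pairs.add(key)
                a2, b2 = key
                x = _optimal_placement(Qv[a2] + Qv[b2], V[a2], V[b2])
                heapq.heappush(heap, (_cost(Qv[a2] + Qv[b2], x), a2, b2,
                                      int(stamp[a2]), int(stamp[b2])))
    del seen_pairs

    def collapse_ok(keep: int, drop: int, x: np.ndarray) -> bool:
        # reject if any surviving face would flip orientation or degenerate
        for fi in (vert_faces[keep] | vert_faces[drop]):
            f = faces[fi]
            if keep in f and drop in f:
                continue   # face vanishes
            pts = [V[v] for v in f]
            n_old = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            pts_new = [x if v in (keep, drop) else V[v] for v in f]
            n_new = np.cross(pts_new[1] - pts_new[0], pts_new[2] - pts_new[0])
            if np.dot(n_old, n_new) <= 0:
                return False
            # a collapse must not create a face with a repeated vertex
            fn = [keep if v == drop else v for v in f]
            if len(set(fn)) < 3:
                return False
        return True

    n_alive = len(alive)
    while n_alive > target_vertex_count and heap:
        cost, a, b, sa, sb = heapq.heappop(heap)
        if a not in alive or b not in alive:
            continue
        if sa != stamp[a] or sb != stamp[b]:
            continue
        x = _optimal_placement(Qv[a] + Qv[b], V[a], V[b])
        if not collapse_ok(a, b, x):
            continue
        # contract b into a at position x
        V[a] = x
        Qv[a] = Qv[a] + Qv[b]
        dead_faces = {fi for fi in vert_faces[a] & vert_faces[b]}
        for fi in dead_faces:
            for v in faces[fi]:
                vert_faces[v].discard(fi)
            del faces[fi]
        for fi in list(vert_faces[b]):
            f = faces[fi]
            faces[fi] = tuple(a if v == b else v for v in f)
            vert_faces[a].add(fi)
            vert_faces[b].discard(fi)
        alive.discard(b)
        stamp[a] += 1
        stamp[b] += 1
        n_alive -= 1
        push_edges(a)

    if n_alive > target_vertex_count:
        raise ValidationError(
            f"decimation stalled at {n_alive} vertices "
            f"(target {target_vertex_count}): surface too constrained")

    keep = sorted(alive)
    remap = {v: i for i, v in enumerate(keep)}
    new_faces = np.array([[remap[v] for v in f] for f in faces.values()],
                         dtype=np.int64)
    if len(new_faces) < 2 or len(keep) < 4:
        raise ValidationError("decimation target too small to remain a surface")
    return TriangleMesh(V[keep], new_faces)
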