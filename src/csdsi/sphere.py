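"""Sphere tessellation utilities (subdivided icosahedron)."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import trimesh
from scipy.spatial import cKDTree


@lru_cache(maxsize=8)
def icosphere(subdivisions: int = 3):
    """Unit icosphere vertices, faces and vertex adjacency.

    Returns ``(directions, faces, neighbors, antipode)`` where
    ``neighbors[i]`` lists the mesh-adjacent vertex indices of vertex i
    and ``antipode[i]`` is the index of the vertex opposite -directions[i]
    (the icosphere is centrosymmetric).  subdivisions=3 gives 642
    antipodally-paired vertices.
    """
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.asarray(mesh.faces, dtype=int)

    neighbors: list[set[int]] = [set() for _ in range(len(verts))]
    for a, b, c in faces:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))
    neighbors_t = tuple(tuple(sorted(s)) for s in neighbors)

    tree = cKDTree(verts)
    dist, antipode = tree.query(-verts)
    if dist.max() > 1e-8:
        raise RuntimeError("icosphere is not antipodally symmetric")
    return verts, faces, neighbors_t, antipode.astype(int)


def angle_between_lines(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between direction lines (sign-free), in [0, 90]."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(c, 1.0))))
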