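"""Icosphere tessellations and angular utilities.

Reconstruction, peak extraction and tracking all operate on nested midpoint
subdivisions of the regular icosahedron: 12, 42, 162 and 642 vertices at
levels 0--3.  The subdivision keeps each level's vertices as a prefix of the
next level's vertex array, and every level's vertex set is closed under
negation, so antipodal bookkeeping is exact (bitwise, not just within
tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphereTessellation",
    "icosphere",
    "angle_between",
    "axial_angle",
    "antipodal_fold",
]

MAX_LEVEL = 4


@dataclass(frozen=True)
class SphereTessellation:
    """A subdivided icosahedron projected onto the unit sphere.

    Attributes
    ----------
    level : int
        Subdivision depth (0 = regular icosahedron).
    vertices : (n, 3) ndarray
        Unit vectors; vertex order is deterministic and nested across levels.
    faces : (m, 3) ndarray of int
        Triangle vertex indices.
    neighbors : tuple of ndarray
        For each vertex, the sorted indices of edge-connected vertices.
    """

    level: int
    vertices: np.ndarray
    faces: np.ndarray
    neighbors: tuple

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def _base_icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return verts, faces


def _subdivide(verts, faces):
    # Midpoint subdivision; new vertices are appended after the old ones so
    # lower levels are index-prefixes of higher levels.
    verts = [v for v in verts]
    cache: dict = {}

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        k = cache.get(key)
        if k is None:
            m = verts[i] + verts[j]
            m = m / np.linalg.norm(m)
            verts.append(m)
            k = len(verts) - 1
            cache[key] = k
        return k

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts), np.array(new_faces, dtype=int)


def _neighbors_from_faces(n_vertices: int, faces: np.ndarray) -> tuple:
    adj = [set() for _ in range(n_vertices)]
    for a, b, c in faces:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return tuple(np.array(sorted(s), dtype=int) for s in adj)


def icosphere(level: int) -> SphereTessellation:
    """Build the icosphere at the given subdivision level.

    Levels 0--3 give 12, 42, 162 and 642 vertices: the starting points for
    peak search (level 1), the deconvolution basis directions (level 2) and
    the PDF evaluation grid (level 3).
    """
    if not isinstance(level, (int, np.integer)) or isinstance(level, bool):
        raise ValueError(f"level must be an integer, got {level!r}")
    if level < 0 or level > MAX_LEVEL:
        raise ValueError(f"level must be in [0, {MAX_LEVEL}], got {level}")
    verts, faces = _base_icosahedron()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
    return SphereTessellation(
        level=int(level),
        vertices=verts,
        faces=faces,
        neighbors=_neighbors_from_faces(len(verts), faces),
    )


def _checked_unit(u, name: str) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    n = float(np.linalg.norm(u))
    if n < 1e-12:
        raise ValueError(f"{name} has zero norm")
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"{name} must be unit-norm (|norm-1| <= 1e-6), got norm {n}")
    return u


def angle_between(u, v) -> float:
    """Angle between two unit vectors, in degrees in [0, 180]."""
    u = _checked_unit(u, "u")
    v = _checked_unit(v, "v")
    d = float(np.clip(u @ v, -1.0, 1.0))
    return float(np.degrees(np.arccos(d)))


def axial_angle(u, v) -> float:
    """Angle between two axes (sign-invariant), in degrees in [0, 90]."""
    a = angle_between(u, v)
    return min(a, 180.0 - a)


def antipodal_fold(u, tol: float = 1e-9) -> np.ndarray:
    """Map a unit vector into the canonical hemisphere.

    Returns ``u`` or ``-u`` such that the last coordinate whose magnitude
    exceeds ``tol`` is positive.  Idempotent; directions are treated as axes
    (fiber orientations have no polarity).
    """
    u = np.asarray(u, dtype=float)
    for c in (u[2], u[1], u[0]):
        if abs(c) > tol:
            return u.copy() if c > 0 else -u
    return u.copy()
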