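"""Triangle-mesh container, validation, and analytic fixture meshes.

The analysed surface is the inner cortical-plate boundary, reconstructed
elsewhere as a closed genus-0 triangulation in mm world coordinates.  This
module provides the in-memory mesh type plus two analytic fixtures used
throughout the test-suite and the synthetic studies: a subdivided icosphere
(matching the standard 40,962-vertex / 81,920-triangle surface resolution)
and a "sulcated" sphere with a pit of known depth, which gives sulcal-depth
computations a constructed ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


#: Subdivision level reproducing the standard cortical surface resolution
#: (40,962 vertices, 81,920 triangles): 10 * 4**6 + 2 and 20 * 4**6.
STANDARD_SUBDIVISIONS = 6


class MeshResourceError(ValueError):
    """Requested mesh would be unreasonably large."""


class MeshValidationError(ValueError):
    """Mesh violates a structural invariant (open, non-manifold, degenerate)."""


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulated surface in mm coordinates.

    Faces are triples of 0-based vertex indices, counter-clockwise when
    viewed from outside.
    """

    vertices: np.ndarray  # (V, 3) float64
    faces: np.ndarray  # (F, 3) int64

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError("vertices must be (V, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError("faces must be (F, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshValidationError("face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, shape (E, 2), sorted per row."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def face_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def validate(self, require_closed: bool = True, area_eps: float = 1e-12) -> None:
        """Check structural invariants; raise :class:`MeshValidationError`.

        ``require_closed`` additionally demands every edge be shared by
        exactly two faces (closed manifold).
        """
        areas = self.face_areas()
        bad = np.flatnonzero(areas <= area_eps)
        if bad.size:
            raise MeshValidationError(
                f"degenerate (zero-area) faces: {bad[:10].tolist()}"
            )
        if require_closed:
            e = np.sort(
                self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
            )
            uniq, counts = np.unique(e, axis=0, return_counts=True)
            offending = uniq[counts != 2]
            if offending.size:
                raise MeshValidationError(
                    "mesh is not a closed 2-manifold; edges not shared by "
                    f"exactly 2 faces: {offending[:10].tolist()}"
                )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to a sphere.

    Vertex count is ``10 * 4**s + 2`` and face count ``20 * 4**s``; at
    ``s = STANDARD_SUBDIVISIONS = 6`` this reproduces the standard
    40,962-vertex, 81,920-triangle cortical surface resolution.
    """
    if subdivisions < 0 or int(subdivisions) != subdivisions:
        raise ValueError("subdivisions must be a non-negative integer")
    if subdivisions > 8:
        raise MeshResourceError(
            f"subdivisions={subdivisions} would create "
            f"{20 * 4 ** subdivisions:,} faces; maximum supported is 8"
        )
    if radius <= 0:
        raise ValueError("radius must be positive")
    m = trimesh.creation.icosphere(subdivisions=int(subdivisions), radius=float(radius))
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


def make_sulcated_sphere(
    radius: float,
    pit_depth: float,
    pit_angular_radius: float,
    seed: int | None = None,
    subdivisions: int = 5,
    center: np.ndarray | None = None,
) -> TriangleMesh:
    """Icosphere with a smooth radial pit of known maximum depth.

    Vertices within ``pit_angular_radius`` of the pit axis are displaced
    radially inward by ``pit_depth * cos(pi/2 * theta/theta0)**2``, a smooth
    profile that vanishes (with zero slope) at the pit rim.  The pit axis is
    ``center`` if given, otherwise a uniform random direction from ``seed``
    (``+z`` when both are omitted).  The result stays star-shaped, hence
    closed and manifold.
    """
    if not 0 <= pit_depth:
        raise MeshValidationError("pit_depth must be non-negative")
    if pit_depth >= radius:
        raise MeshValidationError(
            "pit_depth must be smaller than radius (self-intersecting pit)"
        )
    if not 0 < pit_angular_radius < np.pi:
        raise MeshValidationError("pit_angular_radius must lie in (0, pi)")
    base = make_icosphere(subdivisions, radius)
    if pit_depth == 0:
        return base
    if center is None:
        if seed is None:
            axis = np.array([0.0, 0.0, 1.0])
        else:
            rng = np.random.default_rng(seed)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
    else:
        axis = np.asarray(center, dtype=float)
        axis = axis / np.linalg.norm(axis)

    v = base.vertices.copy()
    r = np.linalg.norm(v, axis=1)
    unit = v / r[:, None]
    theta = np.arccos(np.clip(unit @ axis, -1.0, 1.0))
    inside = theta < pit_angular_radius
    profile = np.zeros(len(v))
    profile[inside] = pit_depth * np.cos(
        0.5 * np.pi * theta[inside] / pit_angular_radius
    ) ** 2
    v = unit * (r - profile)[:, None]
    out = TriangleMesh(v, base.faces)
    out.validate()
    return out


def pit_apex_vertex(mesh: TriangleMesh, axis: np.ndarray | None = None) -> int:
    """Index of the vertex closest to the pit axis (default ``+z``)."""
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    unit = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
    return int(np.argmax(unit @ axis))
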