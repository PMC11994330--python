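"""Cortical surface metrics: vertex area, mean curvature, sulcal depth.

Three per-vertex fields summarise folding morphology:

* **surface area** -- the mixed Voronoi area of each vertex (cotangent
  Voronoi cell for non-obtuse triangles, half/quarter split for obtuse
  ones), which partitions the total mesh area exactly;
* **absolute mean curvature** ``|H|`` (1/mm) -- from the discrete
  cotangent Laplace-Beltrami mean-curvature normal over the same mixed
  patch; on a sphere of radius r this recovers 1/r;
* **sulcal depth** (mm) -- the length of the shortest path from a vertex
  to the cerebral hull constrained to exterior space, computed on a
  voxelisation of the mesh: the hull is a morphological closing of the
  interior mask, and depth is a multi-source geodesic distance through
  non-interior voxels seeded just outside the hull.

Per-region summaries (area sum, area-weighted depth and curvature means)
are produced by :func:`aggregate_regions`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from fetalsurf.mesh import MeshValidationError, TriangleMesh

#: 30 cortical regions per hemisphere: the adult Desikan parcellation with
#: small or immature parcels merged for the fetal brain (one cingulate
#: parcel, banks of STS folded into the temporal gyri, entorhinal into the
#: parahippocampal gyrus).
REGION_NAMES_30 = (
    "precentral",
    "postcentral",
    "paracentral",
    "superiorfrontal",
    "caudalmiddlefrontal",
    "rostralmiddlefrontal",
    "parsopercularis",
    "parstriangularis",
    "parsorbitalis",
    "lateralorbitofrontal",
    "medialorbitofrontal",
    "frontalpole",
    "superiorparietal",
    "inferiorparietal",
    "supramarginal",
    "precuneus",
    "cuneus",
    "pericalcarine",
    "lingual",
    "lateraloccipital",
    "fusiform",
    "inferiortemporal",
    "middletemporal",
    "superiortemporal",
    "transversetemporal",
    "temporalpole",
    "parahippocampal",
    "insula",
    "cingulate",
    "medialfrontal",
)

HEMISPHERES = ("L", "R")


def all_region_ids() -> list[str]:
    """The 60 region identifiers, ``{L,R}_{name}``."""
    return [f"{h}_{n}" for h in HEMISPHERES for n in REGION_NAMES_30]


@dataclass(frozen=True)
class Parcellation:
    """Per-vertex region labels plus the region lookup table.

    ``labels`` holds one region identifier (e.g. ``"L_precentral"``) per
    vertex.  ``table`` maps identifier -> (hemisphere, region name,
    1-based index within hemisphere).
    """

    labels: np.ndarray  # (V,) of str
    table: dict[str, tuple[str, str, int]]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        per_hemi: dict[str, int] = {}
        for _, (hemi, _, _) in self.table.items():
            per_hemi[hemi] = per_hemi.get(hemi, 0) + 1
        for hemi, n in per_hemi.items():
            if n > 30:
                raise ValueError(f"hemisphere {hemi} has {n} > 30 regions")
        unknown = set(np.unique(labels)) - set(self.table)
        if unknown:
            raise ValueError(f"labels not in region table: {sorted(unknown)[:5]}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.table)


def standard_region_table(
    names: tuple[str, ...] = REGION_NAMES_30,
) -> dict[str, tuple[str, str, int]]:
    table = {}
    for hemi in HEMISPHERES:
        for i, name in enumerate(names, start=1):
            table[f"{hemi}_{name}"] = (hemi, name, i)
    return table


def synthetic_parcellation(
    mesh: TriangleMesh, n_per_hemisphere: int = 30
) -> Parcellation:
    """Deterministic 2 x ``n_per_hemisphere`` parcellation of a sphere-like mesh.

    The hemisphere is the sign of x; within a hemisphere vertices are binned
    by latitude band and longitude sector (5 bands x 6 sectors for the
    default 30).  Adequate as a stand-in for a registered template
    parcellation on fixture meshes.
    """
    if n_per_hemisphere > 30:
        raise ValueError("at most 30 regions per hemisphere")
    # factor n into bands x sectors, as square as possible
    bands = int(np.floor(np.sqrt(n_per_hemisphere)))
    while n_per_hemisphere % bands:
        bands -= 1
    sectors = n_per_hemisphere // bands

    v = mesh.vertices - mesh.vertices.mean(axis=0)
    r = np.linalg.norm(v, axis=1)
    # latitude from the hemisphere axis (|x|, so it spans [0, pi/2] within
    # one hemisphere), longitude about it
    lat = np.arccos(np.clip(np.abs(v[:, 0]) / np.maximum(r, 1e-30), -1, 1))
    lon = np.arctan2(v[:, 2], v[:, 1])
    band = np.minimum((lat / (np.pi / 2) * bands).astype(int), bands - 1)
    sector = np.minimum(((lon + np.pi) / (2 * np.pi) * sectors).astype(int), sectors - 1)
    idx = band * sectors + sector  # 0..n-1
    hemi = np.where(v[:, 0] >= 0, "R", "L")
    names = REGION_NAMES_30[:n_per_hemisphere]
    labels = np.array([f"{h}_{names[i]}" for h, i in zip(hemi, idx)])
    return Parcellation(labels, standard_region_table(names))


# ---------------------------------------------------------------------------
# per-vertex fields


def _face_cotangents(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Cotangent of the angle at each face corner, plus squared edge lengths.

    Returns ``(cot, l2)`` with shape (F, 3): ``cot[:, i]`` is the cotangent
    at corner i, ``l2[:, i]`` the squared length of the edge *opposite*
    corner i.
    """
    p = mesh.vertices[mesh.faces]  # (F, 3, 3)
    e = np.stack(
        [p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1
    )  # edge opposite each corner
    l2 = np.einsum("fij,fij->fi", e, e)
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    double_area = np.linalg.norm(cross, axis=1)
    if np.any(double_area <= 1e-14):
        bad = int(np.argmin(double_area))
        raise MeshValidationError(f"degenerate face {bad} (zero area)")
    # cot at corner i = dot of adjacent edges / (2 * area)
    cot = np.empty_like(l2)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        cot[:, i] = -np.einsum("fi,fi->f", e[:, j], e[:, k]) / double_area
    return cot, l2


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Mixed Voronoi area (mm^2) per vertex.

    For non-obtuse triangles each corner receives its cotangent Voronoi
    area; an obtuse triangle gives half its area to the obtuse corner and a
    quarter to each of the others.  The areas partition the surface, so
    they sum exactly to the total mesh area.
    """
    cot, l2 = _face_cotangents(mesh)
    tri_area = mesh.face_areas()
    F = len(mesh.faces)
    contrib = np.empty((F, 3))
    obtuse_corner = np.argmin(cot, axis=1)
    is_obtuse = cot[np.arange(F), obtuse_corner] < 0

    # Voronoi formula for all faces first (valid where non-obtuse)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        contrib[:, i] = (l2[:, j] * cot[:, j] + l2[:, k] * cot[:, k]) / 8.0
    if np.any(is_obtuse):
        rows = np.flatnonzero(is_obtuse)
        contrib[rows] = tri_area[rows, None] / 4.0
        contrib[rows, obtuse_corner[rows]] = tri_area[rows] / 2.0

    areas = np.zeros(mesh.n_vertices)
    np.add.at(areas, mesh.faces.ravel(), contrib.ravel())
    return areas


def mean_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Absolute mean curvature ``|H|`` (1/mm) per vertex.

    Uses the cotangent mean-curvature normal
    ``K(x_i) = (1 / 2A_i) * sum_j (cot a_ij + cot b_ij) (x_i - x_j)``
    over the mixed Voronoi patch; ``|H| = |K| / 2``.
    """
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[mesh.faces.ravel()] = True
    if not used.all():
        raise MeshValidationError(
            f"isolated vertices (no incident face): {np.flatnonzero(~used)[:10].tolist()}"
        )
    cot, _ = _face_cotangents(mesh)
    areas = vertex_areas(mesh)
    v = mesh.vertices
    lap = np.zeros_like(v)
    f = mesh.faces
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        # edge (j, k) opposite corner i carries weight cot_i
        w = cot[:, i][:, None]
        np.add.at(lap, f[:, j], w * (v[f[:, k]] - v[f[:, j]]))
        np.add.at(lap, f[:, k], w * (v[f[:, j]] - v[f[:, k]]))
    knorm = np.linalg.norm(lap, axis=1) / (2.0 * np.maximum(areas, 1e-30))
    return knorm / 2.0


class VoxelizationError(ValueError):
    """The mesh could not be voxelized into a watertight interior mask."""


def sulcal_depth(
    mesh: TriangleMesh,
    voxel_mm: float,
    closing_mm: float = 15.0,
) -> np.ndarray:
    """Sulcal depth (mm) per vertex via an exterior geodesic distance transform.

    The mesh is voxelized at ``voxel_mm`` and filled to an interior mask;
    the cerebral hull is a morphological closing of the interior with a
    spherical element of radius ``closing_mm`` (large enough to bridge
    sulci at fetal scale).  Depth is the shortest 26-connected path with
    Euclidean edge lengths from each vertex to just outside the hull,
    passing only through non-interior voxels.  Convex surfaces therefore
    score ~0 everywhere, and a pit scores its depth below the hull.
    """
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be positive")
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise VoxelizationError("mesh is not watertight; cannot fill interior")
    vox = tm.voxelized(voxel_mm).fill()
    interior = np.asarray(vox.matrix, dtype=bool)
    if interior.sum() <= np.asarray(tm.voxelized(voxel_mm).matrix).sum():
        raise VoxelizationError(
            "voxelization produced no interior; use a smaller voxel_mm"
        )
    # world coordinates of voxel (0,0,0) center and spacing
    transform = np.asarray(vox.transform)
    origin = transform[:3, 3]
    # pad so the closing element and the exterior rim fit inside the grid
    pad = int(np.ceil(closing_mm / voxel_mm)) + 2
    interior = np.pad(interior, pad)
    origin = origin - pad * voxel_mm

    # morphological closing via two Euclidean distance transforms
    dist_to_interior = ndimage.distance_transform_edt(~interior, sampling=voxel_mm)
    dilated = dist_to_interior <= closing_mm
    dist_inside = ndimage.distance_transform_edt(dilated, sampling=voxel_mm)
    hull = dist_inside >= closing_mm
    hull |= interior

    passable = ~interior
    rim = passable & ~hull & ndimage.binary_dilation(hull)
    nodes = (passable & hull) | rim
    node_id = np.full(interior.shape, -1, dtype=np.int64)
    node_idx = np.argwhere(nodes)
    node_id[nodes] = np.arange(len(node_idx))

    rows, cols, wts = [], [], []
    shape = interior.shape
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) <= (0, 0, 0):
                    continue  # half the 26-neighbourhood; graph is undirected
                a = node_id[
                    max(dz, 0) : shape[0] + min(dz, 0),
                    max(dy, 0) : shape[1] + min(dy, 0),
                    max(dx, 0) : shape[2] + min(dx, 0),
                ]
                b = node_id[
                    max(-dz, 0) : shape[0] + min(-dz, 0),
                    max(-dy, 0) : shape[1] + min(-dy, 0),
                    max(-dx, 0) : shape[2] + min(-dx, 0),
                ]
                ok = (a >= 0) & (b >= 0)
                rows.append(a[ok])
                cols.append(b[ok])
                wts.append(
                    np.full(ok.sum(), np.sqrt(dz * dz + dy * dy + dx * dx) * voxel_mm)
                )
    n = len(node_idx)
    graph = sparse.csr_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    sources = node_id[rim]
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)

    node_world = node_idx * voxel_mm + origin
    tree = cKDTree(node_world)
    _, nearest = tree.query(mesh.vertices)
    depth = dist[nearest]
    unreachable = ~np.isfinite(depth)
    if unreachable.any():
        warnings.warn(
            f"{int(unreachable.sum())} vertices map to exterior pockets "
            "unreachable from the hull; their depth is set to 0"
        )
        depth[unreachable] = 0.0
    return np.maximum(depth, 0.0)


# ---------------------------------------------------------------------------
# regional aggregation

METRIC_COLUMNS = {
    "surface_area": "surface_area_mm2",
    "sulcal_depth": "mean_sulcal_depth_mm",
    "mean_curvature": "mean_abs_curvature_per_mm",
}


def aggregate_regions(
    mesh: TriangleMesh,
    parcellation: Parcellation,
    area: np.ndarray,
    depth: np.ndarray,
    curvature: np.ndarray,
    scan_id: str,
) -> pd.DataFrame:
    """Per-region metric table: area sums, area-weighted depth/curvature means.

    Returns one row per region in the parcellation table with columns
    ``scan_id, region, hemisphere, surface_area_mm2, mean_sulcal_depth_mm,
    mean_abs_curvature_per_mm``.  Regions present in the table but absent
    from the mesh produce a zero-area row and a warning.
    """
    for name, fld in (("area", area), ("depth", depth), ("curvature", curvature)):
        if len(fld) != mesh.n_vertices:
            raise ValueError(f"{name} field length != vertex count")
    if len(parcellation.labels) != mesh.n_vertices:
        raise ValueError("parcellation length != vertex count")

    df = pd.DataFrame(
        {
            "region": parcellation.labels,
            "w": area,
            "wd": area * depth,
            "wc": area * curvature,
        }
    )
    g = df.groupby("region", sort=False).sum()
    rows = []
    missing = []
    for region, (hemi, _, _) in parcellation.table.items():
        if region in g.index:
            w = g.at[region, "w"]
            rows.append(
                (
                    scan_id,
                    region,
                    hemi,
                    w,
                    g.at[region, "wd"] / w,
                    g.at[region, "wc"] / w,
                )
            )
        else:
            missing.append(region)
            rows.append((scan_id, region, hemi, 0.0, np.nan, np.nan))
    if missing:
        warnings.warn(f"regions with no labelled vertices: {missing[:10]}")
    return pd.DataFrame(
        rows,
        columns=[
            "scan_id",
            "region",
            "hemisphere",
            "surface_area_mm2",
            "mean_sulcal_depth_mm",
            "mean_abs_curvature_per_mm",
        ],
    )


def compute_scan_metrics(
    mesh: TriangleMesh,
    parcellation: Parcellation,
    scan_id: str,
    voxel_mm: float = 0.5,
    closing_mm: float = 15.0,
) -> pd.DataFrame:
    """Convenience wrapper: all three vertex fields plus regional aggregation."""
    area = vertex_areas(mesh)
    depth = sulcal_depth(mesh, voxel_mm=voxel_mm, closing_mm=closing_mm)
    curv = mean_curvature(mesh)
    return aggregate_regions(mesh, parcellation, area, depth, curv, scan_id)
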