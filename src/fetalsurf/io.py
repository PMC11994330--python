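"""Surface, label and table IO plus the pipeline configuration.

Surfaces are read from GIFTI (``.surf.gii``, via nibabel) or Wavefront
OBJ; labels from a GIFTI label file or two-column text (0-based vertex
index, label).  All tables are comma-separated UTF-8 CSV with a header
row, ``.`` decimal and ``NA`` for missing values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from fetalsurf.mesh import MeshValidationError, TriangleMesh
from fetalsurf.metrics import Parcellation, standard_region_table


class SurfaceParseError(ValueError):
    pass


def _read_obj(path: Path) -> TriangleMesh:
    # minimal v/f reader so parse errors can name the offending line
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            tag = parts[0]
            try:
                if tag == "v":
                    if len(parts) < 4:
                        raise ValueError("vertex needs 3 coordinates")
                    vertices.append([float(x) for x in parts[1:4]])
                elif tag == "f":
                    if len(parts) != 4:
                        raise ValueError("only triangular faces are supported")
                    # OBJ indices are 1-based and may carry /vt/vn suffixes
                    idx = [int(p.split("/")[0]) for p in parts[1:4]]
                    faces.append([i - 1 if i > 0 else len(vertices) + i for i in idx])
                # other tags (vn, vt, o, g, usemtl, ...) are ignored
            except ValueError as err:
                raise SurfaceParseError(
                    f"{path}:{lineno}: cannot parse {line!r} ({err})"
                ) from err
    if not vertices or not faces:
        raise SurfaceParseError(f"{path}: no vertices/faces found (truncated file?)")
    return TriangleMesh(np.asarray(vertices), np.asarray(faces))


def _read_gifti_surface(path: Path) -> TriangleMesh:
    img = nib.load(str(path))
    points = tris = None
    for arr in img.darrays:
        code = arr.intent
        if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            points = np.asarray(arr.data, dtype=float)
        elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(arr.data, dtype=int)
    if points is None or tris is None:
        raise SurfaceParseError(f"{path}: GIFTI lacks POINTSET/TRIANGLE arrays")
    return TriangleMesh(points, tris)


def read_surface(path: str | Path, require_closed: bool = True) -> TriangleMesh:
    """Read and validate a triangle surface from GIFTI or OBJ."""
    path = Path(path)
    if path.suffix.lower() == ".gii" or path.name.endswith(".surf.gii"):
        mesh = _read_gifti_surface(path)
    elif path.suffix.lower() == ".obj":
        mesh = _read_obj(path)
    else:
        raise SurfaceParseError(f"unsupported surface format: {path.suffix}")
    mesh.validate(require_closed=require_closed)
    return mesh


def write_surface(mesh: TriangleMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".gii" or path.name.endswith(".surf.gii"):
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif path.suffix.lower() == ".obj":
        with open(path, "w", encoding="utf-8") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    else:
        raise SurfaceParseError(f"unsupported surface format: {path.suffix}")


def read_labels(path: str | Path, n_vertices: int) -> Parcellation:
    """Read per-vertex region labels.

    GIFTI label files map integer keys through their label table; text
    files carry ``vertex_index label`` pairs (0-based, whitespace
    separated).  Region identifiers must follow the ``{L,R}_{name}``
    convention so the hemisphere is recoverable.
    """
    path = Path(path)
    labels = np.empty(n_vertices, dtype=object)
    labels[:] = ""
    if path.suffix.lower() == ".gii" or path.name.endswith(".label.gii"):
        img = nib.load(str(path))
        keys = np.asarray(img.darrays[0].data, dtype=int)
        if len(keys) != n_vertices:
            raise ValueError(
                f"label file has {len(keys)} entries for {n_vertices} vertices"
            )
        lut = {lab.key: lab.label for lab in img.labeltable.labels}
        labels = np.array([lut[k] for k in keys], dtype=object)
    else:
        table = pd.read_csv(
            path, sep=r"\s+", header=None, names=["vertex", "label"], comment="#"
        )
        if table.vertex.min() < 0 or table.vertex.max() >= n_vertices:
            raise ValueError("vertex index out of range in label file")
        labels[table.vertex.to_numpy()] = table.label.to_numpy()
    if (labels == "").any():
        raise ValueError("not every vertex is labelled")
    names = tuple(dict.fromkeys(str(l).split("_", 1)[1] for l in labels))
    table_full = {
        rid: v
        for rid, v in standard_region_table(names).items()
        if rid in set(labels)
    }
    return Parcellation(np.asarray(labels, dtype=str), table_full)


def write_labels(parcellation: Parcellation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, lab in enumerate(parcellation.labels):
            fh.write(f"{i} {lab}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the end-to-end pipeline run.

    Unknown keys in a YAML config are rejected; numeric settings are
    range-checked.
    """

    out_dir: str = "fetalsurf_out"
    seed: int = 0
    voxel_mm: float = 0.5
    closing_mm: float = 15.0
    family_size: int = 60
    robust: bool = True
    metrics: tuple[str, ...] = ("surface_area",)
    gp_noise_variance: float = 0.01
    gp_max_iter: int = 100
    z_include_noise: bool = True
    simulation: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.voxel_mm <= 5:
            raise ValueError("voxel_mm must be in (0, 5]")
        if not 0 < self.closing_mm <= 100:
            raise ValueError("closing_mm must be in (0, 100]")
        if self.family_size not in (30, 60):
            raise ValueError("family_size must be 30 or 60")
        if not 0 < self.gp_noise_variance <= 1:
            raise ValueError("gp_noise_variance must be in (0, 1]")
        if not 1 <= self.gp_max_iter <= 10_000:
            raise ValueError("gp_max_iter must be in [1, 10000]")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "metrics" in raw:
        raw["metrics"] = tuple(raw["metrics"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
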