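"""File readers and writers.

Images: multi-page TIFF, PNG slice directories, raw 16-bit little-endian
with a JSON sidecar (shape + spacing), and single-file DICOM pixel data
with RescaleSlope/Intercept applied to recover CT values.  Gray output is
quantized to uint8 with round-half-even only at export time.

Meshes: TetGen-style ``.node``/``.ele``/``.poly`` text files (1-based
indices on disk, 0-based in memory) and legacy ASCII VTK unstructured
grids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .tetmesh import ConstraintSet, TetMesh
from .volume import ImageVolume

# ------------------------------------------------------------------ images


def read_image(path, spacing=(1.0, 1.0, 1.0), value_kind="gray_float") -> ImageVolume:
    """Read a TIFF/PNG file or a directory of slices into an ImageVolume."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not slices:
            raise InvalidParameterError(f"no image slices found under {path}")
        vox = np.stack([np.asarray(iio.imread(p), dtype=float) for p in slices])
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        vox = np.asarray(tifffile.imread(path), dtype=float)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        vox = np.asarray(iio.imread(path), dtype=float)
    elif path.suffix.lower() == ".raw":
        return read_raw(path)
    else:
        raise InvalidParameterError(f"unsupported image format: {path.suffix}")
    return ImageVolume(vox, spacing, value_kind)


def read_raw(path) -> ImageVolume:
    """16-bit little-endian raw volume with a ``<name>.json`` sidecar."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    shape = tuple(meta["shape"])
    vox = np.fromfile(path, dtype="<i2").reshape(shape).astype(float)
    return ImageVolume(vox, tuple(meta.get("spacing", (1.0, 1.0, 1.0))), meta.get("value_kind", "ct_value"))


def write_raw(img: ImageVolume, path) -> None:
    path = Path(path)
    img.voxels.astype("<i2").tofile(path)
    meta = {"shape": list(img.shape), "spacing": list(img.spacing), "value_kind": img.value_kind}
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_dicom(path) -> ImageVolume:
    """Single DICOM file -> CT-value volume (RescaleSlope/Intercept applied)."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    spacing_yx = [float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0])]
    dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    return ImageVolume(slope * arr + intercept, (dz, spacing_yx[0], spacing_yx[1]), "ct_value")


def to_uint8(voxels) -> np.ndarray:
    """Quantize gray_float data to uint8 with round-half-even."""
    return np.clip(np.rint(np.asarray(voxels, dtype=float)), 0, 255).astype(np.uint8)


def write_gray8(img, path) -> None:
    """Write a volume (or 2-D array) as 8-bit TIFF or PNG."""
    vox = img.voxels if isinstance(img, ImageVolume) else np.asarray(img)
    data = to_uint8(vox)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data.squeeze(), photometric="minisblack")
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, data.squeeze())
    else:
        raise InvalidParameterError(f"unsupported output format: {path.suffix}")


# ------------------------------------------------------------------ meshes


def write_node(points, path) -> None:
    """TetGen .node: 1-based vertex indices."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    lines = [f"{len(pts)} 3 0 0"]
    lines += [f"{i + 1} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for i, p in enumerate(pts)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_node(path) -> np.ndarray:
    rows = [ln.split() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    n = int(rows[0][0])
    return np.asarray([[float(v) for v in r[1:4]] for r in rows[1 : n + 1]])


def write_ele(mesh: TetMesh, path) -> None:
    """TetGen .ele: 1-based tetrahedron connectivity."""
    lines = [f"{len(mesh.tets)} 4 0"]
    lines += [
        f"{i + 1} {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}"
        for i, t in enumerate(mesh.tets)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_poly(points, constraints: ConstraintSet, path) -> None:
    """TetGen-style .poly with nodes and triangular facets (1-based)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    lines = [f"{len(pts)} 3 0 0"]
    lines += [f"{i + 1} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for i, p in enumerate(pts)]
    lines.append(f"{len(constraints.faces)} 0")
    for f in constraints.faces:
        lines.append("1")
        lines.append(f"3 {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    lines.append("0")  # holes
    Path(path).write_text("\n".join(lines) + "\n")


def read_poly(path):
    """Read nodes + triangular facets from a .poly file.

    Returns ``(points, ConstraintSet)``; facet edges are derived from the
    faces.
    """
    rows = [ln.split() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    it = iter(rows)
    n = int(next(it)[0])
    pts = np.asarray([[float(v) for v in next(it)[1:4]] for _ in range(n)])
    nf = int(next(it)[0])
    faces = []
    for _ in range(nf):
        npoly = int(next(it)[0])
        for _ in range(npoly):
            r = next(it)
            if int(r[0]) != 3:
                raise InvalidParameterError("only triangular facets are supported")
            faces.append((int(r[1]) - 1, int(r[2]) - 1, int(r[3]) - 1))
    edges = sorted({tuple(sorted((f[i], f[(i + 1) % 3]))) for f in faces for i in range(3)})
    return pts, ConstraintSet(edges=edges, faces=faces)


def write_vtk(mesh: TetMesh, path) -> None:
    """Legacy ASCII VTK unstructured grid (cell type 10 = tetrahedron)."""
    pts = mesh.point_array()
    lines = [
        "# vtk DataFile Version 3.0",
        "medsegmesh tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} double",
    ]
    lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in pts]
    lines.append(f"CELLS {len(mesh.tets)} {5 * len(mesh.tets)}")
    lines += [f"4 {t[0]} {t[1]} {t[2]} {t[3]}" for t in mesh.tets]
    lines.append(f"CELL_TYPES {len(mesh.tets)}")
    lines += ["10"] * len(mesh.tets)
    Path(path).write_text("\n".join(lines) + "\n")
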