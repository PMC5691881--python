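"""File formats: labeled PLY/STL meshes, NIfTI/NRRD volumes, landmarks,
configs and report files.

The on-disk mesh contract is ASCII PLY with a per-vertex integer property
``region`` (0 = wall, 1 = upper endplate, 2 = lower endplate); STL carries
geometry only, so labels are dropped with a warning on write and absent on
read.  Volumes use NIfTI (.nii/.nii.gz) or NRRD with axis-aligned grids;
spacing and origin round-trip to 1e-6 mm.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from .densitometry import BodyMask, CTVolume
from .geometry import TriMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "config_hash",
    "write_csv_with_meta",
]


class FileFormatError(ValueError):
    """Malformed input file, with line/record context in the message."""


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def write_mesh(mesh: TriMesh, path) -> None:
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".ply"):
        _write_ply(mesh, path)
    elif suffix.endswith(".stl"):
        if mesh.region is not None:
            warnings.warn(
                "STL cannot carry region labels; writing geometry only",
                stacklevel=2,
            )
        mesh.to_trimesh().export(path)
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")


def read_mesh(path, check_watertight: bool = True) -> TriMesh:
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".ply"):
        mesh = _read_ply(path)
    elif name.endswith(".stl"):
        import trimesh as _tm

        # STL stores one vertex triple per facet; weld them back together
        tm = _tm.load_mesh(str(path), process=True)
        tm.merge_vertices()
        mesh = TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), None)
        warnings.warn("STL carries no region labels", stacklevel=2)
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")
    if check_watertight and not mesh.is_watertight:
        warnings.warn(
            f"{path.name}: mesh is not watertight "
            f"({mesh.open_edge_count()} open edges)",
            stacklevel=2,
        )
    return mesh


def _write_ply(mesh: TriMesh, path: Path) -> None:
    has_region = mesh.region is not None
    lines = [
        "ply",
        "format ascii 1.0",
        "comment vertmorph labeled vertebral-body mesh",
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if has_region:
        lines.append("property int region")
    lines += [
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for i, v in enumerate(mesh.vertices):
        row = f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
        if has_region:
            row += f" {int(mesh.region[i])}"
        lines.append(row)
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_ply(path: Path) -> TriMesh:
    try:
        text = Path(path).read_text()
    except UnicodeDecodeError as exc:
        raise FileFormatError(f"{path.name}: only ASCII PLY is supported") from exc
    lines = text.splitlines()
    n_vertex = n_face = None
    vertex_props: list[str] = []
    in_vertex_element = False
    header_end = None
    for i, line in enumerate(lines):
        tok = line.split()
        if not tok:
            continue
        if i == 0 and tok[0] != "ply":
            raise FileFormatError(f"{path.name}:1: not a PLY file")
        if tok[0] == "format" and tok[1] != "ascii":
            raise FileFormatError(
                f"{path.name}:{i + 1}: only ASCII PLY is supported"
            )
        if tok[0] == "element":
            in_vertex_element = tok[1] == "vertex"
            if tok[1] == "vertex":
                n_vertex = int(tok[2])
            elif tok[1] == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and in_vertex_element and tok[1] != "list":
            vertex_props.append(tok[2])
        elif tok[0] == "end_header":
            header_end = i
            break
    if header_end is None or n_vertex is None or n_face is None:
        raise FileFormatError(f"{path.name}: incomplete PLY header")
    for coord in ("x", "y", "z"):
        if coord not in vertex_props:
            raise FileFormatError(f"{path.name}: vertex property {coord!r} missing")

    body = lines[header_end + 1:]
    if len(body) < n_vertex + n_face:
        raise FileFormatError(
            f"{path.name}: truncated file — expected {n_vertex + n_face} data "
            f"records, found {len(body)}"
        )
    cols = {p: k for k, p in enumerate(vertex_props)}
    verts = np.empty((n_vertex, 3))
    region = np.empty(n_vertex, dtype=np.int64) if "region" in cols else None
    for r in range(n_vertex):
        tok = body[r].split()
        if len(tok) < len(vertex_props):
            raise FileFormatError(
                f"{path.name}:{header_end + 2 + r}: short vertex record"
            )
        try:
            verts[r] = [float(tok[cols["x"]]), float(tok[cols["y"]]), float(tok[cols["z"]])]
            if region is not None:
                region[r] = int(tok[cols["region"]])
        except ValueError as exc:
            raise FileFormatError(
                f"{path.name}:{header_end + 2 + r}: bad vertex record: {exc}"
            ) from exc
    faces = np.empty((n_face, 3), dtype=np.int64)
    for r in range(n_face):
        tok = body[n_vertex + r].split()
        if not tok or tok[0] != "3" or len(tok) < 4:
            raise FileFormatError(
                f"{path.name}:{header_end + 2 + n_vertex + r}: "
                "only triangle faces are supported"
            )
        faces[r] = [int(tok[1]), int(tok[2]), int(tok[3])]
    return TriMesh(verts, faces, region)


# ---------------------------------------------------------------------------
# volumes and masks
# ---------------------------------------------------------------------------


def _read_grid(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        lin = affine[:3, :3]
        if not np.allclose(lin - np.diag(np.diag(lin)), 0.0, atol=1e-6):
            raise FileFormatError(f"{path.name}: non-axis-aligned affine")
        spacing = np.abs(np.diag(lin))
        origin = affine[:3, 3].astype(float)
        data = np.asarray(img.dataobj, dtype=float)
        return data, spacing, origin
    if name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
        return data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())
    raise ValueError(f"unsupported volume format: {path.name}")


def _write_grid(data: np.ndarray, spacing, origin, path: Path) -> None:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
        return
    if name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(data).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path) -> CTVolume:
    data, spacing, origin = _read_grid(Path(path))
    return CTVolume(data, spacing, origin)


def write_volume(vol: CTVolume, path) -> None:
    _write_grid(vol.data, vol.spacing, vol.origin, Path(path))


def read_mask(path, volume: CTVolume | None = None) -> BodyMask:
    data, spacing, origin = _read_grid(Path(path))
    mask = BodyMask(np.rint(data).astype(np.int16), spacing, origin)
    if volume is not None and not mask.matches_grid(volume):
        raise ValueError(
            f"mask grid {mask.labels.shape} does not match volume grid "
            f"{volume.data.shape} (or spacing/origin differ)"
        )
    return mask


def write_mask(mask: BodyMask, path) -> None:
    _write_grid(mask.labels.astype(np.int16), mask.spacing, mask.origin, Path(path))


# ---------------------------------------------------------------------------
# landmarks, config, reports
# ---------------------------------------------------------------------------


def write_landmarks(entry: dict, path) -> None:
    """Per-vertebra landmark JSON: level, a, b, concave_side."""
    out = {
        "level": entry["level"],
        "a": [float(v) for v in entry["a"]],
        "b": [float(v) for v in entry["b"]],
        "concave_side": entry["concave_side"],
    }
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True) + "\n")


def read_landmarks(path) -> dict:
    raw = json.loads(Path(path).read_text())
    for key in ("level", "a", "b", "concave_side"):
        if key not in raw:
            raise FileFormatError(f"{Path(path).name}: landmark key {key!r} missing")
    raw["a"] = np.asarray(raw["a"], dtype=float)
    raw["b"] = np.asarray(raw["b"], dtype=float)
    return raw


def config_hash(obj) -> str:
    """Stable short hash of a configuration object (canonical JSON)."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv_with_meta(df, path, seed=None, cfg_hash: str = "", version: str = "") -> None:
    """CSV with '#'-prefixed metadata header (seed, config hash, version)."""
    meta = [f"# vertmorph{(' ' + version) if version else ''}"]
    if seed is not None:
        meta.append(f"# seed={seed}")
    if cfg_hash:
        meta.append(f"# config={cfg_hash}")
    with open(path, "w") as fh:
        fh.write("\n".join(meta) + "\n")
        df.to_csv(fh, index=False)
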