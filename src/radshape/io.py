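"""Point-cloud, landmark and model-archive I/O.

Supported cloud formats: XYZ (whitespace separated), PLY (ASCII and
binary little-endian), OBJ (``v`` records) and ASCII STL.  Point order is
preserved exactly as stored — downstream correspondence assigns anatomical
meaning to indices, so I/O must never permute points.  All coordinates are
millimetres; no unit conversion is ever applied.

Model archives are ZIP containers with a JSON header (format version,
model type, creation seed/config) and one ``.npy`` entry per array field.
"""

from __future__ import annotations

import csv
import json
import struct
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import FormatError, IntegrityError, ValidationError

ARCHIVE_VERSION = 1

GROUP_LABELS = ("normal", "colles", "smith", "barton")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """An ordered set of M surface points (mm) for one subject's bone.

    ``normals``, when present, are unit vectors with one row per point.
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    subject_id: str = ""
    side: str = "unknown"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(
                f"points must be (M, 3), got {self.points.shape}")
        if self.points.shape[0] < 4:
            raise ValidationError(
                f"a point cloud needs at least 4 points, got {len(self.points)}")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point coordinates must be finite")
        if self.side not in ("left", "right", "unknown"):
            raise ValidationError(f"side must be left/right/unknown, got {self.side!r}")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise ValidationError(
                    f"normals shape {self.normals.shape} != points shape "
                    f"{self.points.shape}")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValidationError("normals must have unit length (tol 1e-6)")

    def __len__(self):
        return len(self.points)

    def with_points(self, points, normals=None) -> "PointCloud":
        return replace(self, points=points, normals=normals)


@dataclass
class LandmarkSet:
    """The four expert landmarks on the distal radius (mm).

    A: sigmoid notch volar lip; B: sigmoid notch dorsal lip;
    C: radial styloid process vertex; D: highest dorsal point of
    Lister's tubercle.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        for name in "ABCD":
            v = np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"landmark {name} has non-finite coordinates")
            setattr(self, name, v)
        if np.array_equal(self.A, self.B):
            raise ValidationError("landmarks A and B coincide (AB segment degenerate)")
        if np.array_equal(self.C, self.D):
            raise ValidationError("landmarks C and D coincide (CD segment degenerate)")

    def as_array(self) -> np.ndarray:
        return np.stack([self.A, self.B, self.C, self.D])

    @classmethod
    def from_array(cls, arr) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=np.float64)
        return cls(A=arr[0], B=arr[1], C=arr[2], D=arr[3])


@dataclass
class ManifestEntry:
    cloud_path: str
    landmark_path: Optional[str]
    label: str

    def __post_init__(self):
        if self.label not in GROUP_LABELS:
            raise ValidationError(
                f"label {self.label!r} not in {GROUP_LABELS}")


@dataclass
class DatasetManifest:
    """Listing of (cloud file, optional landmark file, group label)."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        paths = [e.cloud_path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValidationError("manifest cloud paths must be unique")

    @classmethod
    def read(cls, path) -> "DatasetManifest":
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"cloud", "label"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise FormatError(path, "manifest needs columns: cloud,label[,landmarks]")
            for row in reader:
                lm = row.get("landmarks") or None
                entries.append(ManifestEntry(row["cloud"], lm, row["label"].strip()))
        return cls(entries)

    def write(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cloud", "landmarks", "label"])
            for e in self.entries:
                w.writerow([e.cloud_path, e.landmark_path or "", e.label])


# ---------------------------------------------------------------------------
# point cloud readers/writers
# ---------------------------------------------------------------------------

_EXT_TO_FMT = {".ply": "ply", ".obj": "obj", ".xyz": "xyz", ".stl": "stl",
               ".txt": "xyz"}


def _resolve_fmt(path, fmt):
    if fmt != "auto":
        return fmt
    ext = Path(path).suffix.lower()
    if ext not in _EXT_TO_FMT:
        raise FormatError(path, f"cannot infer format from extension {ext!r}")
    return _EXT_TO_FMT[ext]


def read_point_cloud(path, fmt: str = "auto") -> PointCloud:
    """Read a point cloud or mesh; meshes yield unique vertices in file order.

    STL duplicate vertices (three copies per shared corner) are merged by
    exact coordinate equality, keeping first occurrence order.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(path, "file does not exist")
    fmt = _resolve_fmt(path, fmt)
    if fmt == "xyz":
        points, normals = _read_xyz(path)
    elif fmt == "ply":
        points, normals = _read_ply(path)
    elif fmt in ("obj", "stl"):
        points, normals = _read_mesh_vertices(path, fmt)
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    if len(points) < 4:
        raise ValidationError(f"{path}: fewer than 4 points ({len(points)})")
    return PointCloud(points=points, normals=normals,
                      subject_id=path.stem)


def write_point_cloud(cloud: PointCloud, path, fmt: str = "auto",
                      binary: bool = False) -> None:
    """Write ``cloud`` so that :func:`read_point_cloud` restores it exactly.

    ``binary`` selects binary little-endian PLY; ignored for other formats.
    """
    path = Path(path)
    fmt = _resolve_fmt(path, fmt)
    try:
        if fmt == "xyz":
            _write_xyz(cloud, path)
        elif fmt == "ply":
            _write_ply(cloud, path, binary=binary)
        elif fmt == "obj":
            _write_obj(cloud, path)
        else:
            raise ValidationError(
                f"writing format {fmt!r} is not supported (point clouds have "
                "no faces, so STL output is not meaningful)")
    except OSError as exc:
        raise FormatError(path, f"write failed: {exc}") from exc


def _read_xyz(path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 6):
                raise FormatError(path, f"expected 3 or 6 fields, got {len(parts)}",
                                  line=lineno)
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(path, f"non-numeric field: {exc}", line=lineno)
    if not rows:
        raise FormatError(path, "no coordinate records found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(path, "mixed 3- and 6-field records")
    arr = np.array(rows, dtype=np.float64)
    if arr.shape[1] == 6:
        return arr[:, :3], arr[:, 3:]
    return arr, None


def _write_xyz(cloud, path):
    arr = cloud.points if cloud.normals is None else np.hstack(
        [cloud.points, cloud.normals])
    with open(path, "w") as fh:
        for row in arr:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


_PLY_DTYPES = {"float": "<f4", "float32": "<f4", "double": "<f8",
               "float64": "<f8", "uchar": "<u1", "uint8": "<u1",
               "char": "<i1", "int8": "<i1", "short": "<i2", "ushort": "<u2",
               "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4"}


def _read_ply(path):
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError(path, "not a PLY file (missing 'ply' magic)", line=1)
        fmt = None
        elements = []   # (name, count, [(prop_name, dtype_str)])
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise FormatError(path, "header ended before end_header", line=lineno)
            tok = raw.decode("ascii", "replace").split()
            if not tok:
                continue
            if tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt = tok[1]
                if fmt not in ("ascii", "binary_little_endian"):
                    raise FormatError(path, f"unsupported PLY format {fmt!r}",
                                      line=lineno)
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if not elements:
                    raise FormatError(path, "property before element", line=lineno)
                if tok[1] == "list":
                    elements[-1][2].append((tok[-1], ("list", tok[2], tok[3])))
                else:
                    if tok[1] not in _PLY_DTYPES:
                        raise FormatError(path, f"unsupported type {tok[1]!r}",
                                          line=lineno)
                    elements[-1][2].append((tok[-1], _PLY_DTYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        if fmt is None:
            raise FormatError(path, "PLY header missing format line")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise FormatError(path, "PLY file has no vertex element")
        if fmt == "binary_little_endian" and elements[0][0] != "vertex":
            raise FormatError(path, "binary PLY must store vertex element first")
        _, count, props = vertex
        names = [p[0] for p in props]
        for c in "xyz":
            if c not in names:
                raise FormatError(path, f"vertex element lacks property {c!r}")
        if any(isinstance(p[1], tuple) for p in props):
            raise FormatError(path, "list property inside vertex element")
        if fmt == "ascii":
            rows = []
            got = 0
            while got < count:
                raw = fh.readline()
                lineno += 1
                if not raw:
                    raise FormatError(path, "unexpected EOF in vertex data",
                                      line=lineno)
                vals = raw.split()
                if not vals:
                    continue
                if len(vals) != len(props):
                    raise FormatError(path, f"expected {len(props)} values, got "
                                      f"{len(vals)}", line=lineno)
                rows.append([float(v) for v in vals])
                got += 1
            data = {n: np.array([r[i] for r in rows])
                    for i, n in enumerate(names)}
        else:
            dtype = np.dtype([(n, t) for n, t in props])
            buf = fh.read(count * dtype.itemsize)
            if len(buf) != count * dtype.itemsize:
                raise FormatError(path, "binary vertex data truncated")
            rec = np.frombuffer(buf, dtype=dtype)
            data = {n: rec[n].astype(np.float64) for n in names}
    points = np.column_stack([data["x"], data["y"], data["z"]])
    normals = None
    if all(k in data for k in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]])
    return points, normals


def _write_ply(cloud, path, binary=False):
    has_n = cloud.normals is not None
    props = ["x", "y", "z"] + (["nx", "ny", "nz"] if has_n else [])
    arr = cloud.points if not has_n else np.hstack([cloud.points, cloud.normals])
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {len(arr)}"]
    header += [f"property double {p}" for p in props]
    header += ["end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())
        else:
            for row in arr:
                fh.write((" ".join(repr(float(v)) for v in row) + "\n")
                         .encode("ascii"))


def _write_obj(cloud, path):
    with open(path, "w") as fh:
        for row in cloud.points:
            fh.write("v " + " ".join(repr(float(v)) for v in row) + "\n")


def _read_mesh_vertices(path, fmt):
    import trimesh

    try:
        mesh = trimesh.load(str(path), file_type=fmt, process=False,
                            maintain_order=True)
    except Exception as exc:  # trimesh raises assorted types
        raise FormatError(path, f"mesh load failed: {exc}") from exc
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    if verts.size == 0:
        raise FormatError(path, "mesh contains no vertices")
    if fmt == "stl":
        # STL repeats each shared corner once per facet; merge by exact
        # coordinate equality, keeping first-occurrence order.
        _, first = np.unique(verts, axis=0, return_index=True)
        verts = verts[np.sort(first)]
    return verts, None


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Read landmarks A-D from CSV (``name,x,y,z``) or a JSON object."""
    path = Path(path)
    if not path.exists():
        raise FormatError(path, "file does not exist")
    text = path.read_text()
    coords: dict[str, np.ndarray] = {}
    if text.lstrip().startswith("{"):
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(path, f"invalid JSON: {exc}") from exc
        items = obj.items()
    else:
        items = []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0].lower() in ("name", "landmark"):
                continue  # header
            if len(parts) != 4:
                raise FormatError(path, f"expected name,x,y,z — got {line!r}",
                                  line=lineno)
            items.append((parts[0], parts[1:]))
    for name, xyz in items:
        key = str(name).strip().upper()
        if key not in "ABCD":
            raise FormatError(path, f"unknown landmark name {name!r}")
        if key in coords:
            raise ValidationError(f"{path}: duplicate rows for landmark {key}")
        try:
            coords[key] = np.array([float(v) for v in xyz], dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise FormatError(path, f"bad coordinates for {key}: {exc}")
    missing = [k for k in "ABCD" if k not in coords]
    if missing:
        raise ValidationError(
            f"{path}: missing landmark(s): {', '.join(missing)}")
    return LandmarkSet(**coords)


def write_landmarks(lm: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("name,x,y,z\n")
        for name in "ABCD":
            v = getattr(lm, name)
            fh.write(f"{name}," + ",".join(repr(float(c)) for c in v) + "\n")


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------

def save_model(model, path, seed=None, config=None) -> None:
    """Serialize a ShapeModel or ClassifierModel to a versioned ZIP archive."""
    from .nn import ClassifierModel
    from .ssm import ShapeModel

    if isinstance(model, ShapeModel):
        mtype, arrays, scalars = _shape_model_fields(model)
    elif isinstance(model, ClassifierModel):
        mtype, arrays, scalars = _classifier_fields(model)
    else:
        raise ValidationError(f"cannot archive object of type {type(model).__name__}")
    header = {"format_version": ARCHIVE_VERSION, "model_type": mtype,
              "seed": seed, "config": config, "scalars": scalars,
              "arrays": sorted(k for k, v in arrays.items() if v is not None)}
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        for name, arr in arrays.items():
            if arr is None:
                continue
            import io as _io
            buf = _io.BytesIO()
            np.save(buf, np.asarray(arr), allow_pickle=False)
            zf.writestr(name + ".npy", buf.getvalue())


def load_model(path, expected_type=None):
    """Load a model archive, checking version, integrity and type."""
    from .nn import ClassifierModel
    from .ssm import ShapeModel

    try:
        with zipfile.ZipFile(path) as zf:
            bad = zf.testzip()
            if bad is not None:
                raise IntegrityError(f"{path}: corrupt archive member {bad!r}")
            header = json.loads(zf.read("header.json"))
            if header.get("format_version") != ARCHIVE_VERSION:
                raise IntegrityError(
                    f"{path}: archive version {header.get('format_version')} "
                    f"!= supported version {ARCHIVE_VERSION}")
            import io as _io
            arrays = {name: np.load(_io.BytesIO(zf.read(name + ".npy")),
                                    allow_pickle=False)
                      for name in header["arrays"]}
    except (zipfile.BadZipFile, KeyError, EOFError, OSError) as exc:
        raise IntegrityError(f"{path}: unreadable archive ({exc})") from exc
    mtype = header.get("model_type")
    if expected_type is not None and mtype != expected_type:
        raise IntegrityError(
            f"{path}: expected model_type {expected_type!r}, found {mtype!r}")
    scalars = header.get("scalars", {})
    if mtype == "shape_model":
        from .ssm import ShapeModel
        return ShapeModel(mean_shape=arrays["mean_shape"],
                          eigenvalues=arrays["eigenvalues"],
                          eigenvectors=arrays["eigenvectors"],
                          total_variance=float(scalars["total_variance"]),
                          alpha=float(scalars["alpha"]),
                          t=int(scalars["t"]))
    if mtype == "classifier":
        thresholds = arrays.get("thresholds")
        return ClassifierModel(W=arrays["W"], B=arrays["B"], V=arrays["V"],
                               C=arrays["C"],
                               classes=tuple(scalars["classes"]),
                               feature_scale=arrays["feature_scale"],
                               thresholds=thresholds)
    raise IntegrityError(f"{path}: unknown model_type {mtype!r}")


def _shape_model_fields(model):
    arrays = {"mean_shape": model.mean_shape, "eigenvalues": model.eigenvalues,
              "eigenvectors": model.eigenvectors}
    scalars = {"total_variance": float(model.total_variance),
               "alpha": float(model.alpha), "t": int(model.t)}
    return "shape_model", arrays, scalars


def _classifier_fields(model):
    arrays = {"W": model.W, "B": model.B, "V": model.V, "C": model.C,
              "feature_scale": model.feature_scale,
              "thresholds": model.thresholds}
    scalars = {"classes": list(model.classes)}
    return "classifier", arrays, scalars
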