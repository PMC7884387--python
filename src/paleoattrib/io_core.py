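"""Readers, writers and shared geometric primitives.

Landmark configurations travel as TPS files or long-format CSV, voxel
volumes as NRRD (raw encoding) or multi-page TIFF stacks, and comparative
summary statistics as CSV. All coordinates are millimetres in a
right-handed frame; no unit conversion happens anywhere in the package.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LandmarkSet",
    "Plane",
    "LabeledVolume",
    "ComparativeStats",
    "read_landmarks",
    "write_landmarks",
    "read_volume",
    "write_volume",
    "read_comparative_stats",
]

#: voxel labels recognised by the tissue pipeline
BACKGROUND, ENAMEL, DENTINE, PULP = 0, 1, 2, 3
VALID_LABELS = frozenset({BACKGROUND, ENAMEL, DENTINE, PULP})


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


@dataclass
class LandmarkSet:
    """One specimen's ordered 3D (semi)landmark configuration.

    Parameters
    ----------
    specimen_id : str
        Specimen accession / label.
    coords : (K, 3) float array
        Ordered landmark coordinates in mm.
    curves : dict[str, list[int]]
        Partition of ``range(K)`` into named curves. Defaults to a single
        curve ``"all"`` covering every point.
    metadata : dict
        Free-form side/tooth annotations.
    """

    specimen_id: str
    coords: np.ndarray
    curves: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (K, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        k = self.coords.shape[0]
        if not self.curves:
            self.curves = {"all": list(range(k))}
        assigned = sorted(i for idx in self.curves.values() for i in idx)
        if assigned != list(range(k)):
            raise ValueError(
                "curves must partition the landmark indices exactly once"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def centroid_size(self) -> float:
        """Square root of summed squared deviations from the centroid."""
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c**2).sum()))


@dataclass
class Plane:
    """Plane in signed-distance form ``normal . x = offset`` (mm)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be a nonzero finite vector")
        # renormalise so downstream signed distances are in mm
        self.normal = n / norm
        self.offset = float(self.offset) / norm if norm != 1.0 else float(self.offset)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.normal - self.offset


@dataclass
class LabeledVolume:
    """Segmented voxel grid with isotropic physical voxel size.

    ``labels`` holds 0 = background, 1 = enamel, 2 = dentine, 3 = pulp.
    A voxel's volume is ``voxel_size**3``; its centre sits at
    ``(index + 0.5) * voxel_size`` on each axis (0-based, half-open grid).
    """

    labels: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels grid must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.voxel_size <= 0 or not np.isfinite(self.voxel_size):
            raise ValueError("voxel_size must be positive")
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(f"unknown labels present: {sorted(present - VALID_LABELS)}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def voxel_centers_mm(self, mask: np.ndarray) -> np.ndarray:
        """(N, 3) physical centres of the voxels selected by ``mask``."""
        idx = np.argwhere(mask)
        return (idx + 0.5) * self.voxel_size

    def volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.voxel_size**3


@dataclass
class ComparativeStats:
    """Per-(group, variable) summary used by adjusted Z-scores."""

    group: str
    variable: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError(
                "n must be >= 2: Student's t with n-1 degrees of freedom "
                "requires at least two observations"
            )


# ---------------------------------------------------------------------------
# landmarks


def _parse_tps(text: str, path: str) -> list[LandmarkSet]:
    specs: list[LandmarkSet] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().upper()
        if key not in ("LM3", "LM"):
            raise ParseError(f"{path}:{i}: expected LM3/LM record, got {line!r}")
        try:
            k = int(value)
        except ValueError:
            raise ParseError(f"{path}:{i}: bad landmark count {value!r}") from None
        dim = 3 if key == "LM3" else 2
        pts = []
        for j in range(k):
            if i >= len(lines):
                raise ParseError(f"{path}:{i}: truncated record, expected {k} points")
            fields = lines[i].split()
            i += 1
            if len(fields) != dim:
                raise ParseError(
                    f"{path}:{i}: expected {dim} coordinates, got {len(fields)}"
                )
            try:
                pts.append([float(v) for v in fields])
            except ValueError:
                raise ParseError(f"{path}:{i}: non-numeric coordinate") from None
        coords = np.asarray(pts, float)
        if dim == 2:
            coords = np.column_stack([coords, np.zeros(len(coords))])
        spec_id, image = None, None
        while i < len(lines) and lines[i].strip() and "=" in lines[i]:
            key2, _, value2 = lines[i].strip().partition("=")
            key2 = key2.strip().upper()
            if key2 in ("LM3", "LM"):
                break
            i += 1
            if key2 == "ID":
                spec_id = value2.strip()
            elif key2 == "IMAGE":
                image = value2.strip()
            else:
                warnings.warn(f"{path}: ignoring unsupported TPS key {key2!r}")
        meta = {"image": image} if image else {}
        specs.append(
            LandmarkSet(spec_id or f"specimen_{len(specs)}", coords, metadata=meta)
        )
    if not specs:
        raise ParseError(f"{path}: no landmark records found")
    ks = {s.k for s in specs}
    if len(ks) > 1:
        raise ParseError(f"{path}: inconsistent landmark counts across specimens: {sorted(ks)}")
    return specs


def _parse_landmark_csv(path: str) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    required = {"specimen_id", "curve", "index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df[["x", "y", "z"]].isna().any().any():
        bad = int(df[["x", "y", "z"]].isna().any(axis=1).idxmax()) + 2  # header line
        raise ParseError(f"{path}:{bad}: missing coordinate value")
    out = []
    for sid, g in df.groupby("specimen_id", sort=False):
        g = g.sort_values("index")
        if not np.array_equal(g["index"].to_numpy(), np.arange(len(g))):
            raise ParseError(f"{path}: specimen {sid!r} indices are not 0..K-1")
        curves: dict[str, list[int]] = {}
        for cname, cg in g.groupby("curve", sort=False):
            curves[str(cname)] = cg["index"].astype(int).tolist()
        out.append(LandmarkSet(str(sid), g[["x", "y", "z"]].to_numpy(), curves=curves))
    ks = {s.k for s in out}
    if len(ks) > 1:
        raise ParseError(f"{path}: inconsistent landmark counts across specimens: {sorted(ks)}")
    return out


def read_landmarks(path, format: str | None = None) -> list[LandmarkSet]:
    """Read landmark configurations from a TPS or long-format CSV file.

    Point order and curve assignment are preserved exactly; a write/read
    round trip is the identity.
    """
    path = str(path)
    if format is None:
        format = "tps" if path.lower().endswith(".tps") else "csv"
    if format == "tps":
        with open(path) as fh:
            return _parse_tps(fh.read(), path)
    if format == "csv":
        return _parse_landmark_csv(path)
    raise ValueError(f"unknown landmark format {format!r}")


def write_landmarks(specs: list[LandmarkSet], path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "tps" if path.lower().endswith(".tps") else "csv"
    if format == "tps":
        with open(path, "w") as fh:
            for s in specs:
                fh.write(f"LM3={s.k}\n")
                for p in s.coords:
                    fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
                if s.metadata.get("image"):
                    fh.write(f"IMAGE={s.metadata['image']}\n")
                fh.write(f"ID={s.specimen_id}\n")
        return
    if format == "csv":
        rows = []
        for s in specs:
            inv = {}
            for cname, idx in s.curves.items():
                for i in idx:
                    inv[i] = cname
            for i, p in enumerate(s.coords):
                rows.append((s.specimen_id, inv[i], i, p[0], p[1], p[2]))
        pd.DataFrame(
            rows, columns=["specimen_id", "curve", "index", "x", "y", "z"]
        ).to_csv(path, index=False)
        return
    raise ValueError(f"unknown landmark format {format!r}")


# ---------------------------------------------------------------------------
# volumes

_NRRD_DTYPES = {
    "uint8": np.uint8, "int8": np.int8, "uint16": np.uint16, "int16": np.int16,
    "uint32": np.uint32, "int32": np.int32, "int64": np.int64, "uint64": np.uint64,
    "float": np.float32, "double": np.float64,
}


def _read_nrrd(path: str):
    # Minimal NRRD0004 reader: raw/gzip encodings, the header fields this
    # package writes plus `spacings` / `space directions` for voxel size.
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ParseError(f"{path}: not an NRRD file")
        header: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if text.startswith("#"):
                continue
            key, _, value = text.partition(":")
            header[key.strip().lower()] = value.strip()
        data = fh.read()
    if header.get("encoding", "raw") == "gzip":
        data = gzip.decompress(data)
    elif header.get("encoding", "raw") != "raw":
        raise ParseError(f"{path}: unsupported NRRD encoding {header.get('encoding')!r}")
    sizes = [int(v) for v in header["sizes"].split()]
    dtype = _NRRD_DTYPES[header["type"].strip()]
    arr = np.frombuffer(data, dtype=dtype)[: int(np.prod(sizes))].reshape(sizes[::-1]).T
    spacing = None
    if "spacings" in header:
        spacing = [float(v) for v in header["spacings"].split()]
    elif "space directions" in header:
        vecs = header["space directions"].replace("(", " ").replace(")", " ").replace(",", " ").split()
        vals = [float(v) for v in vecs]
        mat = np.asarray(vals).reshape(-1, 3)
        spacing = list(np.linalg.norm(mat, axis=1))
    return arr, spacing


def _write_nrrd(path: str, arr: np.ndarray, voxel_size: float) -> None:
    arr = np.ascontiguousarray(arr.T)  # NRRD stores fastest axis first
    inv = {v: k for k, v in _NRRD_DTYPES.items()}
    header = (
        "NRRD0004\n"
        f"type: {inv[arr.dtype.type]}\n"
        "dimension: 3\n"
        f"sizes: {arr.shape[2]} {arr.shape[1]} {arr.shape[0]}\n"
        f"spacings: {voxel_size} {voxel_size} {voxel_size}\n"
        "encoding: raw\n\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(arr.tobytes())


def read_volume(path, format: str | None = None, voxel_size: float | None = None) -> LabeledVolume:
    """Read a segmented volume from NRRD or a multi-page TIFF stack.

    The tissue formulas assume isotropic physical voxels: an anisotropic
    spacing in the header is an error unless ``voxel_size`` overrides it.
    """
    path = str(path)
    if format is None:
        format = "nrrd" if path.lower().endswith(".nrrd") else "tiff_stack"
    if format == "nrrd":
        arr, spacing = _read_nrrd(path)
        if voxel_size is None:
            if spacing is None:
                raise ValueError(f"{path}: no voxel size in header; pass voxel_size")
            if not np.allclose(spacing, spacing[0], rtol=1e-6):
                raise ValueError(
                    f"{path}: anisotropic voxels {spacing}; tissue formulas need "
                    "isotropic physical units — pass voxel_size to override"
                )
            voxel_size = float(spacing[0])
    elif format == "tiff_stack":
        arr = tifffile.imread(path)
        if voxel_size is None:
            raise ValueError("TIFF stacks carry no physical spacing; pass voxel_size")
    else:
        raise ValueError(f"unknown volume format {format!r}")
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D grid, got shape {arr.shape}")
    return LabeledVolume(arr.astype(np.int16, copy=False), float(voxel_size))


def write_volume(vol: LabeledVolume, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "nrrd" if path.lower().endswith(".nrrd") else "tiff_stack"
    if format == "nrrd":
        _write_nrrd(path, vol.labels.astype(np.int16), vol.voxel_size)
    elif format == "tiff_stack":
        tifffile.imwrite(path, vol.labels.astype(np.int16))
    else:
        raise ValueError(f"unknown volume format {format!r}")


# ---------------------------------------------------------------------------
# comparative statistics


def read_comparative_stats(path) -> list[ComparativeStats]:
    """Read per-group, per-variable (mean, sd, n) records from CSV.

    Duplicate (group, variable) pairs are rejected: a comparative sample
    must be summarised exactly once.
    """
    df = pd.read_csv(path)
    required = {"group", "variable", "mean", "sd", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["group", "variable"])
    if dup.any():
        pairs = df.loc[dup, ["group", "variable"]].to_records(index=False).tolist()
        raise ParseError(f"{path}: duplicate (group, variable) pairs: {pairs}")
    return [
        ComparativeStats(str(r.group), str(r.variable), float(r.mean), float(r.sd), int(r.n))
        for r in df.itertuples()
    ]
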