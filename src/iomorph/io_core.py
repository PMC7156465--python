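"""Shared geometric types and file IO for the IOM pipeline.

All coordinates are millimetres and all forces Newtons throughout the
package; there is no unit autodetection.  Meshes travel as STL (ASCII or
binary), landmarks and results as JSON, tensile curves as plain CSV with
``#``-prefixed metadata lines, and the pipeline configuration as YAML.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import trimesh
import yaml

from .errors import (
    FormatError,
    MetadataError,
    OrderingError,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Vertex merge tolerance (mm); well below the 17 um voxel size of a
#: micro-CT derived surface model.
MERGE_TOL = 1e-6

#: Landmark roles required per ligament.  CB/AB/DOB are annotated at the
#: proximal and distal insertion points on radius and ulna; the DOAC is a
#: narrow cord annotated only at the mid-fibre radial/ulnar points.
LIGAMENT_ROLES: Mapping[str, frozenset] = {
    "CB": frozenset({"R_p", "R_d", "U_p", "U_d"}),
    "AB": frozenset({"R_p", "R_d", "U_p", "U_d"}),
    "DOB": frozenset({"R_p", "R_d", "U_p", "U_d"}),
    "DOAC": frozenset({"R_m", "U_m"}),
}

LIGAMENTS = tuple(LIGAMENT_ROLES)


def _as_points(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError(f"{name} must be an (n, 3) array, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite coordinates")
    return arr


@dataclass
class SurfaceMesh:
    """A triangulated surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    name : label carried through the pipeline (e.g. ``"radius"``)
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices, "vertices")
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError(f"faces must be (m, 3), got {self.faces.shape}")
        if len(self.vertices) < 3 or len(self.faces) < 1:
            raise ValidationError("mesh needs >= 3 vertices and >= 1 face")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValidationError("face references out-of-range vertex index")
        if (self.face_areas() <= 1e-9).any():
            raise ValidationError("mesh contains faces with (near-)zero area")

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "") -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces), name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Return a rigidly transformed copy (x -> R x + t)."""
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return SurfaceMesh(self.vertices @ r.T + t, self.faces.copy(), self.name)


@dataclass
class LandmarkSet:
    """Named clip positions defining one ligament's attachments."""

    ligament_id: str
    points: dict

    def __post_init__(self) -> None:
        if self.ligament_id not in LIGAMENT_ROLES:
            raise SchemaError(f"unknown ligament id {self.ligament_id!r}")
        required = LIGAMENT_ROLES[self.ligament_id]
        got = frozenset(self.points)
        if got != required:
            raise SchemaError(
                f"{self.ligament_id} requires roles {sorted(required)}, got {sorted(got)}"
            )
        pts = {}
        for role, p in self.points.items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.isfinite(arr).all():
                raise ValidationError(f"landmark {role} is non-finite")
            pts[role] = arr
        roles = sorted(pts)
        for i, a in enumerate(roles):
            for b in roles[i + 1 :]:
                if np.linalg.norm(pts[a] - pts[b]) <= 1e-6:
                    raise ValidationError(
                        f"landmarks {a} and {b} of {self.ligament_id} coincide"
                    )
        self.points = pts

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return LandmarkSet(
            self.ligament_id, {k: r @ v + t for k, v in self.points.items()}
        )


@dataclass
class BoneAxis:
    """Longitudinal bone axis, oriented distal -> proximal."""

    distal_point: np.ndarray
    direction: np.ndarray
    length: float

    def __post_init__(self) -> None:
        self.distal_point = np.asarray(self.distal_point, float).reshape(3)
        self.direction = np.asarray(self.direction, float).reshape(3)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValidationError("axis direction must be a unit vector")
        if not self.length > 0:
            raise ValidationError("axis length must be positive")
        self.length = float(self.length)

    def axial_coordinate(self, point) -> float:
        """Projection of *point* onto the axis, measured from the distal end (mm)."""
        p = np.asarray(point, float).reshape(3)
        return float(np.dot(p - self.distal_point, self.direction))


@dataclass
class TensileCurve:
    """A force-displacement record from a ramp-to-failure tensile test."""

    displacement: np.ndarray
    force: np.ndarray
    gauge_length: float
    specimen_id: str = ""
    ligament_id: str = ""

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float).ravel()
        self.force = np.asarray(self.force, dtype=float).ravel()
        if self.displacement.shape != self.force.shape:
            raise ValidationError("displacement and force must have equal length")
        n = len(self.force)
        if n < 3:
            raise ValidationError("curve needs at least 3 samples")
        if n < 10:
            warnings.warn(
                f"tensile curve has only {n} samples; analyses may refuse it",
                stacklevel=2,
            )
        if not np.isfinite(self.force).all() or not np.isfinite(self.displacement).all():
            raise ValidationError("curve contains non-finite samples")
        if np.any(np.diff(self.displacement) < -1e-6):
            raise OrderingError("displacement must be monotone non-decreasing")
        if not self.gauge_length > 0:
            raise MetadataError("gauge_length must be positive")
        self.gauge_length = float(self.gauge_length)

    @property
    def strain_pct(self) -> np.ndarray:
        """Grip-to-grip engineering strain in percent."""
        return 100.0 * self.displacement / self.gauge_length

    def replace(self, **kw) -> "TensileCurve":
        return replace(self, **kw)


@dataclass
class PipelineConfig:
    """Tunable parameters shared across the measurement stages.

    slab_width
        Total width (mm) of the slab used for thickness cross-sections.
    station_step
        Spacing (mm) of thickness stations along a fibre.
    preload
        Force (N) defining the displacement origin of a tensile curve.
    failure_stop_fraction
        Post-peak truncation level as a fraction of the maximum force.
    linear_fit_min_span
        Minimum width of a candidate linear-fit window, as a fraction of
        the pre-peak strain range.
    width_metric
        ``"axial"`` (longitudinal projection, default) or ``"euclidean"``
        chord for attachment widths.
    doac_clip_half_width
        Half-separation (mm) of the two parallel clip planes used for the
        narrow DOAC cord.
    """

    slab_width: float = 0.2
    station_step: float = 0.05
    preload: float = 0.5
    failure_stop_fraction: float = 0.95
    linear_fit_min_span: float = 0.1
    first_peak_drop: float = 0.05
    r2_threshold: float = 0.9
    width_metric: str = "axial"
    doac_clip_half_width: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.slab_width > 0:
            raise ValidationError("slab_width must be positive")
        if not 0 < self.station_step <= self.slab_width:
            raise ValidationError("station_step must satisfy 0 < step <= slab_width")
        if not 0 < self.failure_stop_fraction < 1:
            raise ValidationError("failure_stop_fraction must be in (0, 1)")
        if not 0 < self.linear_fit_min_span < 1:
            raise ValidationError("linear_fit_min_span must be in (0, 1)")
        if self.width_metric not in ("axial", "euclidean"):
            raise ValidationError("width_metric must be 'axial' or 'euclidean'")


# ---------------------------------------------------------------------------
# mesh IO


def merge_close_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = MERGE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than *tol* and drop degenerate faces."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    new_vertices = vertices[np.sort(first)]
    # remap via the sorted ordering so vertex order stays stable
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    a, b, c = new_faces[:, 0], new_faces[:, 1], new_faces[:, 2]
    keep = (a != b) & (b != c) & (a != c)
    new_faces = new_faces[keep]
    if len(new_faces):
        va, vb, vc = (new_vertices[new_faces[:, i]] for i in range(3))
        areas = 0.5 * np.linalg.norm(np.cross(vb - va, vc - va), axis=1)
        new_faces = new_faces[areas > 1e-9]
    return new_vertices, new_faces


def read_mesh(path, name: str | None = None) -> SurfaceMesh:
    """Read an STL file (ASCII or binary) into a validated SurfaceMesh."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type="stl", force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise FormatError(f"could not parse STL file {path}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise ValidationError(f"mesh {path} is empty")
    vertices, faces = merge_close_vertices(vertices, faces)
    if len(faces) == 0:
        raise ValidationError(f"mesh {path} is degenerate after merging")
    return SurfaceMesh(vertices, faces, name or path.stem)


def write_mesh(mesh: SurfaceMesh, path, ascii: bool = False) -> None:
    """Write a SurfaceMesh as STL; binary by default."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = mesh.to_trimesh()
    if ascii:
        path.write_text(
            trimesh.exchange.stl.export_stl_ascii(tm), encoding="ascii"
        )
    else:
        path.write_bytes(trimesh.exchange.stl.export_stl(tm))


# ---------------------------------------------------------------------------
# landmark IO


def read_landmarks(path) -> list[LandmarkSet]:
    """Read role-tagged ligament landmarks from JSON, in file order."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"landmark file {path} is not valid JSON: {exc}") from exc
    entries = payload["landmarks"] if isinstance(payload, dict) else payload
    out = []
    for entry in entries:
        try:
            out.append(LandmarkSet(entry["ligament_id"], dict(entry["points"])))
        except KeyError as exc:
            raise SchemaError(f"landmark entry missing key {exc}") from exc
    return out


def write_landmarks(landmarks: Sequence[LandmarkSet], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "landmarks": [
            {
                "ligament_id": lm.ligament_id,
                "points": {k: v.tolist() for k, v in lm.points.items()},
            }
            for lm in landmarks
        ]
    }
    path.write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# tensile curve IO (CSV with '#'-prefixed metadata header)


def read_curve(path) -> TensileCurve:
    """Read a force-displacement CSV.

    The file carries metadata in leading comment lines, e.g.::

        # gauge_length_mm: 30.0
        # specimen_id: forearm1
        # ligament_id: CB
        displacement_mm,force_N
        0.0,0.5

    Rows with non-finite values are dropped with a logged count; sample
    order is preserved.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    dropped = 0
    with path.open() as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                header = [c.strip().lower() for c in line.split(",")]
                if header[:2] != ["displacement_mm", "force_n"]:
                    raise FormatError(
                        f"{path}: expected header displacement_mm,force_N, got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            try:
                d, f = float(parts[0]), float(parts[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: bad row {line!r}") from exc
            if np.isfinite(d) and np.isfinite(f):
                rows.append((d, f))
            else:
                dropped += 1
    if dropped:
        log.warning("%s: dropped %d non-finite rows", path, dropped)
    if "gauge_length_mm" not in meta:
        raise MetadataError(f"{path}: missing gauge_length_mm metadata")
    try:
        gauge = float(meta["gauge_length_mm"])
    except ValueError as exc:
        raise MetadataError(f"{path}: unparsable gauge length") from exc
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ValidationError(f"{path}: no data rows")
    return TensileCurve(
        displacement=arr[:, 0],
        force=arr[:, 1],
        gauge_length=gauge,
        specimen_id=meta.get("specimen_id", ""),
        ligament_id=meta.get("ligament_id", ""),
    )


def write_curve(curve: TensileCurve, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"# gauge_length_mm: {float(curve.gauge_length)!r}",
        f"# specimen_id: {curve.specimen_id}",
        f"# ligament_id: {curve.ligament_id}",
        "displacement_mm,force_N",
    ]
    lines += [
        f"{float(d)!r},{float(f)!r}"
        for d, f in zip(curve.displacement, curve.force)
    ]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# config IO


def read_config(path) -> PipelineConfig:
    """Read a YAML file mirroring the PipelineConfig fields."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(payload) - known
    if unknown:
        raise SchemaError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**payload)


def write_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
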