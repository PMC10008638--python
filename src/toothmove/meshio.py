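"""Read/write surface meshes (STL), landmark CSVs and case manifests.

STL is unitless; this package declares millimetres everywhere and the
manifest carries a ``units`` field defaulting to ``"mm"``.  Coordinates are
right-handed.  ``trimesh`` does the actual STL parsing (binary and ASCII,
auto-detected); duplicate vertices inherent to STL's triangle-soup layout
are welded on read.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .geometry import DegenerateGeometryError

__all__ = [
    "LandmarkSet",
    "ToothEntry",
    "CaseManifest",
    "MeshIOError",
    "read_stl",
    "write_stl",
    "read_landmarks",
    "write_landmarks",
    "load_manifest",
    "MANDIBULAR_FDI",
]

#: Mandibular permanent teeth, third molars excluded (the study's arch).
MANDIBULAR_FDI = frozenset(range(31, 38)) | frozenset(range(41, 48))

_LANDMARK_LABELS = ("POG", "MF_L", "MF_R")


class MeshIOError(ValueError):
    """Malformed mesh, landmark or manifest input."""


def _validate_mesh(mesh: trimesh.Trimesh, path: Path) -> trimesh.Trimesh:
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise MeshIOError(f"{path}: empty solid (no triangles)")
    if mesh.faces.max() >= len(mesh.vertices):
        raise MeshIOError(f"{path}: face index out of range")
    return mesh


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Load an STL file (binary or ASCII, auto-detected) as a Trimesh.

    Duplicate vertices are welded; degenerate (zero-area index-repeating)
    faces are dropped.  Raises :class:`MeshIOError` for empty or garbled
    files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=True)
    except Exception as exc:  # trimesh raises various types on bad bytes
        raise MeshIOError(f"{path}: cannot parse STL ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshIOError(f"{path}: STL did not contain a single mesh")
    return _validate_mesh(mesh, path)


def write_stl(mesh: trimesh.Trimesh, path: str | Path, binary: bool = True) -> None:
    """Write a mesh as STL; binary by default, ASCII with ``binary=False``."""
    if len(mesh.faces) == 0:
        raise MeshIOError("refusing to write an empty mesh")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path), file_type="stl" if binary else "stl_ascii")


def _collinear(points: np.ndarray) -> bool:
    p = points - points.mean(axis=0)
    sv = np.linalg.svd(p, compute_uv=False)
    return bool(sv[1] / sv[0] < 1e-6) if sv[0] > 0 else True


@dataclass(frozen=True)
class LandmarkSet:
    """The three stable mandibular landmarks used for rough superimposition:
    pogonion and the left/right mental foramina (mm)."""

    pog: np.ndarray
    mf_left: np.ndarray
    mf_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pog", "mf_left", "mf_right"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise MeshIOError(f"landmark {name} has non-finite coordinates")
            object.__setattr__(self, name, v)
        if np.allclose(self.mf_left, self.mf_right):
            raise MeshIOError("left and right mental foramina coincide")
        if _collinear(self.as_array()):
            raise DegenerateGeometryError("landmarks are collinear")

    def as_array(self) -> np.ndarray:
        """(3, 3) array ordered POG, MF_L, MF_R."""
        return np.vstack([self.pog, self.mf_left, self.mf_right])


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV with header ``label,x,y,z`` and exactly the rows
    POG, MF_L, MF_R (any order)."""
    path = Path(path)
    found: dict[str, np.ndarray] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip().lower() for f in reader.fieldnames] != [
            "label", "x", "y", "z",
        ]:
            raise MeshIOError(f"{path}: expected header 'label,x,y,z'")
        for row in reader:
            label = row["label"].strip().upper()
            if label not in _LANDMARK_LABELS:
                raise MeshIOError(f"{path}: unknown landmark label {label!r}")
            if label in found:
                raise MeshIOError(f"{path}: duplicate landmark label {label!r}")
            found[label] = np.array([float(row[c]) for c in ("x", "y", "z")])
    missing = [lbl for lbl in _LANDMARK_LABELS if lbl not in found]
    if missing:
        raise MeshIOError(f"{path}: missing landmark label(s) {', '.join(missing)}")
    return LandmarkSet(found["POG"], found["MF_L"], found["MF_R"])


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z"])
        for label, point in zip(_LANDMARK_LABELS,
                                (lms.pog, lms.mf_left, lms.mf_right)):
            writer.writerow([label, *(repr(float(c)) for c in point)])


@dataclass(frozen=True)
class ToothEntry:
    fdi: int
    achieved: Path
    predicted: Path
    occlusal_dir: np.ndarray   # world-frame hint: crown's occlusal direction
    buccal_dir: np.ndarray     # world-frame hint: crown's buccal direction


@dataclass(frozen=True)
class CaseManifest:
    """One patient's record: mandible meshes and landmarks at T1 and T2 plus
    per-tooth achieved/predicted crown meshes keyed by FDI label."""

    patient_id: str
    t1_mandible: Path
    t2_mandible: Path
    t1_landmarks: LandmarkSet
    t2_landmarks: LandmarkSet
    teeth: tuple[ToothEntry, ...]
    units: str = "mm"


def _resolve(base: Path, rel: str) -> Path:
    p = Path(rel)
    return p if p.is_absolute() else base / p


def load_manifest(path: str | Path) -> CaseManifest:
    """Load and validate a case manifest (JSON; paths relative to the file).

    Schema::

        {
          "patient_id": "P01", "units": "mm",
          "t1_mandible": "...stl", "t2_mandible": "...stl",
          "t1_landmarks": "...csv", "t2_landmarks": "...csv",
          "teeth": [{"fdi": 31, "achieved": "...stl", "predicted": "...stl",
                     "occlusal_dir": [0,0,1], "buccal_dir": [1,0,0]}, ...]
        }
    """
    path = Path(path)
    base = path.parent
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("patient_id", "t1_mandible", "t2_mandible",
                "t1_landmarks", "t2_landmarks", "teeth"):
        if key not in raw:
            raise MeshIOError(f"{path}: manifest missing key {key!r}")
    teeth: list[ToothEntry] = []
    seen: set[int] = set()
    for entry in raw["teeth"]:
        fdi = int(entry["fdi"])
        if fdi in (38, 48):
            raise MeshIOError(
                f"{path}: FDI {fdi} is a third molar; third molars are excluded"
            )
        if fdi not in MANDIBULAR_FDI:
            raise MeshIOError(
                f"{path}: FDI {fdi} is not a mandibular tooth (expected 31-37/41-47)"
            )
        if fdi in seen:
            raise MeshIOError(f"{path}: duplicate tooth {fdi}")
        seen.add(fdi)
        achieved = _resolve(base, entry["achieved"])
        predicted = _resolve(base, entry["predicted"])
        for p in (achieved, predicted):
            if not p.exists():
                raise MeshIOError(f"{path}: referenced file missing: {p}")
        teeth.append(ToothEntry(
            fdi=fdi,
            achieved=achieved,
            predicted=predicted,
            occlusal_dir=np.asarray(entry.get("occlusal_dir", [0, 0, 1]), dtype=float),
            buccal_dir=np.asarray(entry.get("buccal_dir", [1, 0, 0]), dtype=float),
        ))
    for key in ("t1_mandible", "t2_mandible"):
        p = _resolve(base, raw[key])
        if not p.exists():
            raise MeshIOError(f"{path}: referenced file missing: {p}")
    return CaseManifest(
        patient_id=str(raw["patient_id"]),
        t1_mandible=_resolve(base, raw["t1_mandible"]),
        t2_mandible=_resolve(base, raw["t2_mandible"]),
        t1_landmarks=read_landmarks(_resolve(base, raw["t1_landmarks"])),
        t2_landmarks=read_landmarks(_resolve(base, raw["t2_landmarks"])),
        teeth=tuple(teeth),
        units=str(raw.get("units", "mm")),
    )
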