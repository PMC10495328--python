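"""File formats: landmark JSON, STL/PLY meshes, manifests, run config.

Coordinates are right-handed and in mm throughout; no global axis
convention is required because every measurement is frame-derived.
Landmark files are JSON::

    {"patient_id": ..., "jaw": "maxilla"|"mandible",
     "setup": "crown"|"root1"|"root2"|"initial",
     "occlusal_landmarks": [[x,y,z], [x,y,z], [x,y,z]],
     "teeth": [{"fdi": 16, "M": [..], "D": [..], "A": [..]}, ...],
     "discs": [{"fdi": 16, "origin": [..], "normal": [..], "radius": r}, ...]}

CSV reports use '.' decimals and UTF-8; raw outputs keep full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import FormatError, ParameterError, ParseError, ValidationError
from .exposure import CrestDisc
from .geometry import (
    FDI_IDS,
    LandmarkTriplet,
    OcclusalFrame,
    Plane,
    build_occlusal_frame,
)

JAWS = ("maxilla", "mandible")
SETUPS_ALL = ("initial", "crown", "root1", "root2")


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the pipeline stages."""

    seed: int = 0
    alpha: float = 0.05
    exposure_threshold: float = 2.0
    sampling_density: float = 25.0
    icc_form: str = "icc3"
    out_dir: str = "results"

    def __post_init__(self):
        if self.exposure_threshold <= 0:
            raise ParameterError("exposure threshold must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if self.sampling_density <= 0:
            raise ParameterError("sampling density must be > 0")


@dataclass
class LandmarkDataset:
    """One patient-jaw-setup landmark file in memory."""

    patient_id: str
    jaw: str
    setup: str
    teeth: dict[int, LandmarkTriplet]
    occlusal_landmarks: np.ndarray | None = None  # (3, 3)
    discs: dict[int, CrestDisc] = field(default_factory=dict)

    def occlusal_frame(self) -> OcclusalFrame:
        """Frame from this dataset's occlusal landmarks, oriented by the
        centroid of its own A points (the apices' side of the plane)."""
        if self.occlusal_landmarks is None:
            raise ValidationError(
                f"{self.patient_id}/{self.setup}/{self.jaw}: no occlusal landmarks"
            )
        p = self.occlusal_landmarks
        apex_centroid = np.mean([lm.A for lm in self.teeth.values()], axis=0)
        if self.jaw == "mandible":
            # the superior direction points away from mandibular apices
            plane = Plane(p[0], _plane_normal(p))
            d = plane.signed_distance(apex_centroid)
            normal = plane.normal if d < 0 else -plane.normal
            return OcclusalFrame(Plane(p[0], normal), normal)
        return build_occlusal_frame(p[0], p[1], p[2], apex_centroid)


def _plane_normal(p: np.ndarray) -> np.ndarray:
    n = np.cross(p[1] - p[0], p[2] - p[0])
    return n / np.linalg.norm(n)


def _point(obj, context: str, name: str) -> np.ndarray:
    if name not in obj:
        raise ParseError(f"{context}: missing field {name!r}")
    a = np.asarray(obj[name], dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise ParseError(f"{context}: field {name!r} is not a finite 3-vector")
    return a


def write_landmarks(dataset: LandmarkDataset, path) -> Path:
    path = Path(path)
    doc = {
        "patient_id": dataset.patient_id,
        "jaw": dataset.jaw,
        "setup": dataset.setup,
        "occlusal_landmarks": (
            None if dataset.occlusal_landmarks is None
            else np.asarray(dataset.occlusal_landmarks, float).tolist()
        ),
        "teeth": [
            {"fdi": fdi, "M": lm.M.tolist(), "D": lm.D.tolist(),
             "A": lm.A.tolist()}
            for fdi, lm in sorted(dataset.teeth.items())
        ],
        "discs": [
            {"fdi": fdi, "origin": d.plane.origin.tolist(),
             "normal": d.plane.normal.tolist(), "radius": d.radius}
            for fdi, d in sorted(dataset.discs.items())
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return path


def read_landmarks(path) -> LandmarkDataset:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: unreadable landmark file ({exc})") from exc
    for name in ("patient_id", "jaw", "setup", "teeth"):
        if name not in doc:
            raise ParseError(f"{path}: missing field {name!r}")
    if doc["jaw"] not in JAWS:
        raise ParseError(f"{path}: invalid jaw {doc['jaw']!r}")
    if doc["setup"] not in SETUPS_ALL:
        raise ParseError(f"{path}: invalid setup {doc['setup']!r}")
    teeth: dict[int, LandmarkTriplet] = {}
    for entry in doc["teeth"]:
        if "fdi" not in entry:
            raise ParseError(f"{path}: tooth entry missing 'fdi'")
        fdi = int(entry["fdi"])
        if fdi not in FDI_IDS:
            raise ValidationError(f"{path}: invalid FDI id {fdi}")
        if fdi in teeth:
            raise ValidationError(f"{path}: duplicate FDI id {fdi}")
        ctx = f"{path} tooth {fdi}"
        teeth[fdi] = LandmarkTriplet(
            fdi, _point(entry, ctx, "M"), _point(entry, ctx, "D"),
            _point(entry, ctx, "A"),
        )
    occl = None
    if doc.get("occlusal_landmarks") is not None:
        occl = np.asarray(doc["occlusal_landmarks"], float)
        if occl.shape != (3, 3) or not np.all(np.isfinite(occl)):
            raise ParseError(f"{path}: occlusal_landmarks must be 3 xyz points")
    if doc["setup"] == "root2" and occl is None:
        raise ValidationError(
            f"{path}: root setup-2 requires occlusal landmarks (shared frame)"
        )
    discs: dict[int, CrestDisc] = {}
    for entry in doc.get("discs", []):
        fdi = int(entry.get("fdi", -1))
        if fdi not in FDI_IDS:
            raise ValidationError(f"{path}: disc with invalid FDI id {fdi}")
        ctx = f"{path} disc {fdi}"
        normal = _point(entry, ctx, "normal")
        normal = normal / np.linalg.norm(normal)
        discs[fdi] = CrestDisc(
            fdi, Plane(_point(entry, ctx, "origin"), normal),
            float(entry.get("radius", 4.0)),
        )
    return LandmarkDataset(
        str(doc["patient_id"]), doc["jaw"], doc["setup"], teeth, occl, discs
    )


# ---------------------------------------------------------------------------
# meshes


def read_mesh(path) -> trimesh.Trimesh:
    """Load an STL (binary or ASCII) or PLY mesh; units assumed mm."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such mesh file")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # trimesh raises various types for bad files
        raise FormatError(f"{path}: unreadable mesh ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path}: no triangle geometry found")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, ascii_stl: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        data = trimesh.exchange.stl.export_stl_ascii(mesh).encode() if ascii_stl \
            else trimesh.exchange.stl.export_stl(mesh)
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    elif suffix == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh))
    else:
        raise FormatError(f"unsupported mesh format {suffix!r}")
    return path


# ---------------------------------------------------------------------------
# manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class Manifest:
    """Index of a cohort directory: per patient / setup / jaw file paths
    (relative to the manifest) with checksums."""

    root: Path
    entries: dict  # patient -> setup -> jaw -> {"landmarks": ..., "teeth": {...}, "bone": {...}}
    checksums: dict[str, str] = field(default_factory=dict)

    def path(self, relative: str) -> Path:
        return self.root / relative

    def save(self, name: str = "manifest.json") -> Path:
        doc = {"entries": self.entries, "checksums": self.checksums}
        out = self.root / name
        out.write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")
        return out

    @classmethod
    def load(cls, root, name: str = "manifest.json") -> "Manifest":
        root = Path(root)
        f = root / name
        if not f.exists():
            raise ParseError(f"{f}: manifest not found")
        doc = json.loads(f.read_text(encoding="utf-8"))
        m = cls(root, doc["entries"], doc.get("checksums", {}))
        for rel in m.checksums:
            if not (root / rel).exists():
                raise ValidationError(f"manifest references missing file {rel}")
        return m

    def add_file(self, rel: str) -> None:
        self.checksums[rel] = _sha256(self.root / rel)


def write_cohort(cohort, out_dir, *, with_meshes: bool | None = None) -> Manifest:
    """Write a synthetic cohort as the landmark/mesh files the
    measurement stages consume, plus a ground-truth manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out_dir, {})
    for patient in cohort.patients:
        pentry = manifest.entries.setdefault(patient.patient_id, {})
        for (setup, jaw), arch in sorted(patient.arches.items()):
            sub = Path(patient.patient_id) / setup
            ds = LandmarkDataset(
                patient.patient_id, jaw, setup, arch.landmarks,
                occlusal_landmarks=arch.occlusal_points, discs=arch.discs,
            )
            rel = str(sub / f"{jaw}.json")
            write_landmarks(ds, out_dir / rel)
            manifest.add_file(rel)
            entry = {"landmarks": rel, "teeth": {}, "bone": {}}
            meshes = with_meshes if with_meshes is not None \
                else arch.tooth_meshes is not None
            if meshes and arch.tooth_meshes is not None:
                for fdi, mesh in sorted(arch.tooth_meshes.items()):
                    trel = str(sub / f"{jaw}_tooth_{fdi}.stl")
                    write_mesh(mesh, out_dir / trel)
                    manifest.add_file(trel)
                    entry["teeth"][str(fdi)] = trel
                for fdi, mesh in sorted(arch.bone_meshes.items()):
                    brel = str(sub / f"{jaw}_bone_{fdi}.stl")
                    write_mesh(mesh, out_dir / brel)
                    manifest.add_file(brel)
                    entry["bone"][str(fdi)] = brel
            pentry.setdefault(setup, {})[jaw] = entry
    cohort.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    manifest.add_file("ground_truth.csv")
    manifest.save()
    return manifest
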