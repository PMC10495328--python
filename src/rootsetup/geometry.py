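"""Occlusal reference frame and signed tooth angulation / inclination.

Every tooth carries three landmarks: the most mesial point M, the most
distal point D and the apex point A (apex of single-rooted teeth, centre
of furcation of multi-rooted ones).  The tooth long axis joins A to the
M-D midpoint.  Angles are measured against the occlusal plane -- the
plane through the distobuccal cusp tips of the maxillary second molars
and the maxillary central-incisor contact point:

* **angulation** -- the long axis projected onto the plane through M and
  D perpendicular to the occlusal plane, measured from the occlusal
  normal; positive when the apex is displaced distally.
* **inclination** -- the long axis projected onto the plane perpendicular
  to both the occlusal plane and the angulation plane, measured from the
  occlusal normal; positive when the apex is displaced toward
  lingual/palatal.

Angles are reported in degrees and computed with ``atan2`` of projected
components, which is numerically stable near 0.  "Distal" is
operationalised as ``normalize(D - M)`` in every quadrant: the landmark
labels carry the anatomy, so the sign rule is identical left and right.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError

#: default tolerance for point coincidence, in mm
POINT_TOL = 1e-6
#: default tolerance for near-parallel directions, in radians
PARALLEL_TOL = 1e-3

#: valid FDI ids: quadrants 1-4, positions 1-7
FDI_IDS = frozenset(q * 10 + i for q in (1, 2, 3, 4) for i in range(1, 8))

SETUP_LABELS = ("crown", "root1", "root2", "initial")


def _vec(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"{name} has non-finite coordinates: {a}")
    return a


def _unit(v: np.ndarray, name: str = "vector", tol: float = 1e-12) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < tol:
        raise GeometryError(f"cannot normalise near-zero {name}")
    return v / n


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _vec(self.origin, "plane origin"))
        n = _vec(self.normal, "plane normal")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise GeometryError("plane normal must have unit length (within 1e-9)")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points) -> np.ndarray:
        """Signed distance of ``points`` (in mm), positive on the normal side."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.origin) @ self.normal
        return d if d.size > 1 else float(d[0])


@dataclass(frozen=True)
class LandmarkTriplet:
    """The M, D and A landmarks of one tooth (coordinates in mm)."""

    tooth_id: int
    M: np.ndarray
    D: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        if self.tooth_id not in FDI_IDS:
            raise GeometryError(f"invalid FDI tooth id {self.tooth_id}")
        for name in ("M", "D", "A"):
            object.__setattr__(self, name, _vec(getattr(self, name), name))
        if np.linalg.norm(self.D - self.M) <= POINT_TOL:
            raise GeometryError(f"tooth {self.tooth_id}: M and D coincide")
        mid = 0.5 * (self.M + self.D)
        if np.linalg.norm(self.A - mid) <= POINT_TOL:
            raise GeometryError(
                f"tooth {self.tooth_id}: A coincides with the M-D midpoint"
            )

    @property
    def quadrant(self) -> int:
        return self.tooth_id // 10

    @property
    def position(self) -> int:
        return self.tooth_id % 10

    @property
    def jaw(self) -> str:
        return "maxilla" if self.quadrant in (1, 2) else "mandible"

    def transformed(self, matrix: np.ndarray) -> "LandmarkTriplet":
        """Apply a 4x4 homogeneous transform to all three landmarks."""
        R, t = np.asarray(matrix)[:3, :3], np.asarray(matrix)[:3, 3]
        return LandmarkTriplet(
            self.tooth_id, R @ self.M + t, R @ self.D + t, R @ self.A + t
        )


@dataclass(frozen=True)
class OcclusalFrame:
    """The shared occlusal plane with its superior orientation.

    ``superior`` is the plane normal oriented from the occlusal surfaces
    toward the maxillary root apices.
    """

    plane: Plane
    superior: np.ndarray

    def __post_init__(self):
        s = _vec(self.superior, "superior")
        if not (
            np.allclose(s, self.plane.normal, atol=1e-9)
            or np.allclose(s, -self.plane.normal, atol=1e-9)
        ):
            raise GeometryError("superior must equal the plane normal or its negation")
        object.__setattr__(self, "superior", s)

    def transformed(self, matrix: np.ndarray) -> "OcclusalFrame":
        R, t = np.asarray(matrix)[:3, :3], np.asarray(matrix)[:3, 3]
        plane = Plane(R @ self.plane.origin + t, R @ self.plane.normal)
        return OcclusalFrame(plane, R @ self.superior)


@dataclass(frozen=True)
class AngularMeasurement:
    """Signed angulation and inclination of one tooth in one setup.

    ``frame`` records the occlusal frame the angles were measured in; all
    setups of one patient share the same frame object.
    """

    tooth_id: int
    angulation: float
    inclination: float
    setup_label: str
    frame: "OcclusalFrame | None" = None


def build_occlusal_frame(
    p_molar_right,
    p_molar_left,
    p_incisor_contact,
    apex_centroid,
    *,
    tol: float = POINT_TOL,
) -> OcclusalFrame:
    """Occlusal plane through the two second-molar distobuccal cusps and
    the central-incisor contact point, oriented toward the apex centroid.
    """
    p1 = _vec(p_molar_right, "molar-right cusp")
    p2 = _vec(p_molar_left, "molar-left cusp")
    p3 = _vec(p_incisor_contact, "incisor contact")
    c = _vec(apex_centroid, "apex centroid")
    n = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(n)
    if area <= tol:
        raise GeometryError("occlusal landmarks are collinear (degenerate plane)")
    n = n / np.linalg.norm(n)
    plane = Plane(p1, n)
    d = plane.signed_distance(c)
    if abs(d) < tol:
        raise GeometryError(
            "apex centroid lies on the occlusal plane: superior orientation ambiguous"
        )
    superior = n if d > 0 else -n
    return OcclusalFrame(Plane(p1, superior), superior)


def long_axis(lm: LandmarkTriplet) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint of M and D, and the unit axis from that midpoint to A."""
    mid = 0.5 * (lm.M + lm.D)
    axis = lm.A - mid
    n = np.linalg.norm(axis)
    if n <= POINT_TOL:
        raise GeometryError(f"tooth {lm.tooth_id}: degenerate (zero-length) long axis")
    return mid, axis / n


def _distal_in_plane(
    lm: LandmarkTriplet, frame: OcclusalFrame, tol: float = PARALLEL_TOL
) -> np.ndarray:
    """Unit 'distal' direction: D - M projected into the occlusal plane."""
    md = lm.D - lm.M
    md_u = md / np.linalg.norm(md)
    s = frame.superior
    in_plane = md_u - (md_u @ s) * s
    # sin of the angle between D-M and superior
    if np.linalg.norm(in_plane) < np.sin(tol):
        raise GeometryError(
            f"tooth {lm.tooth_id}: M-D direction is parallel to the occlusal "
            "normal; angulation plane undefined"
        )
    return in_plane / np.linalg.norm(in_plane)


def _signed_angle(comp_along: float, comp_superior: float) -> float:
    """Signed angle (deg) from the occlusal-normal *line* to a projected
    axis with in-plane component ``comp_along`` and normal component
    ``comp_superior``.  Sign follows ``comp_along``.
    """
    if abs(comp_along) < 1e-300 and abs(comp_superior) < 1e-300:
        raise GeometryError("projected axis has near-zero length")
    mag = np.degrees(np.arctan2(abs(comp_along), abs(comp_superior)))
    return float(np.copysign(mag, comp_along)) if comp_along != 0.0 else 0.0


def angulation(
    lm: LandmarkTriplet, frame: OcclusalFrame, *, tol: float = PARALLEL_TOL
) -> float:
    """Signed mesiodistal tip of the long axis, in degrees.

    The axis is projected onto the plane through M and D perpendicular to
    the occlusal plane; positive when the apex is distal to the M-D
    midpoint.
    """
    _, u = long_axis(lm)
    t = _distal_in_plane(lm, frame, tol)
    s = frame.superior
    comp_t, comp_s = float(u @ t), float(u @ s)
    if np.hypot(comp_t, comp_s) < 1e-9:
        raise GeometryError(f"tooth {lm.tooth_id}: degenerate angulation projection")
    return _signed_angle(comp_t, comp_s)


def inclination(
    lm: LandmarkTriplet,
    frame: OcclusalFrame,
    lingual,
    *,
    tol: float = PARALLEL_TOL,
) -> float:
    """Signed buccolingual torque of the long axis, in degrees.

    The axis is projected onto the plane perpendicular to the occlusal
    plane and to the angulation plane; positive when the apex is
    displaced toward ``lingual``.
    """
    lg = _unit(_vec(lingual, "lingual"), "lingual")
    s = frame.superior
    if abs(lg @ s) > 1e-6:
        raise GeometryError("lingual reference must lie in the occlusal plane")
    _, u = long_axis(lm)
    t = _distal_in_plane(lm, frame, tol)
    b = np.cross(s, t)  # in-plane direction perpendicular to the angulation plane
    align = float(b @ lg)
    if abs(align) < np.cos(np.pi / 2 - tol):
        raise GeometryError(
            f"tooth {lm.tooth_id}: lingual reference parallel to M-D direction"
        )
    comp_b, comp_s = float(u @ b), float(u @ s)
    if np.hypot(comp_b, comp_s) < 1e-9:
        raise GeometryError(f"tooth {lm.tooth_id}: degenerate inclination projection")
    return _signed_angle(comp_b * np.sign(align), comp_s)


def lingual_reference(
    arch_midpoints: Sequence, lm: LandmarkTriplet, frame: OcclusalFrame
) -> np.ndarray:
    """Unit vector in the occlusal plane, perpendicular to D-M, pointing
    from the tooth midpoint toward the arch interior (the projected
    centroid of all tooth midpoints)."""
    mids = np.asarray([_vec(p, "arch midpoint") for p in arch_midpoints], dtype=float)
    if len(mids) < 3:
        raise GeometryError("need at least 3 arch midpoints for the lingual reference")
    s = frame.superior
    centroid = mids.mean(axis=0)
    mid, _ = long_axis(lm)
    towards = centroid - mid
    towards -= (towards @ s) * s  # project into the occlusal plane
    t = _distal_in_plane(lm, frame)
    b = np.cross(s, t)
    proj = float(b @ towards)
    if abs(proj) <= POINT_TOL:
        raise GeometryError(
            f"tooth {lm.tooth_id}: arch centroid projection coincides with the "
            "tooth midpoint; lingual direction ambiguous"
        )
    return b if proj > 0 else -b


def measure_setup(
    landmarks: Iterable[LandmarkTriplet],
    frame: OcclusalFrame,
    setup_label: str,
    *,
    arch_midpoints: Sequence | None = None,
) -> list[AngularMeasurement]:
    """Angulation and inclination of every tooth of one setup, all
    measured against the single shared frame.

    With three setups per patient the caller passes the frame built from
    the root setup-2 occlusal landmarks for every setup; a standalone
    model is measured in its own frame.  ``arch_midpoints`` defaults to
    the M-D midpoints of the given landmarks (used to resolve the
    lingual direction).
    """
    if setup_label not in SETUP_LABELS:
        raise GeometryError(f"unknown setup label {setup_label!r}")
    lms = list(landmarks)
    if not lms:
        return []
    if arch_midpoints is None:
        arch_midpoints = [long_axis(lm)[0] for lm in lms]
    out = []
    for lm in lms:
        try:
            lingual = lingual_reference(arch_midpoints, lm, frame)
            ang = angulation(lm, frame)
            inc = inclination(lm, frame, lingual)
        except GeometryError as exc:
            raise GeometryError(f"tooth {lm.tooth_id}: {exc}") from exc
        out.append(AngularMeasurement(lm.tooth_id, ang, inc, setup_label, frame))
    return out
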