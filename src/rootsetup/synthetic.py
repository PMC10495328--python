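"""Seeded synthetic dental-arch cohorts with known ground truth.

The generator emulates the structure of a molar-distalization setup
study: per patient, two 14-tooth jaws observed under an initial scan and
three setup conditions (crown setup, root setup-1, root setup-2) that
differ in angulation/inclination dispersion and in designed root
exposure, with per-tooth crest reference discs and alveolar-bone
channels that can carry designed dehiscences and fenestration windows.

Teeth are frustum-crown + cone-root surfaces of revolution, not anatomic
models: every measured quantity depends only on landmarks and surfaces,
so analytic oracles are exact.  Multi-rooted molars are modelled as a
single cone with the A point at a configured furcation height fraction.

Conventions: coordinates in mm, occlusal plane exactly ``z = 0``,
maxillary apices toward +z, arch along the parabola ``y = c x**2``.
Landmarks are generated exactly: M and D sit at the cervical extremes
along the (horizontal, in-occlusal-plane) distal direction ``t`` and the
long axis is ``normalize(tan(ang) t + tan(inc) l + s)`` toward the apex,
so re-measuring a generated tooth recovers the drawn angles to machine
precision.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.integrate import cumulative_trapezoid

from .errors import LayoutError, ParameterError
from .exposure import TOOTH_TYPE, CrestDisc, SIDES
from .geometry import LandmarkTriplet, OcclusalFrame, Plane, build_occlusal_frame

#: parabolic arch curvature (1/mm): y = ARCH_CURVATURE * x**2
ARCH_CURVATURE = 0.04

SETUPS = ("crown", "root1", "root2")


# ---------------------------------------------------------------------------
# tooth templates

#: per (jaw, position): crown height, mesiodistal width, root length (mm),
#: multi-rooted flag.  Widths/lengths are rounded textbook averages.
_DIMS = {
    ("maxilla", 1): (10.0, 8.5, 13.0, False),
    ("maxilla", 2): (9.0, 6.5, 13.0, False),
    ("maxilla", 3): (10.0, 7.6, 16.5, False),
    ("maxilla", 4): (8.5, 7.2, 14.0, False),
    ("maxilla", 5): (8.5, 6.8, 14.0, False),
    ("maxilla", 6): (7.5, 10.4, 13.0, True),
    ("maxilla", 7): (7.0, 9.8, 13.0, True),
    ("mandible", 1): (9.0, 5.3, 12.5, False),
    ("mandible", 2): (9.5, 5.9, 14.0, False),
    ("mandible", 3): (11.0, 6.8, 15.5, False),
    ("mandible", 4): (8.5, 7.0, 14.0, False),
    ("mandible", 5): (8.0, 7.1, 14.5, False),
    ("mandible", 6): (7.5, 11.4, 14.0, True),
    ("mandible", 7): (7.0, 10.8, 13.0, True),
}

#: gap left between neighbouring cervical contours, mm
_CONTACT_GAP = 0.5


@dataclass(frozen=True)
class ToothTemplate:
    """Parametric frustum-crown + cone-root tooth."""

    tooth_id: int
    crown_height: float
    crown_radius_occlusal: float
    crown_radius_cervical: float
    root_length: float
    root_radius: float
    multi_root: bool = False
    furcation_fraction: float = 0.35

    def __post_init__(self):
        for name in ("crown_height", "crown_radius_occlusal",
                     "crown_radius_cervical", "root_length", "root_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"template {self.tooth_id}: {name} must be > 0")
        if not 0.0 < self.furcation_fraction < 1.0:
            raise ParameterError("furcation_fraction must be in (0, 1)")

    @property
    def apex_distance(self) -> float:
        """Distance from the cervical midpoint to the A point: the cone
        apex for single roots, the furcation centre for multi-rooted."""
        if self.multi_root:
            return self.furcation_fraction * self.root_length
        return self.root_length

    @property
    def jaw(self) -> str:
        return "maxilla" if self.tooth_id // 10 in (1, 2) else "mandible"


def default_templates(jaw: str) -> dict[int, ToothTemplate]:
    """The 14 default templates of one jaw, keyed by FDI id."""
    quads = (1, 2) if jaw == "maxilla" else (4, 3)
    out = {}
    for quad in quads:
        for pos in range(1, 8):
            ch, width, rl, multi = _DIMS[jaw, pos]
            r_cerv = width / 2 - _CONTACT_GAP / 2
            out[quad * 10 + pos] = ToothTemplate(
                tooth_id=quad * 10 + pos,
                crown_height=ch,
                crown_radius_occlusal=0.9 * r_cerv,
                crown_radius_cervical=r_cerv,
                root_length=rl,
                root_radius=0.7 * r_cerv,
                multi_root=multi,
            )
    return out


def _refine_polyline(points: np.ndarray, max_seg: float) -> np.ndarray:
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / max_seg)))
        for i in range(1, n + 1):
            out.append(a + (b - a) * i / n)
    return np.array(out)


def _template_mesh(tpl: ToothTemplate, sections: int = 48) -> trimesh.Trimesh:
    """Watertight surface of revolution: crown below z=0, root apex at
    ``z = root_length``; cervical midpoint at the origin.

    The profile is pre-refined to ~0.8 mm segments so the triangles are
    near-isotropic and downstream subdivision to a sampling step is
    cheap.
    """
    profile = np.array(
        [
            [0.0, -tpl.crown_height],
            [tpl.crown_radius_occlusal, -tpl.crown_height],
            [tpl.crown_radius_cervical, 0.0],
            [tpl.root_radius, 0.0],
            [0.0, tpl.root_length],
        ]
    )
    mesh = trimesh.creation.revolve(_refine_polyline(profile, 0.8),
                                    sections=sections)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def template_landmarks(tpl: ToothTemplate) -> LandmarkTriplet:
    r = tpl.crown_radius_cervical
    return LandmarkTriplet(
        tpl.tooth_id,
        M=np.array([-r, 0.0, 0.0]),
        D=np.array([r, 0.0, 0.0]),
        A=np.array([0.0, 0.0, tpl.apex_distance]),
    )


def build_tooth(
    tpl: ToothTemplate, pose: np.ndarray | None = None
) -> tuple[trimesh.Trimesh, LandmarkTriplet]:
    """Posed template mesh with consistently transformed landmarks.

    ``pose`` is a 4x4 rigid transform (identity when omitted).  The long
    axis of the returned landmarks is the posed template axis.
    """
    mesh = _template_mesh(tpl)
    lm = template_landmarks(tpl)
    if pose is not None:
        pose = np.asarray(pose, float)
        if pose.shape != (4, 4):
            raise ParameterError("pose must be a 4x4 homogeneous transform")
        mesh.apply_transform(pose)
        lm = lm.transformed(pose)
    return mesh, lm


# ---------------------------------------------------------------------------
# arch layout

@dataclass(frozen=True)
class _ToothSite:
    center: np.ndarray   # cervical midpoint
    distal: np.ndarray   # unit, horizontal, M -> D direction
    lingual: np.ndarray  # unit, horizontal, toward arch interior
    apical: np.ndarray   # unit, +/-z


def _arc_to_x(arc_lengths: np.ndarray, c: float) -> np.ndarray:
    xs = np.linspace(0.0, 80.0, 8001)
    ds = np.sqrt(1.0 + (2.0 * c * xs) ** 2)
    S = cumulative_trapezoid(ds, xs, initial=0.0)
    return np.interp(arc_lengths, S, xs)


def _arch_layout(
    jaw: str,
    templates: dict[int, ToothTemplate],
    distalization: float = 0.0,
    curvature: float = ARCH_CURVATURE,
) -> dict[int, _ToothSite]:
    """Cervical sites of the 14 teeth along the parabolic arch."""
    if len(templates) != 14:
        raise ParameterError(f"expected 14 templates per jaw, got {len(templates)}")
    apical_z = 1.0 if jaw == "maxilla" else -1.0
    sites: dict[int, _ToothSite] = {}
    for quad in sorted({fdi // 10 for fdi in templates}):
        fdis = sorted(fdi for fdi in templates if fdi // 10 == quad)
        widths = np.array([2 * templates[f].crown_radius_cervical + _CONTACT_GAP
                           for f in fdis])
        arc = np.cumsum(widths) - widths / 2
        # posterior (distal) shift: molars fully, premolars half
        shift = np.array([
            distalization if templates[f].tooth_id % 10 >= 6
            else distalization / 2 if templates[f].tooth_id % 10 >= 4
            else 0.0
            for f in fdis
        ])
        arc = arc + shift
        x = _arc_to_x(arc, curvature)
        y = curvature * x**2
        sign = 1.0 if quad in (1, 4) else -1.0  # patient's right at x > 0
        for f, xi, yi in zip(fdis, x, y):
            # d/dxi of (sign*xi, c*xi^2): distal = direction of increasing xi
            distal = np.array([sign, 2 * curvature * xi, 0.0])
            distal /= np.linalg.norm(distal)
            lingual = np.array([-2 * curvature * (sign * xi), 1.0, 0.0])
            lingual /= np.linalg.norm(lingual)
            center = np.array([sign * xi, yi,
                               apical_z * templates[f].crown_height])
            sites[f] = _ToothSite(center, distal, lingual,
                                  np.array([0.0, 0.0, apical_z]))
    _check_collisions(sites, templates)
    return sites


def _check_collisions(sites, templates, tol: float = 0.05) -> None:
    fdis = sorted(sites)
    for a, b in itertools.combinations(fdis, 2):
        if abs(a % 10 - b % 10) > 1 and a // 10 == b // 10:
            continue
        d = np.linalg.norm(sites[a].center[:2] - sites[b].center[:2])
        r = templates[a].crown_radius_cervical + templates[b].crown_radius_cervical
        if d < r - tol:
            raise LayoutError(f"teeth {a} and {b} overlap ({d:.2f} mm apart)")


# ---------------------------------------------------------------------------
# scenarios and exposure programs

@dataclass(frozen=True)
class ExposureSpec:
    """One designed bone defect: a crest-level dehiscence of the given
    depth, or a fenestration window of the given height centred mid-root."""

    tooth_id: int
    side: str  # "buccal" | "lingual"
    kind: str  # "dehiscence" | "fenestration"
    depth: float

    def __post_init__(self):
        if self.side not in SIDES:
            raise ParameterError(f"unknown side {self.side!r}")
        if self.kind not in ("dehiscence", "fenestration"):
            raise ParameterError(f"unknown defect kind {self.kind!r}")
        if self.depth < 0:
            raise ParameterError("defect depth must be >= 0")


@dataclass(frozen=True)
class SetupScenario:
    """One setup condition: angular dispersion plus a concrete per-tooth
    exposure program."""

    label: str
    angulation_sd: float
    inclination_sd: float
    exposure_program: tuple[ExposureSpec, ...] = ()
    distalization: float = 0.0

    def __post_init__(self):
        if self.angulation_sd < 0 or self.inclination_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.distalization < 0:
            raise ParameterError("distalization must be >= 0")


#: fenestration windows are centred at this fraction of the root length
FENESTRATION_CENTER_FRACTION = 0.55


@dataclass(frozen=True)
class ExposureModel:
    """Stochastic generator of per-tooth exposure programs.

    ``site_prob`` maps (jaw, side, tooth type) to the probability that a
    tooth of that type carries a defect on that side; defect depths /
    window heights are |N(0, depth_sd)| clipped to sensible mesh-carving
    ranges.
    """

    site_prob: dict[tuple[str, str, str], float] = field(default_factory=dict)
    default_prob: float = 0.0
    depth_sd: float = 3.0
    fenestration_prob: float = 0.25
    min_depth: float = 0.2
    max_depth: float = 5.0
    max_window: float = 3.0

    def draw_program(
        self,
        templates: dict[int, ToothTemplate],
        rng: np.random.Generator,
    ) -> tuple[ExposureSpec, ...]:
        specs = []
        for fdi in sorted(templates):
            tpl = templates[fdi]
            ttype = TOOTH_TYPE[fdi % 10]
            for side in SIDES:
                p = self.site_prob.get((tpl.jaw, side, ttype), self.default_prob)
                if rng.random() >= p:
                    continue
                depth = float(np.clip(abs(rng.normal(0.0, self.depth_sd)),
                                      self.min_depth, self.max_depth))
                if rng.random() < self.fenestration_prob:
                    h = min(depth, self.max_window)
                    specs.append(ExposureSpec(fdi, side, "fenestration", h))
                else:
                    # keep the crest defect clear of the mid-root window zone
                    cap = (FENESTRATION_CENTER_FRACTION * tpl.root_length
                           - self.max_window / 2 - 1.0)
                    specs.append(
                        ExposureSpec(fdi, side, "dehiscence", min(depth, cap))
                    )
        return tuple(specs)


def analytic_exposure_length(tpl: ToothTemplate, spec: ExposureSpec) -> float:
    """Ground-truth measured length of one designed defect.

    A dehiscence of depth d exposes the root down to d below the crest
    disc, so the point-to-plane dehiscence length is d.  A fenestration
    window of height h exposes a band of the cone surface whose extreme
    points are separated by ``hypot(h, dr)`` where dr is the cone-radius
    change across the band.
    """
    if spec.kind == "dehiscence":
        return spec.depth
    dr = tpl.root_radius * spec.depth / tpl.root_length
    return float(np.hypot(spec.depth, dr))


@dataclass(frozen=True)
class ScenarioConfig:
    angulation_sd: float
    inclination_sd: float
    exposure: ExposureModel | None = None
    distalization: float = 0.0


@dataclass(frozen=True)
class CohortEffect:
    """Per-setup generative conditions for a cohort."""

    scenarios: dict[str, ScenarioConfig]

    def draw(self, label: str, templates, rng) -> SetupScenario:
        cfg = self.scenarios[label]
        program = (cfg.exposure.draw_program(templates, rng)
                   if cfg.exposure is not None else ())
        return SetupScenario(label, cfg.angulation_sd, cfg.inclination_sd,
                             program, cfg.distalization)


def study_effect() -> CohortEffect:
    """Default cohort conditions mirroring the study's qualitative
    structure: the crown setup has larger angular dispersion and designed
    posterior/anterior exposures, the root setups are more parallel, and
    root setup-2 has near-zero exposure.  Site probabilities follow the
    crown-setup frequency pattern of the exposure-frequency table
    (maxilla: buccal posterior; mandible: lingual)."""
    crown_sites = {
        ("maxilla", "buccal", "incisor"): 0.25,
        ("maxilla", "buccal", "canine"): 0.45,
        ("maxilla", "buccal", "premolar"): 0.25,
        ("maxilla", "buccal", "molar"): 0.45,
        ("maxilla", "lingual", "incisor"): 0.22,
        ("maxilla", "lingual", "canine"): 0.06,
        ("mandible", "buccal", "incisor"): 0.40,
        ("mandible", "buccal", "canine"): 0.18,
        ("mandible", "lingual", "incisor"): 0.45,
        ("mandible", "lingual", "canine"): 0.40,
        ("mandible", "lingual", "premolar"): 0.16,
        ("mandible", "lingual", "molar"): 0.25,
    }
    designed = ExposureModel(site_prob=crown_sites, depth_sd=3.0)
    minimal = ExposureModel(default_prob=0.02, depth_sd=0.5, max_depth=1.5)
    return CohortEffect(
        {
            "initial": ScenarioConfig(4.0, 4.0, None, 0.0),
            "crown": ScenarioConfig(4.0, 4.0, designed, 2.0),
            "root1": ScenarioConfig(2.5, 2.5, designed, 2.0),
            "root2": ScenarioConfig(2.5, 2.5, minimal, 2.0),
        }
    )


def null_effect() -> CohortEffect:
    """Identical generative distributions for every condition (type-I
    calibration).  Exposure rates give each tooth-side roughly an 11%
    chance of combined exposure above 2 mm, matching the frequency range
    the crown setup shows in practice."""
    model = ExposureModel(default_prob=0.22, depth_sd=3.0)
    cfg = ScenarioConfig(3.0, 3.0, model, 0.0)
    return CohortEffect({label: cfg for label in ("initial", *SETUPS)})


# ---------------------------------------------------------------------------
# arch and cohort assembly

@dataclass
class ArchData:
    """One patient-jaw-setup dataset."""

    patient_id: str
    jaw: str
    setup: str
    landmarks: dict[int, LandmarkTriplet]
    occlusal_points: np.ndarray  # (3, 3): molar-right, molar-left, incisor
    apex_centroid: np.ndarray
    discs: dict[int, CrestDisc]
    truth: list[dict]
    tooth_meshes: dict[int, trimesh.Trimesh] | None = None
    bone_meshes: dict[int, trimesh.Trimesh] | None = None

    def occlusal_frame(self) -> OcclusalFrame:
        p = self.occlusal_points
        return build_occlusal_frame(p[0], p[1], p[2], self.apex_centroid)


def _axis_from_angles(site: _ToothSite, ang_deg: float, inc_deg: float) -> np.ndarray:
    u = (np.tan(np.radians(ang_deg)) * site.distal
         + np.tan(np.radians(inc_deg)) * site.lingual
         + site.apical)
    return u / np.linalg.norm(u)


def _tooth_pose(site: _ToothSite, axis: np.ndarray) -> np.ndarray:
    x = site.distal - (site.distal @ axis) * axis
    x /= np.linalg.norm(x)
    y = np.cross(axis, x)
    T = np.eye(4)
    T[:3, 0], T[:3, 1], T[:3, 2], T[:3, 3] = x, y, axis, site.center
    return T


_BONE_MARGIN = 2.5     # lateral clearance around the root, mm
_BONE_EXTRA_DEPTH = 2.0  # bone continues past the apex, mm
_SEGMENT_FACTOR = 1.6  # per-tooth channel length relative to tooth width


def _ear_clip(poly: np.ndarray) -> np.ndarray:
    """Triangulate a simple CCW polygon by ear clipping."""
    idx = list(range(len(poly)))
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 10000:
        guard += 1
        n = len(idx)
        for k in range(n):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % n]
            a, b, c = poly[i0], poly[i1], poly[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-12:
                continue
            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                if _point_in_tri(poly[j], a, b, c):
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                break
        else:
            raise LayoutError("polygon triangulation failed")
    tris.append((idx[0], idx[1], idx[2]))
    return np.array(tris, dtype=int)


def _point_in_tri(p, a, b, c, eps: float = 1e-12) -> bool:
    d1 = (p[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (p[1] - b[1])
    d2 = (p[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (p[1] - c[1])
    d3 = (p[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (p[1] - a[1])
    neg = (d1 < -eps) or (d2 < -eps) or (d3 < -eps)
    pos = (d1 > eps) or (d2 > eps) or (d3 > eps)
    return not (neg and pos)


def _extrude_polygon(points2d: np.ndarray, length: float) -> trimesh.Trimesh:
    """Watertight prism: ``points2d`` (simple CCW polygon in the local
    (u, v) plane) extruded along w from -length/2 to +length/2."""
    tris = _ear_clip(points2d)
    n = len(points2d)
    bottom = np.column_stack([points2d, np.full(n, -length / 2)])
    top = np.column_stack([points2d, np.full(n, length / 2)])
    verts = np.vstack([bottom, top])
    faces = []
    for (i, j, k) in tris:
        faces.append((i, k, j))          # bottom cap, facing -w
        faces.append((n + i, n + j, n + k))  # top cap, facing +w
    for i in range(n):
        j = (i + 1) % n
        faces.append((i, j, n + j))
        faces.append((i, n + j, n + i))
    return trimesh.Trimesh(verts, np.array(faces), process=False)


def _bone_cross_section(
    tpl: ToothTemplate, specs: list[ExposureSpec]
) -> np.ndarray:
    """Simple polygon in (lingual, apical) coordinates of the bone channel
    around one tooth, with the programmed defects carved out."""
    from shapely.geometry import box
    from shapely.geometry.polygon import orient

    w = tpl.root_radius + _BONE_MARGIN
    H = tpl.root_length + _BONE_EXTRA_DEPTH
    poly = box(-w, 0.0, w, H)  # u: buccal at -w .. lingual at +w; v: apical depth
    for spec in specs:
        if spec.kind == "dehiscence":
            u0, u1 = (-w - 1.0, 0.0) if spec.side == "buccal" else (0.0, w + 1.0)
            cut = box(u0, -1.0, u1, spec.depth)
        else:
            # window cuts stop short of the midline so opposing windows
            # leave a thin mid-channel web and the section stays simple;
            # the web is kept well inside the tapered mid-root radius
            web = 0.2 * tpl.root_radius
            u0, u1 = (-w - 1.0, -web) if spec.side == "buccal" else (web, w + 1.0)
            center = FENESTRATION_CENTER_FRACTION * tpl.root_length
            cut = box(u0, center - spec.depth / 2, u1, center + spec.depth / 2)
        poly = poly.difference(cut)
    if poly.geom_type == "MultiPolygon":  # defensive: keep the main body
        poly = max(poly.geoms, key=lambda g: g.area)
    poly = orient(poly, sign=1.0)
    coords = np.asarray(poly.exterior.coords)[:-1]
    return coords


def _bone_prism(
    tpl: ToothTemplate, site: _ToothSite, specs: list[ExposureSpec]
) -> trimesh.Trimesh:
    section = _bone_cross_section(tpl, specs)
    length = _SEGMENT_FACTOR * 2 * tpl.crown_radius_cervical
    prism = _extrude_polygon(section, length)
    e3 = np.cross(site.lingual, site.apical)
    T = np.eye(4)
    T[:3, 0], T[:3, 1], T[:3, 2] = site.lingual, site.apical, e3
    T[:3, 3] = site.center
    prism.apply_transform(T)
    if prism.volume < 0:
        prism.invert()
    return prism


@lru_cache(maxsize=128)
def _arch_layout_cached(jaw, tpl_items, distalization, curvature):
    return _arch_layout(jaw, dict(tpl_items), distalization, curvature)


@lru_cache(maxsize=8)
def _occlusal_landmarks(curvature: float = ARCH_CURVATURE) -> tuple[np.ndarray, np.ndarray]:
    """Maxillary occlusal landmark points (second-molar distobuccal cusps
    and the incisor contact, all on z = 0) and the apex-side centroid."""
    templates = default_templates("maxilla")
    sites = _arch_layout("maxilla", templates, 0.0, curvature)
    pts = []
    for fdi in (17, 27):
        s = sites[fdi]
        buccal = -s.lingual
        cusp = s.center[:2] + (templates[fdi].crown_radius_cervical - 0.5) * buccal[:2]
        # distobuccal: nudge along the distal direction as well
        cusp = cusp + 2.0 * s.distal[:2]
        pts.append(np.array([cusp[0], cusp[1], 0.0]))
    pts.append(np.zeros(3))  # central-incisor contact point at the midline
    centroid = np.array([0.0, 15.0, 15.0])
    return np.array(pts), centroid


def build_arch(
    patient_id: str,
    jaw: str,
    scenario: SetupScenario,
    rng: np.random.Generator,
    *,
    templates: dict[int, ToothTemplate] | None = None,
    with_meshes: bool = False,
    curvature: float = ARCH_CURVATURE,
) -> ArchData:
    """One jaw of one patient under one setup condition.

    Per tooth, angulation and inclination are drawn from
    ``Normal(0, scenario sd)`` (seeded via ``rng``); the bone channel is
    carved according to the scenario's exposure program; ground truth
    (drawn angles and analytic exposure lengths) is recorded.
    """
    if jaw not in ("maxilla", "mandible"):
        raise ParameterError(f"unknown jaw {jaw!r}")
    templates = templates or default_templates(jaw)
    sites = _arch_layout_cached(
        jaw, tuple(sorted(templates.items())), scenario.distalization, curvature
    )
    occl_pts, apex_centroid = _occlusal_landmarks(curvature)

    program: dict[int, list[ExposureSpec]] = {}
    for spec in scenario.exposure_program:
        program.setdefault(spec.tooth_id, []).append(spec)

    landmarks: dict[int, LandmarkTriplet] = {}
    discs: dict[int, CrestDisc] = {}
    tooth_meshes: dict[int, trimesh.Trimesh] = {}
    bone_meshes: dict[int, trimesh.Trimesh] = {}
    truth: list[dict] = []
    for fdi in sorted(templates):
        tpl, site = templates[fdi], sites[fdi]
        ang = float(rng.normal(0.0, scenario.angulation_sd))
        inc = float(rng.normal(0.0, scenario.inclination_sd))
        axis = _axis_from_angles(site, ang, inc)
        r = tpl.crown_radius_cervical
        landmarks[fdi] = LandmarkTriplet(
            fdi,
            M=site.center - r * site.distal,
            D=site.center + r * site.distal,
            A=site.center + tpl.apex_distance * axis,
        )
        discs[fdi] = CrestDisc(fdi, Plane(site.center, site.apical), radius=r + 1.0)
        specs = program.get(fdi, [])
        exp = {side: 0.0 for side in SIDES}
        for spec in specs:
            exp[spec.side] += analytic_exposure_length(tpl, spec)
        truth.append(
            {
                "patient_id": patient_id,
                "jaw": jaw,
                "setup": scenario.label,
                "fdi": fdi,
                "true_angulation": ang,
                "true_inclination": inc,
                "true_exposure_buccal": exp["buccal"],
                "true_exposure_lingual": exp["lingual"],
            }
        )
        if with_meshes:
            mesh, _ = build_tooth(tpl, _tooth_pose(site, axis))
            tooth_meshes[fdi] = mesh
            bone_meshes[fdi] = _bone_prism(tpl, site, specs)
    return ArchData(
        patient_id, jaw, scenario.label, landmarks, occl_pts, apex_centroid,
        discs, truth,
        tooth_meshes if with_meshes else None,
        bone_meshes if with_meshes else None,
    )


@dataclass
class PatientData:
    patient_id: str
    arches: dict[tuple[str, str], ArchData]  # (setup, jaw) -> data

    def frame(self) -> OcclusalFrame:
        """The shared occlusal frame, built from root setup-2."""
        return self.arches["root2", "maxilla"].occlusal_frame()


@dataclass
class SyntheticCohort:
    seed: int
    patients: list[PatientData]
    ground_truth: "object"  # pandas.DataFrame

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def build_cohort(
    n_patients: int = 16,
    effect: CohortEffect | None = None,
    seed: int = 0,
    *,
    with_meshes: bool = False,
    include_initial: bool = True,
    jaws: tuple[str, ...] = ("maxilla", "mandible"),
) -> SyntheticCohort:
    """A seeded multi-patient cohort with ground truth for every setup.

    All three setup conditions of a patient share the root setup-2
    occlusal frame (identical by construction: the occlusal landmarks of
    every setup lie on z = 0).  Regeneration with the same seed is
    byte-identical.
    """
    import pandas as pd

    if n_patients < 2:
        raise ParameterError("a cohort needs at least 2 patients")
    effect = effect or study_effect()
    labels = (("initial",) if include_initial else ()) + SETUPS
    patients = []
    truth_rows: list[dict] = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        arches = {}
        for si, label in enumerate(labels):
            for ji, jaw in enumerate(("maxilla", "mandible")):
                if jaw not in jaws:
                    continue
                rng = np.random.default_rng([seed, p, si, ji])
                templates = default_templates(jaw)
                scenario = effect.draw(label, templates, rng)
                try:
                    arch = build_arch(
                        pid, jaw, scenario, rng,
                        templates=templates, with_meshes=with_meshes,
                    )
                except LayoutError as exc:
                    raise LayoutError(f"patient {pid}: {exc}") from exc
                arches[label, jaw] = arch
                truth_rows.extend(arch.truth)
        patients.append(PatientData(pid, arches))
    return SyntheticCohort(seed, patients, pd.DataFrame(truth_rows))
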