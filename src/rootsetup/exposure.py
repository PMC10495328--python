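"""Mesh-based root-exposure measurement (dehiscence and fenestration).

A tooth's root surface is sampled apical to its crest reference disc --
the planar marker at the root/alveolar-crest junction -- and each sample
is classified as exposed when it lies outside the (watertight) trimmed
alveolar-bone mesh.  Exposed samples are grouped into connected
components over the surface; components reaching the disc plane are
dehiscence-type (bone loss continuous with the crest) and isolated ones
are fenestration-type (windows surrounded by bone).

Lengths are the linear measurements between embedded points:
dehiscence is the point-to-plane distance from the disc to the
apical-most exposed point; fenestration is the point-to-point distance
between the uppermost and lowermost points of each isolated component,
summed per side; the combined exposure is their sum.

Sampling is deterministic: the tooth mesh is subdivided until no edge is
longer than the sampling step ``1/sqrt(density)`` and its vertices are
the samples, so surface adjacency is simply mesh-edge adjacency and the
step is the connectivity radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .errors import GeometryError, MeshIntegrityError
from .geometry import LandmarkTriplet, OcclusalFrame, Plane, long_axis

#: default surface sampling density, points per mm^2
DEFAULT_DENSITY = 25.0

SIDES = ("buccal", "lingual")


@dataclass(frozen=True)
class CrestDisc:
    """Per-tooth crest reference disc; the plane normal points apically."""

    tooth_id: int
    plane: Plane
    radius: float = 4.0

    def validate_against(self, lm: LandmarkTriplet) -> None:
        if float(self.plane.signed_distance(lm.A)) <= 0:
            raise GeometryError(
                f"tooth {self.tooth_id}: apex is not on the apical side of the "
                "crest disc"
            )


@dataclass
class ExposureComponent:
    """One connected patch of exposed root surface."""

    points: np.ndarray          # (m, 3) sample coordinates
    plane_distance: np.ndarray  # (m,) apical distance from the disc plane
    kind: str                   # "dehiscence" | "fenestration"
    step: float = 0.0           # sampling step the patch was extracted at
    side: str | None = None


@dataclass(frozen=True)
class ExposureResult:
    tooth_id: int
    side: str
    dehiscence: float
    fenestration: float

    def __post_init__(self):
        if self.dehiscence < 0 or self.fenestration < 0:
            raise ValueError("exposure lengths must be non-negative")

    @property
    def combined(self) -> float:
        return self.dehiscence + self.fenestration


@dataclass(frozen=True)
class ExposureCategory:
    tooth_id: int
    category: str  # "buccal" | "lingual" | "none"
    threshold: float


# ---------------------------------------------------------------------------
# point-in-mesh containment (ray parity)

_RAY_DIRECTIONS = (
    np.array([0.5773502691896258, 0.33219098881673514, 0.7458029323791598]),
    np.array([-0.2847592684762857, 0.8135662610954858, -0.5073462299222077]),
    np.array([0.6651728404050411, -0.4402241102577298, 0.6032644260285275]),
)


def _ray_parity(points: np.ndarray, triangles: np.ndarray, direction: np.ndarray):
    """Crossing counts of rays from ``points`` along ``direction`` against
    ``triangles`` (t, 3, 3), plus a mask of numerically suspect points.

    Vectorised Moller-Trumbore over all point/triangle pairs; fine for the
    low-polygon bone meshes this package generates and reads.
    """
    eps = 1e-12
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    h = np.cross(direction, e2)               # (t, 3)
    a = np.einsum("tj,tj->t", e1, h)          # (t,)
    ok = np.abs(a) > eps
    inv_a = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = points[:, None, :] - v0[None, :, :]   # (p, t, 3)
    u = np.einsum("ptj,tj->pt", s, h) * inv_a
    q = np.cross(s, e1[None, :, :])
    v = np.einsum("ptj,j->pt", q, direction) * inv_a
    t = np.einsum("ptj,tj->pt", q, e2) * inv_a
    hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > eps)
    counts = hit.sum(axis=1)
    edge_tol = 1e-9
    grazing = hit & (
        (u < edge_tol) | (v < edge_tol) | (u + v > 1 - edge_tol) | (t < 1e-9)
    )
    suspect = grazing.any(axis=1)
    return counts, suspect


def points_in_mesh(mesh: trimesh.Trimesh, points: np.ndarray,
                   batch: int = 4096) -> np.ndarray:
    """Watertight containment test by ray-crossing parity.

    Points whose ray grazes a triangle edge are re-tested along a second
    (and if needed third) direction.
    """
    if not mesh.is_watertight:
        raise MeshIntegrityError("containment test requires a watertight mesh")
    pts = np.asarray(points, float)
    tri = mesh.triangles.view(np.ndarray)
    inside = np.zeros(len(pts), dtype=bool)
    for start in range(0, len(pts), batch):
        chunk = pts[start : start + batch]
        pending = np.arange(len(chunk))
        result = np.zeros(len(chunk), dtype=bool)
        for direction in _RAY_DIRECTIONS:
            counts, suspect = _ray_parity(chunk[pending], tri, direction)
            settled = ~suspect
            result[pending[settled]] = counts[settled] % 2 == 1
            pending = pending[suspect]
            if len(pending) == 0:
                break
        if len(pending):  # grazing along every probe direction: take parity
            counts, _ = _ray_parity(chunk[pending], tri, _RAY_DIRECTIONS[0])
            result[pending] = counts % 2 == 1
        inside[start : start + batch] = result
    return inside


# ---------------------------------------------------------------------------


def _check_mesh(mesh: trimesh.Trimesh, what: str) -> None:
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshIntegrityError(f"{what}: expected a triangle mesh")
    if not mesh.is_watertight:
        raise MeshIntegrityError(f"{what}: mesh is not watertight")


def sampling_step(density: float) -> float:
    """Sampling step (mm) corresponding to a density in points/mm^2."""
    if density <= 0:
        raise ValueError("sampling density must be positive")
    return 1.0 / np.sqrt(density)


def exposed_root_points(
    tooth: trimesh.Trimesh,
    bone: trimesh.Trimesh,
    disc: CrestDisc,
    sampling_density: float = DEFAULT_DENSITY,
) -> list[ExposureComponent]:
    """Exposed-surface components of one tooth apical to its crest disc.

    Samples the tooth surface apical to the disc plane (subdivision
    vertices), labels each sample exposed when it lies outside ``bone``,
    groups exposed samples into connected components via surface
    adjacency, and classifies components touching the disc plane (within
    one sampling step) as dehiscence-type, the rest as fenestration-type.
    """
    _check_mesh(tooth, f"tooth {disc.tooth_id}")
    if tooth.volume <= 0:
        raise MeshIntegrityError(f"tooth {disc.tooth_id}: non-positive volume")
    _check_mesh(bone, "bone")
    step = sampling_step(sampling_density)

    verts, faces = trimesh.remesh.subdivide_to_size(
        tooth.vertices.view(np.ndarray), tooth.faces.view(np.ndarray),
        max_edge=step,
    )
    fine = trimesh.Trimesh(verts, faces, process=True)
    pts = fine.vertices.view(np.ndarray)
    dist = np.asarray(
        (pts - disc.plane.origin) @ disc.plane.normal
    )  # apical distance
    # keep samples clearly apical to the disc plane; the margin keeps them
    # off the bone's crest face where ray parity would be ambiguous
    apical = dist > step / 4
    if not apical.any():
        return []
    inside = np.zeros(len(pts), dtype=bool)
    inside[apical] = points_in_mesh(bone, pts[apical])
    exposed = apical & ~inside
    if not exposed.any():
        return []

    idx = np.flatnonzero(exposed)
    remap = -np.ones(len(pts), dtype=int)
    remap[idx] = np.arange(len(idx))
    edges = fine.edges_unique
    keep = exposed[edges[:, 0]] & exposed[edges[:, 1]]
    e = remap[edges[keep]]
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(idx), len(idx))
    )
    n_comp, labels = _cc(adj, directed=False)
    out = []
    for ci in range(n_comp):
        sel = idx[labels == ci]
        d = dist[sel]
        kind = "dehiscence" if d.min() <= step else "fenestration"
        out.append(ExposureComponent(pts[sel], d, kind, step))
    return out


def assign_side(
    components: list[ExposureComponent],
    lm: LandmarkTriplet,
    frame: OcclusalFrame,
    lingual: np.ndarray,
) -> list[ExposureComponent]:
    """Label each component buccal or lingual by the majority side of its
    sample points relative to the tooth midpoint."""
    mid, _ = long_axis(lm)
    lg = np.asarray(lingual, float)
    for comp in components:
        votes = (comp.points - mid) @ lg > 0
        comp.side = "lingual" if votes.mean() > 0.5 else "buccal"
    return components


def measure_exposure(
    components: list[ExposureComponent],
    disc: CrestDisc,
) -> dict[str, ExposureResult]:
    """Dehiscence / fenestration / combined lengths per side.

    Both sides are always reported (zeros when nothing is exposed).
    Multiple fenestration components on a side are summed.
    """
    deh = {s: 0.0 for s in SIDES}
    fen = {s: 0.0 for s in SIDES}
    for comp in components:
        if comp.side not in SIDES:
            raise ValueError("components must be side-labelled before measuring")
        if comp.kind == "dehiscence":
            deh[comp.side] = max(deh[comp.side], float(comp.plane_distance.max()))
        else:
            fen[comp.side] += _component_extent(comp)
    return {
        s: ExposureResult(disc.tooth_id, s, deh[s], fen[s]) for s in SIDES
    }


def _component_extent(comp: ExposureComponent) -> float:
    """Distance between the uppermost and lowermost points of a patch.

    The extreme plane distances are attained along whole sample rings on
    band-shaped defects, so the extent is taken as the closest pair
    among near-uppermost and near-lowermost candidates (within half a
    sampling step of the extremes): a deterministic, rotation-stable
    choice that measures along the surface rather than across it.
    """
    d = comp.plane_distance
    tol = comp.step / 2
    top_sel = d <= d.min() + tol
    bot_sel = d >= d.max() - tol
    tops, d_top = comp.points[top_sel], d[top_sel]
    bots, d_bot = comp.points[bot_sel], d[bot_sel]
    sep2 = ((tops[:, None, :] - bots[None, :, :]) ** 2).sum(axis=-1)
    lateral2 = sep2 - (d_top[:, None] - d_bot[None, :]) ** 2
    i, j = np.unravel_index(np.argmin(lateral2), lateral2.shape)
    # half-edge boundary correction: the true border lies on average half
    # a sampling step beyond the outermost exposed sample, at both ends
    return float(np.sqrt(sep2[i, j])) + comp.step


def classify_threshold(
    results: dict[str, ExposureResult], threshold: float = 2.0
) -> ExposureCategory:
    """Assign the tooth to the side whose combined exposure is strictly
    greater than ``threshold`` mm, or "none".

    When both sides exceed the threshold the side with the larger
    combined value wins (tie -> buccal).
    """
    missing = [s for s in SIDES if s not in results]
    if missing:
        raise ValueError(f"both sides must be measured; missing {missing}")
    tooth_id = results["buccal"].tooth_id
    over = {s: results[s].combined for s in SIDES if results[s].combined > threshold}
    if not over:
        return ExposureCategory(tooth_id, "none", threshold)
    if len(over) == 1:
        side = next(iter(over))
    else:
        side = "buccal" if over["buccal"] >= over["lingual"] else "lingual"
    return ExposureCategory(tooth_id, side, threshold)


# ---------------------------------------------------------------------------
# cohort summary tables

TOOTH_TYPE = {1: "incisor", 2: "incisor", 3: "canine", 4: "premolar",
              5: "premolar", 6: "molar", 7: "molar"}

_SETUPS = ("crown", "root1", "root2")


def exposure_tables(results: "pd.DataFrame", threshold: float = 2.0,
                    alpha: float = 0.05,
                    setups: tuple = _SETUPS) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Cohort summaries of root exposure.

    ``results`` is tidy with columns ``patient_id, setup, fdi, side,
    combined`` (mm).  Returns two tables:

    * per tooth type x jaw x side: mean and SD of combined exposure per
      setup, the Friedman p across setups and Bonferroni-adjusted
      Wilcoxon post-hoc labels (``a``: crown, ``b``: root setup-1,
      ``c``: root setup-2);
    * per setup x jaw x tooth type: counts of teeth whose combined
      exposure exceeds ``threshold`` mm on the buccal / lingual side
      (larger side when both; "none" otherwise) with the McNemar p for
      buccal-vs-lingual frequency.

    Teeth missing a setup are excluded from the comparison with a
    warning; statistics on all-zero rows are reported "NA".
    """
    import pandas as pd

    from .stats import RepeatedBlock, friedman_wilcoxon, mcnemar

    df = results.copy()
    df = df[df["setup"].isin(setups)]
    df["jaw"] = np.where(df["fdi"] // 10 <= 2, "maxilla", "mandible")
    df["tooth_type"] = (df["fdi"] % 10).map(TOOTH_TYPE)

    mean_rows = []
    for (jaw, ttype, side), g in df.groupby(["jaw", "tooth_type", "side"]):
        wide = g.pivot_table(index=["patient_id", "fdi"], columns="setup",
                             values="combined", aggfunc="first")
        missing = [s for s in setups if s not in wide.columns]
        if missing:
            wide = wide.reindex(columns=list(setups))
        complete = wide[list(setups)].dropna()
        if len(complete) < len(wide):
            log = __import__("logging").getLogger(__name__)
            log.warning("%s %s %s: excluded %d teeth with unbalanced setups",
                        jaw, ttype, side, len(wide) - len(complete))
        row = {"jaw": jaw, "tooth_type": ttype, "side": side}
        for s in setups:
            row[f"mean_{s}"] = complete[s].mean() if len(complete) else np.nan
            row[f"sd_{s}"] = complete[s].std(ddof=1) if len(complete) > 1 else np.nan
        row["n"] = len(complete)
        if len(complete) >= 2 and np.nanmax(complete.to_numpy()) > 0:
            rep = friedman_wilcoxon(
                RepeatedBlock(tuple(complete.index), tuple(setups),
                              complete.to_numpy()),
                alpha,
            )
            row["p_value"] = rep.omnibus.p_value
            row["posthoc"] = ", ".join(rep.labels) if rep.labels else "NA"
        else:
            row["p_value"] = np.nan
            row["posthoc"] = "NA"
        mean_rows.append(row)
    table2 = pd.DataFrame(mean_rows)

    freq_rows = []
    for (setup, jaw, ttype), g in df.groupby(["setup", "jaw", "tooth_type"]):
        wide = g.pivot_table(index=["patient_id", "fdi"], columns="side",
                             values="combined", aggfunc="first").reindex(
            columns=list(SIDES)).fillna(0.0)
        cats = []
        for (pid, fdi), r in wide.iterrows():
            res = {s: ExposureResult(int(fdi), s, float(r[s]), 0.0) for s in SIDES}
            cats.append(classify_threshold(res, threshold).category)
        cats = pd.Series(cats)
        b = int(((wide["buccal"] > threshold) & ~(wide["lingual"] > threshold)).sum())
        c = int((~(wide["buccal"] > threshold) & (wide["lingual"] > threshold)).sum())
        counts = {s: int((cats == s).sum()) for s in (*SIDES, "none")}
        total = len(wide)
        row = {"setup": setup, "jaw": jaw, "tooth_type": ttype,
               "n_teeth": total,
               "buccal": counts["buccal"], "lingual": counts["lingual"],
               "none": counts["none"],
               "buccal_pct": 100.0 * counts["buccal"] / total if total else np.nan,
               "lingual_pct": 100.0 * counts["lingual"] / total if total else np.nan,
               "none_pct": 100.0 * counts["none"] / total if total else np.nan,
               "discordant_b": b, "discordant_c": c}
        if b + c == 0:
            row["p_value"] = np.nan  # no discordance anywhere: reported NA
        else:
            row["p_value"] = mcnemar(b, c).p_value
        freq_rows.append(row)
    table3 = pd.DataFrame(freq_rows)

    type_order = {"incisor": 0, "canine": 1, "premolar": 2, "molar": 3}
    jaw_order = {"maxilla": 0, "mandible": 1}
    setup_order = {s: i for i, s in enumerate(setups)}
    if len(table2):
        table2 = table2.sort_values(
            ["jaw", "side", "tooth_type"],
            key=lambda s: s.map({**type_order, **jaw_order,
                                 "buccal": 0, "lingual": 1}),
        ).reset_index(drop=True)
    if len(table3):
        table3 = table3.sort_values(
            ["setup", "jaw", "tooth_type"],
            key=lambda s: s.map({**type_order, **jaw_order, **setup_order}),
        ).reset_index(drop=True)
    return table2, table3
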