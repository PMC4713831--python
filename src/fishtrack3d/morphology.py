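"""Construction of the undeformed 3D body-surface model of a fish.

The fish surface is described by a longitudinal series of transverse
cross-sections.  Each cross-section is assembled from up to three
"components" drawn in the local section plane (u = lateral, v = dorsoventral,
units mm):

* a trunk contour — a closed periodic cubic spline through control points,
* an optional pair of eyes — superellipses (Lamé curves) mirrored about the
  midsagittal plane,
* an optional median fin fold — an ordinary ellipse on the midline.

Components at a given arclength station are merged by taking the outermost
contour of their union, resampled to a fixed number of circumferential
points with a canonical start point (dorsal-most) and winding
(counter-clockwise in the (u, v) plane).  Equal point counts across sections
let the sections be stitched into quadrilateral faces, producing a closed,
watertight surface once the two ends are capped by collapsing the terminal
sections to single apex points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.interpolate import CubicSpline, PchipInterpolator
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "SuperellipseSpec",
    "EllipseSpec",
    "CrossSectionSpec",
    "BodyModel",
    "SurfaceMesh",
    "eval_superellipse",
    "eval_trunk_contour",
    "merge_components",
    "build_body_model",
    "load_model_spec",
    "save_model_spec",
    "zebrafish_larva_spec",
]


# --------------------------------------------------------------------------
# Component shapes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperellipseSpec:
    """Lamé curve |u/a|^n + |v/b|^n = 1, mirrored at ±offset_u (an eye pair)."""

    a: float
    b: float
    n: float
    offset_u: float
    offset_v: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("superellipse semi-axes must be positive")
        if self.n <= 0:
            raise ValueError("superellipse exponent must be positive")


@dataclass(frozen=True)
class EllipseSpec:
    """Ordinary ellipse (median fin fold), centred on the midline."""

    a: float
    b: float
    offset_v: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class CrossSectionSpec:
    """One digitised transverse section of the fish at arclength s in [0, 1].

    ``trunk`` holds (C, 2) spline control points of the closed trunk contour
    in the section plane; eyes and fin fold are optional analytic components.
    """

    s: float
    trunk: np.ndarray
    eyes: SuperellipseSpec | None = None
    finfold: EllipseSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("section position s must lie in [0, 1]")
        trunk = np.asarray(self.trunk, dtype=float)
        if trunk.ndim != 2 or trunk.shape[1] != 2 or trunk.shape[0] < 3:
            raise ValueError("trunk control points must be an (C>=3, 2) array")
        object.__setattr__(self, "trunk", trunk)


def eval_superellipse(
    a: float, b: float, n: float, n_points: int = 100,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Sample ``n_points`` on the superellipse |u/a|^n + |v/b|^n = 1.

    Points are uniform in the angular parameter; the contour is open-stored
    (first point not repeated), closure being implicit.
    """
    if a <= 0 or b <= 0 or n <= 0:
        raise ValueError("superellipse parameters must be positive")
    if n_points < 8:
        raise ValueError("need at least 8 points")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    u = a * np.sign(ct) * np.abs(ct) ** (2.0 / n)
    v = b * np.sign(st) * np.abs(st) ** (2.0 / n)
    return np.column_stack([u + center[0], v + center[1]])


def eval_trunk_contour(control_points: np.ndarray, n_points: int = 200) -> np.ndarray:
    """Closed periodic cubic spline through the trunk control points."""
    cp = np.asarray(control_points, dtype=float)
    pts = np.vstack([cp, cp[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= 0):
        # degenerate (collapsed) contour: return the repeated point
        return np.repeat(cp[:1], n_points, axis=0)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    spl = CubicSpline(t / t[-1], pts, bc_type="periodic")
    return spl(np.linspace(0.0, 1.0, n_points, endpoint=False))


# --------------------------------------------------------------------------
# Merging
# --------------------------------------------------------------------------

def _canonical_resample(poly: Polygon, n_points: int) -> np.ndarray:
    """Resample a polygon boundary to ``n_points`` uniform-arclength points.

    Canonical form: start at the dorsal-most (max v) boundary vertex, wind
    counter-clockwise in the (u, v) plane.
    """
    ext = np.asarray(poly.exterior.coords)[:-1]  # drop duplicate closure
    # enforce CCW
    if poly.exterior.is_ccw is False:
        ext = ext[::-1]
    start = int(np.argmax(ext[:, 1]))
    ext = np.roll(ext, -start, axis=0)
    closed = np.vstack([ext, ext[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        return np.repeat(ext[:1], n_points, axis=0)
    ti = np.linspace(0.0, total, n_points, endpoint=False)
    u = np.interp(ti, t, closed[:, 0])
    v = np.interp(ti, t, closed[:, 1])
    return np.column_stack([u, v])


def merge_components(
    contours: Sequence[np.ndarray], n_points: int = 40
) -> np.ndarray:
    """Merge filled component polygons into their outermost contour.

    Returns the boundary of the union, resampled to exactly ``n_points``
    canonical circumferential points.  Raises if the union is disconnected —
    a fish cross-section must be a single region.
    """
    polys = []
    for c in contours:
        c = np.asarray(c, dtype=float)
        if c.shape[0] < 3:
            continue
        p = Polygon(c)
        if not p.is_valid:
            p = p.buffer(0)
        if p.area > 0:
            polys.append(p)
    if not polys:
        raise ValueError("no non-degenerate components to merge")
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        raise ValueError("component union is disconnected; "
                         "cross-section must be a single region")
    return _canonical_resample(merged, n_points)


# --------------------------------------------------------------------------
# Meshes
# --------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A tube surface: M rings of P points plus the M centreline points.

    ``rings`` has shape (M, P, 3) and ``centres`` (M, 3), both in mm.  The
    first and last rings are degenerate (all points coincide with the
    centreline apex), which closes the surface.  The ring/centre structure is
    retained because the inverse-dynamics module partitions the enclosed
    volume into wedge tetrahedra anchored on the centreline.
    """

    rings: np.ndarray
    centres: np.ndarray

    @property
    def n_sections(self) -> int:
        return self.rings.shape[0]

    @property
    def n_circumferential(self) -> int:
        return self.rings.shape[1]

    def vertices_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Triangulate into a closed 2-manifold (apex fans + quad strips)."""
        M, P, _ = self.rings.shape
        verts = np.vstack([
            self.centres[0][None, :],
            self.rings[1:-1].reshape((M - 2) * P, 3),
            self.centres[-1][None, :],
        ])
        faces = []
        def ring_idx(i: int, j: int) -> int:   # i in [1, M-2]
            return 1 + (i - 1) * P + (j % P)
        for j in range(P):                      # snout cap fan
            faces.append([0, ring_idx(1, j), ring_idx(1, j + 1)])
        for i in range(1, M - 2):               # quad strips
            for j in range(P):
                a, b = ring_idx(i, j), ring_idx(i, j + 1)
                c, d = ring_idx(i + 1, j), ring_idx(i + 1, j + 1)
                faces.append([a, c, b])
                faces.append([b, c, d])
        last = verts.shape[0] - 1               # tail cap fan
        for j in range(P):
            faces.append([last, ring_idx(M - 2, j + 1), ring_idx(M - 2, j)])
        return verts, np.asarray(faces, dtype=np.int64)

    def to_trimesh(self):
        import trimesh
        v, f = self.vertices_faces()
        mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
        if mesh.volume < 0:
            mesh.invert()
        return mesh

    def export(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path))


# --------------------------------------------------------------------------
# Body model
# --------------------------------------------------------------------------

@dataclass
class BodyModel:
    """Longitudinal series of merged cross-section contours (straight pose).

    ``sections``: (M, P, 2) local-plane contours, ``s_values``: the M
    normalised arclength stations, ``length``: reference body length ℓ in mm,
    ``stiff_fraction``: anterior fraction with curvature pinned to zero.
    """

    sections: np.ndarray
    s_values: np.ndarray
    length: float
    stiff_fraction: float = 0.10
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sections = np.asarray(self.sections, dtype=float)
        self.s_values = np.asarray(self.s_values, dtype=float)
        M, P, _ = self.sections.shape
        if P < 16 or M < 20:
            raise ValueError("need at least 16 circumferential and "
                             "20 longitudinal points")
        if self.s_values.shape != (M,) or np.any(np.diff(self.s_values) <= 0):
            raise ValueError("s stations must be strictly increasing")

    @property
    def n_sections(self) -> int:
        return self.sections.shape[0]

    @property
    def n_circumferential(self) -> int:
        return self.sections.shape[1]

    def decimate(self, P: int, M: int) -> "BodyModel":
        """Coarser copy (subsampled rings/stations) for fast tracking."""
        M0, P0, _ = self.sections.shape
        si = np.unique(np.round(np.linspace(0, M0 - 1, M)).astype(int))
        pj = np.unique(np.round(np.linspace(0, P0, P, endpoint=False)).astype(int)) % P0
        return BodyModel(self.sections[np.ix_(si, pj)], self.s_values[si],
                         self.length, self.stiff_fraction, dict(self.meta))

    def straight_mesh(self) -> SurfaceMesh:
        """Undeformed surface in the head frame (snout at origin, body −x)."""
        from .kinematics import FishState, deform_and_pose
        state = FishState(0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                          np.zeros(7))
        return deform_and_pose(self, state)


def _interp_rows(s_spec: np.ndarray, values: np.ndarray, s_out: np.ndarray) -> np.ndarray:
    """Piecewise-cubic (monotone) interpolation of parameter rows along s."""
    if len(s_spec) >= 3:
        return PchipInterpolator(s_spec, values, axis=0)(s_out)
    # two sections: linear
    w = (s_out - s_spec[0]) / (s_spec[1] - s_spec[0])
    return values[0] + w[:, None] * (values[1] - values[0])


def build_body_model(
    specs: Sequence[CrossSectionSpec],
    P: int = 40,
    M: int = 51,
    length: float | None = None,
    stiff_fraction: float = 0.10,
) -> BodyModel:
    """Interpolate digitised section specs along s, merge, and assemble.

    Component parameters are interpolated in s with a shape-preserving
    piecewise cubic; eyes and fin fold exist only over the longitudinal
    extent where the specs define them (zero size beyond).  The first and
    last of the M stations are collapsed to apex points so the triangulated
    surface is watertight.
    """
    if len(specs) < 4:
        raise ValueError("need at least 4 cross-section specs")
    s_spec = np.array([sp.s for sp in specs])
    if np.any(np.diff(s_spec) <= 0):
        raise ValueError("specs must be sorted with strictly increasing s")
    if s_spec[0] > 1e-9 or s_spec[-1] < 1 - 1e-9:
        raise ValueError("specs must span s in [0, 1]")
    nc = specs[0].trunk.shape[0]
    if any(sp.trunk.shape[0] != nc for sp in specs):
        raise ValueError("all specs must share the trunk control-point count")

    s_out = np.linspace(0.0, 1.0, M)
    trunk_cp = _interp_rows(
        s_spec, np.stack([sp.trunk.reshape(-1) for sp in specs]), s_out
    ).reshape(M, nc, 2)

    def component_table(getter, fields):
        """(s, params) table over the stations where a component exists."""
        rows = [(sp.s, [getattr(getter(sp), f) for f in fields])
                for sp in specs if getter(sp) is not None]
        if len(rows) < 2:
            return None
        ss = np.array([r[0] for r in rows])
        vals = np.array([r[1] for r in rows])
        interp = _interp_rows(ss, vals, s_out)
        mask = (s_out >= ss[0] - 1e-12) & (s_out <= ss[-1] + 1e-12)
        return interp, mask

    eyes_tab = component_table(lambda sp: sp.eyes,
                               ["a", "b", "n", "offset_u", "offset_v"])
    fin_tab = component_table(lambda sp: sp.finfold, ["a", "b", "offset_v"])

    sections = np.empty((M, P, 2))
    for i in range(M):
        comps = [eval_trunk_contour(trunk_cp[i])]
        if eyes_tab is not None and eyes_tab[1][i]:
            a, b, n, ou, ov = eyes_tab[0][i]
            if a > 1e-6 and b > 1e-6:
                comps.append(eval_superellipse(a, b, max(n, 0.5), 64, (ou, ov)))
                comps.append(eval_superellipse(a, b, max(n, 0.5), 64, (-ou, ov)))
        if fin_tab is not None and fin_tab[1][i]:
            a, b, ov = fin_tab[0][i]
            if a > 1e-6 and b > 1e-6:
                comps.append(eval_superellipse(a, b, 2.0, 64, (0.0, ov)))
        sections[i] = merge_components(comps, P)

    # collapse terminal sections to their centroids (watertight end caps)
    for i in (0, M - 1):
        sections[i] = sections[i].mean(axis=0)

    if length is None:
        length = 1.0
    return BodyModel(sections, s_out, float(length), stiff_fraction,
                     meta={"P": P, "M": M, "n_specs": len(specs)})


# --------------------------------------------------------------------------
# Spec-file I/O and the shipped larval-zebrafish shape
# --------------------------------------------------------------------------

def save_model_spec(path: str | Path, specs: Sequence[CrossSectionSpec],
                    length: float, stiff_fraction: float = 0.10) -> None:
    doc = {
        "length_mm": float(length),
        "stiff_fraction": float(stiff_fraction),
        "sections": [],
    }
    for sp in specs:
        rec: dict = {"s": float(sp.s),
                     "trunk": np.round(sp.trunk, 6).tolist()}
        if sp.eyes is not None:
            rec["eyes"] = {k: float(getattr(sp.eyes, k))
                           for k in ("a", "b", "n", "offset_u", "offset_v")}
        if sp.finfold is not None:
            rec["finfold"] = {k: float(getattr(sp.finfold, k))
                              for k in ("a", "b", "offset_v")}
        doc["sections"].append(rec)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model_spec(path: str | Path) -> tuple[list[CrossSectionSpec], float, float]:
    """Read a body-model spec file; returns (specs, length_mm, stiff_fraction)."""
    doc = yaml.safe_load(Path(path).read_text())
    specs = []
    for rec in doc["sections"]:
        eyes = SuperellipseSpec(**rec["eyes"]) if "eyes" in rec else None
        fin = EllipseSpec(**rec["finfold"]) if "finfold" in rec else None
        specs.append(CrossSectionSpec(rec["s"], np.asarray(rec["trunk"]),
                                      eyes, fin))
    return specs, float(doc["length_mm"]), float(doc.get("stiff_fraction", 0.10))


def _trunk_points(w: float, h: float, v0: float) -> np.ndarray:
    """Eight trunk control points for a rounded section of width w, height h,
    vertically centred at v0 (mm)."""
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False) + np.pi / 2
    return np.column_stack([0.5 * w * np.cos(ang),
                            v0 + 0.5 * h * np.sin(ang)])


def zebrafish_larva_spec(length: float = 5.0) -> list[CrossSectionSpec]:
    """Synthetic stand-in shape of an early larval zebrafish.

    Proportions follow published larval morphology qualitatively: a rounded
    head with laterally bulging eyes, a trunk tapering towards the tail, and
    a thin median fin fold over the posterior two-thirds.  Dimensions scale
    with the requested body length (default 5 mm).
    """
    L = length / 5.0  # scale factor relative to the 5 mm reference
    rows = [
        # s,    width, height, v0,  eyes(a, b, n, ou, ov),  fin(a, b, ov)
        (0.00, 0.10, 0.10, 0.00, None, None),
        (0.06, 0.45, 0.50, 0.00, None, None),
        (0.12, 0.60, 0.70, 0.05, (0.16, 0.13, 3.0, 0.30, 0.02), None),
        (0.20, 0.62, 0.78, 0.08, (0.14, 0.11, 3.0, 0.28, 0.00), None),
        (0.30, 0.55, 0.75, 0.08, None, (0.045, 0.55, 0.10)),
        (0.45, 0.42, 0.60, 0.05, None, (0.040, 0.55, 0.08)),
        (0.60, 0.30, 0.45, 0.02, None, (0.040, 0.50, 0.05)),
        (0.75, 0.20, 0.30, 0.00, None, (0.035, 0.42, 0.00)),
        (0.88, 0.12, 0.18, 0.00, None, (0.030, 0.30, 0.00)),
        (0.96, 0.06, 0.08, 0.00, None, (0.020, 0.12, 0.00)),
        (1.00, 0.02, 0.02, 0.00, None, None),
    ]
    specs = []
    for s, w, h, v0, eyes, fin in rows:
        eyes_spec = None
        if eyes is not None:
            a, b, n, ou, ov = eyes
            eyes_spec = SuperellipseSpec(a * L, b * L, n, ou * L, ov * L)
        fin_spec = None
        if fin is not None:
            a, b, ov = fin
            fin_spec = EllipseSpec(a * L, b * L, ov * L)
        specs.append(CrossSectionSpec(s, _trunk_points(w * L, h * L, v0 * L),
                                      eyes_spec, fin_spec))
    return specs


def default_zebrafish_model(length: float = 5.0, P: int = 40, M: int = 51) -> BodyModel:
    """The shipped larval-zebrafish body model at the requested length."""
    return build_body_model(zebrafish_larva_spec(length), P=P, M=M,
                            length=length, stiff_fraction=0.10)


def capsule_spec(diameter: float, length: float,
                 n_cap_rows: int = 8) -> list[CrossSectionSpec]:
    """Section specs for a cylinder with hemispherical end caps.

    The radius profile is r(x) = sqrt(R² − d²) inside the caps (d = distance
    into the cap) and R elsewhere; sections are circular trunk contours.
    """
    R = diameter / 2.0
    s_cap = R / length
    s_rows = np.concatenate([
        s_cap * (1 - np.cos(np.linspace(0, np.pi / 2, n_cap_rows))),
        np.linspace(1.2 * s_cap, 1 - 1.2 * s_cap, 6),
        1 - s_cap * (1 - np.cos(np.linspace(np.pi / 2, 0, n_cap_rows))),
    ])
    s_rows = np.unique(np.clip(s_rows, 0, 1))
    specs = []
    for s in s_rows:
        d = min(s, 1 - s) * length
        r = R if d >= R else float(np.sqrt(max(R * R - (R - d) ** 2, 1e-8)))
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False) + np.pi / 2
        cp = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        specs.append(CrossSectionSpec(float(s), cp))
    return specs


def cylinder_surface_mesh(diameter: float = 1.25, length: float = 5.0,
                          P: int = 40, M: int = 51) -> SurfaceMesh:
    """Flat-ended triangulated cylinder, axis along x, centred at the origin.

    Built directly as a ring/centre tube so the inverse-dynamics tetrahedral
    partition applies; the flat faces are fans about the face centres.
    """
    # interior stations carry the lateral surface; the two extra end stations
    # duplicate the terminal rings so the caps are flat discs
    x = np.linspace(length / 2.0, -length / 2.0, M)
    ang = np.linspace(0, 2 * np.pi, P, endpoint=False) + np.pi / 2
    ring_uv = np.column_stack([np.cos(ang), np.sin(ang)]) * (diameter / 2.0)
    rings = np.zeros((M + 2, P, 3))
    centres = np.zeros((M + 2, 3))
    centres[0] = (x[0], 0, 0)
    centres[-1] = (x[-1], 0, 0)
    for i, xi in enumerate(x):
        rings[i + 1, :, 0] = xi
        rings[i + 1, :, 1] = ring_uv[:, 0]
        rings[i + 1, :, 2] = ring_uv[:, 1]
        centres[i + 1] = (xi, 0, 0)
    rings[0] = centres[0]
    rings[-1] = centres[-1]
    return SurfaceMesh(rings, centres)
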