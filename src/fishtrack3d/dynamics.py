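"""Inverse dynamics of the tracked, deforming fish body.

From a time series of fitted states (or directly from a matched sequence of
posed surface meshes) this module computes centre-of-mass motion, the
resultant external force, the total angular momentum of the deforming body
and the resultant torque.

The mechanical model assumes a homogeneous body of the density of water:
the triangulated surface then fully determines the mass distribution.  The
resultant force is F = m·a_CoM (Newton's second law; the added mass of the
accelerated water is implicitly part of the reconstructed fluid force).
Because large parts of a swimming fish translate over distances comparable
to its body length, torque is not computed as I·dω/dt but as the time
derivative of the total angular momentum of the deforming body,

    τ = ρ d/dt ∭_V r*(x) × v*(x) dV,

with r* and v* relative to the CoM.  The volume integral is evaluated
exactly for a piecewise-linear velocity field by partitioning the tube
volume into wedge tetrahedra anchored on the centreline (each cross-section
ring, its successor and the two centreline points), with per-vertex
velocities obtained by finite-differencing the matched vertex trajectories.

Raw tracked parameters are smoothed with a Whittaker-type penalised
least-squares smoother (fourth-order difference penalty, so accelerations
are smooth); no further smoothing is applied to derived quantities.
Derivatives use second-order finite differences.  Internally SI units are
used (m, kg, s, N, N·m); tabulated output is reported in mm, µN and µN·mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .kinematics import FishState, deform_and_pose, integrate_centerline, \
    curvature_spline, head_rotation
from .morphology import BodyModel, SurfaceMesh

__all__ = [
    "SmootherConfig",
    "smooth_series",
    "gcv_lambda",
    "differentiate",
    "second_derivative",
    "mass_properties",
    "tube_tetrahedra",
    "angular_momentum",
    "resultant_force",
    "resultant_torque",
    "fish_frame_axes",
    "InverseDynamics",
    "DynamicsResults",
]

WATER_DENSITY = 1000.0  # kg/m^3


# --------------------------------------------------------------------------
# Penalised least-squares smoothing
# --------------------------------------------------------------------------

@dataclass
class SmootherConfig:
    """Whittaker smoother settings.

    ``lam`` is the penalty weight; when None it is derived from
    ``cutoff_hz`` and the frame rate: the fourth-order difference penalty
    acts as a low-pass filter with amplitude response
    1/(1 + λ(2 sin(ω/2))⁸), so λ = (2 sin(π f_c/f_s))⁻⁸ puts the half-power
    point at f_c.  The default cutoff of 80 Hz (roughly twice the
    highest body-wave frequency) retains the body-wave
    kinematics (≲40 Hz) while suppressing frame-to-frame tracking noise.
    If neither λ nor a frame rate is available, λ is chosen per series by
    generalised cross-validation.  ``order`` is fixed at 4 so second time
    derivatives stay smooth; ``edge_trim`` frames at each end are flagged
    as less accurate.
    """

    lam: float | None = None
    cutoff_hz: float | None = 80.0
    order: int = 4
    edge_trim: int = 5
    reflect_pad: bool = True

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")

    def resolve_lambda(self, fps: float | None) -> float | None:
        """λ for a given frame rate (None → fall back to GCV)."""
        if self.lam is not None:
            return self.lam
        if self.cutoff_hz is None or fps is None:
            return None
        fc = min(self.cutoff_hz, 0.45 * fps)
        return float((2.0 * np.sin(np.pi * fc / fps)) ** (-2 * self.order))


def _difference_matrix(n: int, order: int) -> sparse.csc_matrix:
    D = sparse.eye(n, format="csc")
    for _ in range(order):
        D = D[1:] - D[:-1]
    return D


def _whittaker(y: np.ndarray, lam: float, order: int) -> np.ndarray:
    n = y.shape[0]
    if lam == 0:
        return y.copy()
    D = _difference_matrix(n, order)
    A = sparse.eye(n, format="csc") + lam * (D.T @ D)
    return spsolve(A, y)


def gcv_lambda(y: np.ndarray, order: int = 4,
               grid: np.ndarray | None = None) -> float:
    """Generalised cross-validation choice of the smoothing penalty.

    Minimises GCV(λ) = n‖y − ŷ_λ‖² / (n − tr H_λ)² over a log-spaced grid.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if grid is None:
        grid = np.logspace(-2, 10, 25)
    D = _difference_matrix(n, order).toarray()
    DtD = D.T @ D
    best_lam, best_gcv = grid[0], np.inf
    eye = np.eye(n)
    for lam in grid:
        H = np.linalg.solve(eye + lam * DtD, eye)
        yhat = H @ y
        tr = np.trace(H)
        denom = max(n - tr, 1e-9)
        gcv = n * np.sum((y - yhat) ** 2) / denom ** 2
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, lam
    return float(best_lam)


def smooth_series(raw: np.ndarray, cfg: SmootherConfig,
                  fps: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Smooth each column of a uniformly sampled (T, n_par) series.

    Returns (smoothed, lambdas).  λ = 0 reproduces the input exactly;
    polynomials up to degree 3 lie in the penalty null space and pass
    through unchanged for any λ.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    T = raw.shape[0]
    if T < 2 * cfg.order + 1:
        raise ValueError("series too short to smooth (need >= 9 samples)")
    lam_common = cfg.resolve_lambda(fps)
    # even-reflection padding imposes a zero-slope boundary, taming the
    # variance blow-up of the one-sided smoother near the sequence edges
    # (start sequences begin at rest, where the boundary is exact)
    pad = min(T - 1, 3 * cfg.order) if cfg.reflect_pad else 0
    if pad:
        raw_p = np.vstack([raw[pad:0:-1], raw, raw[-2:-pad - 2:-1]])
    else:
        raw_p = raw
    out = np.empty_like(raw_p)
    lams = np.empty(raw.shape[1])
    for j in range(raw.shape[1]):
        lam = (lam_common if lam_common is not None
               else gcv_lambda(raw[:, j], cfg.order))
        lams[j] = lam
        out[:, j] = _whittaker(raw_p[:, j], lam, cfg.order)
    if pad:
        out = out[pad:pad + T]
    return out, lams


# --------------------------------------------------------------------------
# Finite differences
# --------------------------------------------------------------------------

def differentiate(series: np.ndarray, dt: float) -> np.ndarray:
    """First derivative: second-order central differences in the interior,
    second-order one-sided at the two ends."""
    return np.gradient(np.asarray(series, dtype=float), dt,
                       axis=0, edge_order=2)


def second_derivative(series: np.ndarray, dt: float) -> np.ndarray:
    """Second derivative: (f₋ − 2f₀ + f₊)/dt² in the interior, four-point
    one-sided stencils at the ends (exact through quadratics)."""
    y = np.asarray(series, dtype=float)
    d2 = np.empty_like(y)
    d2[1:-1] = (y[2:] - 2 * y[1:-1] + y[:-2]) / dt ** 2
    d2[0] = (2 * y[0] - 5 * y[1] + 4 * y[2] - y[3]) / dt ** 2
    d2[-1] = (2 * y[-1] - 5 * y[-2] + 4 * y[-3] - y[-4]) / dt ** 2
    return d2


# --------------------------------------------------------------------------
# Mass properties and the angular-momentum integral
# --------------------------------------------------------------------------

def mass_properties(mesh: SurfaceMesh, rho: float = WATER_DENSITY):
    """Mass (kg), CoM (mm) and inertia tensor about the CoM (kg·m²) of a
    watertight triangulated surface of homogeneous density ``rho``,
    computed by exact divergence-theorem surface integrals."""
    tm = mesh.to_trimesh() if isinstance(mesh, SurfaceMesh) else mesh
    if not tm.is_watertight:
        raise ValueError("mesh is not watertight")
    tm = tm.copy()
    tm.density = rho * 1e-9          # kg per mm^3
    mp = tm.mass_properties
    inertia = np.asarray(mp["inertia"]) * 1e-6   # kg·mm² → kg·m²
    return float(mp["mass"]), np.asarray(mp["center_mass"]), inertia


def tube_tetrahedra(n_sections: int, n_circ: int) -> np.ndarray:
    """Tetrahedral partition of a ring/centre tube volume.

    Vertex indexing: ring vertex (i, j) → i*P + j; centre i → M*P + i.
    Each slab contributes P wedge prisms (centre-edge triangles of adjacent
    sections), each split into 3 tetrahedra.  Returns (n_tets, 4) indices.
    """
    M, P = n_sections, n_circ
    tets = []
    for i in range(M - 1):
        c0 = M * P + i
        c1 = M * P + i + 1
        for j in range(P):
            k = (j + 1) % P
            p1, p2 = i * P + j, i * P + k
            q1, q2 = (i + 1) * P + j, (i + 1) * P + k
            tets.append([c0, p1, p2, c1])
            tets.append([p1, p2, c1, q1])
            tets.append([p2, c1, q1, q2])
    return np.asarray(tets, dtype=np.int64)


def _tet_volumes(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = verts[tets[:, 1]] - verts[tets[:, 0]]
    b = verts[tets[:, 2]] - verts[tets[:, 0]]
    c = verts[tets[:, 3]] - verts[tets[:, 0]]
    return np.abs(np.einsum("ij,ij->i", np.cross(a, b), c)) / 6.0


def angular_momentum(
    vertices: np.ndarray,
    velocities: np.ndarray,
    tets: np.ndarray,
    rho: float,
    com: np.ndarray,
    vcom: np.ndarray,
) -> np.ndarray:
    """Total angular momentum L = ρ ∭ r*(x) × v*(x) dV (kg·m²/s).

    ``vertices`` (N, 3, m) and ``velocities`` (N, 3, m/s) sample the motion
    at the matched mesh vertices; the velocity field is interpolated
    linearly inside each tetrahedron, for which the integral is exact:
    ∫ λ_i λ_j dV = V(1 + δ_ij)/20 gives, per tet,
    L = ρV/20 [ (Σr_i) × (Σw_j) + Σ r_i × w_i ].
    """
    r = vertices - com
    w = velocities - vcom
    V = _tet_volumes(vertices, tets)
    rt = r[tets]          # (T, 4, 3)
    wt = w[tets]
    S = rt.sum(axis=1)
    W = wt.sum(axis=1)
    diag = np.cross(rt, wt).sum(axis=1)
    per_tet = (np.cross(S, W) + diag) * (V / 20.0)[:, None]
    return rho * per_tet.sum(axis=0)


def resultant_force(acom: np.ndarray, mass: float) -> np.ndarray:
    """F = m·a, per frame (N)."""
    return mass * np.asarray(acom, dtype=float)


def resultant_torque(L_series: np.ndarray, dt: float) -> np.ndarray:
    """τ = dL/dt by second-order finite differences (N·m)."""
    return differentiate(L_series, dt)


# --------------------------------------------------------------------------
# Fish-aligned coordinate frame
# --------------------------------------------------------------------------

def fish_frame_axes(
    state: FishState, model: BodyModel, com_mm: np.ndarray,
) -> np.ndarray:
    """Instantaneous fish coordinate axes (rows: x_fish, y_fish, z_fish).

    x_fish lies in the deformation plane along the resultant body angle —
    the local moment-of-inertia-weighted average of the sectional tangent
    angles (weights: slab mass × squared distance of the slab centroid from
    the CoM); z_fish is the deformation-plane normal; y_fish completes a
    right-handed frame.
    """
    spl = curvature_spline(state, model.stiff_fraction)
    centres, theta, _ = integrate_centerline(spl, model.length, model.s_values)
    # slab weights from the straight-pose section areas (bending preserves
    # section placement, so areas are pose-independent)
    areas = np.array([_polygon_area(sec) for sec in model.sections])
    ds = np.gradient(model.s_values) * model.length
    slab_mass = areas * ds
    R = head_rotation(state).as_matrix()
    centres_world = centres @ R.T + state.position
    d2 = np.sum((centres_world - com_mm) ** 2, axis=1)
    wgt = slab_mass * d2
    if wgt.sum() <= 0:
        wgt = slab_mass
    mean_sin = float(np.sum(wgt * np.sin(theta)) / wgt.sum())
    mean_cos = float(np.sum(wgt * np.cos(theta)) / wgt.sum())
    alpha = np.arctan2(mean_sin, mean_cos)
    x_head = np.array([np.cos(alpha), -np.sin(alpha), 0.0])
    z_head = np.array([0.0, 0.0, 1.0])
    x_fish = R @ x_head
    z_fish = R @ z_head
    y_fish = np.cross(z_fish, x_fish)
    return np.vstack([x_fish, y_fish, z_fish])


def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# --------------------------------------------------------------------------
# The model/results pair
# --------------------------------------------------------------------------

@dataclass
class DynamicsResults:
    """Inverse-dynamics output: smoothed kinematics, CoM motion, resultant
    force, angular momentum and resultant torque (SI units internally)."""

    time: np.ndarray
    mass: float
    com: np.ndarray          # (T, 3) m
    vcom: np.ndarray         # m/s
    acom: np.ndarray         # m/s²
    force: np.ndarray        # N
    Lvec: np.ndarray         # kg·m²/s
    torque: np.ndarray       # N·m
    edge_trim: int = 5
    states: list[FishState] | None = None
    lambdas: np.ndarray | None = None
    axes: np.ndarray | None = None        # (T, 3, 3) fish-frame rows
    force_fish: np.ndarray | None = None  # N, fish-frame components
    torque_fish: np.ndarray | None = None
    forward_force: np.ndarray | None = None
    volume_drift: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def interior(self) -> slice:
        """Frames outside the edge-trimmed bands."""
        return slice(self.edge_trim, self.n_frames - self.edge_trim)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "t": self.time,
            "com_x_mm": self.com[:, 0] * 1e3,
            "com_y_mm": self.com[:, 1] * 1e3,
            "com_z_mm": self.com[:, 2] * 1e3,
            "force_x_uN": self.force[:, 0] * 1e6,
            "force_y_uN": self.force[:, 1] * 1e6,
            "force_z_uN": self.force[:, 2] * 1e6,
            "torque_x_uNmm": self.torque[:, 0] * 1e9,
            "torque_y_uNmm": self.torque[:, 1] * 1e9,
            "torque_z_uNmm": self.torque[:, 2] * 1e9,
        }
        if self.force_fish is not None:
            for i, ax in enumerate(("x", "y", "z")):
                cols[f"force_{ax}fish_uN"] = self.force_fish[:, i] * 1e6
                cols[f"torque_{ax}fish_uNmm"] = self.torque_fish[:, i] * 1e9
        if self.forward_force is not None:
            cols["force_forward_uN"] = self.forward_force * 1e6
        df = pd.DataFrame(cols)
        trim = np.zeros(self.n_frames, dtype=int)
        trim[: self.edge_trim] = 1
        trim[self.n_frames - self.edge_trim:] = 1
        df["edge_flag"] = trim
        return df

    def summary(self) -> str:
        i = self.interior
        fmax = np.linalg.norm(self.force[i], axis=1).max() * 1e6
        tmax = np.linalg.norm(self.torque[i], axis=1).max() * 1e9
        speed = np.linalg.norm(self.vcom[i], axis=1)
        lines = [
            "Inverse dynamics results",
            "========================",
            f"frames:          {self.n_frames} "
            f"(edge trim {self.edge_trim} per side)",
            f"body mass:       {self.mass * 1e6:.3f} mg",
            f"volume drift:    {self.volume_drift * 100:.3f} %",
            f"peak CoM speed:  {speed.max() * 1e3:.1f} mm/s",
            f"peak |force|:    {fmax:.3f} uN",
            f"peak |torque|:   {tmax:.3f} uN*mm",
        ]
        if self.lambdas is not None:
            lines.append(
                f"smoothing lambda: median {np.median(self.lambdas):.3g}")
        return "\n".join(lines)


class InverseDynamics:
    """Inverse-dynamics model of a tracked (or prescribed) body sequence.

    Construct from fitted states plus the body model (the usual route, with
    parameter smoothing), or from an already-posed matched mesh sequence via
    :meth:`from_meshes` (used for rigid-body verification, no smoothing);
    :meth:`fit` computes the full dynamics series.
    """

    def __init__(
        self,
        states: list[FishState],
        model: BodyModel,
        fps: float,
        rho: float = WATER_DENSITY,
        smoother: SmootherConfig | None = None,
    ) -> None:
        self.states = states
        self.model = model
        self.fps = float(fps)
        self.rho = rho
        self.smoother = smoother or SmootherConfig()
        self._meshes: list[SurfaceMesh] | None = None

    @classmethod
    def from_meshes(cls, meshes: list[SurfaceMesh], fps: float,
                    rho: float = WATER_DENSITY,
                    edge_trim: int = 5) -> "InverseDynamics":
        obj = cls.__new__(cls)
        obj.states = None
        obj.model = None
        obj.fps = float(fps)
        obj.rho = rho
        obj.smoother = SmootherConfig(lam=0.0, edge_trim=edge_trim)
        obj._meshes = list(meshes)
        return obj

    # -- pipeline pieces ---------------------------------------------------

    def _smoothed_states(self) -> tuple[list[FishState], np.ndarray]:
        raw = np.vstack([s.to_vector() for s in self.states])
        raw[:, 3:6] = np.unwrap(raw[:, 3:6], axis=0)
        smoothed, lams = smooth_series(raw, self.smoother, fps=self.fps)
        return [FishState.from_vector(v) for v in smoothed], lams

    def fit(self) -> DynamicsResults:
        dt = 1.0 / self.fps
        lams = None
        states = None
        if self._meshes is not None:
            meshes = self._meshes
        else:
            states, lams = self._smoothed_states()
            meshes = [deform_and_pose(self.model, s) for s in states]

        T = len(meshes)
        M, P, _ = meshes[0].rings.shape
        tets = tube_tetrahedra(M, P)
        # matched vertex trajectories, in metres
        verts = np.empty((T, M * P + M, 3))
        for t, mesh in enumerate(meshes):
            verts[t] = np.vstack([mesh.rings.reshape(-1, 3),
                                  mesh.centres]) * 1e-3

        volumes = np.array([_tet_volumes(v, tets).sum() for v in verts])
        vol_drift = float(np.ptp(volumes) / volumes.mean())
        mass = self.rho * volumes.mean()

        com = np.empty((T, 3))
        for t, mesh in enumerate(meshes):
            _, com_mm, _ = mass_properties(mesh, self.rho)
            com[t] = com_mm * 1e-3
        vcom = differentiate(com, dt)
        acom = second_derivative(com, dt)
        force = resultant_force(acom, mass)

        vel = differentiate(verts, dt)
        Lvec = np.empty((T, 3))
        for t in range(T):
            Lvec[t] = angular_momentum(verts[t], vel[t], tets, self.rho,
                                       com[t], vcom[t])
        torque = resultant_torque(Lvec, dt)

        axes = force_fish = torque_fish = forward = None
        if states is not None:
            axes = np.empty((T, 3, 3))
            for t, s in enumerate(states):
                axes[t] = fish_frame_axes(s, self.model, com[t] * 1e3)
            force_fish = np.einsum("tij,tj->ti", axes, force)
            torque_fish = np.einsum("tij,tj->ti", axes, torque)
            speed = np.linalg.norm(vcom, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                forward = np.where(
                    speed > 1e-12,
                    np.einsum("ti,ti->t", force, vcom) / np.maximum(speed, 1e-300),
                    np.nan,
                )

        return DynamicsResults(
            time=np.arange(T) * dt,
            mass=mass,
            com=com, vcom=vcom, acom=acom, force=force,
            Lvec=Lvec, torque=torque,
            edge_trim=self.smoother.edge_trim,
            states=states, lambdas=lams,
            axes=axes, force_fish=force_fish, torque_fish=torque_fish,
            forward_force=forward,
            volume_drift=vol_drift,
        )
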