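"""Deformation and posing of the body model.

A fish state is the parameter vector fitted per video frame: snout-tip
position (x, y, z), Tait–Bryan head angles (roll, pitch, yaw) and midline
curvature values at K control points.  Deformation follows the pure-bending
model: curvature is interpolated along the midline with a natural cubic
spline (zero over the stiff anterior fraction), integrated analytically to
the local tangent angle, and each cross-section is carried along the
deformed centreline, remaining planar and perpendicular to it.  Bending is
lateral only, in the head-frame x–y plane; the posed surface is then rotated
by the intrinsic yaw–pitch–roll rotation and translated to the snout
position.

Conventions (fixed here, self-consistent throughout the package):

* head frame: snout at origin, body extending towards −x (x is
  caudo-rostral), +y the fish's left, +z dorsal;
* rotation order: intrinsic z–y′–x″ (yaw, then pitch, then roll);
* positive curvature bends the tail towards +y (the fish's left).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .morphology import BodyModel, SurfaceMesh

__all__ = [
    "FishState",
    "curvature_control_points",
    "interpolate_curvature",
    "curvature_spline",
    "integrate_centerline",
    "deform_and_pose",
    "head_tail_angle",
    "head_rotation",
]


@dataclass
class FishState:
    """Model parameters Ω for one frame (mm, rad, 1/mm)."""

    x: float
    y: float
    z: float
    phi_roll: float
    phi_pitch: float
    phi_yaw: float
    kappa: np.ndarray = field(default_factory=lambda: np.zeros(7))

    def __post_init__(self) -> None:
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        if self.kappa.size < 3:
            raise ValueError("need at least 3 curvature control points")

    @property
    def n_control(self) -> int:
        return self.kappa.size

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.phi_roll, self.phi_pitch, self.phi_yaw])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.position, self.angles, self.kappa])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "FishState":
        v = np.asarray(v, dtype=float)
        return cls(v[0], v[1], v[2], v[3], v[4], v[5], v[6:].copy())

    def copy(self) -> "FishState":
        return FishState.from_vector(self.to_vector())


def head_rotation(state: FishState) -> Rotation:
    """Intrinsic yaw–pitch–roll head rotation (world ← head frame)."""
    return Rotation.from_euler(
        "ZYX", [state.phi_yaw, state.phi_pitch, state.phi_roll])


def curvature_control_points(n_control: int, stiff_fraction: float = 0.10) -> np.ndarray:
    """Arclength stations of the curvature control points.

    Control points span the flexible part of the body, uniformly from the
    end of the stiff head region to the tail tip.
    """
    return np.linspace(stiff_fraction, 1.0, n_control)


def curvature_spline(state: FishState, stiff_fraction: float = 0.10) -> CubicSpline:
    """Natural cubic spline through the curvature control points."""
    s_ctrl = curvature_control_points(state.n_control, stiff_fraction)
    return CubicSpline(s_ctrl, state.kappa, bc_type="natural")


def interpolate_curvature(
    state: FishState, s_grid: np.ndarray, stiff_fraction: float = 0.10
) -> np.ndarray:
    """Curvature κ(s) at the requested stations (zero over the stiff head)."""
    s_grid = np.asarray(s_grid, dtype=float)
    spl = curvature_spline(state, stiff_fraction)
    out = spl(np.clip(s_grid, stiff_fraction, 1.0))
    out[s_grid < stiff_fraction] = 0.0
    return out


def _tangent_angles(kappa_spline: CubicSpline, ell: float,
                    s: np.ndarray) -> np.ndarray:
    """θ(s) = ℓ∫₀ˢ κ du via the spline's exact per-piece antiderivative."""
    s0 = kappa_spline.x[0]
    F = kappa_spline.antiderivative()
    s = np.asarray(s, dtype=float)
    theta = np.where(s <= s0, 0.0, ell * (F(np.clip(s, s0, None)) - F(s0)))
    return theta


def integrate_centerline(
    kappa_spline: CubicSpline, ell: float, s_stations: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deformed centreline in the head frame from a curvature spline.

    Returns (points (M, 3), theta (M,), kappa (M,)).  The tangent angle is
    the analytic integral of the piecewise-cubic curvature; centreline
    points follow by marching segments of exact length Δs·ℓ along the
    mid-segment tangent direction (second-order accurate, arclength exactly
    preserved).  Positive θ turns the tail direction from −x towards +y.
    """
    s = np.asarray(s_stations, dtype=float)
    theta = _tangent_angles(kappa_spline, ell, s)
    s_mid = 0.5 * (s[:-1] + s[1:])
    theta_mid = _tangent_angles(kappa_spline, ell, s_mid)
    d_mid = np.column_stack([-np.cos(theta_mid), np.sin(theta_mid),
                             np.zeros_like(theta_mid)])
    seg = (np.diff(s) * ell)[:, None] * d_mid
    pts = np.vstack([np.zeros(3), np.cumsum(seg, axis=0)])
    kap = np.where(s < kappa_spline.x[0], 0.0,
                   kappa_spline(np.clip(s, kappa_spline.x[0], None)))
    return pts, theta, kap


def deform_and_pose(model: BodyModel, state: FishState) -> SurfaceMesh:
    """Posed surface mesh for a state: bend in the head frame, then the
    rigid yaw–pitch–roll rotation, then translation to the snout position."""
    spl = curvature_spline(state, model.stiff_fraction)
    centres, theta, _ = integrate_centerline(spl, model.length, model.s_values)

    # section frames: u axis in the bending plane, v axis out-of-plane (+z)
    u_hat = np.column_stack([np.sin(theta), np.cos(theta),
                             np.zeros_like(theta)])            # (M, 3)
    uv = model.sections                                        # (M, P, 2)
    rings = (centres[:, None, :]
             + uv[:, :, 0, None] * u_hat[:, None, :])
    rings[:, :, 2] += uv[:, :, 1]

    R = head_rotation(state).as_matrix()
    t = state.position
    M, P, _ = rings.shape
    rings = rings.reshape(-1, 3) @ R.T + t
    centres = centres @ R.T + t
    return SurfaceMesh(rings.reshape(M, P, 3), centres)


def head_tail_angle(state: FishState, stiff_fraction: float = 0.10,
                    ell: float = 1.0) -> float:
    """Integrated curvature along the body, ℓ∫₀¹κ ds — the angle between the
    body tangent at the snout and at the tail tip (rad)."""
    spl = curvature_spline(state, stiff_fraction)
    return float(_tangent_angles(spl, ell, np.array([1.0]))[0])
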