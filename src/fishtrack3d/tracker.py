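"""Per-frame fitting of the fish state to multi-camera silhouettes.

The tracked quantity per frame is the parameter vector Ω = (x, y, z, roll,
pitch, yaw, κ₁…κ_K).  The objective is

    f_tot(Ω) = f_GoF(Ω) + f_reg(Ω),

where f_GoF counts the pixels that differ between the rendered model
silhouettes and the segmented video silhouettes (symmetric difference,
summed over cameras) and f_reg = ∫ w(s) (dκ/ds)² ds with the head-weighted
exponential w(s) = c₀ e^(−c₁ s) penalises non-smooth curvature, suppressing
ill-posed solutions with unrealistically steep curvature gradients.

Each frame is minimised with Nelder–Mead, first coarsely and then restarted
with ten-fold reduced tolerances; when the converged objective jumps by more
than a threshold relative to the previous frame, additional optimisations
run from randomised perturbations of the previous solution.

The public modelling surface is :class:`FishTracker` (built from the data)
whose :meth:`FishTracker.fit` returns a :class:`TrackResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize

from .kinematics import FishState, curvature_spline, deform_and_pose
from .morphology import BodyModel
from .projection import CameraModel, project_points, render_silhouette
from .segmentation import segment_frame

__all__ = [
    "ObjectiveConfig",
    "TrackResults",
    "FishTracker",
    "goodness_of_fit",
    "regularisation",
    "objective",
    "predict_state",
    "initialize_first_frame",
    "fit_frame",
    "track_sequence",
]


@dataclass
class ObjectiveConfig:
    """Objective and optimiser settings.

    ``c0`` (px² units, making the regulariser commensurate with the
    pixel-count goodness of fit) and ``c1`` (decay rate; c₁ = 2 weights the
    head about 6× more strongly than the tail while leaving the weakly
    observed tail tip a meaningful penalty) shape the curvature
    regulariser.  ``kappa_max`` is a soft physiological cap on midline
    curvature (default 8/ℓ).  The fine optimisation stage always runs at
    ten-fold reduced tolerances relative to the coarse stage.
    """

    c0: float = 100.0
    c1: float = 2.0
    restart_threshold: float = 0.30
    max_restarts: int = 3
    coarse_xtol: float = 0.1       # scaled parameter units (see _scales)
    coarse_ftol_rel: float = 1e-2  # relative objective spread
    coarse_maxfev: int = 300
    fine_maxfev: int = 700
    refine_cycles: int = 3           # fine+block-refine passes per frame
    kappa_max: float | None = None   # 1/mm; default 8/ℓ (physiological cap)
    position_step: float = 1.0     # initial simplex steps, scaled units
    angle_step: float = 2.0
    kappa_step: float = 1.0
    perturb_position: float = 0.01   # fraction of body length
    perturb_angle_deg: float = 5.0
    perturb_kappa: float = 0.20      # fraction of current κ range
    track_P: int | None = None       # optional decimated tracking mesh
    track_M: int | None = None
    seed: int = 0

    @property
    def fine_xtol(self) -> float:
        return self.coarse_xtol / 10.0

    @property
    def fine_ftol_rel(self) -> float:
        return self.coarse_ftol_rel / 10.0


def _scales(model: BodyModel, n_control: int) -> np.ndarray:
    """Per-parameter scaling so the simplex is well conditioned:
    position in 1% body length, angles in degrees, curvature in 1/ℓ."""
    ell = model.length
    return np.concatenate([
        np.full(3, 0.01 * ell),
        np.full(3, np.pi / 180.0),
        np.full(n_control, 1.0 / ell),
    ])


# --------------------------------------------------------------------------
# Objective terms
# --------------------------------------------------------------------------

def _gof_masks(rendered: list[np.ndarray], segmented: list[np.ndarray]) -> int:
    return int(sum(np.count_nonzero(a ^ b)
                   for a, b in zip(rendered, segmented)))


def goodness_of_fit(
    state: FishState,
    silhouettes: list[np.ndarray],
    cams: list[CameraModel],
    model: BodyModel,
) -> int:
    """Σ over cameras of |rendered ∪ segmented| − |rendered ∩ segmented|,
    i.e. the total count of differing (symmetric-difference) pixels."""
    if len(silhouettes) != len(cams):
        raise ValueError("need one silhouette per camera")
    mesh = deform_and_pose(model, state)
    rendered = [render_silhouette(c, mesh) for c in cams]
    return _gof_masks(rendered, silhouettes)


def regularisation(state: FishState, cfg: ObjectiveConfig,
                   stiff_fraction: float = 0.10) -> float:
    """f_reg = ∫ w(s) (dκ/ds)² ds over the flexible body,
    w(s) = c₀ e^(−c₁ s); evaluated by per-piece Gauss–Legendre quadrature
    of the piecewise-quadratic squared spline derivative."""
    if cfg.c0 == 0:
        return 0.0
    spl = curvature_spline(state, stiff_fraction)
    dspl = spl.derivative()
    xg, wg = leggauss(8)
    knots = spl.x
    a, b = knots[:-1], knots[1:]
    mid, half = 0.5 * (a + b), 0.5 * (b - a)
    s = mid[:, None] + half[:, None] * xg[None, :]
    integrand = cfg.c0 * np.exp(-cfg.c1 * s) * dspl(s) ** 2
    return float(np.sum(half[:, None] * wg[None, :] * integrand))


def objective(
    state: FishState,
    silhouettes: list[np.ndarray],
    cams: list[CameraModel],
    model: BodyModel,
    cfg: ObjectiveConfig,
) -> float:
    """f_tot = f_GoF + f_reg."""
    return (goodness_of_fit(state, silhouettes, cams, model)
            + regularisation(state, cfg, model.stiff_fraction))


# --------------------------------------------------------------------------
# Prediction and initialisation
# --------------------------------------------------------------------------

def predict_state(previous_states: list[FishState],
                  window: int = 4) -> FishState:
    """Initial guess for the next frame by extrapolating the history.

    A copy for a single state; otherwise linear extrapolation of every
    parameter, with the slope estimated by least squares over the last
    ``window`` states so that frame-to-frame fitting noise is not doubled
    the way a plain two-point extrapolation would.  With exactly two states
    this reduces to the two-point linear extrapolation.
    """
    if not previous_states:
        raise ValueError("empty history: the first frame must be "
                         "initialised from clicked snout/tail points")
    if len(previous_states) == 1:
        return previous_states[-1].copy()
    arr = np.vstack([s.to_vector() for s in previous_states[-window:]])
    m = arr.shape[0]
    A = np.column_stack([np.ones(m), np.arange(m)])
    coef, *_ = np.linalg.lstsq(A, arr, rcond=None)
    return FishState.from_vector(coef[0] + coef[1] * m)


def _triangulate(cams: list[CameraModel],
                 pixels: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Least-squares 3D point from per-camera pixel observations.

    Orthographic cameras contribute two linear equations each; perspective
    cameras contribute the two normalised-ray equations.  Returns the point
    and the RMS reprojection residual in px.
    """
    rows, rhs, scales = [], [], []
    for cam, p in zip(cams, pixels):
        p = np.asarray(p, dtype=float)
        if cam.orthographic:
            r = (p - np.array([cam.cx, cam.cy])) / cam.scale
            rows.append(cam.rotation[0]); rhs.append(r[0] - cam.translation[0])
            rows.append(cam.rotation[1]); rhs.append(r[1] - cam.translation[1])
            scales += [cam.scale, cam.scale]
        else:
            u = (p[0] - cam.cx) / cam.focal
            v = (p[1] - cam.cy) / cam.focal
            # (R0 - u R2) X = u t_z - t_x  (and likewise for v)
            rows.append(cam.rotation[0] - u * cam.rotation[2])
            rhs.append(u * cam.translation[2] - cam.translation[0])
            rows.append(cam.rotation[1] - v * cam.rotation[2])
            rhs.append(v * cam.translation[2] - cam.translation[1])
            scales += [cam.focal, cam.focal]
    A = np.asarray(rows)
    b = np.asarray(rhs)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-6 * sv[0]:
        raise ValueError("camera rays are nearly parallel; "
                         "triangulation is ill-conditioned")
    X, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid_px = (A @ X - b) * np.asarray(scales)
    return X, float(np.sqrt(np.mean(resid_px ** 2)))


def initialize_first_frame(
    snout_px: list[np.ndarray],
    tail_px: list[np.ndarray],
    cams: list[CameraModel],
    n_control: int = 7,
) -> FishState:
    """First-frame state from clicked snout and tail pixels in ≥2 cameras:
    triangulated snout position, yaw/pitch from the snout→tail direction,
    zero roll and zero curvature (a straight fish)."""
    if len(cams) < 2:
        raise ValueError("need at least two cameras")
    snout, _ = _triangulate(cams, snout_px)
    tail, _ = _triangulate(cams, tail_px)
    h = snout - tail                     # heading: tail → snout
    norm = np.linalg.norm(h)
    if norm == 0:
        raise ValueError("snout and tail coincide")
    h = h / norm
    yaw = float(np.arctan2(h[1], h[0]))
    pitch = float(-np.arcsin(np.clip(h[2], -1.0, 1.0)))
    return FishState(snout[0], snout[1], snout[2], 0.0, pitch, yaw,
                     np.zeros(n_control))


# --------------------------------------------------------------------------
# Per-frame optimisation
# --------------------------------------------------------------------------

def _make_objective(silhouettes, cams, model, cfg, scales):
    kmax = cfg.kappa_max if cfg.kappa_max is not None else 8.0 / model.length

    def f(z: np.ndarray) -> float:
        state = FishState.from_vector(z * scales)
        mesh = deform_and_pose(model, state)
        gof = _gof_masks([render_silhouette(c, mesh) for c in cams],
                         silhouettes)
        # soft barrier keeping curvature physiological; zero inside the band
        excess = np.maximum(np.abs(state.kappa) - kmax, 0.0)
        barrier = 1e4 * float(np.sum(excess ** 2))
        return gof + regularisation(state, cfg, model.stiff_fraction) + barrier
    return f


class _AngleReparam:
    """Bijection between the curvature block and cumulative bend angles.

    The silhouette responds to the integrated curvature (section positions),
    so Nelder–Mead navigates far better in coordinates u_j = θ(s_j) — the
    trapezoid-rule bend angle accumulated up to control point j (rad) —
    than in the raw κ values.  Used internally by the fine optimisation
    stage; the reported state is always in κ.
    """

    def __init__(self, n_control: int, stiff_fraction: float, ell: float):
        from .kinematics import curvature_control_points
        s = curvature_control_points(n_control, stiff_fraction)
        self.ds = np.diff(s) * ell
        self.n = n_control

    def to_u(self, kappa: np.ndarray) -> np.ndarray:
        inc = 0.5 * (kappa[1:] + kappa[:-1]) * self.ds
        return np.concatenate([[kappa[0]], np.cumsum(inc)])

    def to_kappa(self, u: np.ndarray) -> np.ndarray:
        k = np.empty(self.n)
        k[0] = u[0]
        inc = np.diff(u)
        for i in range(self.n - 1):
            k[i + 1] = 2.0 * inc[i] / self.ds[i] - k[i]
        return k


def _nelder_mead(f, z0, steps, xtol, ftol_rel, maxfev):
    n = z0.size
    simplex = np.vstack([z0, z0 + np.diag(steps)])
    f0 = f(z0)
    res = minimize(f, z0, method="Nelder-Mead",
                   options={"initial_simplex": simplex,
                            "xatol": xtol,
                            "fatol": ftol_rel * max(abs(f0), 100.0),
                            "maxfev": maxfev,
                            "adaptive": n > 10})
    return res.x, float(res.fun)


def fit_frame(
    initial: FishState | list[FishState],
    silhouettes: list[np.ndarray],
    cams: list[CameraModel],
    model: BodyModel,
    cfg: ObjectiveConfig,
    prev_objective: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FishState, float, int, bool]:
    """Two-stage Nelder–Mead fit of one frame.

    ``initial`` may be a single state or a list of candidate states (e.g.
    the extrapolated prediction and the previous solution — the latter
    rescues frames where the motion reverses and extrapolation overshoots):
    the coarse stage runs from each candidate and the best result seeds the
    fine stage.  Returns (state, objective, restarts, flagged); ``flagged``
    is set when the restart budget is exhausted without bringing the
    objective within the allowed relative jump from the previous frame.
    """
    candidates = [initial] if isinstance(initial, FishState) else list(initial)
    initial = candidates[0]
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    track_model = model
    if cfg.track_P or cfg.track_M:
        track_model = model.decimate(cfg.track_P or model.n_circumferential,
                                     cfg.track_M or model.n_sections)
    scales = _scales(track_model, initial.n_control)
    f = _make_objective(silhouettes, cams, track_model, cfg, scales)
    K = initial.n_control
    steps = np.concatenate([
        np.full(3, cfg.position_step),
        np.full(3, cfg.angle_step),
        np.full(K, cfg.kappa_step),
    ])
    rep = _AngleReparam(K, track_model.stiff_fraction, track_model.length)

    def g(w):        # fine-stage coordinates: κ block → cumulative angles
        z = w.copy()
        z[6:] = rep.to_kappa(w[6:]) / scales[6:]
        return f(z)

    usteps = np.concatenate([steps[:6] / 5.0, np.full(K, 0.02)])

    def tail_refine(z1, f1):
        # the posterior-most curvature values are weakly constrained by the
        # silhouettes (the tail tip covers few pixels) and stall easily in
        # the full-dimensional simplex; a dedicated low-dimensional search
        # over the last two control points reliably frees them
        idx = np.array([z1.size - 2, z1.size - 1])

        def h(zz):
            zt = z1.copy()
            zt[idx] = zz
            return f(zt)

        zz, ff = _nelder_mead(h, z1[idx], np.full(2, 2.0),
                              cfg.fine_xtol, cfg.fine_ftol_rel, 80)
        if ff < f1:
            z1 = z1.copy()
            z1[idx] = zz
            return z1, ff
        return z1, f1

    def pose_refine(z1, f1):
        # analogous low-dimensional polish of the head angles, which couple
        # with anterior curvature in a narrow valley of the full problem
        idx = np.array([3, 4, 5])

        def h(zz):
            zt = z1.copy()
            zt[idx] = zz
            return f(zt)

        zz, ff = _nelder_mead(h, z1[idx], np.full(3, 1.0),
                              cfg.fine_xtol, cfg.fine_ftol_rel, 90)
        if ff < f1:
            z1 = z1.copy()
            z1[idx] = zz
            return z1, ff
        return z1, f1

    def fine(z1, f1):
        w1 = z1.copy()
        w1[6:] = rep.to_u(z1[6:] * scales[6:])
        w2, f2 = _nelder_mead(g, w1, usteps, cfg.fine_xtol,
                              cfg.fine_ftol_rel, cfg.fine_maxfev)
        z2 = w2.copy()
        z2[6:] = rep.to_kappa(w2[6:]) / scales[6:]
        if f2 > f1:
            z2, f2 = z1, f1
        z3, f3 = tail_refine(z2, f2)
        z3, f3 = pose_refine(z3, f3)
        if f3 < f2:
            w3 = z3.copy()
            w3[6:] = rep.to_u(z3[6:] * scales[6:])
            w4, f4 = _nelder_mead(g, w3, usteps / 2.0, cfg.fine_xtol,
                                  cfg.fine_ftol_rel, 250)
            if f4 < f3:
                z3 = w4.copy()
                z3[6:] = rep.to_kappa(w4[6:]) / scales[6:]
                f3 = f4
        return z3, f3

    def two_stage(z0):
        z1, f1 = _nelder_mead(f, z0, steps, cfg.coarse_xtol,
                              cfg.coarse_ftol_rel, cfg.coarse_maxfev)
        z1, f1 = fine(z1, f1)
        for _ in range(max(cfg.refine_cycles - 1, 0)):
            z1, f1 = fine(z1, f1)
        return z1, f1

    coarse_best = None
    for cand in candidates:
        z1, f1 = _nelder_mead(f, cand.to_vector() / scales, steps,
                              cfg.coarse_xtol, cfg.coarse_ftol_rel,
                              cfg.coarse_maxfev)
        if coarse_best is None or f1 < coarse_best[1]:
            coarse_best = (z1, f1)
    z_best, f_best = fine(*coarse_best)
    restarts = 0
    flagged = False
    if prev_objective is not None and prev_objective > 0:
        ell = track_model.length
        while (f_best > prev_objective * (1.0 + cfg.restart_threshold)
               and restarts < cfg.max_restarts):
            restarts += 1
            v = initial.to_vector().copy()
            v[:3] += rng.normal(0, cfg.perturb_position * ell, 3)
            v[3:6] += rng.normal(0, np.deg2rad(cfg.perturb_angle_deg), 3)
            krange = max(np.ptp(v[6:]), 1.0 / ell)
            v[6:] += rng.normal(0, cfg.perturb_kappa * krange, v.size - 6)
            z, fz = two_stage(v / scales)
            if fz < f_best:
                z_best, f_best = z, fz
        if f_best > prev_objective * (1.0 + cfg.restart_threshold):
            flagged = True
    state = FishState.from_vector(z_best * scales)
    return state, f_best, restarts, flagged


# --------------------------------------------------------------------------
# Sequence tracking
# --------------------------------------------------------------------------

@dataclass
class TrackResults:
    """Result of fitting a full sequence: one state per frame plus
    per-frame diagnostics."""

    states: list[FishState]
    objective: np.ndarray
    restarts: np.ndarray
    flagged: np.ndarray
    fps: float
    config: ObjectiveConfig = field(default_factory=ObjectiveConfig)

    @property
    def n_frames(self) -> int:
        return len(self.states)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def parameter_array(self) -> np.ndarray:
        return np.vstack([s.to_vector() for s in self.states])

    def to_dataframe(self) -> pd.DataFrame:
        arr = self.parameter_array()
        K = arr.shape[1] - 6
        cols = (["t", "x", "y", "z", "roll", "pitch", "yaw"]
                + [f"kappa_{i + 1}" for i in range(K)]
                + ["objective", "restarts", "flagged"])
        data = np.column_stack([
            self.time, arr, self.objective, self.restarts,
            self.flagged.astype(int),
        ])
        return pd.DataFrame(data, columns=cols)

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = [
            "Silhouette tracking results",
            "===========================",
            f"frames:           {self.n_frames}",
            f"frame rate:       {self.fps:g} fps",
            f"parameters/frame: {6 + self.states[0].n_control}",
            f"objective (px):   median {np.median(self.objective):.0f}, "
            f"max {self.objective.max():.0f}",
            f"restarted frames: {int(np.count_nonzero(self.restarts))}",
            f"flagged frames:   {int(np.count_nonzero(self.flagged))}",
            f"snout displacement: "
            f"{np.linalg.norm(df[['x', 'y', 'z']].iloc[-1] - df[['x', 'y', 'z']].iloc[0]):.3f} mm",
        ]
        return "\n".join(lines)


def track_sequence(
    silhouettes: list[np.ndarray],
    cams: list[CameraModel],
    model: BodyModel,
    cfg: ObjectiveConfig,
    first_frame: FishState,
    fps: float = 2000.0,
    verbose: bool = False,
) -> TrackResults:
    """Segment-free core loop: fit every frame of pre-segmented stacks.

    ``silhouettes`` is a list (one per camera) of (T, H, W) boolean stacks.
    ``first_frame`` seeds the optimisation of frame 0 (from
    :func:`initialize_first_frame` or a known state).
    """
    T = silhouettes[0].shape[0]
    if any(s.shape[0] != T for s in silhouettes):
        raise ValueError("cameras must have equal-length synchronised stacks")
    rng = np.random.default_rng(cfg.seed)
    states: list[FishState] = []
    fvals = np.zeros(T)
    restarts = np.zeros(T, dtype=int)
    flagged = np.zeros(T, dtype=bool)
    prev_f: float | None = None
    for t in range(T):
        sils = [s[t] for s in silhouettes]
        if states:
            # extrapolated prediction plus the previous solution, which
            # rescues frames where the motion reverses direction
            init = [predict_state(states), states[-1].copy()]
        else:
            init = first_frame
        st, fv, rs, fl = fit_frame(init, sils, cams, model, cfg,
                                   prev_objective=prev_f, rng=rng)
        states.append(st)
        fvals[t], restarts[t], flagged[t] = fv, rs, fl
        prev_f = fv
        if verbose:
            print(f"frame {t:4d}: f_tot={fv:9.1f} restarts={rs} "
                  f"{'FLAGGED' if fl else ''}")
    return TrackResults(states, fvals, restarts, flagged, fps, cfg)


class FishTracker:
    """Silhouette-based 3D fish-tracking model.

    Built from the observed data — per-camera image stacks (raw grayscale or
    pre-segmented boolean silhouettes), the camera calibrations and the
    body model — plus an :class:`ObjectiveConfig`; :meth:`fit` runs the
    per-frame optimisation pipeline and returns :class:`TrackResults`.
    """

    def __init__(
        self,
        frames: list[np.ndarray],
        cams: list[CameraModel],
        model: BodyModel,
        config: ObjectiveConfig | None = None,
        fps: float = 2000.0,
        grad_threshold: float | None = None,
        relative_threshold: float = 0.25,
    ) -> None:
        if len(frames) != len(cams):
            raise ValueError("need one frame stack per camera")
        self.cams = cams
        self.model = model
        self.config = config or ObjectiveConfig()
        self.fps = fps
        self.silhouettes = []
        for stack in frames:
            stack = np.asarray(stack)
            if stack.dtype == bool:
                self.silhouettes.append(stack)
            else:
                self.silhouettes.append(np.stack([
                    segment_frame(f, grad_threshold, relative_threshold)
                    for f in stack
                ]))

    def initialize(self, snout_px: list[np.ndarray],
                   tail_px: list[np.ndarray],
                   n_control: int = 7) -> FishState:
        return initialize_first_frame(snout_px, tail_px, self.cams, n_control)

    def fit(self, first_frame: FishState, verbose: bool = False) -> TrackResults:
        return track_sequence(self.silhouettes, self.cams, self.model,
                              self.config, first_frame, self.fps, verbose)
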