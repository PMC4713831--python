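"""Calibrated virtual cameras and silhouette rendering.

Cameras map world points (mm) to continuous pixel coordinates with the
origin at the image top-left, x rightward and y downward; the centre of
pixel (row r, column c) is at (c + 0.5, r + 0.5).  The default camera model
is orthographic (parallel projection): shadowgraph imaging with collimated
light makes magnification depth-independent, so a single px/mm scale plus an
orientation fully describes a camera.  A standard perspective pinhole model
is available for completeness.

Silhouettes are rendered by filling the projections of all surface facets;
a pixel belongs to the silhouette when its centre falls inside at least one
projected facet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numba
import numpy as np
import yaml

from .morphology import SurfaceMesh

__all__ = [
    "CameraModel",
    "project_points",
    "render_silhouette",
    "make_standard_rig",
    "load_cameras",
    "save_cameras",
]


@dataclass
class CameraModel:
    """Pinhole or parallel-projection camera.

    ``rotation`` (3, 3) and ``translation`` (3,) map world → camera
    coordinates, with the camera z axis along the viewing direction.  For
    orthographic cameras ``scale`` is px/mm; for perspective cameras
    ``focal`` is the focal length in px.
    """

    width: int
    height: int
    rotation: np.ndarray
    translation: np.ndarray
    scale: float | None = None
    focal: float | None = None
    cx: float | None = None
    cy: float | None = None
    orthographic: bool = True
    camera_id: str = "cam"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-10):
            raise ValueError("camera rotation is not orthonormal")
        if self.cx is None:
            self.cx = self.width / 2.0
        if self.cy is None:
            self.cy = self.height / 2.0
        if self.orthographic and self.scale is None:
            raise ValueError("orthographic camera needs a px/mm scale")
        if not self.orthographic and self.focal is None:
            raise ValueError("perspective camera needs a focal length")

    @property
    def view_direction(self) -> np.ndarray:
        """Viewing direction (camera z axis) in world coordinates."""
        return self.rotation[2]


def project_points(cam: CameraModel, points: np.ndarray) -> np.ndarray:
    """Project world points (mm) to continuous pixel coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    pc = pts @ cam.rotation.T + cam.translation
    if cam.orthographic:
        px = cam.cx + cam.scale * pc[:, 0]
        py = cam.cy + cam.scale * pc[:, 1]
    else:
        if np.any(pc[:, 2] <= 0):
            raise ValueError("point behind perspective camera")
        px = cam.cx + cam.focal * pc[:, 0] / pc[:, 2]
        py = cam.cy + cam.focal * pc[:, 1] / pc[:, 2]
    return np.column_stack([px, py])


@numba.njit(cache=True)
def _raster_triangles(tris: np.ndarray, H: int, W: int) -> np.ndarray:
    """Fill triangles into a boolean raster; a pixel is set when its centre
    (integer lattice point after the −0.5 shift) lies inside a triangle.
    Edge points are included (inclusive edge functions)."""
    mask = np.zeros((H, W), dtype=numba.boolean)
    n = tris.shape[0]
    for k in range(n):
        x0, y0 = tris[k, 0, 0], tris[k, 0, 1]
        x1, y1 = tris[k, 1, 0], tris[k, 1, 1]
        x2, y2 = tris[k, 2, 0], tris[k, 2, 1]
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if area == 0.0:
            continue
        if area < 0.0:   # normalise orientation
            x1, x2 = x2, x1
            y1, y2 = y2, y1
        xmin = int(np.ceil(min(x0, x1, x2)))
        xmax = int(np.floor(max(x0, x1, x2)))
        ymin = int(np.ceil(min(y0, y1, y2)))
        ymax = int(np.floor(max(y0, y1, y2)))
        if xmin < 0:
            xmin = 0
        if ymin < 0:
            ymin = 0
        if xmax > W - 1:
            xmax = W - 1
        if ymax > H - 1:
            ymax = H - 1
        for y in range(ymin, ymax + 1):
            for x in range(xmin, xmax + 1):
                w0 = (x1 - x0) * (y - y0) - (x - x0) * (y1 - y0)
                w1 = (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1)
                w2 = (x0 - x2) * (y - y2) - (x - x2) * (y0 - y2)
                if w0 >= 0.0 and w1 >= 0.0 and w2 >= 0.0:
                    mask[y, x] = True
    return mask


def render_silhouette(cam: CameraModel, mesh: SurfaceMesh) -> np.ndarray:
    """Binary silhouette mask (H, W) of a posed tube surface.

    The mask is the union of the filled projected facets (quad strips
    between adjacent rings plus the two apex fans); a pixel is set when its
    centre falls inside at least one projected facet.  For a closed,
    consistently wound surface the front-facing facets alone cover the
    silhouette, so back-facing quads are culled before rasterisation.
    """
    rings = mesh.rings
    M, P, _ = rings.shape
    # pixel-centre sampling: shift so that integer raster coords are centres
    rp = (project_points(cam, rings.reshape(-1, 3)) - 0.5).reshape(M, P, 2)

    # quad strips between adjacent rings; the degenerate end rings turn the
    # terminal strips into the closing caps
    a = rp[:-1].reshape(-1, 2)
    b = rp[1:].reshape(-1, 2)
    ak = np.roll(rp[:-1], -1, axis=1).reshape(-1, 2)
    bk = np.roll(rp[1:], -1, axis=1).reshape(-1, 2)

    area2 = ((ak[:, 0] - a[:, 0]) * (bk[:, 1] - a[:, 1])
             - (bk[:, 0] - a[:, 0]) * (ak[:, 1] - a[:, 1])
             + (bk[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
             - (b[:, 0] - a[:, 0]) * (bk[:, 1] - a[:, 1]))
    keep = area2 > 0
    if keep.sum() < keep.size // 4:   # inconsistent winding: keep everything
        keep[:] = True
    tris = np.empty((2 * int(keep.sum()), 3, 2))
    tris[0::2, 0] = a[keep]
    tris[0::2, 1] = ak[keep]
    tris[0::2, 2] = bk[keep]
    tris[1::2, 0] = a[keep]
    tris[1::2, 1] = bk[keep]
    tris[1::2, 2] = b[keep]
    return _raster_triangles(tris, cam.height, cam.width)


def _look_at_rotation(view_dir: np.ndarray, up: np.ndarray = np.array([0.0, 0.0, 1.0])) -> np.ndarray:
    """World→camera rotation with camera z along ``view_dir``."""
    z = np.asarray(view_dir, float)
    z = z / np.linalg.norm(z)
    if abs(z @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def make_standard_rig(
    fov_mm: float = 15.0,
    width: int = 1024,
    elevation_deg: float = 30.0,
    distance: float = 60.0,
) -> list[CameraModel]:
    """Three orthographic cameras emulating the experimental arrangement:
    one vertical (looking straight down) and a left- and right-facing camera
    at ``elevation_deg`` above horizontal, all sharing the same square field
    of view centred on the origin."""
    scale = width / fov_mm
    dirs = {
        "cam_top": np.array([0.0, 0.0, -1.0]),
    }
    el = np.deg2rad(elevation_deg)
    for name, sign in (("cam_left", 1.0), ("cam_right", -1.0)):
        # camera sits at azimuth ±90°, elevation above horizontal, looking in
        dirs[name] = np.array([0.0, -sign * np.cos(el), -np.sin(el)])
    cams = []
    for name, d in dirs.items():
        R = _look_at_rotation(d)
        t = np.array([0.0, 0.0, distance])
        cams.append(CameraModel(width, width, R, t, scale=scale,
                                orthographic=True, camera_id=name))
    return cams


def save_cameras(path: str | Path, cams: list[CameraModel]) -> None:
    doc = []
    for c in cams:
        rec = {
            "camera_id": c.camera_id,
            "model": "orthographic" if c.orthographic else "perspective",
            "width": int(c.width), "height": int(c.height),
            "cx": float(c.cx), "cy": float(c.cy),
            "rotation": np.round(c.rotation, 12).tolist(),
            "translation": np.round(c.translation, 9).tolist(),
        }
        if c.orthographic:
            rec["scale_px_per_mm"] = float(c.scale)
        else:
            rec["focal_px"] = float(c.focal)
        doc.append(rec)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_cameras(path: str | Path) -> list[CameraModel]:
    doc = yaml.safe_load(Path(path).read_text())
    cams = []
    for rec in doc:
        ortho = rec["model"] == "orthographic"
        cams.append(CameraModel(
            rec["width"], rec["height"],
            np.asarray(rec["rotation"], float),
            np.asarray(rec["translation"], float),
            scale=rec.get("scale_px_per_mm"),
            focal=rec.get("focal_px"),
            cx=rec.get("cx"), cy=rec.get("cy"),
            orthographic=ortho, camera_id=rec.get("camera_id", "cam"),
        ))
    return cams
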