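"""Frame stacks, run configuration and result files.

Conventions used throughout: 0-based frame indices, time t = index/fps,
pixel origin at the image top-left, world coordinates right-handed with z
up; lengths in mm on disk, forces in µN and torques in µN·mm in the
dynamics table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .dynamics import DynamicsResults, SmootherConfig
from .tracker import ObjectiveConfig, TrackResults

__all__ = [
    "RunConfig",
    "load_frames",
    "write_frames",
    "write_results",
    "load_run_config",
]


def load_frames(directory: str | Path, pattern: str = "*.png") -> np.ndarray:
    """Load a numbered frame stack, sorted by filename, normalised to [0,1]
    by the dtype maximum (8- and 16-bit integer images supported)."""
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(
            f"no frames matching {pattern!r} in {directory}")
    frames = []
    shape = None
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:
            img = img[..., 0]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"mixed frame sizes: {f} is {img.shape}, "
                             f"expected {shape}")
        if np.issubdtype(img.dtype, np.integer):
            img = img.astype(float) / np.iinfo(img.dtype).max
        else:
            img = img.astype(float)
        frames.append(img)
    return np.stack(frames)


def write_frames(directory: str | Path, stack: np.ndarray,
                 prefix: str = "frame") -> list[Path]:
    """Write a (T, H, W) float stack as 8-bit PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack):
        p = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


@dataclass
class RunConfig:
    """Configuration of a full tracking + dynamics run."""

    frame_dirs: list[str]
    camera_file: str
    model_spec: str | None = None
    output_dir: str = "out"
    fps: float = 2000.0
    pattern: str = "*.png"
    n_control: int = 7
    snout_px: list[list[float]] | None = None
    tail_px: list[list[float]] | None = None
    grad_threshold: float | None = None
    relative_threshold: float = 0.25
    background_region: list[int] | None = None  # [row0, row1, col0, col1]
    objective: dict = field(default_factory=dict)
    smoother: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "info"

    def objective_config(self) -> ObjectiveConfig:
        return ObjectiveConfig(seed=self.seed, **self.objective)

    def smoother_config(self) -> SmootherConfig:
        return SmootherConfig(**self.smoother)


def load_run_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    cfg = RunConfig(**doc)
    for p in cfg.frame_dirs + [cfg.camera_file]:
        if not Path(p).exists():
            raise FileNotFoundError(f"configured path does not exist: {p}")
    return cfg


def _config_hash(cfg) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_results(track: TrackResults, dyn: DynamicsResults | None,
                  out_dir: str | Path, extra_meta: dict | None = None) -> dict:
    """Write kinematics/dynamics CSVs and a metadata JSON; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    kin = out / "kinematics.csv"
    track.to_dataframe().to_csv(kin, index=False, float_format="%.10g")
    paths["kinematics"] = str(kin)
    if dyn is not None:
        if dyn.n_frames != track.n_frames:
            raise ValueError("track and dynamics lengths differ")
        dpath = out / "dynamics.csv"
        dyn.to_dataframe().to_csv(dpath, index=False, float_format="%.10g")
        paths["dynamics"] = str(dpath)
    import fishtrack3d
    meta = {
        "package_version": fishtrack3d.__version__,
        "n_frames": track.n_frames,
        "fps": track.fps,
        "config_hash": _config_hash(track.config),
        "objective_config": asdict(track.config),
        "flagged_frames": np.flatnonzero(track.flagged).tolist(),
    }
    if dyn is not None:
        meta.update({
            "mass_kg": dyn.mass,
            "edge_trim": dyn.edge_trim,
            "volume_drift": dyn.volume_drift,
            "smoothing_lambdas": (dyn.lambdas.tolist()
                                  if dyn.lambdas is not None else None),
        })
    if extra_meta:
        meta.update(extra_meta)
    mpath = out / "metadata.json"
    mpath.write_text(json.dumps(meta, indent=2))
    paths["metadata"] = str(mpath)
    return paths
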