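"""Reading and writing frame stacks and trajectory CSV files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Trajectory2D, Trajectory3D

__all__ = [
    "read_frames",
    "write_frames",
    "read_trajectory_2d",
    "write_trajectory_2d",
    "read_trajectory_3d",
    "write_trajectory_3d",
]


def write_frames(stack: np.ndarray, target, prefix: str = "") -> list[Path]:
    """Write a stack as zero-padded numbered PNGs (dir) or multi-page TIFF.

    The target's suffix decides the format: ``.tif``/``.tiff`` writes one
    multi-page file, anything else is treated as a directory of PNGs.
    """
    import imageio.v3 as iio

    stack = np.asarray(stack)
    target = Path(target)
    if target.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        target.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(target, stack, photometric="minisblack")
        return [target]
    target.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(stack):
        path = target / f"{prefix}{k:05d}.png"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def read_frames(source) -> np.ndarray:
    """Read a stack from a directory of numbered PNG/TIFF frames or a TIFF."""
    import imageio.v3 as iio

    source = Path(source)
    if source.is_file():
        import tifffile

        arr = tifffile.imread(source)
        return arr if arr.ndim == 3 else arr[None]
    paths = sorted(
        p for p in source.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not paths:
        raise FileNotFoundError(f"no frames found in {source}")
    return np.stack([iio.imread(p) for p in paths])


def write_trajectory_2d(traj: Trajectory2D, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(traj)),
            "t_s": traj.t,
            "x_px": traj.points[:, 0],
            "y_px": traj.points[:, 1],
            "flag": traj.flags.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_2d(path) -> Trajectory2D:
    df = pd.read_csv(path)
    fs = 1.0 / np.diff(df["t_s"]).mean() if len(df) > 1 else 30.0
    flags = df["flag"].to_numpy(dtype=bool) if "flag" in df else None
    return Trajectory2D(df[["x_px", "y_px"]].to_numpy(), fs=float(round(fs, 6)), flags=flags)


def write_trajectory_3d(traj: Trajectory3D, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(traj)),
            "t_s": traj.t,
            "X_mm": traj.points[:, 0],
            "Y_mm": traj.points[:, 1],
            "Z_mm": traj.points[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_3d(path) -> Trajectory3D:
    df = pd.read_csv(path)
    fs = 1.0 / np.diff(df["t_s"]).mean() if len(df) > 1 else 30.0
    return Trajectory3D(df[["X_mm", "Y_mm", "Z_mm"]].to_numpy(), fs=float(round(fs, 6)))
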