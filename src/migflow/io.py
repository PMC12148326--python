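"""Readers/writers for the pipeline's on-disk formats.

Stacks: multi-page TIFF, one page per frame, 16-bit unsigned, with pixel
size and frame interval carried in a JSON ImageDescription tag. Tracks and
flow fields: CSV. Summaries and manifests: JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    DirectionSummary,
    ImageStack,
    ParameterError,
    TrackSet,
    VectorField,
)

log = logging.getLogger("migflow")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page uint16 TIFF (values clipped to range)."""
    frames = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_min": stack.frame_interval,
    }
    tifffile.imwrite(
        str(path), frames, photometric="minisblack", description=json.dumps(meta)
    )


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Pixel size / frame interval come from the TIFF description when present;
    explicitly supplied values win, with a warning on conflict.
    """
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    tag_px = meta.get("pixel_size_um")
    tag_dt = meta.get("frame_interval_min")
    px = pixel_size if pixel_size is not None else (tag_px if tag_px else 1.0)
    dt = frame_interval if frame_interval is not None else (tag_dt if tag_dt else 5.0)
    if pixel_size is not None and tag_px and not np.isclose(pixel_size, tag_px):
        warnings.warn(
            f"pixel size {pixel_size} overrides TIFF tag value {tag_px}", stacklevel=2
        )
    if frame_interval is not None and tag_dt and not np.isclose(frame_interval, tag_dt):
        warnings.warn(
            f"frame interval {frame_interval} overrides TIFF tag value {tag_dt}",
            stacklevel=2,
        )
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim not in (3, 4):
        raise ParameterError(f"unsupported TIFF shape {frames.shape}")
    return ImageStack(frames.astype(np.float64), pixel_size=px, frame_interval=dt)


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    """Write tracks as CSV with header ``cell_id,frame,x_um,y_um``."""
    tracks.data[list(TrackSet.REQUIRED_COLUMNS)].to_csv(path, index=False)


def read_tracks(
    path: str | Path,
    origin_x: float = 0.0,
    pixel_size: float = 1.0,
    frame_interval: float = 5.0,
    signs_path: str | Path | None = None,
) -> TrackSet:
    data = pd.read_csv(path)
    signs = None
    if signs_path is not None:
        sdf = pd.read_csv(signs_path)
        signs = {int(r.cell_id): int(r.sign) for r in sdf.itertuples()}
    return TrackSet(
        data=data,
        origin_x=origin_x,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        signs=signs,
    )


def write_signs(tracks: TrackSet, path: str | Path) -> None:
    """Export the simulator's ground-truth direction signs (``cell_id,sign``)."""
    if tracks.signs is None:
        raise ParameterError("track set has no ground-truth signs")
    pd.DataFrame(
        {"cell_id": list(tracks.signs), "sign": list(tracks.signs.values())}
    ).to_csv(path, index=False)


def write_fields(fields: list[VectorField], path: str | Path) -> None:
    """Write flow fields as CSV ``frame,cell_x,cell_y,vx,vy,valid``."""
    rows = []
    for f in fields:
        gx, gy = np.meshgrid(f.grid_x, f.grid_y)
        rows.append(
            pd.DataFrame(
                {
                    "frame": f.frame_pair[0],
                    "cell_x": gx.ravel(),
                    "cell_y": gy.ravel(),
                    "vx": f.vx.ravel(),
                    "vy": f.vy.ravel(),
                    "valid": f.valid.ravel().astype(int),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_fields(path: str | Path) -> list[VectorField]:
    df = pd.read_csv(path)
    fields = []
    for t, grp in df.groupby("frame", sort=True):
        xs = np.sort(grp["cell_x"].unique())
        ys = np.sort(grp["cell_y"].unique())
        shape = (ys.size, xs.size)
        piv = grp.sort_values(["cell_y", "cell_x"])
        fields.append(
            VectorField(
                frame_pair=(int(t), int(t) + 1),
                grid_x=xs,
                grid_y=ys,
                vx=piv["vx"].to_numpy().reshape(shape),
                vy=piv["vy"].to_numpy().reshape(shape),
                valid=piv["valid"].to_numpy().astype(bool).reshape(shape),
            )
        )
    return fields


def write_offsets(offsets: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(offsets)), "dx": offsets[:, 0], "dy": offsets[:, 1]}
    ).to_csv(path, index=False)


def read_landmarks(path: str | Path) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Read landmark CSV ``frame,x_src,y_src,x_dst,y_dst`` into per-frame pairs."""
    df = pd.read_csv(path)
    out = {}
    for t, grp in df.groupby("frame"):
        out[int(t)] = (
            grp[["x_src", "y_src"]].to_numpy(float),
            grp[["x_dst", "y_dst"]].to_numpy(float),
        )
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def summary_to_json(summary: DirectionSummary, path: str | Path) -> None:
    write_json(summary.to_dict(), path)
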