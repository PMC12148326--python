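"""Agent-based generator of migration trajectories and rendered image stacks.

The model: each cell draws a persistent direction sign s ∈ {+1, −1} once at
t = 0, with P(s = +1) = q (posterior, +x). Per 1-frame step,

    Δx = s · max(0, N(speed_mean, speed_sd²)) · frame_interval + drift_x
    Δy = N(0, transverse_sd²) + drift_y        (µm)

so speed noise never reverses a cell; reversals enter only through q.
Rendering sums an isotropic Gaussian blob per cell over a static,
spatially-correlated background texture (emulating autofluorescent tissue,
shifted together with the cells by the stage drift) plus i.i.d. Gaussian
sensor noise, clipped to the 16-bit intensity range.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import SimulationConfig
from .datatypes import ImageStack, ParameterError, TrackSet

import pandas as pd

INTENSITY_MAX = 65535.0


def simulate_tracks(config: SimulationConfig) -> TrackSet:
    """Simulate persistent-direction random-walk tracks.

    Returns a :class:`TrackSet` whose ``signs`` attribute records the drawn
    ground-truth direction of every cell, so recovery tests never have to
    re-infer the truth from noisy measurements.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, t = int(config.n_cells), int(config.n_frames)
    width_um, height_um = config.field_um

    signs = np.where(rng.random(n) < config.q, 1, -1)

    y_margin = (
        config.start_y_margin
        if config.start_y_margin is not None
        else 0.3 * height_um
    )
    y_margin = min(y_margin, 0.45 * height_um)
    x0 = config.origin_x + rng.normal(0.0, config.start_x_sd, size=n)
    y0 = rng.uniform(y_margin, height_um - y_margin, size=n)

    speeds = np.maximum(0.0, rng.normal(config.speed_mean, config.speed_sd, size=(t - 1, n)))
    dx = signs[None, :] * speeds * config.frame_interval + config.drift[0]
    dy = rng.normal(0.0, config.transverse_sd, size=(t - 1, n)) + config.drift[1]

    # absorbing field boundary: the imaged region is finite, and the
    # simulator guarantees in-field points; a rare far-tail cell simply
    # stops at the margin instead of leaving the field
    margin = 2.0 * config.pixel_size
    x = np.empty((t, n))
    y = np.empty((t, n))
    x[0] = np.clip(x0, margin, width_um - margin)
    y[0] = np.clip(y0, margin, height_um - margin)
    for k in range(t - 1):
        x[k + 1] = np.clip(x[k] + dx[k], margin, width_um - margin)
        y[k + 1] = np.clip(y[k] + dy[k], margin, height_um - margin)

    frames = np.repeat(np.arange(t), n)
    data = pd.DataFrame(
        {
            "cell_id": np.tile(np.arange(n), t),
            "frame": frames,
            "x_um": x.ravel(),
            "y_um": y.ravel(),
        }
    )
    return TrackSet(
        data=data,
        origin_x=config.origin_x,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        signs={int(i): int(s) for i, s in enumerate(signs)},
    )


def _background_texture(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Static smooth random field with SD ``texture_amplitude`` (periodic)."""
    w, h = config.field_size
    raw = rng.standard_normal((h, w))
    tex = ndimage.gaussian_filter(raw, config.texture_sigma, mode="wrap")
    sd = tex.std()
    if sd > 0:
        tex *= config.texture_amplitude / sd
    return tex


def _shift_wrap(image: np.ndarray, shift_yx: tuple[float, float]) -> np.ndarray:
    """Periodic subpixel translation (linear interpolation)."""
    if shift_yx == (0.0, 0.0):
        return image
    return ndimage.shift(image, shift_yx, order=1, mode="grid-wrap")


def render_stack(tracks: TrackSet, config: SimulationConfig) -> ImageStack:
    """Render a track set into a synthetic time-lapse stack.

    Raises :class:`ParameterError` naming the first offending cell/frame if
    any track point falls outside the field after µm → px conversion.
    """
    config.validate()
    w, h = config.field_size
    n_frames = int(config.n_frames)

    # independent noise stream so track and render noise do not interleave
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    texture = _background_texture(config, rng) if config.texture_amplitude > 0 else None

    # per-cell brightness: lognormal with mean spot_amplitude; real cells
    # differ in fluorescence, which also disambiguates blob correspondence
    cell_ids = tracks.cell_ids
    if config.spot_amplitude_cv > 0:
        s = np.sqrt(np.log1p(config.spot_amplitude_cv**2))
        amps = config.spot_amplitude * np.exp(
            rng.normal(-0.5 * s * s, s, size=len(cell_ids))
        )
    else:
        amps = np.full(len(cell_ids), float(config.spot_amplitude))
    amp_of = dict(zip(cell_ids, amps))

    drift_px = (
        np.arange(n_frames)[:, None]
        * np.asarray(config.drift)[None, :]
        / config.pixel_size
    )  # cumulative (dx, dy) px per frame

    cols = {}
    for cid, frames, xy in tracks.iter_tracks():
        cols[cid] = (frames, xy / config.pixel_size)  # px coordinates

    half = max(1, int(np.ceil(4 * config.spot_sigma)))
    stack = np.empty((n_frames, h, w), dtype=np.float64)
    for t in range(n_frames):
        frame = np.zeros((h, w), dtype=np.float64)
        for cid, (frames, xy_px) in cols.items():
            sel = np.flatnonzero(frames == t)
            if sel.size == 0:
                continue
            cx, cy = xy_px[sel[0], 0], xy_px[sel[0], 1]
            if not (0 <= cx < w and 0 <= cy < h):
                raise ParameterError(
                    f"cell {cid} at frame {t} lies outside the field after "
                    f"pixel conversion: (x={cx:.1f}, y={cy:.1f}) px, field {w}x{h}"
                )
            _add_blob(frame, cx, cy, config.spot_sigma, amp_of[cid], half)
        if texture is not None:
            frame += _shift_wrap(texture, (drift_px[t, 1], drift_px[t, 0]))
        frame += config.background_level
        if config.background_noise_sd > 0:
            frame += rng.normal(0.0, config.background_noise_sd, size=(h, w))
        np.clip(frame, 0.0, INTENSITY_MAX, out=frame)
        stack[t] = frame

    return ImageStack(
        frames=stack,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
    )


def _add_blob(
    frame: np.ndarray, cx: float, cy: float, sigma: float, amplitude: float, half: int
) -> None:
    """Add an isotropic Gaussian blob at (cx, cy), evaluated on a local patch."""
    h, w = frame.shape
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2))
    frame[y0:y1, x0:x1] += amplitude * g


def simulate_stack(config: SimulationConfig) -> tuple[ImageStack, TrackSet]:
    """Convenience wrapper: simulate tracks and render them in one call."""
    tracks = simulate_tracks(config)
    return render_stack(tracks, config), tracks
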