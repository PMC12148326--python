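"""Core in-memory containers shared across the pipeline.

Coordinate convention (used everywhere in this package): frames are 2D
arrays indexed ``[row, col]`` with ``x = column`` (the anterior–posterior
migration axis, posterior = +x) and ``y = row`` (increasing downward, the
usual image convention). Pixel indices are 0-based. Physical track
coordinates are in micrometres; flow vectors are in px/frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """A configuration or argument value is non-finite or out of range."""


@dataclass
class ImageStack:
    """Ordered sequence of single-channel (or RGB) frames.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)`` (grayscale) or ``(T, H, W, 3)`` (RGB).
    pixel_size
        Micrometres per pixel (> 0).
    frame_interval
        Minutes between consecutive frames (> 0).
    """

    frames: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float = 5.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ParameterError(
                f"frames must be (T, H, W) or (T, H, W, C); got shape {self.frames.shape}"
            )
        if not (self.pixel_size > 0 and np.isfinite(self.pixel_size)):
            raise ParameterError(f"pixel_size must be finite and > 0, got {self.pixel_size}")
        if not (self.frame_interval > 0 and np.isfinite(self.frame_interval)):
            raise ParameterError(
                f"frame_interval must be finite and > 0, got {self.frame_interval}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def is_multichannel(self) -> bool:
        return self.frames.ndim == 4

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class RegistrationResult:
    """Output of stack stabilization.

    ``offsets[t] = (dx, dy)`` is the estimated translation of frame ``t``'s
    content relative to the reference frame (so ``offsets[reference] == (0, 0)``
    and the registered frame is the input shifted by ``-offset``).
    """

    stack: ImageStack
    offsets: np.ndarray  # (T, 2) as (dx, dy) in px
    reference: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class VectorField:
    """Per-frame-pair grid of 2D flow vectors.

    ``vx``/``vy`` have shape ``(ny, nx)`` on the grid with cell centres at
    ``grid_x`` (columns) and ``grid_y`` (rows), in pixel units of the source
    frames. ``valid`` marks cells that passed the texture/residual checks.
    """

    frame_pair: tuple[int, int]
    grid_x: np.ndarray  # (nx,)
    grid_y: np.ndarray  # (ny,)
    vx: np.ndarray  # (ny, nx) px/frame
    vy: np.ndarray  # (ny, nx) px/frame
    valid: np.ndarray  # (ny, nx) bool

    def __post_init__(self) -> None:
        if not (self.vx.shape == self.vy.shape == self.valid.shape):
            raise ValueError("vx, vy and valid must share one grid shape")
        if np.any(~np.isfinite(self.vx[self.valid])) or np.any(
            ~np.isfinite(self.vy[self.valid])
        ):
            raise ValueError("valid vectors must be finite")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_vectors(self) -> np.ndarray:
        """Return the valid vectors as an ``(N, 2)`` array of (vx, vy)."""
        return np.column_stack([self.vx[self.valid], self.vy[self.valid]])

    def norms(self) -> np.ndarray:
        """Euclidean norms of the valid vectors."""
        v = self.valid_vectors()
        return np.hypot(v[:, 0], v[:, 1])


@dataclass
class FlowBasis:
    """Orthonormal low-dimensional basis of 2D vector fields over a grid.

    ``components`` has shape ``(K, 2 * G)`` where ``G = ny * nx``; each row is
    a vectorized field ``concat(vx.ravel(), vy.ravel())``. Rows are
    orthonormal under the plain grid inner product. ``mean`` is the training
    mean field (zero for the analytic polynomial basis).
    """

    grid_shape: tuple[int, int]  # (ny, nx)
    components: np.ndarray  # (K, 2G)
    mean: np.ndarray  # (2G,)
    explained_variance: np.ndarray | None = None  # (K,) fractions

    @property
    def K(self) -> int:
        return self.components.shape[0]

    def field(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Return component ``k`` as a pair of (ny, nx) arrays (vx, vy)."""
        ny, nx = self.grid_shape
        g = ny * nx
        return (
            self.components[k, :g].reshape(ny, nx),
            self.components[k, g:].reshape(ny, nx),
        )


@dataclass
class TrackSet:
    """Per-cell trajectories in physical (µm) coordinates.

    ``data`` holds columns ``cell_id, frame, x_um, y_um`` sorted by
    (cell_id, frame). ``signs`` optionally records the simulator's
    ground-truth persistent direction (+1 posterior / −1 anterior) per cell.
    """

    data: pd.DataFrame
    origin_x: float = 0.0
    pixel_size: float = 1.0
    frame_interval: float = 5.0
    signs: dict[int, int] | None = None

    REQUIRED_COLUMNS = ("cell_id", "frame", "x_um", "y_um")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParameterError(f"track table is missing columns {missing}")
        self.data = self.data.sort_values(["cell_id", "frame"]).reset_index(drop=True)
        for cid, grp in self.data.groupby("cell_id"):
            f = grp["frame"].to_numpy()
            if np.any(np.diff(f) <= 0):
                raise ParameterError(f"track {cid}: frame indices must strictly increase")

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.data["cell_id"].unique().tolist())

    @property
    def n_cells(self) -> int:
        return self.data["cell_id"].nunique()

    def iter_tracks(self) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
        """Yield ``(cell_id, frames, xy)`` with ``xy`` of shape (n, 2) in µm."""
        for cid, grp in self.data.groupby("cell_id", sort=True):
            yield int(cid), grp["frame"].to_numpy(), grp[["x_um", "y_um"]].to_numpy(float)

    def positions_at(self, frame: int) -> np.ndarray:
        """(N, 2) array of (x, y) for every cell observed at ``frame``."""
        sel = self.data[self.data["frame"] == frame]
        if sel.empty:
            raise ParameterError(f"no track points at frame {frame}")
        return sel[["x_um", "y_um"]].to_numpy(float)


@dataclass
class DirectionSummary:
    """Per-sample disorderedness statistics of a flow-field sequence.

    ``n_left``/``n_right`` are plain counts, or fractional vote totals when
    mass weighting is enabled (each grid cell votes with the foreground
    fluorescence it contains).
    """

    kappa_per_frame: np.ndarray  # (n_fields,) px/frame
    variance_share_x: float  # in [0, 1]; NaN when undefined
    n_left: float
    n_right: float
    p_hat: float  # estimated Bernoulli parameter, P(left)
    entropy_bits: float  # in [0, 1]

    def to_dict(self) -> dict:
        return {
            "kappa_per_frame": [float(k) for k in self.kappa_per_frame],
            "variance_share_x": float(self.variance_share_x),
            "n_left": float(self.n_left),
            "n_right": float(self.n_right),
            "p_hat": float(self.p_hat),
            "entropy_bits": float(self.entropy_bits),
        }


@dataclass
class CohortMigrationSummary:
    """Leading-edge distances, velocity, straightness and rose histogram."""

    posterior_distance: float  # µm
    anterior_distance: float  # µm
    velocity: float  # µm/min (posterior leading edge / elapsed time)
    per_track_straightness: dict[int, float]
    rose_histogram: np.ndarray  # counts per angular bin
    rose_bin_edges_deg: np.ndarray

    def to_dict(self) -> dict:
        return {
            "posterior_distance_um": float(self.posterior_distance),
            "anterior_distance_um": float(self.anterior_distance),
            "velocity_um_per_min": float(self.velocity),
            "per_track_straightness": {
                int(k): (None if np.isnan(v) else float(v))
                for k, v in self.per_track_straightness.items()
            },
            "rose_histogram": [int(c) for c in self.rose_histogram],
            "rose_bin_edges_deg": [float(e) for e in self.rose_bin_edges_deg],
        }
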