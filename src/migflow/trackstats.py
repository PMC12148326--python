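"""Per-track and per-cohort migration quantities.

Leading-edge distances are measured from the junction origin along the A–P
axis: posterior = how far the frontmost cell has advanced in +x, anterior =
how far the rearmost cell has retreated in −x (both clamped at 0).
Velocity is v = d/t (µm/min). Straightness is d/D, the net displacement
over the summed path length, in [0, 1]. Rose histograms bin movement
directions with +x (posterior) at 0° and angles increasing counter-clockwise
in standard orientation (image y points down, so angles use −Δy).
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    CohortMigrationSummary,
    ImageStack,
    ParameterError,
    TrackSet,
)

__all__ = [
    "leading_edge_distances",
    "leading_edge_from_stack",
    "migration_velocity",
    "straightness",
    "rose_histogram",
    "displacement_traces",
    "cohort_summary",
]


def leading_edge_distances(tracks: TrackSet, at_frame: int) -> tuple[float, float]:
    """(anterior, posterior) leading-edge distances (µm) at ``at_frame``.

    posterior = max(0, max_i x_i − origin_x); anterior = max(0, origin_x −
    min_i x_i).
    """
    if tracks.data.empty:
        raise ParameterError("empty track set")
    xy = tracks.positions_at(at_frame)
    posterior = max(0.0, float(xy[:, 0].max()) - tracks.origin_x)
    anterior = max(0.0, tracks.origin_x - float(xy[:, 0].min()))
    return anterior, posterior


def leading_edge_from_stack(
    stack: ImageStack, origin_x_px: float, threshold: float, frame: int = -1
) -> tuple[float, float]:
    """Intensity-threshold leading edge (µm) for stacks without tracks.

    On the chosen frame, columns whose maximum intensity (over y) exceeds
    ``threshold`` are considered occupied; the extreme occupied columns give
    the anterior/posterior edges relative to ``origin_x_px``.
    """
    img = stack.frames[frame]
    profile = img.max(axis=0)
    occupied = np.flatnonzero(profile > threshold)
    if occupied.size == 0:
        return 0.0, 0.0
    posterior = max(0.0, (occupied.max() - origin_x_px)) * stack.pixel_size
    anterior = max(0.0, (origin_x_px - occupied.min())) * stack.pixel_size
    return float(anterior), float(posterior)


def migration_velocity(distance_um: float, elapsed_min: float) -> float:
    """v = d (µm) / t (min)."""
    if not elapsed_min > 0:
        raise ParameterError(f"elapsed time must be > 0 min, got {elapsed_min}")
    return distance_um / elapsed_min


def straightness(xy: np.ndarray) -> float:
    """d/D: net first→last displacement over summed segment lengths.

    Returns NaN for a fully static track (D = 0) rather than raising.
    """
    xy = np.asarray(xy, float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ParameterError("a track needs >= 2 (x, y) points")
    segs = np.diff(xy, axis=0)
    D = float(np.hypot(segs[:, 0], segs[:, 1]).sum())
    if D == 0.0:
        return float("nan")
    d = float(np.hypot(*(xy[-1] - xy[0])))
    return d / D


def _angles_deg(deltas: np.ndarray) -> np.ndarray:
    """Angles of displacement vectors in degrees, +x = 0°, CCW positive.

    Image y increases downward, so the y component is negated to express
    angles in standard mathematical orientation.
    """
    nonzero = np.hypot(deltas[:, 0], deltas[:, 1]) > 0
    d = deltas[nonzero]
    return np.degrees(np.arctan2(-d[:, 1], d[:, 0]))


def rose_histogram(
    tracks: TrackSet, n_bins: int = 16, mode: str = "per-track"
) -> tuple[np.ndarray, np.ndarray]:
    """Angular histogram of movement directions.

    ``mode='per-step'`` bins every displacement step; ``'per-track'`` bins
    each track's net first→last displacement. Bins are centred so that 0°
    (posterior) sits at a bin centre; zero-length displacements are skipped.
    Returns ``(counts, bin_edges_deg)`` with edges starting at −half-width.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    if mode not in ("per-step", "per-track"):
        raise ParameterError(f"mode must be 'per-step' or 'per-track', got {mode!r}")
    deltas = []
    for _, _, xy in tracks.iter_tracks():
        if xy.shape[0] < 2:
            continue
        if mode == "per-step":
            deltas.append(np.diff(xy, axis=0))
        else:
            deltas.append((xy[-1] - xy[0])[None, :])
    if not deltas:
        return np.zeros(n_bins, dtype=int), _bin_edges(n_bins)
    angles = _angles_deg(np.concatenate(deltas))
    width = 360.0 / n_bins
    shifted = np.mod(angles + width / 2.0, 360.0)
    idx = np.floor(shifted / width).astype(int) % n_bins
    counts = np.bincount(idx, minlength=n_bins)
    return counts, _bin_edges(n_bins)


def _bin_edges(n_bins: int) -> np.ndarray:
    width = 360.0 / n_bins
    return -width / 2.0 + width * np.arange(n_bins + 1)


def displacement_traces(tracks: TrackSet) -> dict[int, np.ndarray]:
    """Each track re-expressed with its first point at the origin (0, 0)."""
    if tracks.data.empty:
        raise ParameterError("empty track set")
    return {cid: xy - xy[0] for cid, _, xy in tracks.iter_tracks()}


def cohort_summary(
    tracks: TrackSet,
    at_frame: int | None = None,
    rose_bins: int = 16,
    rose_mode: str = "per-track",
) -> CohortMigrationSummary:
    """Cohort-level migration summary at ``at_frame`` (default: last frame).

    Velocity is the posterior leading-edge distance divided by the elapsed
    time from frame 0 to ``at_frame``.
    """
    if tracks.data.empty:
        raise ParameterError("empty track set")
    last = int(tracks.data["frame"].max())
    frame = last if at_frame is None else int(at_frame)
    anterior, posterior = leading_edge_distances(tracks, frame)
    first = int(tracks.data["frame"].min())
    elapsed = (frame - first) * tracks.frame_interval
    velocity = migration_velocity(posterior, elapsed) if elapsed > 0 else 0.0
    per_track = {
        cid: straightness(xy) for cid, _, xy in tracks.iter_tracks() if xy.shape[0] >= 2
    }
    counts, edges = rose_histogram(tracks, n_bins=rose_bins, mode=rose_mode)
    return CohortMigrationSummary(
        posterior_distance=posterior,
        anterior_distance=anterior,
        velocity=velocity,
        per_track_straightness=per_track,
        rose_histogram=counts,
        rose_bin_edges_deg=edges,
    )
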