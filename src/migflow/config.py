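"""Configuration dataclasses: simulator, flow-estimation and pipeline runs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datatypes import ParameterError


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _finite(*values: float) -> bool:
    return all(np.isfinite(v) for v in values)


@dataclass
class SimulationConfig:
    """Parameters of the agent-based migration simulator.

    The defaults emulate a pupal tracheal-progenitor movie: a cohort of
    bright cells clustered at the transverse-connective/dorsal-trunk
    junction, migrating along the A–P (x) axis at sub-µm/min speed,
    imaged every 5 min for 2 h.

    ``q`` is the discipline parameter: the probability that a cell's
    persistent direction is posterior (+x). ``q = 1`` is fully disciplined
    (control-like); ``q = 0.5`` is fully bidirectional (fat-body-depleted
    phenotype).
    """

    n_cells: int = 100
    q: float = 1.0
    speed_mean: float = 0.7  # µm/min
    speed_sd: float = 0.2  # µm/min
    transverse_sd: float = 1.0  # µm per step (y jitter)
    drift: tuple[float, float] = (0.0, 0.0)  # µm/frame global stage drift
    n_frames: int = 25  # 2 h at 5-min intervals
    frame_interval: float = 5.0  # min
    field_size: tuple[int, int] = (384, 128)  # (width, height) px
    pixel_size: float = 1.0  # µm/px
    spot_sigma: float = 2.0  # px
    spot_amplitude: float = 1000.0
    spot_amplitude_cv: float = 0.3  # per-cell lognormal brightness variation
    background_noise_sd: float = 10.0
    origin_x: float = 192.0  # µm, junction position
    seed: int = 0
    # starting-cluster geometry
    start_x_sd: float = 25.0  # µm
    start_y_margin: float | None = None  # µm; default 0.3 * field height
    # static background tissue texture (amplitude 0 disables it)
    texture_amplitude: float = 100.0  # intensity SD of the static field
    texture_sigma: float = 2.0  # px, spatial correlation length
    background_level: float = 400.0  # additive intensity offset

    def validate(self) -> "SimulationConfig":
        _check(
            _finite(
                self.q, self.speed_mean, self.speed_sd, self.transverse_sd,
                *self.drift, self.frame_interval, self.pixel_size,
                self.spot_sigma, self.spot_amplitude, self.background_noise_sd,
                self.origin_x, self.start_x_sd, self.texture_amplitude,
                self.texture_sigma, self.background_level,
            ),
            "simulation parameters must be finite",
        )
        _check(int(self.n_cells) == self.n_cells and self.n_cells >= 1,
               f"n_cells must be a positive integer, got {self.n_cells}")
        _check(0.0 <= self.q <= 1.0, f"q must lie in [0, 1], got {self.q}")
        _check(self.speed_mean > 0, f"speed_mean must be > 0, got {self.speed_mean}")
        _check(self.speed_sd >= 0, f"speed_sd must be >= 0, got {self.speed_sd}")
        _check(self.transverse_sd >= 0,
               f"transverse_sd must be >= 0, got {self.transverse_sd}")
        _check(int(self.n_frames) == self.n_frames and self.n_frames >= 2,
               f"n_frames must be an integer >= 2, got {self.n_frames}")
        _check(self.frame_interval > 0,
               f"frame_interval must be > 0, got {self.frame_interval}")
        w, h = self.field_size
        _check(w >= 8 and h >= 8, f"field_size must be at least 8x8 px, got {self.field_size}")
        _check(self.pixel_size > 0, f"pixel_size must be > 0, got {self.pixel_size}")
        _check(self.spot_sigma > 0, f"spot_sigma must be > 0, got {self.spot_sigma}")
        _check(self.spot_amplitude > 0,
               f"spot_amplitude must be > 0, got {self.spot_amplitude}")
        _check(np.isfinite(self.spot_amplitude_cv) and self.spot_amplitude_cv >= 0,
               f"spot_amplitude_cv must be >= 0, got {self.spot_amplitude_cv}")
        _check(self.background_noise_sd >= 0,
               f"background_noise_sd must be >= 0, got {self.background_noise_sd}")
        _check(self.start_x_sd >= 0, f"start_x_sd must be >= 0, got {self.start_x_sd}")
        _check(self.texture_amplitude >= 0 and self.texture_sigma > 0,
               "texture_amplitude must be >= 0 and texture_sigma > 0")
        _check(int(self.seed) == self.seed, f"seed must be an integer, got {self.seed}")
        return self

    @property
    def field_um(self) -> tuple[float, float]:
        """Field extent (width, height) in µm."""
        return self.field_size[0] * self.pixel_size, self.field_size[1] * self.pixel_size

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift"] = list(self.drift)
        d["field_size"] = list(self.field_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "drift" in d:
            d["drift"] = tuple(d["drift"])
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        return cls(**d).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class FlowParams:
    """Sparse-flow and basis-smoothing parameters.

    ``min_eig_scale`` scales the texture (conditioning) threshold: a grid
    cell is texture-valid when the smallest eigenvalue of the local
    gradient normal matrix exceeds ``min_eig_scale * window**2``.
    ``min_significance`` (when set) additionally requires the fitted flow
    to *explain* the local temporal change: the windowed warp residual must
    drop by at least this factor relative to the zero-flow hypothesis,
    (RSS_zero − RSS_flow)/RSS_flow >= min_significance. ``None`` disables
    the gate (every texture-valid cell is kept).
    """

    window: int = 9  # px; small enough to resolve individual cells
    grid_step: int = 4  # px
    n_levels: int = 3  # pyramid levels
    n_iter: int = 3  # Gauss-Newton iterations per level
    smooth_sigma: float = 1.5  # px, inter-iteration flow smoothing
    min_eig_scale: float = 1e-2
    min_significance: float | None = 1.0
    ridge: float = 1e-3
    K: int = 12  # basis size
    poly_degree: int = 2

    def validate(self) -> "FlowParams":
        _check(self.window >= 3, f"window must be >= 3 px, got {self.window}")
        _check(self.grid_step >= 1, f"grid_step must be >= 1, got {self.grid_step}")
        _check(self.n_levels >= 1 and self.n_iter >= 1,
               "n_levels and n_iter must be >= 1")
        _check(self.ridge >= 0, f"ridge must be >= 0, got {self.ridge}")
        _check(self.K >= 1, f"K must be >= 1, got {self.K}")
        return self


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    stack_path: str | None = None
    tracks_path: str | None = None
    out_dir: str = "migflow_out"
    pixel_size: float | None = None  # µm/px; overrides stack metadata
    frame_interval: float | None = None  # min
    origin_x: float | None = None  # µm, junction position for track metrics
    register: bool = True
    reference_frame: int = 0
    flow: FlowParams = field(default_factory=FlowParams)
    magnitude_filter: bool = True  # Q0.2 norm filter before binarization
    kappa_normalize: bool = True  # κ-normalize before pooled variance
    mass_weighting: bool = True  # weight votes by local foreground mass
    persistence_gate: bool = True  # votes must repeat in an adjacent pair
    stats_source: str = "sparse"  # "sparse" | "dense"
    rose_bins: int = 16
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        _check(self.stats_source in ("sparse", "dense"),
               f"stats_source must be 'sparse' or 'dense', got {self.stats_source!r}")
        _check(self.rose_bins >= 2,
               f"rose_bins must be >= 2, got {self.rose_bins}")
        self.flow.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "flow" in d and isinstance(d["flow"], dict):
            d["flow"] = FlowParams(**d["flow"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
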