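"""End-to-end orchestration: registration → optical flow → statistics.

``run_pipeline`` is deterministic given (inputs, config, seed): every
reduction is single-threaded numpy, and all defaults are serialized into
the run manifest so runs are self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .datatypes import (
    CohortMigrationSummary,
    DirectionSummary,
    ImageStack,
    ParameterError,
    TrackSet,
)
from .direction import summarize_directionality
from .flow import flow_pipeline
from .registration import stabilize, to_grayscale
from .trackstats import cohort_summary
from . import io as mio

log = logging.getLogger("migflow")


def _foreground_mass(frame: np.ndarray, field, window: int) -> np.ndarray:
    """Per-grid-cell foreground fluorescence mass: windowed sum of the
    above-median intensity, sampled at the flow grid. Used to weight
    direction votes by cell content instead of covered area."""
    from scipy import ndimage

    fg = np.maximum(frame - np.median(frame), 0.0)
    mass = ndimage.uniform_filter(fg, size=window, mode="nearest") * float(window**2)
    return mass[np.ix_(field.grid_y, field.grid_x)]


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # identifies the analysis, not where it lands
    payload = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def analyze_stack(
    stack: ImageStack, config: RunConfig
) -> tuple[DirectionSummary, dict]:
    """Register a stack, estimate flow and summarize directionality.

    Returns the summary plus a dict of intermediates (registration result,
    sparse and dense fields).
    """
    config.validate()
    stages: dict[str, float] = {}

    t0 = time.perf_counter()
    gray = to_grayscale(stack)
    stages["grayscale"] = time.perf_counter() - t0

    offsets = np.zeros((gray.n_frames, 2))
    if config.register:
        t0 = time.perf_counter()
        reg = stabilize(gray, reference=config.reference_frame)
        for w in reg.warnings:
            log.warning("stabilize: %s", w)
        gray = reg.stack
        offsets = reg.offsets
        stages["stabilize"] = time.perf_counter() - t0

    margin = float(np.ceil(np.abs(offsets).max())) + config.flow.window // 2 + 1
    t0 = time.perf_counter()
    dense, sparse = flow_pipeline(
        gray, config.flow, margin_px=margin, return_sparse=True
    )
    stages["flow"] = time.perf_counter() - t0

    fields = sparse if config.stats_source == "sparse" else dense
    weights = None
    if config.mass_weighting:
        weights = [_foreground_mass(gray.frames[f.frame_pair[0]], f, config.flow.window)
                   for f in fields]
    t0 = time.perf_counter()
    summary = summarize_directionality(
        fields,
        magnitude_filter=config.magnitude_filter,
        kappa_normalize=config.kappa_normalize,
        weights=weights,
        persistence=config.persistence_gate,
    )
    stages["metrics"] = time.perf_counter() - t0

    return summary, {
        "offsets": offsets,
        "sparse": sparse,
        "dense": dense,
        "stages": stages,
    }


def run_pipeline(
    config: RunConfig,
    stack: ImageStack | None = None,
    tracks: TrackSet | None = None,
) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    ``stack``/``tracks`` may be passed in-memory; otherwise they are read
    from the paths in the config. Returns the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "outputs": {},
        "status": "incomplete",
    }
    try:
        if stack is None and config.stack_path:
            stack = mio.read_stack(
                config.stack_path,
                pixel_size=config.pixel_size,
                frame_interval=config.frame_interval,
            )
        if tracks is None and config.tracks_path:
            tracks = mio.read_tracks(
                config.tracks_path,
                origin_x=config.origin_x or 0.0,
                pixel_size=config.pixel_size or 1.0,
                frame_interval=config.frame_interval or 5.0,
            )
        if stack is None and tracks is None:
            raise ParameterError("run_pipeline needs a stack and/or tracks")

        if stack is not None:
            if stack.n_frames < 2:
                raise ParameterError("flow analysis needs >= 2 frames")
            try:
                summary, inter = analyze_stack(stack, config)
            except ParameterError as exc:
                raise ParameterError(f"stage 'flow-analysis': {exc}") from exc
            mio.write_offsets(inter["offsets"], out / "offsets.csv")
            mio.write_fields(inter["sparse"], out / "fields_sparse.csv")
            mio.write_fields(inter["dense"], out / "fields_dense.csv")
            mio.summary_to_json(summary, out / "direction_summary.json")
            manifest["outputs"]["direction_summary"] = "direction_summary.json"
            manifest["outputs"]["offsets"] = "offsets.csv"
            manifest["outputs"]["fields_sparse"] = "fields_sparse.csv"
            manifest["outputs"]["fields_dense"] = "fields_dense.csv"
            for stage, dt in inter["stages"].items():
                log.info("stage %-10s %.2f s", stage, dt)
            manifest["direction_summary"] = summary.to_dict()

        if tracks is not None:
            try:
                cs = cohort_summary(tracks, rose_bins=config.rose_bins)
            except ParameterError as exc:
                raise ParameterError(f"stage 'track-metrics': {exc}") from exc
            mio.write_json(cs.to_dict(), out / "cohort_summary.json")
            manifest["outputs"]["cohort_summary"] = "cohort_summary.json"
            manifest["cohort_summary"] = cs.to_dict()

        manifest["status"] = "complete"
    finally:
        mio.write_json(manifest, out / "manifest.json")
    return manifest
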