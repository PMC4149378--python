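"""End-to-end orchestration: simulate/load -> extract -> fit -> model.

A single configured run takes a staining time series (either simulated
from the phantom generator or loaded from a TIFF stack with its JSON
sidecar), extracts a transmural line profile per timepoint, detects the
epicardial edge on a reference timepoint (default: the last and
most-stained scan, where the boundary contrast is strongest), assembles
the depth x time intensity grid, fits the saturation curve per depth,
tabulates time-to-saturation and fits the exponential depth-time model
per saturation level.  Artifacts (CSV tables and a JSON report) are
written to the configured output directory; given a fixed configuration
the CSV outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import (
    DEFAULT_LEVELS,
    IntensityTimeSeries,
    SaturationCurveFit,
    SaturationTimeTable,
    build_saturation_table,
    fit_saturation_curve,
)
from .phantom import (
    ExactModelParams,
    PhantomConfig,
    SliceImage,
    read_stack,
    simulate_stack,
)
from .profiles import (
    DEFAULT_DROP_FRACTION,
    DEFAULT_SIGMA_PX,
    detect_epicardial_edge,
    discretize_profile,
    extract_line_profile,
)
from .timemodel import TabulationResult, tabulate_models

__all__ = [
    "RunConfig",
    "RunReport",
    "Finding",
    "ConfigError",
    "StageError",
    "validate_config",
    "run_pipeline",
]

log = logging.getLogger("stainkinetics")

MIN_TIMEPOINTS = 4  # 3 free parameters per depth + 1


class ConfigError(ValueError):
    """The run configuration is invalid (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""

    def __init__(self, stage: str, context: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed ({context}): {cause}")
        self.stage = stage
        self.context = context
        self.cause = cause


@dataclasses.dataclass(frozen=True)
class Finding:
    """One machine-readable configuration problem."""

    code: str
    message: str


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one pipeline run.

    ``input`` is either the literal string ``"simulate"`` (the phantom
    generator provides the stack) or a path to a multi-page TIFF with a
    JSON metadata sidecar.  ``ray_start``/``ray_end`` are (x, y) pixel
    coordinates of the sampling ray; when simulating they default to a
    horizontal ray from the left image edge to the annulus centre.
    """

    input: str = "simulate"
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    model: ExactModelParams = dataclasses.field(default_factory=ExactModelParams)
    ray_start: tuple[float, float] | None = None
    ray_end: tuple[float, float] | None = None
    width_px: int = 5
    sigma_px: float = DEFAULT_SIGMA_PX
    drop_fraction: float = DEFAULT_DROP_FRACTION
    reference_timepoint: int | str = "last"
    seg_len_mm: float = 0.1
    n_segments: int = 20
    levels: tuple[float, ...] = DEFAULT_LEVELS
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict = {}
        if "phantom" in raw:
            kwargs["phantom"] = PhantomConfig(**raw.pop("phantom"))
        if "model" in raw:
            kwargs["model"] = ExactModelParams(**raw.pop("model"))
        ray = raw.pop("ray", None)
        if ray:
            if ray.get("start") is not None:
                kwargs["ray_start"] = tuple(ray["start"])
            if ray.get("end") is not None:
                kwargs["ray_end"] = tuple(ray["end"])
        edge = raw.pop("edge", None)
        if edge:
            for key in ("sigma_px", "drop_fraction", "reference_timepoint"):
                if key in edge:
                    kwargs[key] = edge[key]
        segments = raw.pop("segments", None)
        if segments:
            if "seg_len_mm" in segments:
                kwargs["seg_len_mm"] = segments["seg_len_mm"]
            if "n_segments" in segments:
                kwargs["n_segments"] = segments["n_segments"]
        if "levels" in raw:
            kwargs["levels"] = tuple(float(s) for s in raw.pop("levels"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except OSError as exc:
            raise ConfigError(f"unreadable config file {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a YAML mapping")
        return cls.from_dict(raw)

    def canonical_json(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=encode, allow_nan=False
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclasses.dataclass(frozen=True)
class RunReport:
    """All results of one pipeline run plus provenance."""

    fits: tuple[SaturationCurveFit, ...]
    table: SaturationTimeTable
    models: TabulationResult
    edge_position_mm: float
    provenance: dict
    artifacts: dict


def validate_config(cfg: RunConfig) -> list[Finding]:
    """Check a run configuration; an empty list means it is valid."""
    findings: list[Finding] = []
    for s in cfg.levels:
        if not (0.0 < s < 1.0):
            findings.append(
                Finding("level_out_of_range", f"saturation level {s} outside (0, 1)")
            )
    if list(cfg.levels) != sorted(cfg.levels):
        findings.append(Finding("levels_not_sorted", "levels must be sorted ascending"))
    if cfg.width_px < 1 or cfg.width_px % 2 == 0:
        findings.append(
            Finding("width_not_odd", f"profile width {cfg.width_px} must be odd and >= 1")
        )
    if cfg.sigma_px <= 0:
        findings.append(Finding("sigma_not_positive", "edge sigma_px must be > 0"))
    if not (0.0 < cfg.drop_fraction < 1.0):
        findings.append(
            Finding("drop_fraction_out_of_range", "drop_fraction must lie in (0, 1)")
        )
    if cfg.seg_len_mm <= 0 or cfg.n_segments < 1:
        findings.append(
            Finding("bad_segmentation", "seg_len_mm must be > 0 and n_segments >= 1")
        )
    if cfg.input == "simulate":
        span = cfg.n_segments * cfg.seg_len_mm
        if span > cfg.phantom.wall_thickness:
            findings.append(
                Finding(
                    "segments_exceed_wall",
                    f"{cfg.n_segments} x {cfg.seg_len_mm} mm segments ({span:g} mm) "
                    f"exceed the phantom wall thickness {cfg.phantom.wall_thickness:g} mm",
                )
            )
        if len(cfg.phantom.times) < MIN_TIMEPOINTS:
            findings.append(
                Finding(
                    "too_few_timepoints",
                    f"{len(cfg.phantom.times)} timepoints; at least "
                    f"{MIN_TIMEPOINTS} (including t = 0) are required",
                )
            )
    else:
        if not Path(cfg.input).exists():
            findings.append(Finding("input_missing", f"input stack not found: {cfg.input}"))
    if isinstance(cfg.reference_timepoint, str) and cfg.reference_timepoint != "last":
        findings.append(
            Finding(
                "bad_reference_timepoint",
                "reference_timepoint must be 'last' or an integer index",
            )
        )
    return findings


def _stage(name: str, context: str):
    """Decorator-free stage wrapper used inline below."""

    class _Ctx:
        def __enter__(self):
            log.info("stage=%s %s", name, context)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, context, exc) from exc
            return False

    return _Ctx()


def _acquire(cfg: RunConfig) -> tuple[list[SliceImage], list[float]]:
    if cfg.input == "simulate":
        return simulate_stack(cfg.phantom, cfg.model), list(cfg.phantom.times)
    images, times = read_stack(cfg.input)
    return images, times


def _default_ray(img: SliceImage) -> tuple[tuple[float, float], tuple[float, float]]:
    ny, nx = img.pixels.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    return (0.0, cy), (cx, cy)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis described in the module docstring."""
    findings = validate_config(cfg)
    if findings:
        raise ConfigError(
            "; ".join(f"[{f.code}] {f.message}" for f in findings)
        )

    with _stage("acquire", f"input={cfg.input}"):
        images, times = _acquire(cfg)
        if len(images) < MIN_TIMEPOINTS:
            raise ValueError(
                f"stack has {len(images)} timepoints; at least "
                f"{MIN_TIMEPOINTS} (including t = 0) are required to fit "
                "the 3-parameter saturation curve"
            )
        if abs(times[0]) > 1e-9:
            raise ValueError("first timepoint must be the unstained t = 0 scan")

    start, end = cfg.ray_start, cfg.ray_end
    if start is None or end is None:
        if cfg.input != "simulate":
            raise ConfigError("ray_start and ray_end are required for loaded stacks")
        start, end = _default_ray(images[0])

    with _stage("extract", f"ray {start} -> {end}, width {cfg.width_px}px"):
        profiles = [
            extract_line_profile(im, start, end, cfg.width_px) for im in images
        ]

    ref = len(images) - 1 if cfg.reference_timepoint == "last" else int(cfg.reference_timepoint)
    with _stage("edge", f"reference timepoint index {ref} (t={times[ref]} h)"):
        edge = detect_epicardial_edge(profiles[ref], cfg.sigma_px, cfg.drop_fraction)

    with _stage("discretize", f"{cfg.n_segments} x {cfg.seg_len_mm} mm segments"):
        rows = []
        for t, prof in zip(times, profiles):
            for seg in discretize_profile(prof, edge, cfg.seg_len_mm, cfg.n_segments):
                rows.append((seg.depth, t, seg.mean_intensity, seg.n_samples))
        grid = pd.DataFrame(
            rows, columns=["depth_mm", "time_h", "intensity", "n_samples"]
        )

    with _stage("fit", f"{cfg.n_segments} depth series"):
        fits = []
        for depth, sub in grid.groupby("depth_mm", sort=True):
            sub = sub.sort_values("time_h")
            series = IntensityTimeSeries(
                depth=float(depth),
                times=sub["time_h"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
            )
            fits.append(fit_saturation_curve(series))
        fits = tuple(fits)

    with _stage("saturation_table", f"levels {list(cfg.levels)}"):
        table = build_saturation_table(fits, cfg.levels)

    with _stage("model", "log-linear depth-time fit per level"):
        models = tabulate_models(table)

    provenance = {
        "package": "stainkinetics",
        "version": __version__,
        "config": json.loads(cfg.canonical_json()),
        "config_sha256": cfg.config_hash(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "n_timepoints": len(images),
        "reference_timepoint_index": ref,
        "edge_position_mm": edge.edge_position,
        "skipped_depths_mm": list(table.skipped_depths),
        "unfittable_levels": [
            {"level": lvl, "reason": msg} for lvl, msg in models.unfittable
        ],
    }

    artifacts: dict = {}
    if cfg.output_dir is not None:
        with _stage("write", f"output_dir={cfg.output_dir}"):
            artifacts = _write_artifacts(
                Path(cfg.output_dir), times, profiles, grid, fits, table, models, provenance
            )

    return RunReport(
        fits=fits,
        table=table,
        models=models,
        edge_position_mm=edge.edge_position,
        provenance=provenance,
        artifacts=artifacts,
    )


_CSV_KW = {"index": False, "float_format": "%.10g", "lineterminator": "\n"}


def _write_artifacts(outdir, times, profiles, grid, fits, table, models, provenance):
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    prof_rows = [
        (t, pos, inten)
        for t, prof in zip(times, profiles)
        for pos, inten in zip(prof.positions, prof.intensities)
    ]
    pd.DataFrame(prof_rows, columns=["time_h", "position_mm", "intensity"]).to_csv(
        outdir / "profile.csv", **_CSV_KW
    )
    paths["profile"] = str(outdir / "profile.csv")

    grid.to_csv(outdir / "grid.csv", **_CSV_KW)
    paths["grid"] = str(outdir / "grid.csv")

    pd.DataFrame(
        [
            (f.depth, f.I0, f.Imax, f.tau, f.rss, f.converged, f.degenerate)
            for f in fits
        ],
        columns=["depth_mm", "I0", "Imax", "tau_h", "rss", "converged", "degenerate"],
    ).to_csv(outdir / "fits.csv", **_CSV_KW)
    paths["fits"] = str(outdir / "fits.csv")

    pd.DataFrame(
        [(e.level, e.depth, e.time) for e in table.entries],
        columns=["level", "depth_mm", "T_h"],
    ).to_csv(outdir / "saturation_times.csv", **_CSV_KW)
    paths["saturation_times"] = str(outdir / "saturation_times.csv")

    pd.DataFrame(
        [(m.level, m.A, m.B, m.r_squared_log, m.n_points) for m in models],
        columns=["level", "A_hours", "B_per_mm", "r_squared_log", "n_points"],
    ).to_csv(outdir / "coefficients.csv", **_CSV_KW)
    paths["coefficients"] = str(outdir / "coefficients.csv")

    report = dict(provenance)
    report["coefficients"] = [
        {"level": m.level, "A_hours": m.A, "B_per_mm": m.B, "r_squared_log": m.r_squared_log}
        for m in models
    ]
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    paths["report"] = str(outdir / "report.json")
    return paths
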