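"""Exponential staining-time-versus-depth model and staining planning.

The required staining time T to reach a given saturation level grows
exponentially with transmural depth d:

    T(d) = A * exp(B * d),

with A the time at the tissue surface (hours) and B the exponential rate
(per mm).  On a semi-logarithmic plot this is a straight line, so the
coefficients are fitted by ordinary least squares of ln T on d, which is
exactly invertible on noiseless data.  Reference coefficients fitted to
mouse ventricular wall at 90 / 95 / 99 % saturation ship with the
package and back the staining-time calculator.
"""

from __future__ import annotations

import csv
import dataclasses
import importlib.resources
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .kinetics import SaturationTimeTable

__all__ = [
    "StainTimeModel",
    "StainPlan",
    "TabulationResult",
    "fit_staining_time_model",
    "required_staining_time",
    "plan_staining",
    "tabulate_models",
    "mouse_heart_models",
]


@dataclasses.dataclass(frozen=True)
class StainTimeModel:
    """Coefficients of T(d) = A * exp(B * d) at one saturation level.

    ``r_squared_log`` is the coefficient of determination of the
    log-linear fit; it is ``None`` for reference coefficient sets whose
    fit diagnostics are not available.
    """

    level: float  # saturation fraction in (0, 1)
    A: float  # h, time at zero depth
    B: float  # per mm
    n_points: int | None = None
    r_squared_log: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.n_points is not None and self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.r_squared_log is not None and not (
            -1e-12 <= self.r_squared_log <= 1 + 1e-12
        ):
            raise ValueError("r_squared_log must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class StainPlan:
    """Recommended staining time for a sample of given thickness.

    Dual-sided staining exposes both surfaces simultaneously, halving
    the maximum diffusion distance: the effective depth is
    ``thickness / 2`` instead of ``thickness``.
    """

    thickness: float  # mm
    level: float
    dual_sided: bool
    effective_depth: float  # mm
    recommended_time: float  # h


def fit_staining_time_model(
    entries: Sequence[tuple[float, float]], level: float
) -> StainTimeModel:
    """Fit T(d) = A * exp(B * d) by OLS of ln T on d.

    ``entries`` are (depth mm, time h) pairs; all times must be positive
    and at least two distinct depths are required.
    """
    if len(entries) < 2:
        raise ValueError(f"need >= 2 (depth, time) points, got {len(entries)}")
    d = np.asarray([e[0] for e in entries], dtype=float)
    T = np.asarray([e[1] for e in entries], dtype=float)
    if np.any(T <= 0):
        raise ValueError("all staining times must be positive for a log-linear fit")
    if np.ptp(d) == 0:
        raise ValueError("all depths identical; exponential rate is unidentifiable")
    res = stats.linregress(d, np.log(T))
    r2 = float(res.rvalue**2)
    return StainTimeModel(
        level=float(level),
        A=float(math.exp(res.intercept)),
        B=float(res.slope),
        n_points=len(entries),
        r_squared_log=min(max(r2, 0.0), 1.0),
    )


def required_staining_time(m: StainTimeModel, d: float) -> float:
    """Required staining time T = A * exp(B * d) at depth ``d`` mm."""
    if d < 0:
        raise ValueError("depth must be non-negative")
    return float(m.A * math.exp(m.B * d))


def plan_staining(
    m: StainTimeModel, thickness: float, dual_sided: bool = False
) -> StainPlan:
    """Recommend a staining time for a sample of given thickness (mm).

    Single-sided staining must carry stain through the full thickness;
    dual-sided staining halves the maximum diffusion distance.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    effective = thickness / 2.0 if dual_sided else thickness
    return StainPlan(
        thickness=float(thickness),
        level=m.level,
        dual_sided=dual_sided,
        effective_depth=effective,
        recommended_time=required_staining_time(m, effective),
    )


@dataclasses.dataclass(frozen=True)
class TabulationResult:
    """Per-level depth-time models plus any levels that could not be fitted."""

    models: tuple[StainTimeModel, ...]
    unfittable: tuple[tuple[float, str], ...] = ()

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)

    def for_level(self, level: float) -> StainTimeModel:
        for m in self.models:
            if m.level == level:
                return m
        raise KeyError(f"no fitted model at level {level}")


def tabulate_models(table: SaturationTimeTable) -> TabulationResult:
    """Fit one depth-time model per saturation level of a table.

    A level that cannot be fitted (e.g. a single depth) is reported in
    ``unfittable`` with the reason; the remaining levels are still
    returned.  Raises only if no level at all can be fitted.
    """
    models: list[StainTimeModel] = []
    unfittable: list[tuple[float, str]] = []
    for level in table.levels:
        pairs = table.for_level(level)
        try:
            models.append(fit_staining_time_model(pairs, level))
        except ValueError as exc:
            unfittable.append((level, str(exc)))
    if not models:
        raise ValueError(
            "no saturation level could be fitted: "
            + "; ".join(f"{lvl:g}: {msg}" for lvl, msg in unfittable)
        )
    return TabulationResult(models=tuple(models), unfittable=tuple(unfittable))


def mouse_heart_models() -> dict[float, StainTimeModel]:
    """Reference coefficients for I2KI staining of mouse ventricular wall.

    Returns one model per saturation level (0.90, 0.95, 0.99), loaded
    from the packaged coefficient table (level, A hours, B per mm).
    """
    path = importlib.resources.files("stainkinetics") / "data" / "mouse_heart_coefficients.csv"
    models: dict[float, StainTimeModel] = {}
    with path.open() as fh:
        for row in csv.DictReader(fh):
            level = float(row["level"])
            models[level] = StainTimeModel(
                level=level, A=float(row["A_hours"]), B=float(row["B_per_mm"])
            )
    return models
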