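"""Exponential saturation-curve fitting of depth-resolved intensity series.

Each depth segment's intensity over staining time is modelled as an
exponential approach to a ceiling,

    I(t) = Imax - (Imax - I0) * exp(-t / tau),

where I0 is the unstained intensity, Imax the saturated intensity at
that depth and tau the time constant.  The fit minimises the residual
sum of squares with a derivative-free simplex (Nelder–Mead), and the
time for the tissue to reach a saturation ratio I/Imax = s follows in
closed form.  Using the ratio I/Imax rather than absolute intensity
removes the depth-dependent ceiling bias introduced by beam hardening.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "IntensityTimeSeries",
    "SaturationCurveFit",
    "SaturationTimeEntry",
    "SaturationTimeTable",
    "DegenerateFitError",
    "AllFitsDegenerateError",
    "fit_saturation_curve",
    "time_to_saturation",
    "build_saturation_table",
]

DEFAULT_LEVELS = (0.90, 0.95, 0.99)


class DegenerateFitError(ValueError):
    """Operation requires a non-degenerate (non-flat) saturation fit."""


class AllFitsDegenerateError(ValueError):
    """Every supplied fit was degenerate; no saturation table can be built."""


@dataclasses.dataclass(frozen=True)
class IntensityTimeSeries:
    """Segment intensity versus staining time at one transmural depth."""

    depth: float  # mm
    times: np.ndarray  # h, strictly increasing, starting at 0
    intensities: np.ndarray  # counts

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("times and intensities must be 1-D and equal length")
        if len(t) < 4:
            raise ValueError(
                f"need at least 4 timepoints to fit 3 parameters, got {len(t)}"
            )
        if abs(t[0]) > 1e-9:
            raise ValueError("times must start at 0 h")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


@dataclasses.dataclass(frozen=True)
class SaturationCurveFit:
    """Fitted parameters of the saturation curve at one depth."""

    depth: float  # mm
    I0: float  # counts
    Imax: float  # counts
    tau: float  # h (nan when degenerate)
    rss: float  # squared counts
    converged: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")
        if not self.degenerate:
            if not self.Imax > self.I0:
                raise ValueError("non-degenerate fit requires Imax > I0")
            if not self.tau > 0:
                raise ValueError("non-degenerate fit requires tau > 0")

    def predict(self, t):
        """Fitted intensity at staining time(s) ``t`` hours."""
        if self.degenerate:
            return np.full_like(np.asarray(t, dtype=float), self.I0)
        return self.Imax - (self.Imax - self.I0) * np.exp(
            -np.asarray(t, dtype=float) / self.tau
        )


@dataclasses.dataclass(frozen=True)
class SaturationTimeEntry:
    depth: float  # mm
    level: float  # saturation fraction
    time: float  # h


@dataclasses.dataclass(frozen=True)
class SaturationTimeTable:
    """Required staining time per (depth, saturation level)."""

    levels: tuple[float, ...]
    entries: tuple[SaturationTimeEntry, ...]
    skipped_depths: tuple[float, ...] = ()

    def for_level(self, level: float) -> list[tuple[float, float]]:
        """(depth, time) pairs at one saturation level, ordered by depth."""
        pairs = [(e.depth, e.time) for e in self.entries if e.level == level]
        return sorted(pairs)


def _rss(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    i0, log_span, log_tau = theta
    span = math.exp(min(log_span, 700.0))
    tau = math.exp(min(log_tau, 700.0))
    resid = (i0 + span * (1.0 - np.exp(-t / tau))) - y
    return float(resid @ resid)


def _simplex(theta0: np.ndarray, t: np.ndarray, y: np.ndarray):
    scale = max(1.0, float(np.mean(np.abs(y))))
    return optimize.minimize(
        _rss,
        theta0,
        args=(t, y),
        method="Nelder-Mead",
        options={
            "xatol": 1e-10,
            "fatol": 1e-10 * scale**2,
            "maxiter": 20000,
            "maxfev": 20000,
        },
    )


def fit_saturation_curve(
    s: IntensityTimeSeries,
    init: tuple[float, float, float] | None = None,
) -> SaturationCurveFit:
    """Least-squares fit of the saturation curve to one depth's time series.

    Optimisation is derivative-free simplex on (I0, log(Imax - I0),
    log tau); the log parameterisation keeps the simplex out of
    non-physical regions (Imax <= I0 or tau <= 0) without constraints.
    Initialisation: I0 from the first sample, Imax from the last
    (inflated by 5 % when the series is non-increasing) and tau at a
    third of the time span.  The solution is polished by a second
    simplex run, and restarted once from a perturbed start if the first
    attempt fails to converge.  A series whose intensity range is below
    1e-6 of its mean magnitude is flagged degenerate and returned with
    I0 = Imax = mean and tau unset.

    ``init`` optionally overrides the default initialisation with
    explicit (I0, Imax, tau) starting values; refitting from a fitted
    solution is a fixed point of the optimiser.
    """
    t = s.times
    y = s.intensities
    mean = float(y.mean())
    if float(np.ptp(y)) < 1e-6 * max(abs(mean), 1e-300):
        resid = y - mean
        return SaturationCurveFit(
            depth=s.depth,
            I0=mean,
            Imax=mean,
            tau=float("nan"),
            rss=float(resid @ resid),
            converged=True,
            degenerate=True,
        )

    if init is not None:
        i0_init, imax_init, tau_init = (float(v) for v in init)
        if imax_init <= i0_init or tau_init <= 0:
            raise ValueError("init requires Imax > I0 and tau > 0")
    else:
        i0_init = float(y[0])
        imax_init = float(y[-1])
        if imax_init <= i0_init:
            imax_init = i0_init * 1.05 if i0_init > 0 else i0_init + float(np.ptp(y))
        tau_init = (float(t[-1]) - float(t[0])) / 3.0
    span_init = max(imax_init - i0_init, 1e-9 * max(abs(mean), 1.0))
    theta0 = np.array([i0_init, math.log(span_init), math.log(tau_init)])

    res = _simplex(theta0, t, y)
    if not res.success:
        res_retry = _simplex(theta0 * 1.1 + 0.1, t, y)
        if res_retry.fun < res.fun:
            res = res_retry
    # polish: refit from the solution so the result is a simplex fixed point
    res2 = _simplex(res.x, t, y)
    if res2.fun <= res.fun:
        res = res2

    i0, log_span, log_tau = res.x
    return SaturationCurveFit(
        depth=s.depth,
        I0=float(i0),
        Imax=float(i0 + math.exp(log_span)),
        tau=float(math.exp(log_tau)),
        rss=float(res.fun),
        converged=bool(res.success),
    )


def time_to_saturation(f: SaturationCurveFit, s: float) -> float:
    """Staining time at which the fitted curve reaches I/Imax = s.

    Closed form from the saturation model:
    T = tau * ln((Imax - I0) / ((1 - s) * Imax)), clamped to 0 when the
    unstained intensity already satisfies I0 >= s * Imax.
    """
    if f.degenerate:
        raise DegenerateFitError(
            f"cannot compute saturation time for degenerate fit at depth {f.depth} mm"
        )
    if not (0.0 < s < 1.0):
        raise ValueError("saturation level must lie in (0, 1)")
    if (1.0 - s) * f.Imax <= 0:
        raise ValueError("fit has non-positive Imax; saturation ratio undefined")
    if f.I0 >= s * f.Imax:
        return 0.0
    return float(f.tau * math.log((f.Imax - f.I0) / ((1.0 - s) * f.Imax)))


def build_saturation_table(
    fits: Sequence[SaturationCurveFit],
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> SaturationTimeTable:
    """Tabulate time-to-saturation for each (non-degenerate depth, level).

    Degenerate depths are skipped and reported in ``skipped_depths``.
    """
    levels = tuple(float(s) for s in levels)
    for s in levels:
        if not (0.0 < s < 1.0):
            raise ValueError(f"saturation level {s} outside (0, 1)")
    good = [f for f in fits if not f.degenerate]
    skipped = tuple(f.depth for f in fits if f.degenerate)
    if not good:
        raise AllFitsDegenerateError(
            "all fits are degenerate; no saturation table can be built"
        )
    entries = tuple(
        SaturationTimeEntry(depth=f.depth, level=s, time=time_to_saturation(f, s))
        for s in levels
        for f in sorted(good, key=lambda f: f.depth)
    )
    return SaturationTimeTable(levels=levels, entries=entries, skipped_depths=skipped)
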