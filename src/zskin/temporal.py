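"""Parameter trajectories over a session and trends across a cohort.

Each time point of a session is fitted independently (no warm
starting, so errors at consecutive sweeps stay uncorrelated), the
fitted parameters are strung into per-parameter trajectories, cohorts
are summarized by the pointwise median across subjects, and each
trajectory is classified as increasing / decreasing / flat from the
sign of a least-squares slope with a relative-change floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .circuits import CircuitModel
from .errors import ValidationError
from .fitting import FitConfig, FitResult, fit_multistart
from .spectra import SessionSeries

__all__ = [
    "ParameterTrajectory",
    "CohortTrend",
    "fit_session",
    "cohort_median",
    "classify_trend",
    "cohort_trends",
]


@dataclass
class ParameterTrajectory:
    """One fitted parameter followed across the time points of a session."""

    parameter: str
    times: np.ndarray
    values: np.ndarray
    subject: str | None = None
    electrode_type: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValidationError("trajectory times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")


@dataclass
class CohortTrend:
    """Median-across-subjects trajectory of one parameter, with its trend call."""

    electrode_type: str
    parameter: str
    times: np.ndarray
    median_values: np.ndarray
    trend: str                      # "increasing" | "decreasing" | "flat"
    relative_change: float          # first -> last, on the least-squares line
    n_subjects: int = 1


def fit_session(
    series: SessionSeries,
    m: CircuitModel,
    cfg: FitConfig | None = None,
) -> tuple[list[FitResult | None], dict[str, ParameterTrajectory]]:
    """Independent multi-start fit at every time point of a session.

    A time point whose fit fails is recorded as ``None`` in the result
    list and simply missing from the trajectories; it does not abort
    the session.  Requires at least two time points.
    """
    if len(series) < 2:
        raise ValidationError("fit_session needs a session with >= 2 time points")
    cfg = cfg or FitConfig()
    results: list[FitResult | None] = []
    for s in series:
        try:
            results.append(fit_multistart(s, m, cfg))
        except Exception:
            results.append(None)
    times = series.times
    trajectories: dict[str, ParameterTrajectory] = {}
    for name in m.parameter_names:
        ok = [(t, r.parameters.values[name]) for t, r in zip(times, results) if r is not None]
        if len(ok) >= 2:
            t_ok, v_ok = zip(*ok)
            trajectories[name] = ParameterTrajectory(
                parameter=name,
                times=np.array(t_ok),
                values=np.array(v_ok),
                subject=series.subject,
                electrode_type=series.electrode_type,
            )
    return results, trajectories


def cohort_median(trajectories: Sequence[ParameterTrajectory]) -> ParameterTrajectory:
    """Pointwise median across subjects of aligned same-parameter trajectories."""
    if not trajectories:
        raise ValidationError("cohort_median needs at least one trajectory")
    first = trajectories[0]
    for t in trajectories[1:]:
        if t.parameter != first.parameter:
            raise ValidationError(
                f"mixed parameters in cohort: {t.parameter!r} vs {first.parameter!r}"
            )
        if t.times.size != first.times.size or not np.allclose(t.times, first.times):
            raise ValidationError("subject trajectories are not on aligned time grids")
    stacked = np.vstack([t.values for t in trajectories])
    return ParameterTrajectory(
        parameter=first.parameter,
        times=first.times.copy(),
        values=np.median(stacked, axis=0),
        subject="median",
        electrode_type=first.electrode_type,
    )


def classify_trend(
    t: ParameterTrajectory, flat_threshold: float = 0.05
) -> tuple[str, float]:
    """Trend sign and relative change of a trajectory.

    Fits a least-squares line to (time, value); the relative change is
    the line's first-to-last excursion divided by its starting value.
    The trend is ``flat`` when |relative change| < ``flat_threshold``,
    otherwise the sign of the slope.
    """
    if t.times.size < 3:
        raise ValidationError("classify_trend needs >= 3 time points")
    slope, intercept = np.polyfit(t.times, t.values, 1)
    y0 = slope * t.times[0] + intercept
    y1 = slope * t.times[-1] + intercept
    rel = float((y1 - y0) / y0)
    if abs(rel) < flat_threshold:
        return "flat", rel
    return ("increasing" if slope > 0 else "decreasing"), rel


def cohort_trends(
    trajectories: Mapping[tuple[str, str], Mapping[str, ParameterTrajectory]],
    flat_threshold: float = 0.05,
) -> list[CohortTrend]:
    """Median trajectories and trend calls per (electrode type, parameter).

    ``trajectories`` is keyed ``(subject, electrode_type)`` as returned
    by running :func:`fit_session` over a cohort.
    """
    by_group: dict[tuple[str, str], list[ParameterTrajectory]] = {}
    for (_subject, etype), per_param in trajectories.items():
        for name, traj in per_param.items():
            by_group.setdefault((etype, name), []).append(traj)
    trends = []
    for (etype, name), trajs in sorted(by_group.items()):
        med = cohort_median(trajs)
        trend, rel = classify_trend(med, flat_threshold)
        trends.append(
            CohortTrend(
                electrode_type=etype,
                parameter=name,
                times=med.times,
                median_values=med.values,
                trend=trend,
                relative_change=rel,
                n_subjects=len(trajs),
            )
        )
    return trends
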