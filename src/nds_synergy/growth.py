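"""Growth quantification from OD600 time series.

Two scalar summaries of a background-subtracted growth curve are provided:

* ``augc`` — area under the growth curve (trapezoidal rule over a fixed
  window, by default 24 h of 15-min readings), in OD*hours. This is the
  default effectiveness measure.
* ``max_growth_rate`` — maximum slope of a five-point moving average of
  log(OD - background) versus time, per hour (natural log). An alternative
  measure that typically agrees with AUGC; not used by default.

A condition is called *effective* when its (replicate-aggregated) measure is
at or below a threshold t — e.g. a small fraction of the drug-free control
AUGC for "complete inhibition".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError


@dataclass
class GrowthCurve:
    """An OD600 time series for one well.

    ``times`` are minutes from inoculation (nondecreasing); ``od`` are the
    raw readings; ``background`` is subtracted before any quantification.
    If ``background`` is None it defaults to the first reading of the well.
    """

    times: np.ndarray
    od: np.ndarray
    plate: str = ""
    well: str = ""
    background: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and od must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) < 0):
            raise InvalidParameterError("times must be nondecreasing")

    def resolved_background(self) -> float:
        if self.background is not None:
            return float(self.background)
        if self.od.size == 0:
            raise InsufficientDataError("empty curve has no background")
        return float(self.od[0])


@dataclass(frozen=True)
class EffectivenessThreshold:
    """Effectiveness rule: a condition is effective when measure <= value."""

    measure: str  # "AUGC" | "max_growth_rate"
    value: float

    def __post_init__(self):
        if self.measure not in ("AUGC", "max_growth_rate"):
            raise InvalidParameterError(f"unknown measure {self.measure!r}")
        if not np.isfinite(self.value):
            raise InvalidParameterError("threshold value must be finite")


@dataclass
class EffectivenessTable:
    """Per-condition aggregated measures and boolean effectiveness calls.

    ``data`` has one row per condition with at least the columns
    ``subset`` (semicolon-joined drug names, empty for controls),
    ``step_index``, ``ratio``, ``measure_value``, ``effective`` and
    ``n_replicates``. The threshold and replicate rule that produced the
    calls are kept alongside for provenance.
    """

    data: pd.DataFrame
    threshold: EffectivenessThreshold
    replicate_rule: str = "mean"

    REQUIRED = ("subset", "step_index", "ratio", "measure_value", "effective", "n_replicates")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"effectiveness table missing columns: {missing}")


def augc(curve: GrowthCurve, window_hours: float = 24.0) -> float:
    """Area under (od - background) within [0, window_hours], in OD*hours.

    Trapezoidal rule on the actual timestamps; negative excursions below
    background are *not* clamped (clamping noise would bias the area
    upward). Needs at least two in-window points.
    """
    bg = curve.resolved_background()
    hours = curve.times / 60.0
    mask = (hours >= 0) & (hours <= window_hours)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 points within 0..{window_hours} h, found {int(mask.sum())}"
        )
    return float(np.trapezoid(curve.od[mask] - bg, hours[mask]))


def max_growth_rate(curve: GrowthCurve, window_hours: float = 24.0) -> float:
    """Maximum slope of a smoothed log-growth curve, per hour (natural log).

    log(od - background) is computed for points above background (others are
    excluded: the log is undefined there), smoothed with a centred moving
    average (symmetric windows of 1/3/5 points, so an exact exponential's
    log-slope is preserved), and the largest slope between consecutive
    smoothed points is returned.
    """
    bg = curve.resolved_background()
    hours = curve.times / 60.0
    mask = (hours >= 0) & (hours <= window_hours) & (curve.od > bg)
    t = hours[mask]
    y = np.log(curve.od[mask] - bg)
    n = t.size
    if n < 6:
        raise InsufficientDataError(f"need >= 6 usable points (od > background), found {n}")
    smoothed = np.empty(n)
    for i in range(n):
        hw = min(2, i, n - 1 - i)
        smoothed[i] = y[i - hw : i + hw + 1].mean()
    dt = np.diff(t)
    good = dt > 0
    if not np.any(good):
        raise InsufficientDataError("all timestamps coincide; no slope defined")
    slopes = np.diff(smoothed)[good] / dt[good]
    return float(slopes.max())


_AGGREGATORS = {
    "mean": lambda v: float(np.mean(v)),
    "all": lambda v: float(np.max(v)),  # effective iff every replicate <= t
    "any": lambda v: float(np.min(v)),  # effective iff some replicate <= t
}


def call_effectiveness(
    measures: Mapping[tuple, Sequence[float]] | pd.DataFrame,
    threshold: EffectivenessThreshold,
    replicate_rule: str = "mean",
) -> EffectivenessTable:
    """Aggregate replicate measures per condition and call effectiveness.

    Parameters
    ----------
    measures
        Either a DataFrame with columns ``subset``, ``step_index``,
        ``ratio``, ``measure_value`` (one row per replicate), or a mapping
        from ``(subset, step_index, ratio)`` keys to replicate value lists.
    threshold
        The effectiveness threshold t; comparison is inclusive
        (measure <= t is effective).
    replicate_rule : {"mean", "all", "any"}
        "mean" compares the replicate mean with t; "all" requires every
        replicate <= t; "any" requires at least one.
    """
    if replicate_rule not in _AGGREGATORS:
        raise InvalidParameterError(
            f"unknown replicate rule {replicate_rule!r}; expected one of {sorted(_AGGREGATORS)}"
        )
    agg = _AGGREGATORS[replicate_rule]
    if isinstance(measures, pd.DataFrame):
        df = measures
        rows = []
        for (subset, step, ratio), grp in df.groupby(
            ["subset", "step_index", "ratio"], dropna=False, sort=False
        ):
            vals = grp["measure_value"].to_numpy(dtype=float)
            if vals.size < 1:
                raise InsufficientDataError(f"condition {subset!r} step {step} has no replicates")
            rows.append((subset, step, ratio, agg(vals), agg(vals) <= threshold.value, vals.size))
    else:
        rows = []
        for (subset, step, ratio), vals in measures.items():
            vals = np.asarray(list(vals), dtype=float)
            if vals.size < 1:
                raise InsufficientDataError(f"condition {subset!r} step {step} has no replicates")
            rows.append((subset, step, ratio, agg(vals), agg(vals) <= threshold.value, vals.size))
    out = pd.DataFrame(
        rows,
        columns=["subset", "step_index", "ratio", "measure_value", "effective", "n_replicates"],
    )
    return EffectivenessTable(out, threshold, replicate_rule)


def control_threshold(
    control_measures: Sequence[float], fraction: float = 0.1, measure: str = "AUGC"
) -> EffectivenessThreshold:
    """Threshold t = fraction * mean drug-free control measure.

    The default fraction 0.1 operationalizes "complete inhibition" as growth
    at no more than 10% of the uninhibited control area.
    """
    vals = np.asarray(list(control_measures), dtype=float)
    if vals.size < 1:
        raise InsufficientDataError("no control measures supplied")
    if not (0 < fraction):
        raise InvalidParameterError("fraction must be positive")
    return EffectivenessThreshold(measure, float(fraction * vals.mean()))
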