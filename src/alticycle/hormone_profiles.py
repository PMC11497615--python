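"""Mean peak luteal progesterone and ovulation classification.

The cycle-level progesterone statistic is the *mean peak luteal P4*: the mean
daily concentration over the span of days ±2.5 days around the day of the
observed luteal peak, i.e. AUC(P4, x..y) / (y − x) with P4(t) defined by
linear interpolation of the observed every-other-day samples.  Averaging
around the *observed* peak, rather than a pre-specified cycle day, is robust
to inter-cycle variation in the timing of the luteal rise.

Ovulation is then ascribed by thresholding this statistic.  The threshold is
a mandatory configuration value with documented provenance — it is never
hard-coded, because published cut-offs are assay- and population-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycle_data import HormoneSeries

__all__ = [
    "MeanPeakResult",
    "ExtrapolationError",
    "EmptyWindowError",
    "DegenerateWindowError",
    "interpolate_p4",
    "windowed_mean_p4",
    "find_luteal_peak",
    "mean_peak_luteal_p4",
    "classify_ovulation",
]

PEAK_HALF_WIDTH_DAYS = 2.5  # the ±2.5 d window around the observed peak


class ExtrapolationError(ValueError):
    """Requested a value outside the observed span — no extrapolation, ever."""


class EmptyWindowError(ValueError):
    """No observed samples inside the requested search window."""


class DegenerateWindowError(ValueError):
    """Clipping left a zero-length averaging window."""


@dataclass(frozen=True)
class MeanPeakResult:
    """Mean peak luteal P4 with the window it was averaged over.

    ``coverage_fraction`` is the share of the nominal ±2.5 d window that the
    observed span actually covers; windows clipped at the edge of the series
    report coverage < 1 and are flagged unreliable below ``min_coverage``.
    """

    mpl_p4: float
    peak_day: float
    window_start: float
    window_end: float
    coverage_fraction: float
    reliable: bool = True


def _check_series(series: HormoneSeries) -> tuple[np.ndarray, np.ndarray]:
    if len(series) < 2:
        raise ValueError("need at least 2 samples for interpolation")
    return series.days, series.values


def interpolate_p4(series: HormoneSeries, t: float) -> float:
    """Piecewise-linear P4 at day ``t``; exact at sample days."""
    days, vals = _check_series(series)
    if t < days[0] or t > days[-1]:
        raise ExtrapolationError(
            f"t={t} outside observed span [{days[0]}, {days[-1]}]"
        )
    return float(np.interp(t, days, vals))


def windowed_mean_p4(series: HormoneSeries, x: float, y: float) -> float:
    """AUC of the linear interpolant over [x, y] divided by (y − x).

    Computed exactly by inserting interpolated knots at x and y and applying
    the trapezoid rule on the resulting node set.
    """
    days, vals = _check_series(series)
    if not x < y:
        raise DegenerateWindowError(f"window [{x}, {y}] has non-positive length")
    if x < days[0] or y > days[-1]:
        raise ExtrapolationError(
            f"window [{x}, {y}] outside observed span [{days[0]}, {days[-1]}]"
        )
    inner = days[(days > x) & (days < y)]
    knots = np.concatenate(([x], inner, [y]))
    kvals = np.interp(knots, days, vals)
    auc = np.trapezoid(kvals, knots)
    return float(auc / (y - x))


def find_luteal_peak(
    series: HormoneSeries, search_start: float, search_end: float
) -> float:
    """Day of the maximum observed sample within [search_start, search_end].

    Ties are broken by the earliest day (deterministic).
    """
    days, vals = _check_series(series)
    mask = (days >= search_start) & (days <= search_end)
    if not mask.any():
        raise EmptyWindowError(
            f"no samples in search window [{search_start}, {search_end}]"
        )
    d, v = days[mask], vals[mask]
    return float(d[int(np.argmax(v))])  # argmax returns the first maximum


def default_luteal_window(series: HormoneSeries) -> tuple[float, float]:
    """Default luteal search window: cycle midpoint to the last observed day.

    The midpoint boundary excludes the follicular/peri-ovulatory part of the
    cycle; the true follicular–luteal boundary is not observable from P4
    sampling alone, so the window is configurable.
    """
    days, _ = _check_series(series)
    length = series.cycle_length if series.cycle_length is not None else days[-1]
    return (float(length) / 2.0, float(days[-1]))


def mean_peak_luteal_p4(
    series: HormoneSeries,
    luteal_window: tuple[float, float] | None = None,
    half_width: float = PEAK_HALF_WIDTH_DAYS,
    min_coverage: float = 0.5,
) -> MeanPeakResult:
    """Mean P4 over ±``half_width`` days around the observed luteal peak.

    The averaging window is clipped (not rejected) where it exceeds the
    observed span — every-other-day sampling makes edge peaks common — and
    ``coverage_fraction`` records how much of the nominal window survived.
    Results with coverage below ``min_coverage`` are flagged unreliable.
    """
    days, _ = _check_series(series)
    if luteal_window is None:
        luteal_window = default_luteal_window(series)
    peak = find_luteal_peak(series, luteal_window[0], luteal_window[1])
    x_nom, y_nom = peak - half_width, peak + half_width
    x = max(x_nom, float(days[0]))
    y = min(y_nom, float(days[-1]))
    if not x < y:
        raise DegenerateWindowError(
            f"clipped window [{x}, {y}] around peak day {peak} has zero length"
        )
    coverage = (y - x) / (y_nom - x_nom)
    mpl = windowed_mean_p4(series, x, y)
    return MeanPeakResult(
        mpl_p4=mpl,
        peak_day=peak,
        window_start=x,
        window_end=y,
        coverage_fraction=float(coverage),
        reliable=bool(coverage >= min_coverage),
    )


def classify_ovulation(mpl_p4: float, threshold: float | None) -> int:
    """1 if ``mpl_p4 >= threshold`` (boundary counts as ovulatory), else 0."""
    if threshold is None:
        raise ValueError(
            "ovulation threshold is a mandatory config value (pmol/l); "
            "it has no default"
        )
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if not mpl_p4 >= 0:
        raise ValueError(f"mpl_p4 must be non-negative, got {mpl_p4}")
    return int(mpl_p4 >= threshold)
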