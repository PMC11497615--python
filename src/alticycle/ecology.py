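"""Season calendar, anaemia grading, winsorizing, standardization, body-fat score.

The agropastoral year on the Bolivian altiplano splits into *arduous* periods
(harvesting, days 1–91; planting, days 245–282 of a 366-day year) with high
workload, lower food availability and higher pathogen exposure, and *better*
periods (late harvest 92–136, winter 137–244, rainy growing season 283–366).
Arduous seasons total 129 days, better seasons 237.

Haemoglobin runs high at 3800 m as an adaptation to hypoxia, so anaemia
cut-offs are shifted upward: the altitude-adjusted anaemia threshold is
14.6 g/dl.  Severity bounds below it are shipped as configuration, applying
the same +2.6 g/dl altitude shift to the standard mild/moderate/severe bands
(an assumption, documented as such).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeasonCalendar",
    "AnaemiaCutoffs",
    "DEFAULT_CALENDAR",
    "DEFAULT_ANAEMIA_CUTOFFS",
    "assign_season",
    "season_day_totals",
    "classify_anaemia",
    "winsorize",
    "z_standardize",
    "body_fat_score",
]

ARDUOUS = "arduous"
BETTER = "better"


@dataclass(frozen=True)
class SeasonCalendar:
    """Inclusive day-of-year ranges partitioning a 366-day year into two labels."""

    arduous_ranges: tuple[tuple[int, int], ...] = ((1, 91), (245, 282))
    better_ranges: tuple[tuple[int, int], ...] = ((92, 136), (137, 244), (283, 366))
    year_length: int = 366

    def __post_init__(self):
        covered = np.zeros(self.year_length, dtype=int)
        for lo, hi in self.arduous_ranges + self.better_ranges:
            if not (1 <= lo <= hi <= self.year_length):
                raise ValueError(f"range ({lo}, {hi}) outside 1..{self.year_length}")
            covered[lo - 1 : hi] += 1
        if not (covered == 1).all():
            raise ValueError(
                "season ranges must partition the year: every day labelled exactly once"
            )

    def labels(self) -> np.ndarray:
        """Array of length year_length with the label of each day (1-based day i at [i-1])."""
        lab = np.empty(self.year_length, dtype=object)
        for lo, hi in self.arduous_ranges:
            lab[lo - 1 : hi] = ARDUOUS
        for lo, hi in self.better_ranges:
            lab[lo - 1 : hi] = BETTER
        return lab


DEFAULT_CALENDAR = SeasonCalendar()


@dataclass(frozen=True)
class AnaemiaCutoffs:
    """Altitude-adjusted haemoglobin cut-offs (g/dl).

    ``anaemia_threshold`` separates none from any anaemia; ``mild_lower`` and
    ``moderate_lower`` are the lower bounds of the mild and moderate grades
    (severe is everything below ``moderate_lower``).  Boundaries are inclusive
    on the lower side of each grade.
    """

    anaemia_threshold: float = 14.6
    mild_lower: float = 13.6
    moderate_lower: float = 10.6

    def __post_init__(self):
        if not self.moderate_lower < self.mild_lower < self.anaemia_threshold:
            raise ValueError(
                "cutoffs must satisfy moderate_lower < mild_lower < anaemia_threshold"
            )


DEFAULT_ANAEMIA_CUTOFFS = AnaemiaCutoffs()


def assign_season(day_of_year: int, cal: SeasonCalendar = DEFAULT_CALENDAR) -> str:
    """Label ('arduous' or 'better') of the unique range containing the day."""
    day = int(day_of_year)
    if not 1 <= day <= cal.year_length:
        raise ValueError(f"day_of_year must be in 1..{cal.year_length}, got {day}")
    for lo, hi in cal.arduous_ranges:
        if lo <= day <= hi:
            return ARDUOUS
    return BETTER


def season_day_totals(cal: SeasonCalendar = DEFAULT_CALENDAR) -> tuple[int, int]:
    """(arduous_days, better_days); sums to the year length."""
    arduous = sum(hi - lo + 1 for lo, hi in cal.arduous_ranges)
    return arduous, cal.year_length - arduous


def classify_anaemia(
    hb: float, cutoffs: AnaemiaCutoffs = DEFAULT_ANAEMIA_CUTOFFS
) -> str:
    """Grade haemoglobin as none / mild / moderate / severe anaemia."""
    if not hb > 0:
        raise ValueError(f"hb must be positive, got {hb}")
    if hb >= cutoffs.anaemia_threshold:
        return "none"
    if hb >= cutoffs.mild_lower:
        return "mild"
    if hb >= cutoffs.moderate_lower:
        return "moderate"
    return "severe"


def winsorize(
    values, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> tuple[np.ndarray, float, float]:
    """Cap values outside the [lo_pct, hi_pct] centiles to the centile values.

    Centiles use linear interpolation between order statistics (the "type 7"
    quantile convention).  Count and order are preserved; returns
    ``(capped, lo_cap, hi_cap)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.isfinite(v).all():
        raise ValueError("winsorize requires >= 2 finite values")
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError(f"need 0 <= lo_pct < hi_pct <= 100, got ({lo_pct}, {hi_pct})")
    lo_cap = float(np.percentile(v, lo_pct, method="linear"))
    hi_cap = float(np.percentile(v, hi_pct, method="linear"))
    return np.clip(v, lo_cap, hi_cap), lo_cap, hi_cap


def z_standardize(values, reference=None) -> np.ndarray:
    """(v − mean(reference)) / sd(reference), sample SD (n−1 denominator).

    ``reference`` defaults to ``values`` itself; standardizing a season
    stratum against the full analytic sample keeps effect sizes comparable
    across strata.
    """
    v = np.asarray(values, dtype=float)
    ref = v if reference is None else np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValueError("reference must have >= 2 values")
    sd = float(np.std(ref, ddof=1))
    if not sd > 0:
        raise ValueError("reference has zero standard deviation")
    return (v - float(np.mean(ref))) / sd


def body_fat_score(
    anthro, orient_column: int = 0
) -> tuple[np.ndarray, float]:
    """First principal component of column-standardized anthropometrics.

    A single retained component on standardized measurements is the
    deterministic near-equivalent of a one-factor analysis and captures the
    shared "energetic reserves" axis (weight, skinfolds, circumferences).
    Scores are sign-oriented so that ``orient_column`` (weight, by
    convention the first column) loads positively.  Returns
    ``(scores, variance_explained)`` where variance_explained is the leading
    eigenvalue share of the correlation matrix.
    """
    X = np.asarray(anthro, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3 or X.shape[0] < 5:
        raise ValueError("need a matrix with >= 5 rows and >= 3 columns")
    if not np.isfinite(X).all():
        raise ValueError("anthropometrics must be complete; impute first")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant column(s) at {np.flatnonzero(sd == 0).tolist()}")
    Z = (X - X.mean(axis=0)) / sd
    # SVD of the standardized matrix <=> eigen-decomposition of the correlation matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[0]
    if loadings[orient_column] < 0:
        loadings = -loadings
    scores = Z @ loadings
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return scores, var_explained
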