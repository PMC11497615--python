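"""Data model, CSV ingest/egress and validation for the woman / cycle / sample hierarchy.

The unit of analysis is a menstrual cycle.  Each cycle carries one haemoglobin
measurement (g/dl, with its day of year), socio-demographic covariates, and an
every-other-day salivary progesterone series (pmol/l).  On disk a dataset is a
pair of CSV files:

``cycles.csv``
    woman_id, cycle_index, hb, hb_day_of_year, age, breastfeeding,
    trad_econ, body_fat, cycle_length  (+ optional derived columns
    mpl_p4, ovulatory, season)

``p4_samples.csv``
    woman_id, cycle_index, day, p4_pmol_l

Missing covariates are empty cells on disk and ``NaN`` in memory — never
silent zeros, so that imputation can see the missingness.
Days-in-cycle are 1-based (day 1 = first day of menses); day-of-year is
1-based over a 366-day (leap) year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HormoneSample",
    "HormoneSeries",
    "CycleRecord",
    "Dataset",
    "SchemaError",
    "IntegrityError",
    "read_cycle_table",
    "write_cycle_table",
    "validate_dataset",
    "CYCLES_COLUMNS",
    "SAMPLES_COLUMNS",
]

CYCLES_COLUMNS = [
    "woman_id",
    "cycle_index",
    "hb",
    "hb_day_of_year",
    "age",
    "breastfeeding",
    "trad_econ",
    "body_fat",
    "cycle_length",
]
DERIVED_COLUMNS = ["mpl_p4", "ovulatory", "season"]
SAMPLES_COLUMNS = ["woman_id", "cycle_index", "day", "p4_pmol_l"]


class SchemaError(ValueError):
    """A CSV is missing a mandatory column or has an unusable layout."""


class IntegrityError(ValueError):
    """Keys violate the (woman_id, cycle_index) uniqueness contract."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class HormoneSample:
    """One salivary progesterone observation within a cycle."""

    day: float  # day in cycle, day 1 = first day of menses
    p4: float   # progesterone, pmol/l

    def __post_init__(self):
        if not (self.day >= 1):
            raise ValueError(f"sample day must be >= 1, got {self.day}")
        if not (np.isfinite(self.p4) and self.p4 >= 0):
            raise ValueError(f"p4 must be finite and >= 0, got {self.p4}")


@dataclass
class HormoneSeries:
    """An ordered, irregularly sampled progesterone time-series for one cycle.

    Sampling is nominally every other day; gaps of 1–4 days are tolerated.
    At least two samples are required for any interpolation.
    """

    samples: list[HormoneSample] = field(default_factory=list)
    cycle_length: int | None = None

    def __post_init__(self):
        days = [s.day for s in self.samples]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sample days must be strictly increasing")

    @property
    def days(self) -> np.ndarray:
        return np.asarray([s.day for s in self.samples], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.asarray([s.p4 for s in self.samples], dtype=float)

    def __len__(self) -> int:
        return len(self.samples)

    @classmethod
    def from_arrays(cls, days, p4, cycle_length=None) -> "HormoneSeries":
        samples = [HormoneSample(float(d), float(v)) for d, v in zip(days, p4)]
        return cls(samples=samples, cycle_length=cycle_length)


@dataclass
class CycleRecord:
    """One menstrual cycle: haemoglobin, covariates and the hormone series.

    ``trad_econ`` and ``body_fat`` may be missing (NaN).  The derived fields
    ``mpl_p4``, ``ovulatory`` and ``season`` are filled by the pipeline.
    """

    woman_id: str
    cycle_index: int
    hb: float
    hb_day_of_year: int
    age: float
    breastfeeding: int
    trad_econ: float = math.nan
    body_fat: float = math.nan
    series: HormoneSeries = field(default_factory=HormoneSeries)
    mpl_p4: float | None = None
    ovulatory: int | None = None
    season: str | None = None

    def __post_init__(self):
        # NaN hb means "not measured" and is left for validate_dataset to flag
        if not _is_missing(self.hb) and not self.hb > 0:
            raise ValueError(f"hb must be positive, got {self.hb}")
        if not 1 <= self.hb_day_of_year <= 366:
            raise ValueError(
                f"hb_day_of_year must be in 1..366, got {self.hb_day_of_year}"
            )
        if not 20 <= self.age <= 40:
            warnings.warn(
                f"age {self.age} outside the 20-40 range typical of study-like data",
                stacklevel=2,
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.woman_id, int(self.cycle_index))


@dataclass
class Dataset:
    """A collection of cycle records with unique (woman_id, cycle_index) keys."""

    records: list[CycleRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise IntegrityError(f"duplicate (woman_id, cycle_index) keys: {dupes}")
        counts = pd.Series([r.woman_id for r in self.records]).value_counts()
        if len(counts) and (counts > 3).any():
            many = sorted(counts[counts > 3].index.tolist())
            warnings.warn(
                f"women with more than 3 cycles (unusual for study-like data): {many}",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_women(self) -> int:
        return len({r.woman_id for r in self.records})

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (cycles, samples) DataFrames mirroring the CSV schemas."""
        cyc_rows, samp_rows = [], []
        for r in self.records:
            cyc_rows.append(
                {
                    "woman_id": r.woman_id,
                    "cycle_index": r.cycle_index,
                    "hb": r.hb,
                    "hb_day_of_year": r.hb_day_of_year,
                    "age": r.age,
                    "breastfeeding": r.breastfeeding,
                    "trad_econ": r.trad_econ,
                    "body_fat": r.body_fat,
                    "cycle_length": r.series.cycle_length,
                    "mpl_p4": math.nan if r.mpl_p4 is None else r.mpl_p4,
                    "ovulatory": math.nan if r.ovulatory is None else r.ovulatory,
                    "season": r.season,
                }
            )
            for s in r.series.samples:
                samp_rows.append(
                    {
                        "woman_id": r.woman_id,
                        "cycle_index": r.cycle_index,
                        "day": s.day,
                        "p4_pmol_l": s.p4,
                    }
                )
        cycles = pd.DataFrame(cyc_rows, columns=CYCLES_COLUMNS + DERIVED_COLUMNS)
        samples = pd.DataFrame(samp_rows, columns=SAMPLES_COLUMNS)
        return cycles, samples

    def copy(self) -> "Dataset":
        recs = [
            replace(
                r,
                series=HormoneSeries(list(r.series.samples), r.series.cycle_length),
            )
            for r in self.records
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return Dataset(records=recs, provenance=self.provenance)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_cycle_table(cycles_csv, samples_csv, provenance: str = "") -> Dataset:
    """Read a (cycles.csv, p4_samples.csv) pair into a :class:`Dataset`.

    Samples are attached to their cycles and sorted by day.  Empty cells in
    ``trad_econ`` / ``body_fat`` are preserved as NaN.  A missing mandatory
    column raises :class:`SchemaError`; duplicate keys raise
    :class:`IntegrityError`.
    """
    cycles = pd.read_csv(cycles_csv)
    samples = pd.read_csv(samples_csv)
    _require_columns(cycles, CYCLES_COLUMNS, cycles_csv)
    _require_columns(samples, SAMPLES_COLUMNS, samples_csv)

    if cycles.duplicated(subset=["woman_id", "cycle_index"]).any():
        dup = cycles[cycles.duplicated(subset=["woman_id", "cycle_index"], keep=False)]
        keys = sorted(set(map(tuple, dup[["woman_id", "cycle_index"]].values.tolist())))
        raise IntegrityError(f"{cycles_csv}: duplicate (woman_id, cycle_index): {keys}")

    samples = samples.sort_values(["woman_id", "cycle_index", "day"])
    grouped = {
        k: g for k, g in samples.groupby(["woman_id", "cycle_index"], sort=False)
    }

    records = []
    for row in cycles.itertuples(index=False):
        key = (str(row.woman_id), int(row.cycle_index))
        g = grouped.get(key)
        clen = None if _is_missing(row.cycle_length) else int(row.cycle_length)
        if g is not None:
            series = HormoneSeries.from_arrays(
                g["day"].to_numpy(), g["p4_pmol_l"].to_numpy(), cycle_length=clen
            )
        else:
            series = HormoneSeries(cycle_length=clen)
        rec = CycleRecord(
            woman_id=key[0],
            cycle_index=key[1],
            hb=float(row.hb),
            hb_day_of_year=int(row.hb_day_of_year),
            age=float(row.age),
            breastfeeding=int(row.breastfeeding),
            trad_econ=math.nan if _is_missing(row.trad_econ) else float(row.trad_econ),
            body_fat=math.nan if _is_missing(row.body_fat) else float(row.body_fat),
            series=series,
        )
        for col in DERIVED_COLUMNS:
            if hasattr(row, col):
                val = getattr(row, col)
                if not _is_missing(val):
                    if col == "season":
                        rec.season = str(val)
                    elif col == "ovulatory":
                        rec.ovulatory = int(val)
                    else:
                        rec.mpl_p4 = float(val)
        records.append(rec)
    return Dataset(records=records, provenance=provenance)


def write_cycle_table(ds: Dataset, cycles_csv, samples_csv) -> None:
    """Write ``ds`` as the two-file CSV layout; inverse of :func:`read_cycle_table`."""
    cycles, samples = ds.to_frames()
    cycles.to_csv(cycles_csv, index=False)
    samples.to_csv(samples_csv, index=False)


def validate_dataset(ds: Dataset) -> list[dict]:
    """Return machine-readable issue descriptions; never mutates the input.

    Issue kinds: ``missing_hb``, ``insufficient_series`` (fewer than 2
    samples), ``day_of_year_out_of_range``, ``irregular_sampling_gap``
    (inter-sample gap outside 1–4 days).
    """
    issues: list[dict] = []
    for r in ds.records:
        where = {"woman_id": r.woman_id, "cycle_index": r.cycle_index}
        if _is_missing(r.hb) or not r.hb > 0:
            issues.append({"kind": "missing_hb", **where})
        if len(r.series) < 2:
            issues.append(
                {"kind": "insufficient_series", "n_samples": len(r.series), **where}
            )
        if not 1 <= r.hb_day_of_year <= 366:
            issues.append(
                {
                    "kind": "day_of_year_out_of_range",
                    "day_of_year": r.hb_day_of_year,
                    **where,
                }
            )
        gaps = np.diff(r.series.days)
        bad = gaps[(gaps < 1) | (gaps > 4)]
        if bad.size:
            issues.append(
                {"kind": "irregular_sampling_gap", "gaps": bad.tolist(), **where}
            )
    return issues
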