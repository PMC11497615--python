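import math

import numpy as np
import pytest

from alticycle.cycle_data import CycleRecord, Dataset, HormoneSeries


def make_series(days, p4, cycle_length=None) -> HormoneSeries:
    return HormoneSeries.from_arrays(days, p4, cycle_length=cycle_length)


def make_record(woman_id="W001", cycle_index=1, hb=15.0, doy=50, age=30.0,
                breastfeeding=0, trad_econ=0.1, body_fat=-0.2, series=None,
                **derived) -> CycleRecord:
    if series is None:
        series = make_series([1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27],
                             [50, 52, 48, 51, 55, 60, 80, 120, 180, 230, 250, 200, 120, 70],
                             cycle_length=28)
    return CycleRecord(
        woman_id=woman_id, cycle_index=cycle_index, hb=hb, hb_day_of_year=doy,
        age=age, breastfeeding=breastfeeding, trad_econ=trad_econ,
        body_fat=body_fat, series=series, **derived,
    )


@pytest.fixture
def jagged_series():
    """8 irregular samples spanning days 5-23 with a luteal-like rise."""
    return make_series([5, 7, 9, 12, 14, 16, 19, 23],
                       [40, 55, 35, 80, 150, 240, 180, 60], cycle_length=28)


@pytest.fixture
def two_cycle_dataset():
    r1 = make_record("W001", 1, hb=14.2, doy=30, trad_econ=0.5)
    r2 = make_record("W002", 1, hb=16.1, doy=200, trad_econ=math.nan,
                     series=make_series([2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26],
                                        [45, 44, 50, 47, 52, 49, 51, 48, 46, 50, 47, 45, 44],
                                        cycle_length=27))
    return Dataset(records=[r1, r2], provenance="toy fixture")


def random_series(rng: np.random.Generator, n_min=6, n_max=14):
    n = int(rng.integers(n_min, n_max + 1))
    days = np.sort(rng.uniform(1, 28, n))
    while np.min(np.diff(days)) < 0.2:  # keep days distinct
        days = np.sort(rng.uniform(1, 28, n))
    vals = rng.uniform(5, 300, n)
    return make_series(days, vals)
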