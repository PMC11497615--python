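import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alticycle.ecology import (
    ARDUOUS,
    BETTER,
    DEFAULT_ANAEMIA_CUTOFFS,
    DEFAULT_CALENDAR,
    AnaemiaCutoffs,
    SeasonCalendar,
    assign_season,
    body_fat_score,
    classify_anaemia,
    season_day_totals,
    winsorize,
    z_standardize,
)


def random_two_label_calendar(rng):
    """Random contiguous partition of 1..366 into alternating labels."""
    n_cuts = int(rng.integers(1, 8))
    cuts = np.sort(rng.choice(np.arange(2, 366), size=n_cuts, replace=False))
    bounds = [1, *cuts.tolist(), 367]
    ranges = [(bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)]
    ard = tuple(r for i, r in enumerate(ranges) if i % 2 == 0)
    bet = tuple(r for i, r in enumerate(ranges) if i % 2 == 1)
    if not bet:  # ensure both labels exist
        return random_two_label_calendar(rng)
    return SeasonCalendar(arduous_ranges=ard, better_ranges=bet)


class TestSeasons:
    def test_calendar_day_labels(self):
        assert assign_season(1) == ARDUOUS       # early harvest
        assert assign_season(92) == BETTER       # late harvest
        assert assign_season(366) == BETTER      # rainy growing season
        assert assign_season(245) == ARDUOUS     # planting
        assert assign_season(282) == ARDUOUS
        assert assign_season(283) == BETTER

    def test_default_day_totals(self):
        assert season_day_totals(DEFAULT_CALENDAR) == (129, 237)

    def test_degenerate_all_better_calendar(self):
        cal = SeasonCalendar(arduous_ranges=(), better_ranges=((1, 366),))
        assert season_day_totals(cal) == (0, 366)

    def test_random_calendars_match_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cal = random_two_label_calendar(rng)
            brute = sum(assign_season(d, cal) == ARDUOUS for d in range(1, 367))
            a, b = season_day_totals(cal)
            assert (a, b) == (brute, 366 - brute)
            assert a + b == cal.year_length

    def test_day_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_season(0)
        with pytest.raises(ValueError):
            assign_season(367)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            SeasonCalendar(arduous_ranges=((1, 100),), better_ranges=((90, 366),))


class TestAnaemia:
    def test_above_cutoff_is_none(self):
        assert classify_anaemia(15.0) == "none"

    def test_boundary_inclusive(self):
        assert classify_anaemia(DEFAULT_ANAEMIA_CUTOFFS.anaemia_threshold) == "none"
        assert classify_anaemia(DEFAULT_ANAEMIA_CUTOFFS.mild_lower) == "mild"
        assert classify_anaemia(DEFAULT_ANAEMIA_CUTOFFS.moderate_lower) == "moderate"

    def test_grid_matches_chained_comparison_oracle(self):
        cut = AnaemiaCutoffs(anaemia_threshold=14.6, mild_lower=13.6, moderate_lower=10.6)

        def oracle(hb):
            return ("none" if hb >= 14.6 else
                    "mild" if 13.6 <= hb < 14.6 else
                    "moderate" if 10.6 <= hb < 13.6 else "severe")

        for hb in np.arange(5.0, 21.0, 0.05):
            assert classify_anaemia(float(hb), cut) == oracle(hb)

    def test_severity_monotone_in_hb(self):
        order = {"severe": 3, "moderate": 2, "mild": 1, "none": 0}
        grades = [order[classify_anaemia(h)] for h in np.arange(6, 20, 0.1)]
        assert all(a >= b for a, b in zip(grades, grades[1:]))

    def test_invalid_cutoff_ordering_rejected(self):
        with pytest.raises(ValueError):
            AnaemiaCutoffs(anaemia_threshold=12, mild_lower=13, moderate_lower=10)


class TestWinsorize:
    def test_values_inside_caps_unchanged(self):
        v = [14.0, 15.0, 15.5, 16.0, 14.8, 15.2, 15.1, 14.9, 15.3, 15.6,
             14.7, 15.4, 15.05, 14.95, 15.15, 15.25, 14.85, 15.35, 15.45, 15.0]
        capped, lo, hi = winsorize(v, 5, 95)
        inside = (np.asarray(v) >= lo) & (np.asarray(v) <= hi)
        assert np.all(capped[inside] == np.asarray(v)[inside])

    def test_centile_rule_on_1_to_100(self):
        v = np.arange(1.0, 101.0)
        capped, lo, hi = winsorize(v, 5, 95)
        # type-7 quantile of 1..100 at p: 1 + 99 p
        assert lo == pytest.approx(1 + 99 * 0.05)
        assert hi == pytest.approx(1 + 99 * 0.95)
        assert capped.min() == pytest.approx(lo) and capped.max() == pytest.approx(hi)

    def test_idempotent_and_shape_preserving(self):
        rng = np.random.default_rng(17)
        v = rng.normal(15, 2, 200)
        c1, lo, hi = winsorize(v)
        c2, _, _ = winsorize(c1)
        assert c1.shape == v.shape
        assert c1.min() >= v.min() and c1.max() <= v.max()
        # capping the capped sample moves nothing outside its own caps
        assert np.allclose(np.clip(c2, c1.min(), c1.max()), c2)

    def test_rejects_tiny_input(self):
        with pytest.raises(ValueError):
            winsorize([15.0])


class TestZStandardize:
    def test_self_standardization(self):
        rng = np.random.default_rng(19)
        z = z_standardize(rng.normal(10, 3, 50))
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1, rel=1e-12)

    def test_two_point_hand_value(self):
        z = z_standardize([14.0, 16.0])
        # sample SD of {14,16} is sqrt(2); (16-15)/sqrt(2) = 0.7071...
        assert z == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 10), b=st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        v = np.array([1.0, 2.5, 4.0, 8.0, 9.5])
        assert np.allclose(z_standardize(a * v + b), z_standardize(v), atol=1e-8)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            z_standardize([3.0, 3.0, 3.0])


class TestBodyFatScore:
    def test_perfectly_correlated_columns_explain_everything(self):
        rng = np.random.default_rng(23)
        w = rng.normal(60, 8, 30)
        X = np.column_stack([w, 2 * w + 5, -0.5 * w + 3])
        scores, var = body_fat_score(X)
        assert var == pytest.approx(1.0)
        assert np.corrcoef(scores, w)[0, 1] > 0.999  # weight loads positively

    def test_one_factor_recovery(self):
        rng = np.random.default_rng(29)
        f = rng.normal(0, 1, 200)
        loadings = np.array([0.9, 0.8, 0.85, 0.7, 0.75])
        X = np.outer(f, loadings) + rng.normal(0, 0.15, (200, 5))
        scores, var = body_fat_score(X)
        assert abs(np.corrcoef(scores, f)[0, 1]) > 0.95
        assert scores @ f > 0  # orientation follows the first (weight) column
        assert 0.5 < var <= 1.0

    def test_sign_flip_restores_orientation(self):
        rng = np.random.default_rng(31)
        f = rng.normal(0, 1, 50)
        X = np.outer(f, [1.0, 0.9, 0.8]) + rng.normal(0, 0.1, (50, 3))
        s1, _ = body_fat_score(X)
        s2, _ = body_fat_score(-X)
        assert np.allclose(np.abs(s1), np.abs(s2), atol=1e-8)
        # orientation rule: the column-1 variable loads positively either way
        assert np.corrcoef(s1, X[:, 0])[0, 1] > 0
        assert np.corrcoef(s2, -X[:, 0])[0, 1] > 0

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
        with pytest.raises(ValueError, match="constant"):
            body_fat_score(X)
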