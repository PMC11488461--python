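"""Daily measures, minute grid, cohort summaries, and the DST design."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import MS_PER_DAY, MS_PER_HOUR, MS_PER_MINUTE
from screenbouts.bouts import Bout
from screenbouts.errors import ContractViolationError
from screenbouts.measures import (
    DstDesign,
    cohort_daily_summary,
    daily_measures,
    dst_design,
    logodds_to_or,
    minute_grid,
    pointwise_logodds,
    split_at_midnight,
)

DAY0 = pd.Timestamp("1970-01-01", tz="UTC")


def hm(day, hours, minutes=0, seconds=0):
    return day * MS_PER_DAY + hours * MS_PER_HOUR + minutes * MS_PER_MINUTE + seconds * 1000


def all_valid(n_days, start=DAY0):
    idx = pd.date_range(start, periods=n_days, freq="D")
    return pd.Series(True, index=idx)


@st.composite
def bout_sets(draw, max_days=4):
    points = draw(
        st.lists(st.integers(0, max_days * MS_PER_DAY), min_size=2, max_size=40, unique=True)
    )
    points = sorted(points)
    return [Bout(a, b) for a, b in zip(points[::2], points[1::2])]


class TestSplitAtMidnight:
    def test_bout_crossing_midnight_splits_in_two(self):
        (first, second) = split_at_midnight([Bout(hm(0, 23, 50), hm(1, 0, 10))])
        assert (first.start_ms, first.end_ms) == (hm(0, 23, 50), hm(1, 0))
        assert (second.start_ms, second.end_ms) == (hm(1, 0), hm(1, 0, 10))

    def test_bout_within_one_day_unchanged(self):
        bouts = [Bout(hm(0, 10), hm(0, 11))]
        assert split_at_midnight(bouts) == bouts

    @settings(max_examples=100, derandomize=True)
    @given(bout_sets())
    def test_duration_conserved_exactly(self, bouts):
        split = split_at_midnight(bouts)
        assert sum(b.duration_ms for b in split) == sum(b.duration_ms for b in bouts)
        for b in split:
            assert b.start_ms // MS_PER_DAY == (b.end_ms - 1) // MS_PER_DAY


class TestDailyMeasures:
    def test_two_fragment_day(self):
        bouts = [Bout(hm(0, 10), hm(0, 10, 30)), Bout(hm(0, 20), hm(0, 20, 10))]
        (row,) = daily_measures(bouts, all_valid(1)).itertuples(index=False)
        assert row.total_on_minutes == 40
        assert row.on_bout_count == 2
        assert row.mean_on_bout_minutes == 20
        assert row.mean_off_bout_minutes == 570
        assert row.log_on_bout_count == pytest.approx(math.log(2))

    def test_single_fragment_day_has_no_off_bout(self):
        (row,) = daily_measures([Bout(hm(0, 9), hm(0, 9, 30))], all_valid(1)).itertuples(index=False)
        assert row.total_on_minutes == 30
        assert row.mean_on_bout_minutes == 30
        assert math.isnan(row.mean_off_bout_minutes)

    def test_log_count_of_55_bouts(self):
        bouts = [Bout(hm(0, 1) + i * 2 * MS_PER_MINUTE, hm(0, 1) + (2 * i + 1) * MS_PER_MINUTE) for i in range(55)]
        (row,) = daily_measures(bouts, all_valid(1)).itertuples(index=False)
        assert row.on_bout_count == 55
        assert row.log_on_bout_count == pytest.approx(4.007, abs=5e-4)

    def test_valid_day_without_bouts_counts_zero(self):
        (row,) = daily_measures([], all_valid(1)).itertuples(index=False)
        assert row.total_on_minutes == 0 and row.on_bout_count == 0
        assert math.isnan(row.log_on_bout_count)  # ln(0) stays undefined, no +1 offset

    def test_invalid_days_are_not_emitted(self):
        day_valid = pd.Series([True, False], index=pd.date_range(DAY0, periods=2, freq="D"))
        out = daily_measures([Bout(hm(1, 10), hm(1, 11))], day_valid)
        assert len(out) == 1 and out.iloc[0]["total_on_minutes"] == 0

    def test_unsplit_bout_rejected(self):
        with pytest.raises(ContractViolationError):
            daily_measures([Bout(hm(0, 23), hm(1, 1))], all_valid(2))

    @settings(max_examples=50, derandomize=True)
    @given(bout_sets())
    def test_conservation_and_mean_identity(self, bouts):
        split = split_at_midnight(bouts)
        table = daily_measures(split, all_valid(5))
        assert table["total_on_minutes"].sum() * MS_PER_MINUTE == pytest.approx(
            sum(b.duration_ms for b in split), abs=1e-6
        )
        with_bouts = table[table["on_bout_count"] >= 1]
        assert np.allclose(
            with_bouts["mean_on_bout_minutes"] * with_bouts["on_bout_count"],
            with_bouts["total_on_minutes"],
            atol=1e-9,
        )


class TestMinuteGrid:
    def test_partial_minute_overlap(self):
        grid = minute_grid([Bout(hm(0, 10, 0, 30), hm(0, 10, 2, 15))])
        by_minute = grid.set_index("minute")["on_seconds"]
        assert by_minute.loc[600] == 30
        assert by_minute.loc[601] == 60
        assert by_minute.loc[602] == 15
        assert grid["binary_on"].sum() == 3

    def test_no_bouts_is_all_zero(self):
        days = pd.date_range(DAY0, periods=1, freq="D")
        grid = minute_grid([], days=days)
        assert len(grid) == 1440 and grid["on_seconds"].sum() == 0

    @settings(max_examples=50, derandomize=True)
    @given(bout_sets())
    def test_seconds_conserved_and_consistent_with_daily(self, bouts):
        grid = minute_grid(bouts, days=pd.date_range(DAY0, periods=5, freq="D"))
        assert grid["on_seconds"].sum() == pytest.approx(sum(b.duration_s for b in bouts), abs=1e-6)
        per_day = grid.groupby("date")["on_seconds"].sum() / 60.0
        table = daily_measures(split_at_midnight(bouts), all_valid(5)).set_index("date")
        assert np.allclose(per_day.reindex(table.index), table["total_on_minutes"], atol=1e-9)

    def test_binary_on_iff_any_seconds(self):
        grid = minute_grid([Bout(hm(0, 1, 0, 59), hm(0, 1, 1))])  # 1-second bout
        assert ((grid["binary_on"] == 1) == (grid["on_seconds"] > 0)).all()
        assert grid["binary_on"].sum() == 1


class TestCohortSummary:
    def _measures(self, values_by_pid, n_days=10):
        frames = []
        for pid, value in values_by_pid.items():
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "date": pd.date_range("2021-01-01", periods=n_days, freq="D", tz="UTC"),
                        "total_on_minutes": value,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_constant_measure_gives_constant_percentiles(self):
        out = cohort_daily_summary(self._measures({"a": 100.0, "b": 100.0, "c": 100.0}), "total_on_minutes")
        assert np.allclose(out[["p10", "p25", "p50", "p75", "p90"]], 100.0)

    def test_single_participant_percentiles_coincide(self):
        out = cohort_daily_summary(self._measures({"a": 42.0}), "total_on_minutes")
        assert np.allclose(out[["p10", "p50", "p90"]].to_numpy(), 42.0)

    def test_step_change_crosses_midpoint_near_the_step(self):
        n = 30
        frames = []
        for pid in ("a", "b", "c"):
            vals = [0.0] * 15 + [100.0] * 15
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "date": pd.date_range("2021-01-01", periods=n, freq="D", tz="UTC"),
                        "total_on_minutes": vals,
                    }
                )
            )
        out = cohort_daily_summary(pd.concat(frames, ignore_index=True), "total_on_minutes")
        crossing = out.loc[out["p50"] >= 50, "rel_day"].iloc[0]
        assert abs(crossing - 15) <= 3


def design_from_counts(n0, k0, n1, k1, minute=0):
    """Design whose minute-`minute` proportions are k0/n0 (pre) and k1/n1 (post)."""
    matrix = np.zeros((n0 + n1, 1440), dtype=np.int8)
    matrix[:k0, minute] = 1
    matrix[n0 : n0 + k1, minute] = 1
    meta = pd.DataFrame(
        {
            "participant_id": "p",
            "date": pd.date_range("2021-03-01", periods=n0 + n1, freq="D", tz="UTC"),
            "post": [0] * n0 + [1] * n1,
        }
    )
    return DstDesign(matrix=matrix, meta=meta, window_days=14, transition_instant=0)


@pytest.fixture(scope="module")
def grid():
    bouts = [Bout(hm(d, 12), hm(d, 12, 30)) for d in range(40)]
    return minute_grid(bouts, participant_id="p")


class TestDstDesign:

    def test_window_membership_and_post_indicator(self, grid):
        transition = hm(20, 7)  # 07:00 UTC on day 20
        design = dst_design(grid, transition, window_days=14)
        days = design.meta["date"].values.astype("datetime64[D]").astype(int)
        assert 20 not in days  # transition day excluded
        assert days.min() == 6 and days.max() == 34
        assert (design.meta["post"] == (days > 20)).all()
        assert len(design.meta) <= 2 * 14

    def test_far_days_excluded(self, grid):
        design = dst_design(grid, hm(20, 7), window_days=7)
        days = design.meta["date"].values.astype("datetime64[D]").astype(int)
        assert days.min() == 13 and days.max() == 27

    def test_non_positive_window_rejected(self, grid):
        with pytest.raises(ContractViolationError):
            dst_design(grid, hm(20, 7), window_days=0)


class TestPointwiseLogodds:
    def test_identical_groups_give_zero(self):
        design = design_from_counts(50, 13, 50, 13)
        assert np.allclose(pointwise_logodds(design), 0.0)

    def test_reported_proportions_give_reported_logodds(self):
        # p0 = 0.26, p1 = 0.17 -> log[(0.17/0.83)/(0.26/0.74)] ~ -0.540
        design = design_from_counts(50, 13, 100, 17)
        assert pointwise_logodds(design)[0] == pytest.approx(-0.540, abs=1e-3)

    def test_antisymmetric_under_group_swap(self):
        design = design_from_counts(40, 10, 60, 30)
        swapped = DstDesign(
            matrix=design.matrix,
            meta=design.meta.assign(post=1 - design.meta["post"]),
            window_days=design.window_days,
            transition_instant=design.transition_instant,
        )
        assert np.allclose(pointwise_logodds(design), -pointwise_logodds(swapped))

    def test_continuity_correction_keeps_estimates_finite(self):
        design = design_from_counts(30, 0, 30, 30)
        est = pointwise_logodds(design)
        assert np.isfinite(est).all() and est[0] > 0

    def test_empty_group_rejected(self):
        design = design_from_counts(10, 2, 10, 3)
        bad = DstDesign(
            matrix=design.matrix,
            meta=design.meta.assign(post=0),
            window_days=14,
            transition_instant=0,
        )
        with pytest.raises(ContractViolationError):
            pointwise_logodds(bad)


class TestLogoddsToOr:
    @pytest.mark.parametrize("beta, expected", [(0.0, 1.0), (0.71, 2.034), (-1.13, 0.323)])
    def test_exponentiation(self, beta, expected):
        assert logodds_to_or(beta) == pytest.approx(expected, abs=1e-3)
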