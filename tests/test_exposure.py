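"""Exposure summaries: daily maxima, exceedance runs, bands, comparisons."""

import numpy as np
import pandas as pd
import pytest

from heatexposure import exposure as ex
from conftest import make_series


# ------------------------------------------------------------- oracles


def brute_force_daily_max(df, value_col):
    out = []
    sub = df.dropna(subset=[value_col]).sort_values("timestamp", kind="stable")
    for (unit, date), grp in sub.groupby(
        ["unit_id", sub["timestamp"].dt.date], sort=False
    ):
        best = None
        for _, row in grp.iterrows():
            if best is None or row[value_col] > best[value_col]:
                best = row  # strict > keeps the earliest of equal maxima
        out.append((unit, date, best[value_col], best["timestamp"]))
    return out


def brute_force_runs(df, threshold, max_gap_h, value_col="wbgt_c"):
    """Maximal-window enumeration: a window of observed records is a run
    iff every record is at/above threshold and consecutive records are at
    most max_gap hours apart, and it extends neither left nor right."""
    obs = df.dropna(subset=[value_col]).sort_values("timestamp")
    ts = list(obs["timestamp"])
    vals = list(obs[value_col])
    n = len(ts)
    gap = pd.Timedelta(hours=max_gap_h)

    def valid(i, j):
        for k in range(i, j + 1):
            if vals[k] < threshold:
                return False
        for k in range(i, j):
            if ts[k + 1] - ts[k] > gap:
                return False
        return True

    runs = []
    for i in range(n):
        for j in range(i, n):
            if (
                valid(i, j)
                and (i == 0 or not valid(i - 1, j))
                and (j == n - 1 or not valid(i, j + 1))
            ):
                n_bridged = sum(
                    1 for k in range(i, j) if ts[k + 1] - ts[k] > pd.Timedelta(hours=1)
                )
                runs.append(
                    (
                        ts[i],
                        ts[j],
                        (ts[j] - ts[i]) / pd.Timedelta(hours=1) + 1.0,
                        j - i + 1,
                        n_bridged,
                    )
                )
    return runs


def random_series(rng, n_hours=48, center=28.0):
    hours = np.arange(n_hours)
    keep = rng.random(n_hours) > 0.25  # random missingness
    vals = rng.normal(center, 2.0, n_hours)
    vals[rng.random(n_hours) < 0.05] = np.nan
    return make_series(hours[keep], vals[keep])


# ------------------------------------------------------------- daily max


class TestDailyMax:
    def test_tie_breaks_to_earliest_record(self):
        s = make_series([6, 13, 15], [29.1, 30.0, 30.0])
        out = ex.daily_max_tw(s)
        assert len(out) == 1
        assert out.loc[0, "value"] == 30.0
        assert out.loc[0, "at"].hour == 13

    def test_single_record_day(self):
        s = make_series([9], [27.3])
        out = ex.daily_max_tw(s)
        assert out.loc[0, "value"] == 27.3 and out.loc[0, "at"].hour == 9

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            s = random_series(rng, n_hours=rng.integers(12, 96))
            got = ex.daily_max_tw(s, value_col="tw_c")
            want = brute_force_daily_max(s, "tw_c")
            assert len(got) == len(want)
            for row, (unit, date, val, at) in zip(got.itertuples(), want):
                assert row.unit_id == unit and row.date == date
                assert row.value == val and row.at == at


# -------------------------------------------------------- exceedance runs


class TestExceedanceRuns:
    def test_no_record_above_threshold(self):
        s = make_series(range(5), [20, 21, 22, 23, 24])
        assert ex.exceedance_runs(s, 30.0) == []

    def test_missing_hour_bridged(self):
        s = make_series([1, 2, 3, 5, 6], [31, 31, 31, 31, 31])
        runs = ex.exceedance_runs(s, 30.0)
        assert len(runs) == 1
        r = runs[0]
        assert r.start.hour == 1 and r.end.hour == 6
        assert r.duration_h == 6.0 and r.n_records == 5 and r.n_bridged_gaps == 1

    def test_observed_below_threshold_breaks_run(self):
        # a cool recorded value terminates a run even inside the gap window
        s = make_series([1, 2, 3, 4], [31, 31, 25, 31])
        runs = ex.exceedance_runs(s, 30.0)
        assert len(runs) == 2
        assert runs[0].duration_h == 2.0 and runs[1].duration_h == 1.0

    def test_gap_longer_than_allowance_splits(self):
        s = make_series([1, 2, 5, 6], [31, 31, 31, 31])
        runs = ex.exceedance_runs(s, 30.0, max_gap_h=2.0)
        assert [r.n_records for r in runs] == [2, 2]

    def test_unsorted_input_rejected(self):
        s = make_series([3, 1, 2], [31, 31, 31])
        with pytest.raises(ValueError):
            ex.exceedance_runs(s, 30.0)

    def test_matches_brute_force_enumerator(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            s = random_series(rng, n_hours=int(rng.integers(10, 60)))
            thr = float(rng.uniform(26, 30))
            gap = float(rng.integers(1, 4))
            got = ex.exceedance_runs(s, thr, gap)
            want = brute_force_runs(s, thr, gap)
            assert len(got) == len(want)
            for r, (start, end, dur, n, nb) in zip(got, want):
                assert (r.start, r.end, r.duration_h, r.n_records, r.n_bridged_gaps) == (
                    start,
                    end,
                    dur,
                    n,
                    nb,
                )

    def test_conservation_and_nesting(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = random_series(rng, n_hours=72)
            lo_runs = ex.exceedance_runs(s, 27.0)
            hi_runs = ex.exceedance_runs(s, 30.0)
            vals = s["wbgt_c"].dropna()
            assert sum(r.n_records for r in lo_runs) == int((vals >= 27.0).sum())
            for hi in hi_runs:
                assert any(
                    lo.start <= hi.start and hi.end <= lo.end for lo in lo_runs
                ), "higher-threshold run not nested in a lower-threshold run"


class TestRunHistogram:
    def test_empty(self):
        hist, cut = ex.run_length_histogram([])
        assert len(hist) == 0 and cut == {}

    def test_counts_and_cutoffs(self):
        s = make_series(range(20), [31] * 3 + [20] + [31] * 3 + [20] + [31] * 6 + [20] * 6)
        runs = ex.exceedance_runs(s, 30.0)
        hist, cut = ex.run_length_histogram(runs, duration_cutoffs=(5.0,))
        table = dict(zip(hist["duration_h"], hist["count"]))
        assert table == {3.0: 2, 6.0: 1}
        assert cut[(30.0, 5.0)] == 1
        assert hist["count"].sum() == len(runs)


class TestBandFrequencies:
    def test_all_below_lowest(self):
        out = ex.band_frequencies([20.0, 22.0, 24.9])
        assert out["cumulative"][">=25"] == 0.0

    def test_direct_count_example(self):
        out = ex.band_frequencies([24, 26, 29, 31, 34])
        assert out["cumulative"] == {
            ">=25": 0.8,
            ">=28": 0.6,
            ">=30": 0.4,
            ">=33": 0.2,
        }

    def test_bands_partition(self):
        rng = np.random.default_rng(1)
        out = ex.band_frequencies(rng.uniform(15, 40, 500))
        assert sum(out["bands"].values()) == pytest.approx(1.0)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            ex.ActivityThresholds({"a": 30.0, "b": 25.0})


class TestDayNight:
    def test_split_is_exhaustive_and_disjoint(self):
        s = make_series(range(24), list(range(24)))
        day, night = ex.day_night_split(s)
        assert len(day) + len(night) == 24
        assert set(day["timestamp"].dt.hour) == set(range(6, 18))
        assert 12 in set(day["timestamp"].dt.hour)
        assert 3 in set(night["timestamp"].dt.hour)


class TestStationComparison:
    @staticmethod
    def _daily(values, unit="U", start="2019-03-01"):
        dates = pd.date_range(start, periods=len(values), freq="D", tz="UTC")
        return pd.DataFrame(
            {
                "unit_id": unit,
                "date": [d.date() for d in dates],
                "value": values,
                "at": dates,
            }
        )

    def test_identical_series_zero_difference(self):
        a = self._daily([28.0, 29.0, 30.0])
        out = ex.station_comparison(a, a.assign(unit_id="ST"))
        assert out["mean_difference"] == 0.0 and out["n_days"] == 3

    def test_constant_offset_recovered_exactly(self):
        st = self._daily([27.0, 27.5, 28.0, 28.5], unit="ST")
        situ = st.assign(unit_id="S01", value=st["value"] + 1.3)
        out = ex.station_comparison(situ, st)
        assert out["mean_difference"] == pytest.approx(1.3)

    def test_injected_offset_with_noise_within_two_se(self):
        rng = np.random.default_rng(99)
        n = 200
        base = 27.0 + np.sin(np.arange(n) / 9.0)
        st = self._daily(base, unit="ST")
        situ = self._daily(base + 1.3 + rng.normal(0, 0.4, n), unit="S01")
        out = ex.station_comparison(situ, st)
        assert abs(out["mean_difference"] - 1.3) <= 2 * out["se_difference"]

    def test_unpaired_days_counted_and_empty_overlap_rejected(self):
        a = self._daily([28.0, 29.0, 30.0])
        b = self._daily([27.0, 27.0], unit="ST", start="2019-03-02")
        out = ex.station_comparison(a, b)
        assert out["n_days"] == 2 and out["n_unpaired_days"] == 1
        with pytest.raises(ValueError):
            ex.station_comparison(a, self._daily([27.0], unit="ST", start="2020-01-01"))
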