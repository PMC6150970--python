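import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from travelmode.epoch_features import (build_epoch_features, detect_nonwear,
                                       fft_mean_strength, kurtosis,
                                       mad_from_median, percentile,
                                       resolve_speed, segment_epochs,
                                       skewness, sum_snr)
from travelmode.io_formats import AccelData, GpsTrack

T0 = pd.Timestamp("2024-03-04 08:00:00", tz="UTC")


def _samples(values, rate=30.0, start=T0, ay=None, az=None):
    n = len(values)
    return pd.DataFrame({
        "timestamp": start + pd.to_timedelta(np.arange(n) / rate, unit="s"),
        "ax": np.asarray(values, dtype=float),
        "ay": np.asarray(ay, dtype=float) if ay is not None else np.zeros(n),
        "az": np.asarray(az, dtype=float) if az is not None else np.ones(n)})


finite_floats = st.floats(-10, 10, allow_nan=False)


class TestSummaryStatistics:
    def test_mad_examples(self):
        assert mad_from_median([5.0] * 10) == 0.0
        assert mad_from_median([1, 2, 3, 4, 5]) == 1.0
        with pytest.raises(ValueError):
            mad_from_median([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(finite_floats, min_size=3, max_size=50), finite_floats)
    def test_mad_translation_invariant(self, values, shift):
        v = np.asarray(values)
        assert mad_from_median(v + shift) == pytest.approx(
            mad_from_median(v), abs=1e-9)

    def test_percentile_examples(self):
        assert percentile([7.0] * 5, 10) == 7.0 == percentile([7.0] * 5, 90)
        # type-7 interpolation: 11 evenly spaced values, q=10 -> 1.0
        assert percentile(np.arange(11.0), 10) == pytest.approx(1.0)

    def test_percentile_monotone_in_q(self, rng):
        for _ in range(20):
            v = rng.normal(size=40)
            assert percentile(v, 10) <= percentile(v, 90)

    def test_skewness_symmetric_and_degenerate(self):
        assert skewness([-1.0, 0.0, 1.0]) == 0.0
        assert skewness([2.0, 2.0, 2.0]) == 0.0
        assert kurtosis([2.0, 2.0, 2.0]) == 0.0
        with pytest.raises(ValueError):
            skewness([1.0, 2.0])
        with pytest.raises(ValueError):
            kurtosis([1.0, 2.0])

    def test_moments_match_direct_computation(self, rng):
        for _ in range(100):
            v = rng.normal(size=int(rng.integers(10, 300)))
            d = v - v.mean()
            m2, m3, m4 = (d ** 2).mean(), (d ** 3).mean(), (d ** 4).mean()
            assert skewness(v) == pytest.approx(m3 / m2 ** 1.5, abs=1e-12)
            assert kurtosis(v) == pytest.approx(m4 / m2 ** 2 - 3, abs=1e-12)


class TestFftMeanStrength:
    def test_constant_signal_is_zero(self):
        assert fft_mean_strength(np.full(300, 2.5)) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_amplitude(self):
        t = np.arange(300) / 30.0
        base = fft_mean_strength(np.sin(2 * np.pi * 2 * t))
        doubled = fft_mean_strength(2 * np.sin(2 * np.pi * 2 * t))
        assert doubled == pytest.approx(2 * base, rel=1e-9)
        assert base > 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fft_mean_strength(np.ones(5))

    def test_matches_naive_dft_oracle(self, rng):
        n = 300
        k = np.arange(n)
        dft = np.exp(-2j * np.pi * np.outer(k[: n // 2 + 1], k) / n)
        for _ in range(100):
            v = rng.normal(size=n)
            naive = np.abs(dft @ (v - v.mean()))[1:].mean() / n
            assert fft_mean_strength(v) == pytest.approx(naive, abs=1e-9)


class TestGpsScalars:
    def test_sum_snr(self):
        assert sum_snr([38.0, 42.0]) == 80.0
        assert sum_snr([]) == 0.0

    def test_sum_snr_matches_fold(self, rng):
        for _ in range(50):
            v = list(rng.uniform(0, 60, int(rng.integers(0, 12))))
            acc = 0.0
            for x in v:
                acc += x
            assert sum_snr(v) == pytest.approx(acc)

    def test_device_speed_passthrough(self):
        fix = {"device_speed": 12.0}
        assert resolve_speed(fix) == 12.0

    def test_fallback_from_positions(self):
        prev = {"timestamp": T0, "lat": 51.5, "lon": -0.1, "device_speed": None}
        lat2 = 51.5 + 100.0 / 111_194.9267
        fix = {"timestamp": T0 + pd.Timedelta(seconds=10), "lat": lat2,
               "lon": -0.1, "device_speed": None}
        assert resolve_speed(fix, prev) == pytest.approx(36.0, rel=1e-3)

    def test_stationary_duplicate_fixes(self):
        prev = {"timestamp": T0, "lat": 51.5, "lon": -0.1, "device_speed": None}
        fix = {"timestamp": T0 + pd.Timedelta(seconds=10), "lat": 51.5,
               "lon": -0.1, "device_speed": None}
        assert resolve_speed(fix, prev) == 0.0
        assert resolve_speed(fix, None) == 0.0


class TestSegmentEpochs:
    def test_boundary_aligned_single_epoch(self):
        df = _samples(np.zeros(300))
        out, complete = segment_epochs(df, 30.0)
        assert complete.sum() == 1 and len(complete) == 1
        assert out["epoch_start"].nunique() == 1

    def test_mid_epoch_start_flags_partials(self):
        df = _samples(np.zeros(450), start=T0 + pd.Timedelta(seconds=6))
        out, complete = segment_epochs(df, 30.0)
        # 15 s of data from +6 s: partial head and tail epochs, one full
        assert len(complete) == 3
        assert list(complete) == [False, True, False]

    def test_assignment_matches_floor_division(self, rng):
        keep = rng.random(900) > 0.3  # random gaps
        df = _samples(np.zeros(int(keep.sum())))
        ts = T0 + pd.to_timedelta(np.flatnonzero(keep) / 30.0, unit="s")
        df["timestamp"] = ts
        out, _ = segment_epochs(df, 30.0)
        expect = [t.floor("10s") for t in ts]
        assert list(out["epoch_start"]) == expect


class TestDetectNonwear:
    def test_two_hours_constant_fully_flagged(self):
        n = int(2 * 3600 * 5)
        df = _samples(np.zeros(n), rate=5.0)
        iv = detect_nonwear(df, 5.0)
        assert len(iv) == 1
        start, end = iv[0]
        assert start == T0 and (end - T0).total_seconds() >= 2 * 3600 - 1

    def test_active_signal_not_flagged(self, rng):
        n = int(2 * 3600 * 5)
        df = _samples(rng.normal(0, 0.02, n), rate=5.0,
                      ay=rng.normal(0, 0.02, n), az=1 + rng.normal(0, 0.02, n))
        assert detect_nonwear(df, 5.0) == []

    def test_one_quiet_axis_is_not_nonwear(self, rng):
        # SD below threshold on one axis only: still wear time
        n = int(90 * 60 * 5)
        df = _samples(rng.normal(0, 0.001, n), rate=5.0,
                      ay=rng.normal(0, 0.05, n), az=1 + rng.normal(0, 0.05, n))
        assert detect_nonwear(df, 5.0) == []

    def test_threshold_monotonicity(self, rng):
        n = int(3 * 3600)
        quiet = rng.normal(0, 0.012, n)
        df = _samples(quiet, rate=1.0, ay=rng.normal(0, 0.012, n))
        lo = detect_nonwear(df, 1.0, sd_threshold_g=0.010)
        hi = detect_nonwear(df, 1.0, sd_threshold_g=0.013)
        span = lambda iv: sum((e - s).total_seconds() for s, e in iv)
        assert span(lo) <= span(hi)

    def test_matches_brute_force_window_scan(self, rng):
        # 3-h trace at 1 Hz with alternating wear/non-wear blocks
        rate, hours = 1.0, 3
        n = int(hours * 3600 * rate)
        sd = np.where((np.arange(n) // 4500) % 2 == 0, 0.001, 0.05)
        df = _samples(rng.normal(0, 1, n) * sd, rate=rate,
                      ay=rng.normal(0, 1, n) * sd,
                      az=1 + rng.normal(0, 1, n) * sd)
        got = detect_nonwear(df, rate)
        # oracle: evaluate every 15-min-step window position directly
        win, step = 3600, 900
        flagged = np.zeros(n, dtype=bool)
        for i0 in range(0, n - win + 1, step):
            block = df[["ax", "ay", "az"]].iloc[i0:i0 + win].to_numpy()
            if (block.std(axis=0, ddof=1) < 0.013).sum() >= 2:
                flagged[i0:i0 + win] = True
        got_mask = np.zeros(n, dtype=bool)
        for s, e in got:
            got_mask |= ((df["timestamp"] >= s)
                         & (df["timestamp"] < e)).to_numpy()
        assert (got_mask == flagged).all()


class TestBuildEpochFeatures:
    def _accel(self, n_epochs, rng):
        n = n_epochs * 300
        sig = rng.normal(0, 0.05, n)
        return AccelData(_samples(sig, ay=rng.normal(0, 0.05, n),
                                  az=1 + rng.normal(0, 0.05, n)), 30.0)

    def _gps(self, ts_offsets):
        fixes = pd.DataFrame({
            "timestamp": [T0 + pd.Timedelta(seconds=o) for o in ts_offsets],
            "lat": 51.5, "lon": -0.1, "device_speed": 5.0,
            "n_sat_used": 8, "sat_snr": [[40.0, 41.0]] * len(ts_offsets)})
        return GpsTrack(fixes)

    def test_epoch_with_fix(self, rng):
        res = build_epoch_features(self._accel(1, rng), self._gps([3.0]),
                                   None, "P1")
        assert len(res.epochs) == 1
        row = res.epochs.iloc[0]
        assert row["has_gps"] and row["sum_snr"] == 81.0
        assert row["speed_kmh"] == 5.0

    def test_epoch_without_fix(self, rng):
        res = build_epoch_features(self._accel(1, rng), self._gps([15.0]),
                                   None, "P1")
        row = res.epochs.iloc[0]
        assert not row["has_gps"] and np.isnan(row["sum_snr"])

    def test_empty_input(self):
        empty = AccelData.__new__(AccelData)
        empty.samples = pd.DataFrame(columns=["timestamp", "ax", "ay", "az"])
        empty.sample_rate_hz = 30.0
        empty.n_skipped = 0
        res = build_epoch_features(empty, None, None, "P1")
        assert res.epochs.empty

    def test_attached_fixes_lie_within_epoch(self, one_participant):
        network, pid, accel, gps, _ = one_participant
        res = build_epoch_features(accel, gps, network, pid)
        ep = res.epochs[res.epochs["has_gps"]]
        fix_ts = gps.fixes["timestamp"]
        for t0 in ep["epoch_start"].sample(25, random_state=0):
            in_win = fix_ts[(fix_ts >= t0)
                            & (fix_ts < t0 + pd.Timedelta(seconds=10))]
            assert len(in_win) >= 1

    def test_vectorised_features_match_scalar_functions(self):
        acc = self._accel(5, np.random.default_rng(99))
        res = build_epoch_features(acc, None, None, "P1")
        for k, row in res.epochs.iterrows():
            block = acc.samples[acc.samples["timestamp"].dt.floor("10s")
                                == row["epoch_start"]]
            v = block["ax"].to_numpy()
            assert row["mad_x"] == pytest.approx(mad_from_median(v), abs=1e-12)
            assert row["p10_x"] == pytest.approx(percentile(v, 10), abs=1e-12)
            assert row["p90_x"] == pytest.approx(percentile(v, 90), abs=1e-12)
            assert row["skew_x"] == pytest.approx(skewness(v), abs=1e-10)
            assert row["kurt_x"] == pytest.approx(kurtosis(v), abs=1e-10)
            assert row["fftmean_x"] == pytest.approx(
                fft_mean_strength(v), abs=1e-12)

    def test_translation_consistency(self, rng):
        acc = self._accel(3, rng)
        shifted = AccelData(acc.samples.assign(ax=acc.samples["ax"] + 0.5), 30.0)
        a = build_epoch_features(acc, None, None, "P1").epochs
        b = build_epoch_features(shifted, None, None, "P1").epochs
        np.testing.assert_allclose(b["p10_x"], a["p10_x"] + 0.5, atol=1e-9)
        np.testing.assert_allclose(b["p90_x"], a["p90_x"] + 0.5, atol=1e-9)
        for col in ("mad_x", "skew_x", "kurt_x", "fftmean_x"):
            np.testing.assert_allclose(b[col], a[col], atol=1e-9)
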