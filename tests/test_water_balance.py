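import logging

import numpy as np
import pandas as pd
import pytest

from soilmulch.water_balance import (SMEP_LAYERS, SWC_LAYERS, IrrigationEvent,
                                     LayerSpec, compute_smep, compute_swc,
                                     detect_irrigation_events, events_from_log)

DEPTHS = (5.0, 10.0, 20.0, 30.0)


def moisture_frame(profile: np.ndarray, freq="30min", start="2021-01-01"):
    """Build a sensor frame with the same moisture at every depth."""
    times = pd.date_range(start, periods=len(profile), freq=freq)
    rows = []
    for t, m in zip(times, profile):
        for d in DEPTHS:
            rows.append({"timestamp": t, "treatment": "bare", "depth_cm": d,
                         "temperature_c": 20.0, "moisture_pct": m})
    return pd.DataFrame(rows), times


def event(i, onset, before, after):
    """Shorthand: same theta at every depth, onset also used as peak."""
    return IrrigationEvent(
        index=i, onset=pd.Timestamp(onset), peak_time=pd.Timestamp(onset),
        theta_before={d: b for d, b in zip(DEPTHS, before)},
        theta_after={d: a for d, a in zip(DEPTHS, after)},
    )


class TestDetection:
    def test_monotone_drydown_yields_no_events(self, caplog):
        prof = np.linspace(30.0, 20.0, 200)
        df, _ = moisture_frame(prof)
        with caplog.at_level(logging.WARNING):
            assert detect_irrigation_events(df) == []
        assert any("no irrigation events" in r.message for r in caplog.records)

    def test_single_pulse_brackets_theta(self):
        prof = np.r_[np.linspace(25, 24, 48), np.linspace(34, 33, 48)]
        df, times = moisture_frame(prof)
        events = detect_irrigation_events(df, delta_pct=1.5)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset == times[48]
        assert ev.theta_before[5.0] == pytest.approx(24.0)
        assert ev.theta_after[5.0] == pytest.approx(34.0)

    def test_two_close_pulses_merge_into_one_event(self):
        # pulses 1 h apart with a 6 h window
        prof = np.full(400, 22.0)
        prof[100:] += 4.0   # first pulse
        prof[102:] += 4.0   # second pulse, 2 samples = 1 h later
        prof -= np.linspace(0, 1.0, 400)  # slow drydown
        df, times = moisture_frame(prof)
        events = detect_irrigation_events(df, delta_pct=1.5, window="6h")
        assert len(events) == 1
        assert events[0].onset == times[100]
        # peak reflects the cumulative rise of both pulses
        assert events[0].theta_after[5.0] == pytest.approx(prof[102:].max())

    def test_distant_pulses_stay_separate(self):
        prof = np.full(600, 22.0)
        prof[100:] += 5.0
        prof[400:] += 5.0
        prof -= np.linspace(0, 2.0, 600)
        df, times = moisture_frame(prof)
        events = detect_irrigation_events(df, delta_pct=1.5, window="6h")
        assert [e.onset for e in events] == [times[100], times[400]]

    def test_events_from_log_bypasses_detection(self):
        prof = np.r_[np.linspace(25, 24, 48), np.linspace(34, 33, 48)]
        df, times = moisture_frame(prof)
        events = events_from_log(df, [times[48]])
        assert len(events) == 1
        assert events[0].theta_before[5.0] == pytest.approx(24.0)
        assert events[0].theta_after[5.0] == pytest.approx(34.0)

    def test_bad_delta_rejected(self):
        df, _ = moisture_frame(np.full(10, 20.0))
        with pytest.raises(ValueError, match="delta"):
            detect_irrigation_events(df, delta_pct=0.0)


class TestComputeSwc:
    def test_no_depletion_means_zero(self):
        evs = [event(0, "2021-01-01", (20,) * 4, (30,) * 4),
               event(1, "2021-01-10", (30,) * 4, (30,) * 4)]
        res = compute_swc(evs)
        assert res.season_total_mm == pytest.approx(0.0)

    def test_hand_arithmetic_three_layers(self):
        # layer thetas after event 0: (30, 28, 26); before event 1: (20, 24, 25)
        evs = [
            IrrigationEvent(0, pd.Timestamp("2021-01-01"), pd.Timestamp("2021-01-01"),
                            theta_before={5.0: 0, 10.0: 0, 20.0: 0, 30.0: 0},
                            theta_after={5.0: 30, 10.0: 30, 20.0: 26, 30.0: 26}),
            IrrigationEvent(1, pd.Timestamp("2021-01-10"), pd.Timestamp("2021-01-10"),
                            theta_before={5.0: 20, 10.0: 20, 20.0: 28, 30.0: 22},
                            theta_after={5.0: 0, 10.0: 0, 20.0: 0, 30.0: 0}),
        ]
        # 0-10: (30-20)=10 -> 10 mm; 10-20: (28-24)=4 -> 4 mm; 20-30: (26-25)=1 -> 1 mm
        res = compute_swc(evs)
        by_layer = res.per_interval.set_index("layer")["swc_mm"]
        assert by_layer["0-10cm"] == pytest.approx(10.0)
        assert by_layer["10-20cm"] == pytest.approx(4.0)
        assert by_layer["20-30cm"] == pytest.approx(1.0)
        assert res.season_total_mm == pytest.approx(15.0)

    def test_single_event_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compute_swc([event(0, "2021-01-01", (20,) * 4, (30,) * 4)])

    def test_negative_interval_kept_and_flagged(self, caplog):
        evs = [event(0, "2021-01-01", (20,) * 4, (25,) * 4),
               event(1, "2021-01-10", (28,) * 4, (30,) * 4)]
        with caplog.at_level(logging.WARNING):
            res = compute_swc(evs)
        assert res.per_interval["negative"].all()
        assert res.season_total_mm == pytest.approx(-9.0)

    def test_additivity_and_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_events = rng.integers(2, 6)
            evs = [
                event(i, pd.Timestamp("2021-01-01") + pd.Timedelta(days=7 * i),
                      rng.uniform(14, 36, 4), rng.uniform(14, 36, 4))
                for i in range(n_events)
            ]
            res = compute_swc(evs)
            # independent loop over (interval, layer)
            expected = 0.0
            for i in range(n_events - 1):
                for layer in SWC_LAYERS:
                    after = np.mean([evs[i].theta_after[d] for d in layer.sensors])
                    before = np.mean([evs[i + 1].theta_before[d] for d in layer.sensors])
                    expected += (after - before) / 100.0 * layer.thickness_mm
            assert res.season_total_mm == pytest.approx(expected, abs=1e-12)
            assert res.season_total_mm == pytest.approx(
                res.per_interval["swc_mm"].sum(), abs=1e-12)
            assert res.cumulative["cumulative_mm"].iloc[-1] == pytest.approx(
                res.season_total_mm, abs=1e-12)

    def test_dat_axis_anchored_at_transplant(self):
        evs = [event(0, "2021-01-01 10:00", (20,) * 4, (30,) * 4),
               event(1, "2021-01-11 10:00", (25,) * 4, (30,) * 4)]
        res = compute_swc(evs, transplant_date=pd.Timestamp("2020-12-31 10:00"))
        assert res.cumulative["dat"].iloc[0] == pytest.approx(11.0)


class TestComputeSmep:
    def test_hand_arithmetic_shares(self):
        layers = SWC_LAYERS
        evs = [
            IrrigationEvent(0, pd.Timestamp("2021-01-01"), pd.Timestamp("2021-01-01"),
                            theta_before={d: 0 for d in DEPTHS},
                            theta_after={5.0: 30, 10.0: 30, 20.0: 26, 30.0: 26}),
            IrrigationEvent(1, pd.Timestamp("2021-01-10"), pd.Timestamp("2021-01-10"),
                            theta_before={5.0: 20, 10.0: 20, 20.0: 28, 30.0: 22},
                            theta_after={d: 0 for d in DEPTHS}),
        ]
        res = compute_smep(evs, layers=layers)
        shares = res.per_interval.set_index("layer")["smep_pct"]
        assert shares["0-10cm"] == pytest.approx(100 * 10 / 15)
        assert shares["10-20cm"] == pytest.approx(100 * 4 / 15)
        assert shares["20-30cm"] == pytest.approx(100 * 1 / 15)

    def test_single_layer_takes_all(self):
        layers = (LayerSpec("0-30cm", 0.0, 30.0, DEPTHS),)
        evs = [event(0, "2021-01-01", (20,) * 4, (30,) * 4),
               event(1, "2021-01-10", (25,) * 4, (30,) * 4)]
        res = compute_smep(evs, layers=layers)
        assert res.per_interval["smep_pct"].iloc[0] == pytest.approx(100.0)

    def test_rows_sum_to_100_for_every_interval(self):
        rng = np.random.default_rng(7)
        evs = []
        for i in range(6):
            after = rng.uniform(30, 36, 4)
            before = rng.uniform(14, 29, 4)
            evs.append(event(i, pd.Timestamp("2021-01-01") + pd.Timedelta(days=10 * i),
                             before, after))
        res = compute_smep(evs, layers=SMEP_LAYERS)
        sums = res.per_interval.groupby("interval")["smep_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_gaining_interval_excluded_with_warning(self, caplog):
        evs = [event(0, "2021-01-01", (20,) * 4, (25,) * 4),
               event(1, "2021-01-10", (30,) * 4, (34,) * 4),   # gained water
               event(2, "2021-01-20", (22,) * 4, (30,) * 4)]
        with caplog.at_level(logging.WARNING):
            res = compute_smep(evs)
        assert res.excluded_intervals == (0,)
        assert set(res.per_interval["interval"]) == {1}

    def test_all_intervals_excluded_is_fatal(self):
        evs = [event(0, "2021-01-01", (20,) * 4, (25,) * 4),
               event(1, "2021-01-10", (30,) * 4, (34,) * 4)]
        with pytest.raises(ValueError, match="non-positive"):
            compute_smep(evs)
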