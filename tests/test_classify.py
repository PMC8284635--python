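import numpy as np
import pytest

from accelbird.classify import (
    FlapEvent,
    PitchChangeEvent,
    assemble_ethogram,
    classify,
    classify_dives,
    classify_rest,
    classify_surface_seizing,
    detect_flaps,
    detect_takeoffs,
    group_flight,
    group_pitch_events,
    pitch_change_events,
)
from accelbird.io import TagKind
from accelbird.signal import DecomposedSeries, OdbaSeries, PitchSeries


def _dec_from_zd(zd, fs=20.0):
    zero = np.zeros_like(np.asarray(zd, float))
    return DecomposedSeries(fs=fs, x_s=zero, y_s=zero, z_s=zero,
                            x_d=zero, y_d=zero, z_d=np.asarray(zd, float))


def _event(t, mag=50.0, direction="up", origin=-20.0, end=None):
    return PitchChangeEvent(
        time_s=t, end_time_s=t + 0.5 if end is None else end,
        magnitude_deg=mag, direction=direction, origin_pitch_deg=origin,
    )


class TestDetectFlaps:
    def test_glide_only_empty(self, simple_profile, rng):
        d = _dec_from_zd(0.02 * rng.normal(size=400))
        assert detect_flaps(d, simple_profile) == []

    def test_sine_flap_count(self, simple_profile):
        fs, dur = 20.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        d = _dec_from_zd(0.4 * np.sin(2 * np.pi * 4.0 * t), fs=fs)
        flaps = detect_flaps(d, simple_profile)
        # 40 wingbeat cycles -> ~80 alternating extremum pairs
        assert abs(len(flaps) - 79) <= 2
        assert all(f.amplitude_g >= simple_profile.flap_threshold_g for f in flaps)

    def test_boundary_amplitude_included(self, simple_profile):
        # peak-trough difference exactly at the threshold
        zd = np.array([0.0, 0.4, 0.0, 0.1, 0.0])
        d = _dec_from_zd(zd)
        amps = [f.amplitude_g for f in detect_flaps(d, simple_profile)]
        assert 0.4 in amps


class TestGroupFlight:
    def _flaps(self, times, fs=20.0):
        return [
            FlapEvent(int(t * fs), int(t * fs) + 1, 1.0) for t in times
        ]

    def test_close_flaps_one_bout(self):
        out = group_flight(self._flaps([0.0, 0.4, 0.8]), fs=20.0)
        assert len(out) == 1

    def test_long_gap_two_intervals(self):
        out = group_flight(self._flaps([0.0, 10.0, 45.0]), fs=20.0)
        assert len(out) == 2

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(20):
            times = np.sort(rng.uniform(0, 400, size=40))
            flaps = self._flaps(times, fs=20.0)
            got = group_flight(flaps, fs=20.0)
            # oracle: union-find over the two-stage gap graph
            spans = sorted((f.start_index / 20.0, f.end_index / 20.0)
                           for f in flaps)

            def closure(spans, gap, strict):
                parent = list(range(len(spans)))

                def find(i):
                    while parent[i] != i:
                        parent[i] = parent[parent[i]]
                        i = parent[i]
                    return i

                for i in range(len(spans)):
                    for j in range(i + 1, len(spans)):
                        g = spans[j][0] - spans[i][1]
                        if (g < gap) if strict else (g <= gap):
                            parent[find(j)] = find(i)
                groups = {}
                for i, sp in enumerate(spans):
                    groups.setdefault(find(i), []).append(sp)
                return sorted(
                    (min(a for a, _ in g), max(b for _, b in g))
                    for g in groups.values()
                )

            bouts = closure(spans, 0.5, True)
            expected = closure(bouts, 30.0, False)
            assert [(pytest.approx(a), pytest.approx(b)) for a, b in expected] \
                == got


class TestDetectTakeoffs:
    def test_upward_event_at_onset(self, simple_profile):
        flights = [(100.0, 200.0)]
        ev = [_event(99.0, mag=1.2 * simple_profile.large_pitch_change_deg)]
        out = detect_takeoffs(flights, ev, simple_profile)
        assert len(out) == 1 and out[0][0] == pytest.approx(99.0)

    def test_downward_only_no_takeoff(self, simple_profile):
        flights = [(100.0, 200.0)]
        ev = [_event(99.5, direction="down")]
        assert detect_takeoffs(flights, ev, simple_profile) == []

    def test_event_outside_window_ignored(self, simple_profile):
        flights = [(100.0, 200.0)]
        ev = [_event(95.0)]
        assert detect_takeoffs(flights, ev, simple_profile) == []

    def test_back_mounted_high_origin_suppressed(self, simple_profile):
        simple_profile.tag_kind = TagKind.back_mounted
        flights = [(100.0, 200.0)]
        high = [_event(99.5, origin=0.0)]    # above min_med (-20)
        low = [_event(99.5, origin=-25.0)]   # below min_med
        assert detect_takeoffs(flights, high, simple_profile) == []
        assert len(detect_takeoffs(flights, low, simple_profile)) == 1


class TestGroupPitchEvents:
    def test_chained_within_window(self):
        ev = [_event(t) for t in (0.0, 20.0, 40.0)]
        assert len(group_pitch_events(ev)) == 1

    def test_split_beyond_window(self):
        ev = [_event(t) for t in (0.0, 30.0)]
        assert len(group_pitch_events(ev)) == 2

    def test_matches_single_linkage_oracle(self, rng):
        for _ in range(25):
            times = np.sort(rng.uniform(0, 500, size=30))
            ev = [_event(t) for t in times]
            got = group_pitch_events(ev, 23.3)
            # oracle: cut wherever the successive gap exceeds 23.3
            cuts = np.flatnonzero(np.diff(times) > 23.3)
            expected_sizes = np.diff(np.concatenate(([0], cuts + 1, [len(times)])))
            assert [len(g) for g in got] == list(expected_sizes)


class TestClassifyDives:
    def _pitch(self, values, fs=20.0):
        return PitchSeries(pitch_deg=np.asarray(values, float), fs=fs)

    def test_dip_and_recovery_is_dive(self, simple_profile):
        fs = 20.0
        p = np.zeros(400)
        p[100:140] = -70.0   # below -20 - 30 = -50
        p[150:170] = 20.0    # above 0 + 2*5 = 10, within 10 s
        group = [_event(5.0), _event(7.5, end=8.5)]
        dives = classify_dives(group, self._pitch(p), simple_profile)
        assert len(dives) == 1
        s, e = dives[0]
        assert s == pytest.approx(100 / fs) and e == pytest.approx(151 / fs)

    def test_dip_without_recovery_no_dive(self, simple_profile):
        p = np.zeros(400)
        p[100:140] = -70.0
        group = [_event(5.0), _event(7.5)]
        assert classify_dives(group, self._pitch(p), simple_profile) == []

    def test_recovery_too_late_no_dive(self, simple_profile):
        fs = 20.0
        p = np.zeros(int(40 * fs))
        p[100:140] = -70.0
        p[int(16 * fs):int(17 * fs)] = 20.0  # 11 s after the descent crossing
        group = [_event(5.0), _event(16.0, end=17.0)]
        assert classify_dives(group, self._pitch(p), simple_profile) == []


class TestClassifySurfaceSeizing:
    def test_three_events_within_two_seconds(self):
        g = [_event(0.0), _event(1.5), _event(3.0)]
        spans = classify_surface_seizing(g)
        assert len(spans) == 1
        assert spans[0][0] == 0.0 and spans[0][1] == pytest.approx(3.5)

    def test_sparse_events_unknown(self):
        g = [_event(0.0), _event(3.0), _event(6.0)]
        assert classify_surface_seizing(g) == []

    def test_two_events_insufficient(self):
        g = [_event(0.0), _event(1.0)]
        assert classify_surface_seizing(g) == []

    def test_all_pairs_stricter_than_chain(self):
        # chain passes (successive gaps 2 s) but the 0-4 s pair exceeds 2 s
        g = [_event(0.0), _event(2.0), _event(4.0)]
        assert len(classify_surface_seizing(g, all_pairs=False)) == 1
        assert classify_surface_seizing(g, all_pairs=True) == []


class TestClassifyRest:
    def test_all_zero_dynamic_entire_series(self):
        ob = OdbaSeries(odba=np.zeros(200), odmn=np.zeros(200), fs=20.0)
        [(s, e)] = classify_rest(ob)
        assert s == 0.0 and e == pytest.approx(10.0)

    def test_flight_level_odba_no_rest(self):
        ob = OdbaSeries(odba=np.ones(200), odmn=np.ones(200), fs=20.0)
        assert classify_rest(ob) == []

    def test_runs_found(self):
        odmn = np.concatenate([np.zeros(100), np.ones(50), np.zeros(50)])
        ob = OdbaSeries(odba=odmn, odmn=odmn, fs=20.0)
        assert classify_rest(ob) == [(0.0, 5.0), (7.5, 10.0)]


class TestAssembleEthogram:
    def test_dive_wins_over_flight(self):
        eth = assemble_ethogram(
            n_samples=200, fs=20.0,
            dives=[(2.0, 4.0)], seizing=[], takeoffs=[],
            flights=[(0.0, 10.0)], rests=[],
        )
        labels = dict(((s, e), l) for s, e, l in eth.intervals)
        assert labels[(2.0, 4.0)] == "foraging_dive"
        assert labels[(0.0, 2.0)] == "flight"

    def test_no_detections_all_unknown(self):
        eth = assemble_ethogram(100, 20.0, [], [], [], [], [])
        assert eth.intervals == [(0.0, 5.0, "unknown")]

    def test_partitions_record(self, rng):
        n, fs = 2000, 20.0
        def spans(k):
            starts = np.sort(rng.uniform(0, n / fs, size=k))
            return [(s, min(n / fs, s + rng.uniform(0.5, 10))) for s in starts]
        eth = assemble_ethogram(n, fs, spans(3), spans(3), spans(2),
                                spans(4), spans(4), spans(2))
        assert eth.total_duration() == pytest.approx(n / fs)
        for (s0, e0, _), (s1, _, _) in zip(eth.intervals, eth.intervals[1:]):
            assert s1 == e0


class TestPipelineProperties:
    def test_ethogram_partitions_record(self, two_hour_run):
        series = two_hour_run["series"]
        eth = two_hour_run["result"].ethogram
        assert eth.total_duration() == pytest.approx(series.duration_s)

    def test_raising_flap_threshold_monotone_flight(self, two_hour_run):
        from dataclasses import replace

        series, profile = two_hour_run["series"], two_hour_run["profile"]
        base = two_hour_run["result"]
        from accelbird.signal import decompose

        dec = decompose(series)
        base_flight = sum(e - s for s, e in base.flights)
        for factor in (1.5, 2.5):
            hi = replace(profile, flap_threshold_g=profile.flap_threshold_g * factor)
            flaps = detect_flaps(dec, hi)
            flights = group_flight(flaps, series.fs)
            assert sum(e - s for s, e in flights) <= base_flight + 1e-9
            base_flight = sum(e - s for s, e in flights)

    def test_rest_threshold_monotone(self, two_hour_run):
        from accelbird.signal import decompose, odba

        series = two_hour_run["series"]
        ob = odba(decompose(series))
        durations = [
            sum(e - s for s, e in classify_rest(ob, threshold_g=thr))
            for thr in (0.1, 0.2, 0.4)
        ]
        assert durations == sorted(durations)

    def test_rest_blocks_recovered(self, two_hour_run):
        """ODBA thresholding recovers the generator's rest blocks."""
        from accelbird.signal import decompose, odba

        series, truth = two_hour_run["series"], two_hour_run["truth"]
        ob = odba(decompose(series))
        rests = classify_rest(ob)
        true_rest = truth.select("rest")
        total = sum(e - s for s, e in true_rest)
        inside = sum(
            max(0.0, min(e, te) - max(s, ts))
            for s, e in rests
            for ts, te in true_rest
        )
        assert inside / total >= 0.90

    def test_mount_filter_changes_event_set(self, two_hour_run):
        from dataclasses import replace

        from accelbird.signal import decompose, pitch

        series, profile = two_hour_run["series"], two_hour_run["profile"]
        ps = pitch(decompose(series))
        chest = pitch_change_events(ps, profile)
        back = pitch_change_events(
            ps, replace(profile, tag_kind=TagKind.back_mounted)
        )
        assert len(back) <= len(chest)
        assert all(
            not (e.direction == "up"
                 and e.origin_pitch_deg > profile.pfm_pitch_min_med_deg)
            for e in back
        )
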