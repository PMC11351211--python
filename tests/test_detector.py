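"""Decision rules, queues, peak candidates, streaming equivalence, WS/WP."""
import numpy as np
import pytest

from dgei import (
    ContractError,
    DetectorConfig,
    DetectorState,
    DgeiParams,
    GaitSignal,
    InvalidInputError,
    ScenarioSpec,
    StreamingDetector,
    WeightedQueue,
    current_sleeptime,
    current_threshold,
    generate_scenario,
    run_detector,
    splice_scenarios,
    validate_event,
    weighted_mean,
)
from dgei.detector import _scan_peaks, candidate_peaks
from dgei.signal_model import dgei_curves


class TestWeightedQueue:
    @pytest.mark.parametrize(
        "entries, expected",
        [
            ([10, 10, 10], 10.0),
            ([30, 60, 90], 70.0),  # (30*1 + 60*2 + 90*3) / 6
            ([7.5], 7.5),
        ],
    )
    def test_weighted_mean(self, entries, expected):
        q = WeightedQueue(5)
        for x in entries:
            q.push(x)
        assert weighted_mean(q) == pytest.approx(expected)

    def test_eviction_keeps_newest(self):
        q = WeightedQueue(3)
        for x in [1, 2, 3, 4]:
            q.push(x)
        assert q.entries == [2, 3, 4]

    def test_empty_queue_is_undefined(self):
        with pytest.raises(InvalidInputError):
            weighted_mean(WeightedQueue(3))


class TestAdaptiveSpans:
    def test_cold_start_uses_seeds(self):
        state = DetectorState(DetectorConfig(sleeptime0=60, threshold0=12.0))
        assert current_sleeptime(state, "TO") == 60.0
        assert current_threshold(state, "TO") == 12.0

    def test_steady_intervals_hold(self):
        state = DetectorState(DetectorConfig(sleeptime0=60))
        for _ in range(4):
            state.per_type["TO"].interval_queue.push(55.0)
        assert current_sleeptime(state, "TO") == pytest.approx(55.0)

    def test_sleeptime_shortens_under_acceleration(self):
        state = DetectorState(DetectorConfig(sleeptime0=60, queue_len_q=3))
        for x in [80, 70, 60]:
            state.per_type["TO"].interval_queue.push(x)
        assert current_sleeptime(state, "TO") == pytest.approx((80 + 140 + 180) / 6)

    def test_sleep_floor_prevents_collapse(self):
        state = DetectorState(DetectorConfig(sleeptime0=60))
        for _ in range(5):
            state.per_type["TO"].interval_queue.push(5.0)
        assert current_sleeptime(state, "TO") == 30.0  # sleeptime0 / 2

    def test_threshold_is_sixty_percent_of_weighted_mean(self):
        state = DetectorState(DetectorConfig(queue_len_q=3))
        for x in [100, 100, 100]:
            state.per_type["TO"].amp_queue.push(x)
        assert current_threshold(state, "TO") == pytest.approx(60.0)
        state2 = DetectorState(DetectorConfig(queue_len_q=3))
        for x in [50, 100, 150]:
            state2.per_type["HS"].amp_queue.push(x)
        assert current_threshold(state2, "HS") == pytest.approx(70.0)


class TestCandidatePeaks:
    def test_single_peak_above_baseline(self):
        assert _scan_peaks([0, 1, 3, 1, 0], 2.0) == [(2, 3)]

    def test_monotone_curve_has_no_candidates(self):
        assert _scan_peaks([0, 1, 2, 3, 4], 0.0) == []

    def test_plateau_resolves_to_first_frame(self):
        assert _scan_peaks([0, 2, 5, 5, 5, 1, 0], 1.0) == [(2, 5)]

    def test_baseline_filters_small_peaks(self):
        assert _scan_peaks([0, 1, 0, 4, 0], 2.0) == [(3, 4)]

    def test_polarities_map_to_event_types(self, clean_gait, profile):
        params, config = profile
        curves = dgei_curves(clean_gait.signal, params)
        cands = candidate_peaks(curves, config.bar)
        assert len(cands["TO"]) == 20 and len(cands["HS"]) == 20
        assert all(a > 0 for _, a in cands["TO"])
        assert all(a > 0 for _, a in cands["HS"])


class TestValidateEvent:
    def _state(self, **kw):
        return DetectorState(DetectorConfig(**kw))

    def test_alternating_steady_stream_all_accepted(self):
        state = self._state(sleeptime0=60)
        frames = []
        for i in range(6):
            frames.append((i * 60 + 10, "TO", 100.0))
            frames.append((i * 60 + 40, "HS", 100.0))
        assert all(validate_event(c, state) for c in frames)

    def test_repeat_inside_refractory_rejected(self):
        state = self._state(sleeptime0=60, alternation="off")
        assert validate_event((10, "TO", 100.0), state)
        assert not validate_event((15, "TO", 100.0), state)
        assert state.log[-1]["reason"] == "sleep"

    def test_below_threshold_rejected(self):
        state = self._state(threshold0=70.0)
        assert not validate_event((10, "TO", 50.0), state)
        assert state.log[-1]["reason"] == "threshold"

    def test_same_type_repeat_without_opposite_rejected(self):
        state = self._state(sleeptime0=5)
        assert validate_event((10, "TO", 100.0), state)
        assert not validate_event((100, "TO", 100.0), state)
        assert state.log[-1]["reason"] == "alternation"

    def test_alternation_off_allows_repeats(self):
        state = self._state(sleeptime0=5, alternation="off")
        assert validate_event((10, "TO", 100.0), state)
        assert validate_event((100, "TO", 100.0), state)

    def test_out_of_order_candidates_rejected(self):
        state = self._state()
        validate_event((50, "TO", 100.0), state)
        with pytest.raises(ContractError):
            validate_event((40, "HS", 100.0), state)


class TestRunDetector:
    def test_flat_signal_yields_nothing(self, profile):
        assert run_detector(GaitSignal(np.zeros(600)), *profile) == []

    def test_clean_gait_recovered(self, clean_gait, profile):
        events = run_detector(clean_gait.signal, *profile)
        by_type = {t: [e.frame for e in events if e.type == t] for t in ("TO", "HS", "WS", "WP")}
        assert by_type["TO"] == clean_gait.truth_frames("TO")
        assert by_type["HS"] == clean_gait.truth_frames("HS")
        assert len(by_type["WS"]) == 1 and len(by_type["WP"]) == 0

    def test_alternation_of_output(self, clean_gait, profile):
        gait = [e for e in run_detector(clean_gait.signal, *profile) if e.type in ("TO", "HS")]
        assert all(a.type != b.type for a, b in zip(gait, gait[1:]))

    def test_determinism(self, walk_stand_walk, profile):
        first = run_detector(walk_stand_walk.signal, *profile)
        second = run_detector(walk_stand_walk.signal, *profile)
        assert first == second

    def test_events_sorted_by_frame(self, walk_stand_walk, profile):
        events = run_detector(walk_stand_walk.signal, *profile)
        assert [e.frame for e in events] == sorted(e.frame for e in events)


class TestWalkTransitions:
    def test_static_then_walk_single_start(self, profile):
        ann = splice_scenarios(
            [
                ScenarioSpec(kind="static_posture", n_cycles=4, noise_sd=0.0, seed=5),
                ScenarioSpec(n_cycles=8, period_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0, seed=6),
            ]
        )
        events = run_detector(ann.signal, *profile)
        assert sum(e.type == "WS" for e in events) == 1
        first_gait = next(e for e in events if e.type in ("TO", "HS"))
        ws = next(e for e in events if e.type == "WS")
        assert ws.frame == first_gait.frame

    def test_walk_stand_walk_pause_then_restart(self, walk_stand_walk, profile):
        events = run_detector(walk_stand_walk.signal, *profile)
        marks = [(e.frame, e.type) for e in events if e.type in ("WS", "WP")]
        assert [t for _, t in marks] == ["WS", "WP", "WS"]
        assert marks[1][0] < marks[2][0]

    def test_trailing_static_emits_pause(self, profile):
        ann = splice_scenarios(
            [
                ScenarioSpec(n_cycles=8, period_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0, seed=8),
                ScenarioSpec(kind="static_posture", n_cycles=5, noise_sd=0.0, seed=9),
            ]
        )
        events = run_detector(ann.signal, *profile)
        assert sum(e.type == "WP" for e in events) == 1


class TestStreamingEquivalence:
    def test_sample_by_sample_equals_batch(self, walk_stand_walk, profile):
        params, config = profile
        batch = run_detector(walk_stand_walk.signal, params, config)
        stream = StreamingDetector(params, config, walk_stand_walk.signal.sample_rate_hz)
        assert stream.run(walk_stand_walk.signal.values) == batch

    def test_equivalence_on_noisy_pathological(self, profile):
        params, config = profile
        ann = generate_scenario(ScenarioSpec(kind="tremor_pathological", n_cycles=15, seed=13))
        batch = run_detector(ann.signal, params, config)
        stream = StreamingDetector(params, config, ann.signal.sample_rate_hz)
        assert stream.run(ann.signal.values) == batch


class TestRobustness:
    def test_tremor_spike_inside_refractory_is_inert(self, clean_gait, profile, rng):
        params, config = profile
        base = run_detector(clean_gait.signal, params, config, full=True)
        base_events = base.events
        accepted = [e for e in base_events if e.type in ("TO", "HS")]
        spike_w = 6
        lobe = 3.0 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(spike_w + 1) / spike_w))
        for _ in range(100):
            ev = accepted[int(rng.integers(0, len(accepted)))]
            offset = int(rng.integers(2, 15))  # inside the refractory window
            pos = ev.frame + offset
            values = clean_gait.signal.values.copy()
            values[pos : pos + spike_w + 1] += lobe[: len(values) - pos]
            perturbed = run_detector(GaitSignal(values), params, config)
            assert [(e.frame, e.type) for e in perturbed] == [
                (e.frame, e.type) for e in base_events
            ]

    def test_refractory_tracks_halved_period(self, profile):
        params, config = profile
        ann = splice_scenarios(
            [
                ScenarioSpec(n_cycles=8, period_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0, seed=31),
                ScenarioSpec(n_cycles=16, period_frames=30.0, period_jitter=0.0,
                             amplitude_jitter=0.0, noise_sd=0.0, seed=32),
            ],
            crossfade_frames=0,
        )
        result = run_detector(ann.signal, params, config, full=True)
        switch = 8 * 60
        realized = [
            entry["sleeptime_to"]
            for entry in result.log
            if entry["type"] == "TO" and entry["frame"] > switch
        ]
        assert all(b <= a + 1e-9 for a, b in zip(realized, realized[1:]))
        # within q events of the switch the span reaches the new 30-frame interval
        assert realized[min(len(realized) - 1, config.queue_len_q)] == pytest.approx(30.0, abs=1.0)
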