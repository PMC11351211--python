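"""Event detection on top of the slope-accumulator curves.

Candidate peaks of the positive curve are toe-off (TO) candidates; candidate
troughs of the negative curve are heel-strike (HS) candidates.  Candidates
pass through three decision rules before becoming events:

1. *alternation* — within one gait cycle HS and TO alternate, so a
   same-type repeat with no opposite-type event in between is rejected
   (``soft`` mode; ``off`` disables the rule for irregular gaits);
2. *refractory* ("sleep time") — after an accepted event, same-type
   candidates are suppressed for a span that adapts to the walker's cadence
   via a weighted queue of recent inter-candidate intervals;
3. *adaptive threshold* — a candidate's curve amplitude must exceed a
   fraction (default 60 %) of the weighted mean of recently accepted peak
   amplitudes.

Walking-start (WS) and walking-pause (WP) events are derived from
quiescence: WS fires at the first validated event after a long event-free
span (the stream start counts as such a span), WP when no validated event
arrives for a multiple of the current refractory span.

The batch entry point is :func:`run_detector`; :class:`StreamingDetector`
consumes one sample at a time and produces the identical event stream.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

from .errors import ContractError, InvalidInputError
from .signal_model import DgeiCurves, DgeiParams, GaitSignal, dgei_curves

EventType = Literal["HS", "TO", "WS", "WP"]
EVENT_TYPES = ("HS", "TO", "WS", "WP")

# Deterministic ordering for events sharing a frame: a pause closes before a
# start, a start precedes the gait event that triggered it, TO before HS.
_EVENT_RANK = {"WP": 0, "WS": 1, "TO": 2, "HS": 3}
_GAIT_TYPES = ("TO", "HS")


class WeightedQueue:
    """Fixed-capacity FIFO whose weighted mean favours recent entries.

    Position weights increase 1..len from the oldest entry (next to leave)
    to the newest (just entered), so the mean tracks recent gait while
    retaining a short memory.
    """

    def __init__(self, capacity: int):
        if int(capacity) < 1:
            raise InvalidInputError("queue capacity must be >= 1")
        self.capacity = int(capacity)
        self._items: deque[float] = deque(maxlen=self.capacity)

    def push(self, value: float) -> None:
        self._items.append(float(value))

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    @property
    def entries(self) -> list[float]:
        """Oldest first."""
        return list(self._items)

    @property
    def weights(self) -> np.ndarray:
        return np.arange(1, len(self._items) + 1)

    def weighted_mean(self) -> float:
        return weighted_mean(self)


def weighted_mean(queue: WeightedQueue) -> float:
    """``sum(entry_i * w_i) / sum(w_i)`` with weights 1..q from the oldest entry."""
    n = len(queue)
    if n == 0:
        raise InvalidInputError("weighted_mean of an empty queue is undefined")
    total = 0.0
    wsum = 0.0
    for i, x in enumerate(queue, start=1):
        total += x * i
        wsum += i
    return total / wsum


@dataclass
class DetectorConfig:
    """Decision-rule configuration.

    ``sleeptime0`` (frames) seeds the refractory span until the interval
    queue fills; ``bar`` is the candidate baseline (and, by convention, the
    curve indicator threshold — the two stages share one hyperparameter);
    ``threshold0`` seeds the amplitude threshold (0 accepts the first peak,
    avoiding a cold-start deadlock); ``threshold_fraction`` is the 60 % rule;
    ``refractory_fraction`` scales the cadence estimate down to the enforced
    same-type gap — a refractory equal to the *mean* stride interval would
    reject every stride arriving slightly early under natural cadence
    jitter, so the enforced gap is the minimum plausible stride (90 % of
    the estimate by default); ``queue_len_q`` sizes both weighted queues;
    ``sleep_floor`` bounds the adaptive span from below (default
    ``sleeptime0 / 2``) so it cannot collapse; ``ws_quiet_frames`` and
    ``wp_quiet_multiplier`` drive the walking-start / walking-pause
    quiescence rules.
    """

    sleeptime0: int = 60
    bar: float = 9.0
    threshold0: float = 0.0
    threshold_fraction: float = 0.60
    refractory_fraction: float = 0.90
    queue_len_q: int = 5
    ws_quiet_frames: int = 120
    wp_quiet_multiplier: float = 2.0
    alternation: Literal["soft", "off"] = "soft"
    sleep_floor: float | None = None

    def __post_init__(self) -> None:
        if self.sleeptime0 < 0:
            raise InvalidInputError("sleeptime0 must be >= 0")
        self.sleeptime0 = int(self.sleeptime0)
        if self.bar < 0:
            raise InvalidInputError("bar must be non-negative")
        if self.threshold0 < 0:
            raise InvalidInputError("threshold0 must be non-negative")
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise InvalidInputError("threshold_fraction must be in (0, 1]")
        if not (0.0 < self.refractory_fraction <= 1.0):
            raise InvalidInputError("refractory_fraction must be in (0, 1]")
        if int(self.queue_len_q) < 1 or int(self.queue_len_q) > 50:
            raise InvalidInputError("queue_len_q must be in 1..50")
        self.queue_len_q = int(self.queue_len_q)
        if int(self.ws_quiet_frames) < 1:
            raise InvalidInputError("ws_quiet_frames must be positive")
        self.ws_quiet_frames = int(self.ws_quiet_frames)
        if not self.wp_quiet_multiplier > 1.0:
            raise InvalidInputError("wp_quiet_multiplier must be > 1")
        if self.alternation not in ("soft", "off"):
            raise InvalidInputError(f"unknown alternation mode {self.alternation!r}")
        if self.sleep_floor is not None and self.sleep_floor < 0:
            raise InvalidInputError("sleep_floor must be non-negative")

    @property
    def effective_sleep_floor(self) -> float:
        return self.sleeptime0 / 2.0 if self.sleep_floor is None else float(self.sleep_floor)


@dataclass(frozen=True)
class GaitEvent:
    """A detected or annotated gait event.

    ``frame`` indexes the raw signal (0-based); ``value`` is the curve
    amplitude at detection for HS/TO, the raw signal value for WS/WP and
    ground-truth annotations.
    """

    frame: int
    type: EventType
    value: float = 0.0
    source: str = "state_machine"

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise InvalidInputError(f"unknown event type {self.type!r}")
        if self.frame < 0:
            raise InvalidInputError("event frame must be non-negative")


@dataclass
class _TypeState:
    amp_queue: WeightedQueue
    interval_queue: WeightedQueue
    sleep_until: float = 0.0
    last_accept_frame: int | None = None
    last_candidate_frame: int | None = None


class DetectorState:
    """Mutable validation state plus a per-candidate decision log."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        self.per_type: dict[str, _TypeState] = {
            t: _TypeState(
                amp_queue=WeightedQueue(config.queue_len_q),
                interval_queue=WeightedQueue(config.queue_len_q),
            )
            for t in _GAIT_TYPES
        }
        self.last_gait_type: str | None = None
        self.last_processed_frame: int | None = None
        self.log: list[dict] = []


def current_sleeptime(state: DetectorState, event_type: str) -> float:
    """Refractory span (frames) in force for ``event_type``.

    Weighted mean of recent inter-candidate intervals, seeded with
    ``sleeptime0`` while the queue is empty and clamped below by the floor.
    """
    ts = state.per_type[event_type]
    if len(ts.interval_queue) == 0:
        return float(state.config.sleeptime0)
    return max(state.config.effective_sleep_floor, weighted_mean(ts.interval_queue))


def current_threshold(state: DetectorState, event_type: str) -> float:
    """Amplitude threshold in force: fraction x weighted mean of accepted peaks."""
    ts = state.per_type[event_type]
    if len(ts.amp_queue) == 0:
        return float(state.config.threshold0)
    return state.config.threshold_fraction * weighted_mean(ts.amp_queue)


class _PeakTracker:
    """Online strict-local-maximum detector (plateaus resolve to their first frame).

    ``push`` returns a confirmed ``(index, value)`` peak, if any, once a
    strictly lower value arrives.  ``min_future_index`` bounds the index of
    any peak this tracker could still emit, which lets a caller merge two
    trackers' candidates in frame order.
    """

    def __init__(self, baseline: float):
        self.baseline = float(baseline)
        self.n = 0
        self.run_start = 0
        self.run_val: float | None = None
        self.asc = False

    def push(self, value: float) -> tuple[int, float] | None:
        j = self.n
        self.n += 1
        if j == 0:
            self.run_start = 0
            self.run_val = value
            return None
        if value == self.run_val:
            return None
        out = None
        if value < self.run_val:
            if self.asc and self.run_val > self.baseline:
                out = (self.run_start, self.run_val)
            self.asc = False
        else:
            self.asc = True
        self.run_start = j
        self.run_val = value
        return out

    @property
    def min_future_index(self) -> int:
        return self.run_start if self.asc else self.n


def _scan_peaks(values: Iterable[float], baseline: float) -> list[tuple[int, float]]:
    tracker = _PeakTracker(baseline)
    out = []
    for v in values:
        hit = tracker.push(float(v))
        if hit is not None:
            out.append(hit)
    return out


def candidate_peaks(curves: DgeiCurves, bar: float) -> dict[str, list[tuple[int, float]]]:
    """Candidate ``(frame, amplitude)`` lists per polarity.

    TO candidates are strict local maxima of the positive curve with value
    above the ``bar`` baseline; HS candidates are strict local minima of the
    negative curve with magnitude above the baseline.  Plateaus resolve to
    their first frame.  Frames index the raw signal.
    """
    off = curves.frame_offset
    to = [(j + off, v) for j, v in _scan_peaks(curves.pos, bar)]
    hs = [(j + off, v) for j, v in _scan_peaks(-curves.neg, bar)]
    return {"TO": to, "HS": hs}


def validate_event(
    candidate: tuple[int, str, float],
    state: DetectorState,
) -> bool:
    """Apply the three decision rules to one candidate, updating ``state``.

    ``candidate`` is ``(frame, type, amplitude)``; candidates must arrive in
    frame order.  Threshold-passing candidates feed the cadence (interval)
    queue whether or not they are finally accepted, so the refractory span
    keeps tracking step rate even while it is suppressing events; amplitudes
    enter the peak queue only on acceptance.
    """
    frame, etype, amplitude = candidate
    if etype not in _GAIT_TYPES:
        raise InvalidInputError(f"cannot validate event type {etype!r}")
    if state.last_processed_frame is not None and frame < state.last_processed_frame:
        raise ContractError(
            f"candidates must arrive in frame order ({frame} after {state.last_processed_frame})"
        )
    state.last_processed_frame = frame
    ts = state.per_type[etype]
    config = state.config

    sleeptime_in_force = current_sleeptime(state, etype)
    threshold_in_force = current_threshold(state, etype)

    passes_threshold = amplitude >= threshold_in_force
    if passes_threshold:
        if ts.last_candidate_frame is not None:
            interval = frame - ts.last_candidate_frame
            # a gap long enough to count as a walking pause is not a stride
            # interval; it must not inflate the cadence estimate
            if interval <= config.wp_quiet_multiplier * sleeptime_in_force:
                ts.interval_queue.push(interval)
        ts.last_candidate_frame = frame

    if not passes_threshold:
        accepted, reason = False, "threshold"
    elif frame < ts.sleep_until:
        accepted, reason = False, "sleep"
    elif config.alternation == "soft" and state.last_gait_type == etype:
        accepted, reason = False, "alternation"
    else:
        accepted, reason = True, "accepted"

    sleep_applied = None
    if accepted:
        ts.amp_queue.push(amplitude)
        sleep_applied = config.refractory_fraction * current_sleeptime(state, etype)
        ts.sleep_until = frame + sleep_applied
        ts.last_accept_frame = frame
        state.last_gait_type = etype

    state.log.append(
        {
            "frame": frame,
            "type": etype,
            "amplitude": amplitude,
            "threshold_in_force": threshold_in_force,
            "sleeptime_in_force": sleeptime_in_force,
            "sleep_applied": sleep_applied,
            "accepted": accepted,
            "reason": reason,
            "sleeptime_to": current_sleeptime(state, "TO"),
            "sleeptime_hs": current_sleeptime(state, "HS"),
        }
    )
    return accepted


def _signal_value(signal: GaitSignal, frame: int) -> float:
    idx = min(max(frame - signal.start_frame, 0), len(signal) - 1)
    return float(signal.values[idx])


def detect_walk_transitions(
    events: list[GaitEvent],
    signal: GaitSignal,
    config: DetectorConfig,
    sleeptime_trail: list[tuple[int, float, float]] | None = None,
) -> list[GaitEvent]:
    """Derive WS/WP events from the validated HS/TO stream.

    ``sleeptime_trail`` holds ``(frame, sleeptime_TO, sleeptime_HS)`` after
    each accepted event (the detector supplies it from its log); without it
    the refractory spans are reconstructed from the accepted intervals
    alone.  WS is stamped at the triggering gait event's frame (the stream
    start counts as quiescence, so the first event always starts a bout);
    WP is stamped at ``last_event_frame + span`` where
    ``span = wp_quiet_multiplier x max(per-type sleeptime)``.
    """
    gait = [e for e in events if e.type in _GAIT_TYPES]
    if not gait:
        return []
    if sleeptime_trail is None:
        sleeptime_trail = _reconstruct_trail(gait, config)
    if len(sleeptime_trail) != len(gait):
        raise ContractError("sleeptime_trail must have one entry per gait event")
    out: list[GaitEvent] = []
    end_frame = signal.start_frame + len(signal) - 1
    out.append(
        GaitEvent(gait[0].frame, "WS", _signal_value(signal, gait[0].frame), "state_machine")
    )
    for i, ev in enumerate(gait):
        _, st_to, st_hs = sleeptime_trail[i]
        span = config.wp_quiet_multiplier * max(st_to, st_hs)
        nxt = gait[i + 1].frame if i + 1 < len(gait) else None
        if nxt is not None:
            if nxt - ev.frame > span:
                wp_frame = ev.frame + int(round(span))
                out.append(GaitEvent(wp_frame, "WP", _signal_value(signal, wp_frame), "state_machine"))
            if nxt - ev.frame >= config.ws_quiet_frames:
                out.append(GaitEvent(nxt, "WS", _signal_value(signal, nxt), "state_machine"))
        elif end_frame - ev.frame > span:
            wp_frame = ev.frame + int(round(span))
            out.append(GaitEvent(wp_frame, "WP", _signal_value(signal, wp_frame), "state_machine"))
    return out


def _reconstruct_trail(gait: list[GaitEvent], config: DetectorConfig) -> list[tuple[int, float, float]]:
    state = DetectorState(config)
    trail = []
    for ev in gait:
        ts = state.per_type[ev.type]
        if ts.last_accept_frame is not None:
            interval = ev.frame - ts.last_accept_frame
            if interval <= config.wp_quiet_multiplier * current_sleeptime(state, ev.type):
                ts.interval_queue.push(interval)
        ts.last_accept_frame = ev.frame
        trail.append((ev.frame, current_sleeptime(state, "TO"), current_sleeptime(state, "HS")))
    return trail


def _merge_events(*streams: list[GaitEvent]) -> list[GaitEvent]:
    merged = [e for s in streams for e in s]
    merged.sort(key=lambda e: (e.frame, _EVENT_RANK[e.type]))
    return merged


@dataclass
class DetectionResult:
    """Full detector output: events plus the curves and decision log."""

    events: list[GaitEvent]
    curves: DgeiCurves
    state: DetectorState

    @property
    def log(self) -> list[dict]:
        return self.state.log


def run_detector(
    signal: GaitSignal,
    dgei: DgeiParams | None = None,
    config: DetectorConfig | None = None,
    full: bool = False,
):
    """Single-pass batch detection: curves -> candidates -> validation -> WS/WP.

    Deterministic (no randomness); returns the ordered event list, or a
    :class:`DetectionResult` when ``full=True``.
    """
    dgei = dgei or DgeiParams()
    config = config or DetectorConfig()
    curves = dgei_curves(signal, dgei)
    cands = candidate_peaks(curves, config.bar)
    merged = sorted(
        [(f, "TO", a) for f, a in cands["TO"]] + [(f, "HS", a) for f, a in cands["HS"]],
        key=lambda c: (c[0], _EVENT_RANK[c[1]]),
    )
    state = DetectorState(config)
    accepted: list[GaitEvent] = []
    trail: list[tuple[int, float, float]] = []
    for cand in merged:
        if validate_event(cand, state):
            frame, etype, amp = cand
            source = "pos_curve" if etype == "TO" else "neg_curve"
            accepted.append(GaitEvent(frame, etype, amp, source))
            trail.append((frame, current_sleeptime(state, "TO"), current_sleeptime(state, "HS")))
    transitions = detect_walk_transitions(accepted, signal, config, trail)
    events = _merge_events(accepted, transitions)
    if full:
        return DetectionResult(events=events, curves=curves, state=state)
    return events


class StreamingDetector:
    """Sample-by-sample detector, event-identical to :func:`run_detector`.

    Feed samples with :meth:`push` (returns events finalized by that
    sample) and call :meth:`finish` at end of stream for trailing
    candidates and a trailing walking-pause.
    """

    def __init__(
        self,
        dgei: DgeiParams | None = None,
        config: DetectorConfig | None = None,
        sample_rate_hz: float = 60.0,
        start_frame: int = 0,
    ):
        self.dgei = dgei or DgeiParams()
        self.config = config or DetectorConfig()
        self.sample_rate_hz = float(sample_rate_hz)
        self.start_frame = int(start_frame)
        self.state = DetectorState(self.config)
        self._values: list[float] = []
        self._prev: float | None = None
        self._m = 0  # number of differences seen
        # running alpha/beta accumulators
        self._s1 = 0.0
        self._s2 = 0.0
        self._sr = 0.0
        self._warned_degenerate = False
        w = self.dgei.window_w
        self._win_pos: deque[float] = deque(maxlen=w + 1)
        self._win_neg: deque[float] = deque(maxlen=w + 1)
        self._track_pos = _PeakTracker(self.config.bar)
        self._track_neg = _PeakTracker(self.config.bar)
        self._pending: list[tuple[int, str, float]] = []
        self._accepted: list[GaitEvent] = []
        self._last_event: GaitEvent | None = None
        self._quiet_span: float = math.inf
        self._wp_pending = False
        self._finished = False

    # -- curve update -------------------------------------------------------
    def _alpha_beta(self, count: int) -> tuple[float, float]:
        if self.dgei.alpha_beta_mode == "fixed":
            return float(self.dgei.fixed_alpha), float(self.dgei.fixed_beta)
        if count <= self.dgei.window_w:
            return 0.5, 0.5
        mean = self._s1 / count
        var = self._s2 / count - mean * mean
        sigma = np.sqrt(np.clip(var, 0.0, None))
        mu = self._sr / count
        denom = sigma + mu
        if denom > 0:
            return float(sigma / denom), float(mu / denom)
        if not self._warned_degenerate:
            self._warned_degenerate = True
        return 0.5, 0.5

    def _curve_point(self, value: float) -> tuple[float, float] | None:
        if self._prev is None:
            self._prev = value
            return None
        d = value - self._prev
        self._prev = value
        r = d * self.sample_rate_hz
        self._m += 1
        self._s1 += d
        self._s2 += d * d
        self._sr += r if self.dgei.signed_rate_mean else abs(r)
        a, b = self._alpha_beta(self._m)
        term = a * d + b * r
        bar = self.dgei.bar
        pos_term = term if d > bar else 0.0
        if self.dgei.indicator_mode == "symmetric":
            neg_term = term if d < -bar else 0.0
        else:
            neg_term = term if d <= bar else 0.0
        self._win_pos.append(pos_term)
        self._win_neg.append(neg_term)
        pos = float(np.sum(np.asarray(self._win_pos)))
        neg = float(np.sum(np.asarray(self._win_neg)))
        return pos, neg

    # -- candidate ordering across the two polarities -----------------------
    def _min_future_frame(self, tracker: _PeakTracker) -> int:
        return tracker.min_future_index + self.start_frame + 1

    def _flush_pending(self, drain: bool) -> list[GaitEvent]:
        out: list[GaitEvent] = []
        self._pending.sort(key=lambda c: (c[0], _EVENT_RANK[c[1]]))
        while self._pending:
            frame, etype, amp = self._pending[0]
            if not drain:
                other = self._track_neg if etype == "TO" else self._track_pos
                other_key = (self._min_future_frame(other), _EVENT_RANK["HS" if etype == "TO" else "TO"])
                if (frame, _EVENT_RANK[etype]) >= other_key:
                    break
            self._pending.pop(0)
            out.extend(self._validate_and_emit((frame, etype, amp)))
        return out

    def _validate_and_emit(self, cand: tuple[int, str, float]) -> list[GaitEvent]:
        out: list[GaitEvent] = []
        if not validate_event(cand, self.state):
            return out
        frame, etype, amp = cand
        source = "pos_curve" if etype == "TO" else "neg_curve"
        ev = GaitEvent(frame, etype, amp, source)
        value = self._values[min(frame - self.start_frame, len(self._values) - 1)]
        if self._last_event is None:
            out.append(GaitEvent(frame, "WS", value, "state_machine"))
        elif frame - self._last_event.frame >= self.config.ws_quiet_frames:
            out.append(GaitEvent(frame, "WS", value, "state_machine"))
        out.append(ev)
        self._accepted.append(ev)
        self._last_event = ev
        st_to = current_sleeptime(self.state, "TO")
        st_hs = current_sleeptime(self.state, "HS")
        self._quiet_span = self.config.wp_quiet_multiplier * max(st_to, st_hs)
        self._wp_pending = True
        return out

    def _check_wp(self, horizon_frame: int) -> list[GaitEvent]:
        """Emit a WP once no unprocessed candidate can precede the WP point."""
        if not self._wp_pending or self._last_event is None:
            return []
        wp_point = self._last_event.frame + self._quiet_span
        if horizon_frame <= wp_point:
            return []
        pending_min = self._pending[0][0] if self._pending else math.inf
        if pending_min <= wp_point:
            return []
        wp_frame = self._last_event.frame + int(round(self._quiet_span))
        value = self._values[min(wp_frame - self.start_frame, len(self._values) - 1)]
        self._wp_pending = False
        return [GaitEvent(wp_frame, "WP", value, "state_machine")]

    # -- public API ---------------------------------------------------------
    def push(self, value: float) -> list[GaitEvent]:
        if self._finished:
            raise ContractError("cannot push after finish()")
        value = float(value)
        if not math.isfinite(value):
            raise InvalidInputError("non-finite sample")
        self._values.append(value)
        out: list[GaitEvent] = []
        point = self._curve_point(value)
        if point is None:
            return out
        pos, neg = point
        j = self._m - 1  # curve index of this point
        frame = j + self.start_frame + 1
        hit_pos = self._track_pos.push(pos)
        if hit_pos is not None:
            self._pending.append((hit_pos[0] + self.start_frame + 1, "TO", hit_pos[1]))
        hit_neg = self._track_neg.push(-neg)
        if hit_neg is not None:
            self._pending.append((hit_neg[0] + self.start_frame + 1, "HS", hit_neg[1]))
        out.extend(self._flush_pending(drain=False))
        horizon = min(
            frame + 1,
            self._min_future_frame(self._track_pos),
            self._min_future_frame(self._track_neg),
        )
        out.extend(self._check_wp(horizon))
        return out

    def finish(self) -> list[GaitEvent]:
        if self._finished:
            return []
        self._finished = True
        out = self._flush_pending(drain=True)
        if self._values and self._last_event is not None and self._wp_pending:
            end_frame = self.start_frame + len(self._values) - 1
            if end_frame - self._last_event.frame > self._quiet_span:
                wp_frame = self._last_event.frame + int(round(self._quiet_span))
                value = self._values[min(wp_frame - self.start_frame, len(self._values) - 1)]
                out.append(GaitEvent(wp_frame, "WP", value, "state_machine"))
        return out

    def run(self, values: Iterable[float]) -> list[GaitEvent]:
        """Convenience: push all samples, finish, return the full stream."""
        events: list[GaitEvent] = []
        for v in values:
            events.extend(self.push(v))
        events.extend(self.finish())
        return events
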