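"""Synthetic single-channel gait signals with ground-truth annotations.

Each gait cycle mimics the sagittal shank-angle morphology the detector is
built for: a brisk push-off rise peaking at toe-off, a slow swing-phase
descent, a sharp two-frame impact transient bottoming out exactly at heel
strike, and a gentle recovery back to baseline.  The asymmetry matters —
steep slopes occur only in the push-off and impact segments, so the
positive and negative accumulator curves each see one steep-slope burst
per cycle, terminating at the annotated extremum.  The waveform family is
otherwise deliberately simple; the detector operates on slope structure,
not waveform identity.

Scenario presets reproduce the qualitative regimes of shank-IMU walking
data: steady locomotion, fast start/stop bouts bracketed by standing,
turning (lower amplitude, quicker push-off), shuffling (low, noisy),
simulated pathological gait (period/amplitude jitter plus attenuated
"dropped" pulses), and static posture (flat baseline with sparse
sub-threshold tremor spikes).

Every generator is fully seeded: the same :class:`ScenarioSpec` yields a
byte-identical :class:`AnnotatedSignal`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detector import GaitEvent, _EVENT_RANK
from .errors import InvalidInputError
from .signal_model import GaitSignal

SCENARIO_KINDS = (
    "standard_locomotion",
    "fast_start_stop",
    "turning",
    "static_posture",
    "shuffling",
    "tremor_pathological",
)

# Scenario presets scale the base spec. `rise_frames` is the push-off
# support; push-off and impact durations are roughly cadence-independent,
# so they do not scale with the period.
_PRESETS: dict[str, dict] = {
    "standard_locomotion": dict(rise_frames=4),
    "fast_start_stop": dict(rise_frames=4, period_mult=0.7, amplitude_mult=1.2,
                            lead_static=120, tail_static=120),
    "turning": dict(rise_frames=3, period_mult=1.1, amplitude_mult=0.75),
    "shuffling": dict(rise_frames=3, period_mult=0.9, amplitude_mult=0.7, noise_mult=2.0),
    "tremor_pathological": dict(rise_frames=4, extra_period_jitter=0.12,
                                extra_amplitude_jitter=0.15, drop_prob=0.10,
                                noise_mult=2.0),
    "static_posture": dict(),
}


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    Defaults describe steady adult walking recorded at 60 Hz: a 60-frame
    (1 s) stride of 30 degrees peak-to-baseline amplitude, mild cycle-to-cycle
    variability and a small amount of sensor noise.  ``tremor_rate`` is the
    expected number of tremor spikes per 100 frames during static spans;
    spikes stay below 0.3x the gait amplitude.
    """

    kind: str = "standard_locomotion"
    n_cycles: int = 20
    period_frames: float = 60.0
    period_jitter: float = 0.02
    amplitude: float = 30.0
    amplitude_jitter: float = 0.05
    noise_sd: float = 0.3
    tremor_rate: float = 2.0
    seed: int = 0
    sample_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise InvalidInputError(f"unknown scenario kind {self.kind!r}")
        if self.period_frames < 4:
            raise InvalidInputError("period_frames must be >= 4")
        if min(self.period_jitter, self.amplitude_jitter, self.noise_sd, self.tremor_rate) < 0:
            raise InvalidInputError("jitters, noise and tremor rate must be >= 0")
        if self.n_cycles < 0:
            raise InvalidInputError("n_cycles must be >= 0")


@dataclass
class AnnotatedSignal:
    """A signal plus its ground-truth events and per-cycle spans."""

    signal: GaitSignal
    truth: list[GaitEvent]
    spec: ScenarioSpec | tuple[ScenarioSpec, ...]
    cycle_spans: list[tuple[int, int]] = field(default_factory=list)

    def truth_frames(self, event_type: str) -> list[int]:
        return [e.frame for e in self.truth if e.type == event_type]


def generate_cycle_waveform(
    period: int,
    amplitude: float,
    rise_frames: int = 4,
    impact_frames: int = 2,
    trough_depth: float = 0.8,
    impact_depth: float = 0.7,
    to_phase: float = 0.30,
    hs_phase: float = 0.65,
) -> tuple[np.ndarray, int, int]:
    """One gait cycle on a zero baseline; returns ``(samples, to_offset, hs_offset)``.

    Morphology, in order: flat baseline; push-off rise (quarter-cosine over
    ``rise_frames``, steepest just before the peak) cresting at the TO
    offset; slow swing descent; a sharp impact drop of ``impact_depth x
    amplitude`` over ``impact_frames`` bottoming out at the HS offset
    (depth ``trough_depth x amplitude`` below baseline); gentle recovery to
    zero.  The returned offsets are the exact argmax/argmin of the emitted
    vector, and endpoints are zero so cycles concatenate continuously.
    """
    period = int(period)
    if period < 4:
        raise InvalidInputError("cycle period must be >= 4 frames")
    to_off = max(1, min(int(round(to_phase * period)), period - 4))
    hs_off = max(to_off + 1, min(max(to_off + 2, int(round(hs_phase * period))), period - 2))
    wr = max(1, min(int(rise_frames), to_off))
    wi = max(1, min(int(impact_frames), hs_off - to_off - 1))
    amp = float(amplitude)
    depth = trough_depth * amp
    impact = impact_depth * amp
    mid_level = impact - depth  # level just before the impact transient
    y = np.zeros(period)
    s = np.arange(1, wr + 1)
    y[to_off - wr + 1 : to_off + 1] = amp * (1.0 - np.cos(np.pi * s / (2.0 * wr)))
    d = hs_off - wi - to_off  # slow-descent span, >= 1 by construction
    s = np.arange(1, d + 1)
    y[to_off + 1 : to_off + d + 1] = amp + (mid_level - amp) * 0.5 * (
        1.0 - np.cos(np.pi * s / d)
    )
    s = np.arange(1, wi + 1)
    y[hs_off - wi + 1 : hs_off + 1] = mid_level - impact * (
        1.0 - np.cos(np.pi * s / (2.0 * wi))
    )
    rec = period - 1 - hs_off
    if rec > 0:
        s = np.arange(1, rec + 1)
        y[hs_off + 1 :] = -depth * 0.5 * (1.0 + np.cos(np.pi * s / rec))
    return y, to_off, hs_off


def _static_segment(rng: np.random.Generator, length: int, gait_amplitude: float,
                    tremor_rate: float) -> np.ndarray:
    """Flat baseline with sparse smooth tremor spikes (< 0.3x gait amplitude)."""
    seg = np.zeros(int(length))
    if length <= 0:
        return seg
    n_spikes = int(rng.poisson(tremor_rate * length / 100.0))
    w = 6
    t = np.arange(w + 1)
    lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / w))
    for _ in range(n_spikes):
        pos = int(rng.integers(0, max(1, length - w - 1)))
        amp = rng.uniform(0.10, 0.25) * gait_amplitude * rng.choice([-1.0, 1.0])
        hi = min(length, pos + w + 1)
        seg[pos:hi] += amp * lobe[: hi - pos]
    return seg


def _transition_truth(
    spans: Sequence[tuple[int, int]], n_frames: int, gap_threshold: float
) -> list[tuple[int, str]]:
    """WS at the first cycle of each walking bout; WP after a bout followed by rest."""
    if not spans:
        return []
    out: list[tuple[int, str]] = []
    bouts: list[list[tuple[int, int]]] = [[spans[0]]]
    for span in spans[1:]:
        if span[0] - bouts[-1][-1][1] - 1 > gap_threshold:
            bouts.append([span])
        else:
            bouts[-1].append(span)
    for i, bout in enumerate(bouts):
        out.append((bout[0][0], "WS"))
        trailing = (n_frames - 1) - bout[-1][1]
        if i + 1 < len(bouts) or trailing >= gap_threshold:
            out.append((bout[-1][1], "WP"))
    return out


def _gap_threshold(spans: Sequence[tuple[int, int]]) -> float:
    lengths = [b - a + 1 for a, b in spans]
    return 2.0 * float(np.median(lengths)) if lengths else 120.0


def generate_scenario(spec: ScenarioSpec) -> AnnotatedSignal:
    """Generate one seeded scenario with TO/HS/WS/WP ground truth."""
    rng = np.random.default_rng(spec.seed)
    preset = _PRESETS[spec.kind]
    if spec.kind == "static_posture":
        n = int(round(spec.n_cycles * spec.period_frames))
        values = _static_segment(rng, n, spec.amplitude, spec.tremor_rate)
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, n)
        sig = GaitSignal(values, spec.sample_rate_hz)
        return AnnotatedSignal(signal=sig, truth=[], spec=spec, cycle_spans=[])

    base_period = spec.period_frames * preset.get("period_mult", 1.0)
    base_amp = spec.amplitude * preset.get("amplitude_mult", 1.0)
    pj = spec.period_jitter + preset.get("extra_period_jitter", 0.0)
    aj = spec.amplitude_jitter + preset.get("extra_amplitude_jitter", 0.0)
    noise_sd = spec.noise_sd * preset.get("noise_mult", 1.0)
    drop_prob = preset.get("drop_prob", 0.0)
    rise_frames = preset.get("rise_frames", 4)

    parts: list[np.ndarray] = []
    spans: list[tuple[int, int]] = []
    gait_truth: list[tuple[int, str]] = []
    offset = 0

    lead = int(preset.get("lead_static", 0))
    if lead:
        parts.append(_static_segment(rng, lead, base_amp, spec.tremor_rate))
        offset += lead
    for _ in range(spec.n_cycles):
        period = int(round(base_period * (1.0 + rng.normal(0.0, pj)))) if pj > 0 else int(round(base_period))
        period = max(6, period)
        amp = base_amp * max(0.1, 1.0 + rng.normal(0.0, aj)) if aj > 0 else base_amp
        if drop_prob and rng.random() < drop_prob:
            amp *= 0.25  # dropped pulse: the step happened, the push-off barely registered
        cycle, to_off, hs_off = generate_cycle_waveform(period, amp, rise_frames=rise_frames)
        gait_truth.append((offset + to_off, "TO"))
        gait_truth.append((offset + hs_off, "HS"))
        spans.append((offset, offset + period - 1))
        parts.append(cycle)
        offset += period
    tail = int(preset.get("tail_static", 0))
    if tail:
        parts.append(_static_segment(rng, tail, base_amp, spec.tremor_rate))
        offset += tail

    values = np.concatenate(parts) if parts else np.zeros(0)
    if spec.noise_sd > 0 and noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.size)
    sig = GaitSignal(values, spec.sample_rate_hz)
    truth_tuples = gait_truth + _transition_truth(spans, values.size, _gap_threshold(spans))
    truth = _as_truth_events(truth_tuples, values)
    return AnnotatedSignal(signal=sig, truth=truth, spec=spec, cycle_spans=spans)


def _as_truth_events(frame_types: list[tuple[int, str]], values: np.ndarray) -> list[GaitEvent]:
    events = [
        GaitEvent(frame, etype, float(values[frame]), "truth")
        for frame, etype in frame_types
    ]
    events.sort(key=lambda e: (e.frame, _EVENT_RANK[e.type]))
    return events


def splice_scenarios(
    specs: Sequence[ScenarioSpec], crossfade_frames: int = 5
) -> AnnotatedSignal:
    """Concatenate scenarios into one continuous stream.

    Segment boundaries are blended over ``crossfade_frames`` (overlap is
    removed from the total length), gait truths are re-offset, and WS/WP
    truths are recomputed globally at walking/static boundaries so that a
    bout spanning a splice point is annotated once.
    """
    specs = list(specs)
    if not specs:
        raise InvalidInputError("splice_scenarios needs at least one spec")
    parts = [generate_scenario(s) for s in specs]
    if len(parts) == 1:
        return parts[0]
    rate = parts[0].signal.sample_rate_hz
    if any(p.signal.sample_rate_hz != rate for p in parts):
        raise InvalidInputError("all spliced scenarios must share a sample rate")
    values = parts[0].signal.values.copy()
    spans = list(parts[0].cycle_spans)
    gait_truth = [(e.frame, e.type) for e in parts[0].truth if e.type in ("TO", "HS")]
    for part in parts[1:]:
        nxt = part.signal.values
        k = max(0, min(int(crossfade_frames), values.size, nxt.size))
        offset = values.size - k
        if k:
            wgt = np.linspace(0.0, 1.0, k)
            blended = values[offset:] * (1.0 - wgt) + nxt[:k] * wgt
            values = np.concatenate([values[:offset], blended, nxt[k:]])
        else:
            values = np.concatenate([values, nxt])
        gait_truth += [
            (e.frame + offset, e.type) for e in part.truth if e.type in ("TO", "HS")
        ]
        spans += [(a + offset, b + offset) for a, b in part.cycle_spans]
    truth_tuples = gait_truth + _transition_truth(spans, values.size, _gap_threshold(spans))
    truth = _as_truth_events(truth_tuples, values)
    sig = GaitSignal(values, rate)
    return AnnotatedSignal(signal=sig, truth=truth, spec=tuple(specs), cycle_spans=spans)
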