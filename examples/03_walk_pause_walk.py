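"""Walking-start / walking-pause detection on a spliced stream.

Splices walk (10 cycles) -> stand (5 s) -> walk (10 cycles) and shows the
detector emitting WS at each bout's first validated event and WP once the
adaptive quiet span elapses after the last event of the first bout.
"""
from dgei import ScenarioSpec, default_profile, run_detector, splice_scenarios

ann = splice_scenarios(
    [
        ScenarioSpec(n_cycles=10, period_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0, seed=1),
        ScenarioSpec(kind="static_posture", n_cycles=5, noise_sd=0.0, tremor_rate=1.0, seed=2),
        ScenarioSpec(n_cycles=10, period_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0, seed=3),
    ]
)
events = run_detector(ann.signal, *default_profile())
gait = [e for e in events if e.type in ("TO", "HS")]
marks = [e for e in events if e.type in ("WS", "WP")]
print(f"{len(ann.signal)} frames, {len(gait)} gait events recovered "
      f"(truth has {sum(e.type in ('TO', 'HS') for e in ann.truth)})")
for e in marks:
    print(f"  frame {e.frame:4d}  t={e.frame / 60:6.2f}s  {e.type}")
# Expected: WS at the first step, WP ~2 strides into the standing span
# (stamped at last_event + quiet span), WS again when walking resumes.
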