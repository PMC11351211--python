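# Methods

## The detection problem

A single inertial sensor strapped to the shank reports the sagittal-plane
tibial orientation at 60 Hz. Within each gait cycle this channel shows one
dominant rise cresting at **toe-off (TO)** and one sharp dip bottoming out at
**heel strike (HS)**; standing spans are flat apart from low-amplitude tremor.
The detector must label TO, HS, **walking start (WS)** and **walking pause
(WP)** causally — one forward pass, no look-ahead beyond the single sample
needed to confirm a local extremum — so that it can drive assistive devices in
real time.

## Slope-accumulator curves

For samples `y_k` at interval `dt = 1/f_s`, each frame contributes a weighted
slope term

    term_k = alpha * dy_k + beta * dy_k / dt,        dy_k = y_k - y_{k-1}

which is routed by an indicator on `dy_k` against a threshold `bar` and summed
over a trailing window `k = i - w .. i` (inclusive, `w + 1` terms):

    pos[i] = sum(term_k * [dy_k >  bar])     (rising-slope accumulator)
    neg[i] = sum(term_k * [dy_k < -bar])     (falling-slope accumulator)

`pos` crests at push-off, `neg` dips at impact. Because the accumulators
integrate *slope*, their extrema never lag the raw waveform's extrema, and lead
them when the final approach to a peak is shallower than `bar` (the
anticipation property tested in the suite).

Two indicator conventions are implemented. `symmetric` (default) routes
`dy < -bar` to the negative accumulator, which matches trough detection.
`verbatim` uses the literal complement `dy <= bar`, so with `bar > 0` small
positive changes land in the negative accumulator; it is retained because the
defining equations can be read either way, and both are exercised by the
brute-force equivalence tests.

### Adaptive weights

`alpha = sigma / (sigma + mu)` and `beta = mu / (sigma + mu)`, where `sigma`
is the standard deviation of the changes and `mu` the mean rate of change, so
`alpha + beta = 1`. Two estimation scopes exist: `fixed` (constants supplied,
for offline replication) and `running` (default), a causal expanding-window
estimate with the first `w` frames pinned at 0.5/0.5. The running mean uses
`|dy/dt|` by default: a signed mean is ~0 on any roughly symmetric signal,
which would collapse `beta`; a `signed_rate_mean` switch restores the literal
reading. A fully degenerate history (`sigma + mu = 0`, e.g. a constant signal)
falls back to 0.5/0.5 with a warning. Window frames before `i = w` use the
growing partial window `0..i` so output exists from the second sample.

## Decision rules

Curve extrema (strict local extrema; plateaus resolve to their first frame;
magnitude must exceed the `bar` baseline) become candidates, then pass three
rules:

1. **Alternation** — HS and TO alternate within a cycle; a same-type repeat
   with no opposite-type event between is rejected (`soft`; `off` available
   for irregular gaits where whole events drop out).
2. **Adaptive refractory ("sleep time")** — after an accepted event,
   same-type candidates are suppressed. The cadence estimate is the weighted
   mean of a length-`q` FIFO of recent same-type inter-candidate intervals,
   with positional weights 1..q favouring the newest entry; it is seeded with
   `sleeptime0` while empty and floored at `sleeptime0 / 2` so it cannot
   collapse onto noise.
3. **Adaptive amplitude threshold** — a candidate must reach
   `threshold_fraction` (default 60 %) of the weighted mean of recently
   *accepted* peak amplitudes of its type; `threshold0 = 0` seeds the queue so
   the first peak cannot deadlock the cold start.

Two deliberate refinements to the plain rules, both load-bearing:

* **Enforced gap = 90 % of the cadence estimate** (`refractory_fraction`).
  A refractory equal to the *mean* stride interval would reject roughly half
  of all strides under natural zero-mean cadence jitter, since an interval
  falls below its own running mean with probability ~0.5. The enforced gap is
  therefore the minimum plausible stride — 90 % of the estimate — which
  tolerates the 2–4 % cadence variability of healthy gait while still
  suppressing double-fires (measured on the default noisy scenarios: 92–100 %
  detection vs ~68 % with the fraction at 1.0).
* **Cadence learns from threshold-passing candidates, not only accepted
  events, and ignores pause-length gaps.** If only accepted intervals fed the
  queue, a cadence increase could never be learned: faster candidates are
  sleep-rejected, so accepted intervals never shrink below the refractory in
  force (positive feedback at the old cadence). Candidates that clear the
  amplitude threshold therefore update the interval queue even when the
  refractory rejects them. Conversely, an inter-candidate gap longer than the
  walking-pause quiet span is a pause, not a stride, and is excluded —
  otherwise one standing span inflates the refractory enough to drop several
  strides at every restart.

### Walking start / pause

WS is stamped at the first validated gait event of a bout: at the first event
of the stream (stream start counts as quiescence) and at any event following a
gap of at least `ws_quiet_frames` (default 120 frames = 2 s). WP is stamped at
`last_event_frame + span` once no validated event arrives within
`span = wp_quiet_multiplier x max(TO, HS cadence estimate)` (default 2x, i.e.
about two missing strides). Sub-threshold tremor during standing produces no
candidates at all under the default `bar`, so quiescence is never broken by
noise. These stamping conventions are package conventions — fixed, documented,
and tested — rather than biomechanical claims.

### Streaming = batch

`StreamingDetector` consumes one sample at a time and reproduces the batch
event list exactly: terms are formed once per frame with the weights current
at that frame, window sums and running statistics use the same accumulation
order as the vectorized batch path, extrema are confirmed with a one-sample
delay, and candidates from the two polarities are released to validation in
frame order using each tracker's lower bound on future peak frames. The
equivalence is asserted on clean, spliced and pathological fixtures and on 10
random configurations.

## Evaluation metrics

Detected and truth frames are paired one-to-one within a tolerance. Because
both lists are sorted, an optimal matching (maximum pairs, then minimum total
absolute error) can be chosen non-crossing; a dynamic program finds it in
O(n·m), and tests verify equality with an independent assignment solver and
an exhaustive small-n oracle. Reported columns:

* **detection rate** — matched-truth percentage at ±5 frames;
* **sensitivity** — `100·TP/(TP+FN)` at a stricter ±3 frames (the two
  tolerances are separate flags; the stricter one reflects the ~3-frame error
  range of correct detections);
* **average difference** — mean |frame error| over matched pairs (0 for an
  empty pair set; scenarios with no positives report 0.00 by convention);
* **MCC** — Matthews correlation from (TP, FP, TN, FN), 0 when a denominator
  factor vanishes. True negatives are ill-defined for sparse point events;
  the convention here partitions the recording into gait-cycle-sized bins
  (median same-type inter-truth interval; 60 frames when fewer than two
  truths) and counts bins containing neither truth nor detection. A fully
  continuous walk therefore has TN ~ 0 and an MCC near 0 even at perfect
  detection — MCC is informative only for recordings containing quiet spans,
  which is where false positives live.

## Synthetic gait generator

No public recordings accompany the method, so the generator is the package's
data source and defines its study conditions. Defaults model steady adult
walking at 60 Hz: 60-frame (1 s) stride, 30° amplitude, 2 % period CV, 5 %
amplitude CV, 0.3° Gaussian sensor noise. Each cycle is piecewise-cosine and
deliberately asymmetric, mirroring where steep slopes live in real shank
signals: a 4-frame push-off rise cresting at the TO annotation, a slow swing
descent, a 2-frame impact transient (70 % of amplitude) bottoming out exactly
at the HS annotation (depth 80 % of amplitude), and a gentle recovery to
baseline. Scenario presets rescale this template: fast start/stop (0.7x
period, 1.2x amplitude, standing spans fore and aft), turning (1.1x period,
0.75x amplitude, quicker push-off), shuffling (0.7x amplitude, doubled
noise), pathological (12 % period and 15 % amplitude jitter added, 10 % of
push-offs attenuated to 25 %, doubled noise), and static posture (flat
baseline plus sparse tremor spikes below 0.3x gait amplitude). Every cycle is
annotated even when its push-off is attenuated — the step occurred; the
sensor barely saw it — which is precisely what degrades detection in the
pathological preset (~44 % under defaults). Splicing concatenates scenarios
with a 5-frame cross-fade and recomputes WS/WP truths globally from
walking-bout boundaries (bout gap threshold: twice the median cycle length).

What the generator does **not** emulate: multi-axis coupling, orientation
drift, soft-tissue artefact, inter-subject morphology differences, or real
pathological waveforms. Passing the closed-loop tests shows the detector's
rules behave as specified on signals with the assumed slope structure; it is
not clinical validation.

## Hyperparameter surfaces

The tuner exhaustively evaluates `sleeptime` 0–100 by `bar` 0–30 (step 1,
3131 cells; ranges and steps configurable), scoring each cell per event type
and combined. It reports per-metric optima, 1-D profiles, a Pareto set (no
scalarization is imposed across metrics), and a coupling summary: the maximum
absolute first difference of each surface along each axis, plus the size of
the 4-connected region within 1 % of the optimum. One structural note: on any
input, sensitivity at `sleeptime = 0` is never below sensitivity at larger
seeds, because a refractory can only suppress detections and false positives
do not enter sensitivity — so the sensitivity-optimal band always reaches
down to 0 and is bounded above near the stride period. MCC, which false
positives do punish, is the metric that penalizes an absent refractory.

## Numerical and convention notes

* Frames are 0-based; `time_s = frame / sample_rate_hz`; uniform sampling is
  required (irregular timestamps are rejected, not resampled).
* `dt` is constant `1/f_s`; the rate term is exactly `f_s · dy`.
* Population (ddof = 0) standard deviation in the weight estimate.
* Candidate baseline and curve indicator share the single `bar`
  hyperparameter; both stages are thresholded as printed.
* Plateau extrema resolve to the plateau's first frame (earliest causal
  commitment); events tied on a frame order WP < WS < TO < HS.
* The default profile (sleeptime 60, bar 9, fraction 0.6, q 5, w 10) is the
  published operating point for 60 Hz shank data; an alternative reading of
  the source gives bar 6, which sits inside the same broad optimum plateau.
* Test problem sizes (20–25 cycles per scenario, 200-frame grid fixture,
  500–1000 randomized oracle instances) were chosen so the full suite
  completes in well under a minute while every code path is exercised.

## Known limitations

* HS is detected on the negative accumulator only; signals whose heel-strike
  signature is a raw-channel trough without a steep approach slope will be
  missed at high `bar`.
* The alternation rule propagates single misses: a lost TO also rejects the
  following HS in `soft` mode (use `off` for gaits with frequent dropouts).
* WS/WP logic is a quiescence heuristic with fixed stamping conventions, not
  a learned gait-initiation model.
* MCC depends on the TN binning convention described above and is not
  comparable across different bin choices.
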