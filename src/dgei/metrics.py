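"""Evaluation of detected events against ground-truth annotations.

Detected and true event frames are paired one-to-one under a frame
tolerance (±5 by default).  Because both lists are sorted, an optimal
matching (maximum number of pairs, then minimum total |error|) can always
be chosen non-crossing, which a dynamic program finds in O(n·m).

From the matching we report the conventional table columns:

* detection rate  — percentage of truth events with a match (±5 frames),
* sensitivity     — TP / (TP + FN) under a stricter ±3-frame match,
* average difference — mean absolute frame error over matched pairs,
* MCC             — Matthews correlation coefficient; the true-negative
  count, ill-defined for sparse point events, is taken over gait-cycle-sized
  frame bins containing neither a truth nor a detection.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .detector import GaitEvent
from .errors import ContractError, InvalidInputError

DEFAULT_TOLERANCE = 5
DEFAULT_SENSITIVITY_TOLERANCE = 3


@dataclass
class MatchResult:
    """One-to-one pairing of truth and detected frames within a tolerance."""

    pairs: list[tuple[int, int]]
    tp: int
    fp: int
    fn: int
    tn: int = 0
    tolerance_frames: int = DEFAULT_TOLERANCE

    @property
    def errors(self) -> list[int]:
        """Signed frame errors, detected minus truth."""
        return [d - t for t, d in self.pairs]


def match_events(truth, detected, tolerance: int = DEFAULT_TOLERANCE) -> MatchResult:
    """Optimal one-to-one matching of sorted frame lists within ``tolerance``.

    Maximizes the number of matched pairs, then minimizes the total
    absolute error; ties resolve deterministically (preferring a match,
    then consuming the earlier detected frame).  Unmatched truths count as
    FN, unmatched detections as FP.  Raises :class:`ContractError` on
    unsorted input.
    """
    t = [int(x) for x in truth]
    d = [int(x) for x in detected]
    if any(b < a for a, b in zip(t, t[1:])) or any(b < a for a, b in zip(d, d[1:])):
        raise ContractError("truth and detected frames must be sorted ascending")
    if tolerance < 0:
        raise InvalidInputError("tolerance must be >= 0")
    n, m = len(t), len(d)
    # DP over prefixes: best (tp, -total_error) lexicographically.
    tp_tab = np.zeros((n + 1, m + 1), dtype=np.int64)
    er_tab = np.zeros((n + 1, m + 1), dtype=float)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 skip truth, 1 skip det, 2 match
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            best_tp, best_er, best_mv = tp_tab[i - 1][j], er_tab[i - 1][j], 0
            if j >= 1:
                cand = (tp_tab[i][j - 1], er_tab[i][j - 1], 1)
                if (cand[0], -cand[1]) > (best_tp, -best_er):
                    best_tp, best_er, best_mv = cand
                err = abs(t[i - 1] - d[j - 1])
                if err <= tolerance:
                    cand = (tp_tab[i - 1][j - 1] + 1, er_tab[i - 1][j - 1] + err, 2)
                    if (cand[0], -cand[1]) >= (best_tp, -best_er):
                        best_tp, best_er, best_mv = cand
            tp_tab[i][j], er_tab[i][j], move[i][j] = best_tp, best_er, best_mv
    # first row: only skipping detections
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j >= 0:
        mv = move[i][j]
        if mv == 2:
            pairs.append((t[i - 1], d[j - 1]))
            i, j = i - 1, j - 1
        elif mv == 1:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    tp = len(pairs)
    return MatchResult(
        pairs=pairs,
        tp=tp,
        fp=m - tp,
        fn=n - tp,
        tolerance_frames=int(tolerance),
    )


def sensitivity(tp: int, fn: int) -> float:
    """True positive rate in percent; NaN when no positives exist."""
    if tp < 0 or fn < 0:
        raise InvalidInputError("counts must be non-negative")
    if tp + fn == 0:
        return math.nan
    return 100.0 * tp / (tp + fn)


def average_difference(pairs) -> float:
    """Mean absolute frame error over matched pairs (0 for an empty set)."""
    if len(pairs) == 0:
        return 0.0
    return float(np.mean([abs(t - d) for t, d in pairs]))


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if min(tp, fp, tn, fn) < 0:
        raise InvalidInputError("counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def detection_rate(n_matched: int, n_truth: int) -> float:
    """Percentage of truth events with a match; 0.00 for an empty truth set."""
    if n_matched < 0 or n_truth < 0:
        raise InvalidInputError("counts must be non-negative")
    if n_truth == 0:
        return 0.0
    if n_matched > n_truth:
        raise InvalidInputError("matched count cannot exceed truth count")
    return 100.0 * n_matched / n_truth


def error_histogram(pairs) -> tuple[dict[int, int], float]:
    """Counts of signed frame errors (detected - truth) and the zero-error fraction."""
    errors = [d - t for t, d in pairs]
    hist = dict(sorted(Counter(errors).items()))
    zero_fraction = hist.get(0, 0) / len(errors) if errors else 0.0
    return hist, zero_fraction


def count_true_negatives(
    truth,
    detected,
    n_frames: int,
    bin_frames: int | None = None,
) -> int:
    """Event-free frame bins, the negative universe used for MCC.

    ``bin_frames`` defaults to the median inter-truth interval (one gait
    cycle), falling back to 60 frames when fewer than two truths exist.
    """
    if n_frames <= 0:
        return 0
    truth = np.asarray(list(truth), dtype=int)
    detected = np.asarray(list(detected), dtype=int)
    if bin_frames is None:
        bin_frames = int(np.median(np.diff(truth))) if truth.size >= 2 else 60
    bin_frames = max(1, int(bin_frames))
    n_bins = max(1, math.ceil(n_frames / bin_frames))
    occupied = set()
    for f in np.concatenate([truth, detected]):
        occupied.add(min(int(f) // bin_frames, n_bins - 1))
    return n_bins - len(occupied)


@dataclass
class EvalReport:
    """Per-scenario evaluation summary mirroring the standard table columns."""

    scenario: str
    n_truth: int
    n_detected: int
    detection_rate: float
    sensitivity: float
    average_difference: float
    mcc: float
    error_histogram: dict[int, int] = field(default_factory=dict)
    zero_error_fraction: float = 0.0
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    tolerance_frames: int = DEFAULT_TOLERANCE
    sensitivity_tolerance_frames: int = DEFAULT_SENSITIVITY_TOLERANCE

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "scenario", "n_truth", "n_detected", "detection_rate", "sensitivity",
            "average_difference", "mcc", "zero_error_fraction",
            "tp", "fp", "fn", "tn", "tolerance_frames", "sensitivity_tolerance_frames",
        )}
        d["error_histogram"] = {str(k): v for k, v in self.error_histogram.items()}
        return d


def evaluate_frames(
    truth,
    detected,
    n_frames: int | None = None,
    scenario: str = "",
    tolerance: int = DEFAULT_TOLERANCE,
    sensitivity_tolerance: int = DEFAULT_SENSITIVITY_TOLERANCE,
    bin_frames: int | None = None,
) -> EvalReport:
    """Evaluate one event type: match, then compute the table columns.

    The detection rate uses the ±``tolerance`` matching; sensitivity uses
    the stricter ±``sensitivity_tolerance`` matching.  When no positives
    exist, sensitivity is reported as 0.00 (the empty-scenario convention).
    """
    truth = sorted(int(x) for x in truth)
    detected = sorted(int(x) for x in detected)
    m_loose = match_events(truth, detected, tolerance)
    m_strict = match_events(truth, detected, sensitivity_tolerance)
    tn = count_true_negatives(truth, detected, n_frames, bin_frames) if n_frames else 0
    sens = sensitivity(m_strict.tp, m_strict.fn)
    hist, zero_frac = error_histogram(m_loose.pairs)
    return EvalReport(
        scenario=scenario,
        n_truth=len(truth),
        n_detected=len(detected),
        detection_rate=detection_rate(m_loose.tp, len(truth)),
        sensitivity=0.0 if math.isnan(sens) else sens,
        average_difference=average_difference(m_loose.pairs),
        mcc=mcc(m_loose.tp, m_loose.fp, tn, m_loose.fn),
        error_histogram=hist,
        zero_error_fraction=zero_frac,
        tp=m_loose.tp,
        fp=m_loose.fp,
        fn=m_loose.fn,
        tn=tn,
        tolerance_frames=tolerance,
        sensitivity_tolerance_frames=sensitivity_tolerance,
    )


def evaluate_events(
    truth: list[GaitEvent],
    detected: list[GaitEvent],
    n_frames: int | None = None,
    types: tuple[str, ...] = ("TO", "HS"),
    scenario: str = "",
    tolerance: int = DEFAULT_TOLERANCE,
    sensitivity_tolerance: int = DEFAULT_SENSITIVITY_TOLERANCE,
) -> dict[str, EvalReport]:
    """Per-type reports plus a ``combined`` report pooling all listed types."""
    out: dict[str, EvalReport] = {}
    for etype in types:
        out[etype] = evaluate_frames(
            [e.frame for e in truth if e.type == etype],
            [e.frame for e in detected if e.type == etype],
            n_frames=n_frames,
            scenario=f"{scenario}/{etype}" if scenario else etype,
            tolerance=tolerance,
            sensitivity_tolerance=sensitivity_tolerance,
        )
    reports = list(out.values())
    pooled_pairs = sum(r.tp for r in reports)
    combined = EvalReport(
        scenario=f"{scenario}/combined" if scenario else "combined",
        n_truth=sum(r.n_truth for r in reports),
        n_detected=sum(r.n_detected for r in reports),
        detection_rate=detection_rate(pooled_pairs, sum(r.n_truth for r in reports)),
        sensitivity=float(np.mean([r.sensitivity for r in reports])) if reports else 0.0,
        average_difference=(
            sum(r.average_difference * r.tp for r in reports) / pooled_pairs
            if pooled_pairs else 0.0
        ),
        mcc=mcc(
            sum(r.tp for r in reports),
            sum(r.fp for r in reports),
            sum(r.tn for r in reports),
            sum(r.fn for r in reports),
        ),
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
        tn=sum(r.tn for r in reports),
        tolerance_frames=tolerance,
        sensitivity_tolerance_frames=sensitivity_tolerance,
    )
    out["combined"] = combined
    return out
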