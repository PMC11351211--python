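"""Slope-accumulator curves for gait event detection.

The detector consumes a single sagittal-plane tibial orientation channel
sampled uniformly (nominally 60 Hz).  Each frame-to-frame change
``dy_k = y_k - y_{k-1}`` contributes a weighted slope term

    term_k = alpha * dy_k + beta * dy_k / dt_k

where ``dt_k`` is the (constant) sampling interval.  Terms are routed by the
sign of ``dy_k`` relative to a threshold ``bar`` and summed over a trailing
window of ``w + 1`` frames (``k = i - w .. i``, both ends inclusive),
producing two curves:

* the *positive* curve accumulates rising-slope terms and peaks with the
  toe-off push of each gait cycle;
* the *negative* curve accumulates falling-slope terms and dips with the
  heel-strike impact.

``alpha`` and ``beta`` balance raw change against rate of change.  They are
estimated from the signal itself as ``alpha = sigma / (sigma + mu)`` and
``beta = mu / (sigma + mu)``, with ``sigma`` the standard deviation of the
changes and ``mu`` the mean rate of change, so ``alpha + beta = 1``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidInputError

IndicatorMode = Literal["symmetric", "verbatim"]
AlphaBetaMode = Literal["running", "fixed"]

#: Default trailing-window length in frames (~167 ms at 60 Hz).
DEFAULT_WINDOW_W = 10


@dataclass
class GaitSignal:
    """A uniformly sampled single-channel gait series.

    Parameters
    ----------
    values
        Angle samples in degrees (or angular velocity in deg/s; the detector
        only relies on slope structure).
    sample_rate_hz
        Sampling rate, > 0. Default 60 Hz.
    start_frame
        0-based frame index of the first sample, used when a recording is a
        slice of a longer stream.
    """

    values: np.ndarray
    sample_rate_hz: float = 60.0
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("signal values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise InvalidInputError(
                f"non-finite sample at frame {bad + self.start_frame}"
            )
        if not self.sample_rate_hz > 0:
            raise InvalidInputError("sample_rate_hz must be positive")
        self.start_frame = int(self.start_frame)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sample_rate_hz

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.values.size) + self.start_frame

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds (``frame / sample_rate_hz``)."""
        return self.frames / self.sample_rate_hz


@dataclass
class DgeiParams:
    """Parameters of the slope-accumulator curves.

    ``indicator_mode`` selects how the negative branch fires: ``symmetric``
    (default) routes ``dy < -bar`` to the negative accumulator, matching the
    trough-detection intent; ``verbatim`` routes ``dy <= bar``, the literal
    complement of the positive branch.  ``alpha_beta_mode='running'`` uses a
    causal expanding-window estimate of alpha/beta (first ``window_w`` frames
    fall back to 0.5/0.5); ``'fixed'`` uses the supplied constants.
    ``signed_rate_mean`` controls whether the mean rate of change is taken
    over signed values (can be ~0 on symmetric signals) or magnitudes
    (default).
    """

    window_w: int = DEFAULT_WINDOW_W
    bar: float = 9.0
    alpha_beta_mode: AlphaBetaMode = "running"
    fixed_alpha: float | None = None
    fixed_beta: float | None = None
    indicator_mode: IndicatorMode = "symmetric"
    signed_rate_mean: bool = False

    def __post_init__(self) -> None:
        if int(self.window_w) < 1:
            raise InvalidInputError("window_w must be >= 1")
        self.window_w = int(self.window_w)
        if self.bar < 0:
            raise InvalidInputError("bar must be non-negative")
        if self.alpha_beta_mode not in ("running", "fixed"):
            raise InvalidInputError(f"unknown alpha_beta_mode {self.alpha_beta_mode!r}")
        if self.indicator_mode not in ("symmetric", "verbatim"):
            raise InvalidInputError(f"unknown indicator_mode {self.indicator_mode!r}")
        if self.alpha_beta_mode == "fixed":
            if self.fixed_alpha is None or self.fixed_beta is None:
                raise InvalidInputError("fixed mode requires fixed_alpha and fixed_beta")
            if abs(self.fixed_alpha + self.fixed_beta - 1.0) > 1e-9:
                raise InvalidInputError("fixed_alpha + fixed_beta must equal 1")


@dataclass
class DgeiCurves:
    """Per-frame curve outputs.

    All arrays have length ``n - 1`` for an ``n``-sample signal; index ``j``
    corresponds to raw frame ``j + frame_offset`` (differences are defined
    from the second sample on).
    """

    diff: np.ndarray
    rate: np.ndarray
    pos: np.ndarray
    neg: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    frame_offset: int
    sample_rate_hz: float = 60.0

    def __len__(self) -> int:
        return self.diff.size

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.diff.size) + self.frame_offset

    def as_dataframe(self):
        """Columns ``frame, diff, rate, pos, neg, alpha, beta``."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frames,
                "diff": self.diff,
                "rate": self.rate,
                "pos": self.pos,
                "neg": self.neg,
                "alpha": self.alpha,
                "beta": self.beta,
            }
        )


def first_difference(signal: GaitSignal) -> np.ndarray:
    """Per-frame change ``dy_k = y_k - y_{k-1}``, length ``n - 1``."""
    if len(signal) < 2:
        raise InvalidInputError("first_difference requires at least 2 samples")
    return np.diff(signal.values)


def indicator(delta_y: float, bar: float, mode: IndicatorMode = "symmetric") -> tuple[int, int]:
    """Branch indicators ``(positive, negative)`` for one change value.

    The positive branch fires iff ``delta_y > bar`` in both modes.  The
    negative branch fires iff ``delta_y < -bar`` (symmetric) or
    ``delta_y <= bar`` (verbatim).
    """
    if bar < 0:
        raise InvalidInputError("bar must be non-negative")
    pos = 1 if delta_y > bar else 0
    if mode == "symmetric":
        neg = 1 if delta_y < -bar else 0
    elif mode == "verbatim":
        neg = 1 if delta_y <= bar else 0
    else:
        raise InvalidInputError(f"unknown indicator mode {mode!r}")
    return pos, neg


def adaptive_weights(
    diff_history: np.ndarray,
    rate_history: np.ndarray,
    signed_mean: bool = False,
) -> tuple[float, float]:
    """Estimate ``(alpha, beta)`` from change and rate histories.

    ``alpha = sigma / (sigma + mu)`` and ``beta = mu / (sigma + mu)`` where
    ``sigma`` is the population standard deviation of ``diff_history`` and
    ``mu`` the mean of ``|rate_history|`` (or of the signed values when
    ``signed_mean``).  Degenerate histories (``sigma + mu == 0``, e.g. a
    constant signal) fall back to 0.5/0.5 with a warning.
    """
    diff_history = np.asarray(diff_history, dtype=float)
    rate_history = np.asarray(rate_history, dtype=float)
    if diff_history.size == 0 or diff_history.size != rate_history.size:
        raise InvalidInputError("histories must be non-empty and the same length")
    sigma = float(np.std(diff_history))
    mu = float(np.mean(rate_history if signed_mean else np.abs(rate_history)))
    denom = sigma + mu
    if denom <= 0:
        warnings.warn(
            "sigma + mu is zero (degenerate history); falling back to alpha = beta = 0.5",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.5, 0.5
    return sigma / denom, mu / denom


def _running_alpha_beta(
    diff: np.ndarray, rate: np.ndarray, window_w: int, signed_mean: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Causal expanding-window alpha/beta, warm-up of ``window_w`` frames."""
    m = diff.size
    idx = np.arange(1, m + 1, dtype=float)
    s1 = np.cumsum(diff)
    s2 = np.cumsum(diff * diff)
    mean = s1 / idx
    var = s2 / idx - mean * mean
    sigma = np.sqrt(np.clip(var, 0.0, None))
    mu = np.cumsum(rate if signed_mean else np.abs(rate)) / idx
    denom = sigma + mu
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(denom > 0, sigma / denom, 0.5)
        beta = np.where(denom > 0, mu / denom, 0.5)
    alpha[: min(window_w, m)] = 0.5
    beta[: min(window_w, m)] = 0.5
    return alpha, beta


def _window_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Trailing sum over ``w + 1`` terms with a growing partial window."""
    m = x.size
    out = np.empty(m, dtype=float)
    head = min(w, m)
    for j in range(head):
        out[j] = x[: j + 1].sum()
    if m > w:
        out[w:] = sliding_window_view(x, w + 1).sum(axis=1)
    return out


def dgei_curves(signal: GaitSignal, params: DgeiParams | None = None) -> DgeiCurves:
    """Compute the positive/negative slope-accumulator curves.

    Frames before the window fills use a growing partial window so the
    output is defined (and causal) from the second sample onward.  In
    running alpha/beta mode the weights at frame ``k`` are estimated from
    all changes seen up to and including ``k``; each term is formed once
    with the weights current at its own frame.
    """
    params = params or DgeiParams()
    w = params.window_w
    if len(signal) < w + 1:
        raise InvalidInputError(
            f"signal too short: need at least window_w + 1 = {w + 1} samples, got {len(signal)}"
        )
    diff = np.diff(signal.values)
    rate = diff * signal.sample_rate_hz
    if params.alpha_beta_mode == "fixed":
        alpha = np.full(diff.size, float(params.fixed_alpha))
        beta = np.full(diff.size, float(params.fixed_beta))
    else:
        alpha, beta = _running_alpha_beta(diff, rate, w, params.signed_rate_mean)
    terms = alpha * diff + beta * rate
    pos_mask = diff > params.bar
    if params.indicator_mode == "symmetric":
        neg_mask = diff < -params.bar
    else:
        neg_mask = diff <= params.bar
    pos = _window_sum(np.where(pos_mask, terms, 0.0), w)
    neg = _window_sum(np.where(neg_mask, terms, 0.0), w)
    return DgeiCurves(
        diff=diff,
        rate=rate,
        pos=pos,
        neg=neg,
        alpha=alpha,
        beta=beta,
        frame_offset=signal.start_frame + 1,
        sample_rate_hz=signal.sample_rate_hz,
    )
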