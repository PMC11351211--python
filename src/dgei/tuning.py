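"""Grid search over the *sleeptime* and *bar* hyperparameters.

``sleeptime`` seeds the adaptive refractory span (frames, default range
0–100) and ``bar`` the slope threshold / candidate baseline (default range
0–30), both stepped by 1.  Every cell runs the detector on one annotated
signal and scores it with sensitivity, average difference and MCC per event
type; the result exposes 1-D profiles, 2-D surfaces, per-metric optima, a
Pareto set, and a smoothness/coupling summary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .detector import DetectorConfig, run_detector
from .errors import InvalidInputError
from .metrics import evaluate_events
from .signal_model import DgeiParams
from .synth import AnnotatedSignal

METRICS = ("sensitivity", "average_difference", "mcc")
#: metrics where smaller is better
_MINIMIZE = {"average_difference"}


@dataclass
class GridSpec:
    """Inclusive integer grids for the two hyperparameters."""

    sleeptime_values: np.ndarray = field(default_factory=lambda: np.arange(0, 101))
    bar_values: np.ndarray = field(default_factory=lambda: np.arange(0, 31))
    metrics: tuple[str, ...] = METRICS

    def __post_init__(self) -> None:
        self.sleeptime_values = np.asarray(self.sleeptime_values, dtype=int)
        self.bar_values = np.asarray(self.bar_values, dtype=int)
        if self.sleeptime_values.size == 0 or self.bar_values.size == 0:
            raise InvalidInputError("grid ranges must be non-empty")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise InvalidInputError(f"unknown metrics {sorted(unknown)}")

    @classmethod
    def from_ranges(cls, sleeptime=(0, 100, 1), bar=(0, 30, 1), metrics=METRICS):
        s0, s1, ss = sleeptime
        b0, b1, bs = bar
        if ss <= 0 or bs <= 0:
            raise InvalidInputError("grid steps must be positive")
        return cls(np.arange(s0, s1 + 1, ss), np.arange(b0, b1 + 1, bs), tuple(metrics))

    @property
    def n_cells(self) -> int:
        return self.sleeptime_values.size * self.bar_values.size


@dataclass
class GridResult:
    """Exhaustive grid evaluation: long table, per-metric surfaces and optima."""

    table: pd.DataFrame
    sleeptime_values: np.ndarray
    bar_values: np.ndarray
    event_types: tuple[str, ...]
    metrics: tuple[str, ...]
    surfaces: dict[str, dict[str, np.ndarray]]
    best: dict[str, dict]

    def pareto_front(self) -> pd.DataFrame:
        """Cells not dominated on (sensitivity up, MCC up, average difference down)."""
        s = self.table["sensitivity_combined"].to_numpy()
        m = self.table["mcc_combined"].to_numpy()
        a = self.table["average_difference_combined"].to_numpy()
        n = len(s)
        dominated = np.zeros(n, dtype=bool)
        ge = (s[:, None] >= s[None, :]) & (m[:, None] >= m[None, :]) & (a[:, None] <= a[None, :])
        gt = (s[:, None] > s[None, :]) | (m[:, None] > m[None, :]) | (a[:, None] < a[None, :])
        dominated = np.any(ge & gt, axis=0)
        return self.table[~dominated].reset_index(drop=True)


def _evaluate_cell(
    annotated: AnnotatedSignal,
    sleeptime: int,
    bar: int,
    base_config: DetectorConfig,
    base_params: DgeiParams,
    event_types: tuple[str, ...],
    tolerance: int,
    sensitivity_tolerance: int,
) -> dict:
    config = replace(base_config, sleeptime0=int(sleeptime), bar=float(bar), sleep_floor=None)
    params = replace(base_params, bar=float(bar))
    events = run_detector(annotated.signal, params, config)
    reports = evaluate_events(
        annotated.truth,
        events,
        n_frames=len(annotated.signal),
        types=event_types,
        tolerance=tolerance,
        sensitivity_tolerance=sensitivity_tolerance,
    )
    row: dict = {"sleeptime": int(sleeptime), "bar": int(bar)}
    for etype in (*event_types, "combined"):
        rep = reports[etype]
        row[f"sensitivity_{etype}"] = rep.sensitivity
        row[f"average_difference_{etype}"] = rep.average_difference
        row[f"mcc_{etype}"] = rep.mcc
        row[f"detection_rate_{etype}"] = rep.detection_rate
    return row


def grid_search(
    annotated: AnnotatedSignal,
    grid: GridSpec | None = None,
    base_config: DetectorConfig | None = None,
    base_params: DgeiParams | None = None,
    event_types: tuple[str, ...] = ("TO", "HS"),
    tolerance: int = 5,
    sensitivity_tolerance: int = 3,
    n_jobs: int = 1,
) -> GridResult:
    """Evaluate every (sleeptime, bar) cell; deterministic and order-independent.

    ``n_jobs`` > 1 evaluates cells in parallel (joblib) with results
    identical to the serial run.
    """
    grid = grid or GridSpec()
    base_config = base_config or DetectorConfig()
    base_params = base_params or DgeiParams()
    if not any(annotated.truth_frames(t) for t in event_types):
        raise InvalidInputError("annotated truth is empty for all requested event types")
    cells = [(int(s), int(b)) for s in grid.sleeptime_values for b in grid.bar_values]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(_evaluate_cell)(annotated, s, b, base_config, base_params,
                                    event_types, tolerance, sensitivity_tolerance)
            for s, b in cells
        )
    else:
        rows = [
            _evaluate_cell(annotated, s, b, base_config, base_params,
                           event_types, tolerance, sensitivity_tolerance)
            for s, b in cells
        ]
    table = pd.DataFrame(rows)
    n_s, n_b = grid.sleeptime_values.size, grid.bar_values.size
    surfaces: dict[str, dict[str, np.ndarray]] = {}
    for metric in grid.metrics:
        surfaces[metric] = {
            etype: table[f"{metric}_{etype}"].to_numpy().reshape(n_s, n_b)
            for etype in (*event_types, "combined")
        }
    best: dict[str, dict] = {}
    for metric in grid.metrics:
        col = table[f"{metric}_combined"]
        idx = int(col.idxmin() if metric in _MINIMIZE else col.idxmax())
        best[metric] = table.iloc[idx].to_dict()
    return GridResult(
        table=table,
        sleeptime_values=grid.sleeptime_values,
        bar_values=grid.bar_values,
        event_types=tuple(event_types),
        metrics=tuple(grid.metrics),
        surfaces=surfaces,
        best=best,
    )


def profile_1d(result: GridResult, axis: str, fixed_other: int) -> pd.DataFrame:
    """Slice the table along one hyperparameter with the other held fixed."""
    if axis == "sleeptime":
        if fixed_other not in set(result.bar_values.tolist()):
            raise InvalidInputError(f"bar={fixed_other} not in the evaluated grid")
        out = result.table[result.table["bar"] == fixed_other].sort_values("sleeptime")
    elif axis == "bar":
        if fixed_other not in set(result.sleeptime_values.tolist()):
            raise InvalidInputError(f"sleeptime={fixed_other} not in the evaluated grid")
        out = result.table[result.table["sleeptime"] == fixed_other].sort_values("bar")
    else:
        raise InvalidInputError("axis must be 'sleeptime' or 'bar'")
    return out.reset_index(drop=True)


def coupling_report(result: GridResult, event_type: str = "combined") -> dict[str, dict]:
    """Surface smoothness and optimum-region summary per metric.

    Smoothness is the maximum absolute first difference along each axis.
    The optimum region is the 4-connected component, containing the optimal
    cell, of cells within 1 % of the metric's range of the optimum value.
    """
    from scipy import ndimage

    out: dict[str, dict] = {}
    for metric in result.metrics:
        surf = result.surfaces[metric][event_type]
        d_sleep = np.abs(np.diff(surf, axis=0))
        d_bar = np.abs(np.diff(surf, axis=1))
        if metric in _MINIMIZE:
            flat_idx = int(np.argmin(surf))
        else:
            flat_idx = int(np.argmax(surf))
        oi, oj = np.unravel_index(flat_idx, surf.shape)
        opt_val = float(surf[oi, oj])
        spread = float(surf.max() - surf.min())
        mask = np.abs(surf - opt_val) <= 0.01 * spread + 1e-12
        labels, _ = ndimage.label(mask)
        region_size = int(np.sum(labels == labels[oi, oj]))
        out[metric] = {
            "max_first_diff_sleeptime": float(d_sleep.max()) if d_sleep.size else 0.0,
            "max_first_diff_bar": float(d_bar.max()) if d_bar.size else 0.0,
            "optimum_value": opt_val,
            "optimum_sleeptime": int(result.sleeptime_values[oi]),
            "optimum_bar": int(result.bar_values[oj]),
            "optimum_region_size": region_size,
            "optimum_region_fraction": region_size / surf.size,
        }
    return out
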