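"""Lag time, zero-order rate and extent extraction from microcosm series.

Sulfide accumulation in these microcosms is summarised by three numbers per
culture: the lag before production starts, the maximum zero-order
production rate, and the maximum extent. The operational rule is a rate
threshold: the production window opens with the first sampling interval
whose finite-difference rate exceeds 0.05 mM/d (50 uM/d) and closes when
the rate falls back below it (first contiguous qualifying run). The
zero-order rate is then the endpoint secant over that window,

    rate = (S(-II)_end - S(-II)_start) / (t_end - t_start),

deliberately not a least-squares fit: with typical sampling only 2-4 points
fall inside the window. Lag time is the window start.

Internal units are uM for sulfide and days for time; readers convert mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLD",
    "MicrocosmSeries",
    "RateSummary",
    "interval_rates",
    "production_window",
    "max_zero_order_rate",
    "lag_time",
    "max_extent",
    "summarize",
]

#: production threshold defining the rate window, uM/d (= 0.05 mM/d)
DEFAULT_THRESHOLD = 50.0

TREATMENTS = ("Gly", "Gly+S", "S0", "control", "uninoculated")


@dataclass
class MicrocosmSeries:
    """Per-analyte time series for one microcosm.

    ``analytes`` maps analyte name (e.g. "sulfide_uM", "glycerol_mM",
    "pH", "OD600", "Fe_mM") to an (n, 2) array of (time_d, value) rows
    with strictly increasing times.
    """

    microcosm_id: str
    treatment: str
    generation: int = 1
    analytes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, arr in self.analytes.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name}: expected (n, 2) (time, value) array")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"{name}: times must be strictly increasing")
            clean[name] = arr
        self.analytes = clean

    def series(self, analyte: str) -> np.ndarray:
        return self.analytes[analyte]


@dataclass
class RateSummary:
    """Summary row for one microcosm: lag, zero-order rate, extent."""

    microcosm_id: str
    treatment: str
    generation: int
    lag_days: float | None
    max_rate_uM_d: float
    max_extent_uM: float
    window: tuple[float, float] | None
    n_points_in_window: int


def _as_tv(series) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (n, 2) (time, value) series")
    return arr


def interval_rates(series) -> list[tuple[tuple[float, float], float]]:
    """Finite-difference rates ((t_i, t_{i+1}), dv/dt) between samples."""
    arr = _as_tv(series)
    if len(arr) < 2:
        raise ValueError("need at least two points for rates")
    dt = np.diff(arr[:, 0])
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in series")
    rates = np.diff(arr[:, 1]) / dt
    return [
        ((arr[i, 0], arr[i + 1, 0]), rates[i]) for i in range(len(rates))
    ]


def production_window(
    series, threshold: float = DEFAULT_THRESHOLD
) -> tuple[float, float] | None:
    """First contiguous run of intervals whose rate exceeds ``threshold``.

    Returns (start_time, end_time) or None if no interval qualifies.
    """
    rates = interval_rates(series)
    start = None
    end = None
    for (t0, t1), r in rates:
        if r > threshold:
            if start is None:
                start = t0
            end = t1
        elif start is not None:
            break
    if start is None:
        return None
    return (start, end)


def _points_in(series, window: tuple[float, float]) -> np.ndarray:
    arr = _as_tv(series)
    mask = (arr[:, 0] >= window[0]) & (arr[:, 0] <= window[1])
    return arr[mask]


def max_zero_order_rate(series, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Endpoint-secant rate (uM/d) over the production window; 0 if none."""
    window = production_window(series, threshold)
    if window is None:
        return 0.0
    pts = _points_in(series, window)
    return (pts[-1, 1] - pts[0, 1]) / (pts[-1, 0] - pts[0, 0])


def lag_time(series, threshold: float = DEFAULT_THRESHOLD) -> float | None:
    """Start time of the production window; None if production never starts."""
    window = production_window(series, threshold)
    return None if window is None else window[0]


def max_extent(series) -> float:
    """Maximum value of the series (uM for sulfide), window-independent."""
    arr = _as_tv(series)
    return float(np.max(arr[:, 1])) if len(arr) else 0.0


def summarize(
    series_set: Iterable[MicrocosmSeries],
    analyte: str = "sulfide_uM",
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """One unaveraged row per microcosm: lag, rate, extent, window.

    Replicates are reported individually (no averaging); microcosms whose
    series never cross the threshold carry NaN lag and zero rate.
    """
    rows = []
    for mc in series_set:
        if analyte not in mc.analytes or len(mc.analytes[analyte]) < 2:
            rows.append(
                {
                    "microcosm_id": mc.microcosm_id,
                    "treatment": mc.treatment,
                    "generation": mc.generation,
                    "lag_days": np.nan,
                    "max_rate_uM_d": np.nan,
                    "max_extent_uM": np.nan,
                    "window_start_d": np.nan,
                    "window_end_d": np.nan,
                    "n_points_in_window": 0,
                }
            )
            continue
        series = mc.analytes[analyte]
        window = production_window(series, threshold)
        rate = max_zero_order_rate(series, threshold)
        n_pts = len(_points_in(series, window)) if window else 0
        rows.append(
            {
                "microcosm_id": mc.microcosm_id,
                "treatment": mc.treatment,
                "generation": mc.generation,
                "lag_days": window[0] if window else np.nan,
                "max_rate_uM_d": rate,
                "max_extent_uM": max_extent(series),
                "window_start_d": window[0] if window else np.nan,
                "window_end_d": window[1] if window else np.nan,
                "n_points_in_window": n_pts,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["treatment", "generation", "microcosm_id"]).reset_index(
        drop=True
    )
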