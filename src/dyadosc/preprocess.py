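"""Interbeat-interval preprocessing: windowed segmentation, linear
detrending, and dyad-level quality control.

Beat-level IBI events are reduced to fixed-window means (2-s windows
over a 5-min task give 150 samples per person), each person's series is
linearly detrended by regressing on time and keeping the residuals
(removing the intercept too), and dyads with excessive missingness are
excluded before model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SampledSeries", "QCReport", "segment_ibi", "detrend_linear", "qc_dyad"]


@dataclass
class SampledSeries:
    """One person's evenly sampled IBI series within a dyad.

    values : IBI in ms (raw) or ms-residual (detrended); NaN marks a
        missing window.  Sample k covers time [k*window_s, (k+1)*window_s).
    """

    values: np.ndarray
    dyad_id: int | str = 0
    person: int = 0
    window_s: float = 2.0
    detrended: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.person not in (0, 1):
            raise ValueError("person label must be 0 or 1")

    @property
    def t_index(self) -> np.ndarray:
        return np.arange(len(self.values))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class QCReport:
    dyad_id: int | str
    n_missing: tuple[int, int]
    longest_gap: tuple[int, int]
    n_interpolated: tuple[int, int]
    include: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.include and not self.reason:
            raise ValueError("an excluded dyad must carry a non-empty reason")


def segment_ibi(
    beats: list[tuple[float, float]] | np.ndarray,
    window_s: float = 2.0,
    task_len_s: float = 300.0,
    dyad_id: int | str = 0,
    person: int = 0,
) -> SampledSeries:
    """Average beat-level IBIs into fixed windows.

    ``beats`` is a sequence of (time_s, ibi_ms) pairs.  Each window
    [k*w, (k+1)*w) receives the arithmetic mean of the IBIs whose beat
    time falls inside it; windows with no beats are NaN.  Exactly
    task_len_s / window_s samples are returned.
    """
    beats = np.asarray(beats, dtype=float)
    if beats.size == 0:
        raise ValueError("no beats provided")
    if beats.ndim != 2 or beats.shape[1] != 2:
        raise ValueError("beats must be (time_s, ibi_ms) pairs")
    n_windows = task_len_s / window_s
    if abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError(
            f"window_s={window_s} does not divide task_len_s={task_len_s}"
        )
    n_windows = int(round(n_windows))
    times, ibis = beats[:, 0], beats[:, 1]
    if np.any(times < 0) or np.any(times >= task_len_s):
        raise ValueError("beat times must lie within [0, task_len_s)")
    win = np.floor(times / window_s).astype(int)
    sums = np.bincount(win, weights=ibis, minlength=n_windows)
    counts = np.bincount(win, minlength=n_windows)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SampledSeries(values=values, dyad_id=dyad_id, person=person, window_s=window_s)


def detrend_linear(series: SampledSeries) -> SampledSeries:
    """Remove a fitted line (intercept and slope on time) from a series.

    Output values are OLS residuals of value on t_index; missing samples
    stay missing.  Requires at least 3 non-missing values.
    """
    y = series.values
    ok = ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("detrending needs at least 3 non-missing values")
    t = series.t_index[ok].astype(float)
    design = np.column_stack([np.ones(ok.sum()), t])
    coef, *_ = np.linalg.lstsq(design, y[ok], rcond=None)
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - design @ coef
    return replace(series, values=resid, detrended=True)


def _longest_gap(values: np.ndarray) -> int:
    longest = run = 0
    for missing in np.isnan(values):
        run = run + 1 if missing else 0
        longest = max(longest, run)
    return longest


def _interp_short_gaps(values: np.ndarray, gap_limit: int) -> tuple[np.ndarray, int]:
    """Linearly fill interior NaN runs of length <= gap_limit."""
    out = values.copy()
    ok = ~np.isnan(out)
    if ok.all() or gap_limit <= 0:
        return out, 0
    idx = np.arange(len(out))
    n_filled = 0
    i = 0
    while i < len(out):
        if np.isnan(out[i]):
            j = i
            while j < len(out) and np.isnan(out[j]):
                j += 1
            interior = i > 0 and j < len(out)
            if interior and (j - i) <= gap_limit:
                out[i:j] = np.interp(idx[i:j], [i - 1, j], [out[i - 1], out[j]])
                n_filled += j - i
            i = j
        else:
            i += 1
    return out, n_filled


def qc_dyad(
    series_a: SampledSeries,
    series_b: SampledSeries,
    max_missing_frac: float = 0.10,
    interp_gap_limit: int = 3,
) -> tuple[QCReport, SampledSeries, SampledSeries]:
    """Quality-control a dyad: fill short gaps, flag excess missingness.

    Interior gaps of at most ``interp_gap_limit`` samples are linearly
    interpolated; the dyad is excluded when either person's missing
    fraction still exceeds ``max_missing_frac`` afterwards.
    """
    if len(series_a) != len(series_b) or series_a.window_s != series_b.window_s:
        raise ValueError("dyad members must share the same sampling grid")
    cleaned, n_interp, n_miss, gaps = [], [], [], []
    for s in (series_a, series_b):
        filled, k = _interp_short_gaps(s.values, interp_gap_limit)
        cleaned.append(replace(s, values=filled))
        n_interp.append(k)
        n_miss.append(int(np.isnan(filled).sum()))
        gaps.append(_longest_gap(filled))
    frac = max(n_miss) / len(series_a)
    if frac > max_missing_frac:
        include, reason = False, (
            f"missing fraction {frac:.2f} exceeds limit {max_missing_frac:.2f}"
        )
    else:
        include, reason = True, ""
    report = QCReport(
        dyad_id=series_a.dyad_id,
        n_missing=(n_miss[0], n_miss[1]),
        longest_gap=(gaps[0], gaps[1]),
        n_interpolated=(n_interp[0], n_interp[1]),
        include=include,
        reason=reason,
    )
    if not include:
        logger.info("dyad %s excluded: %s", series_a.dyad_id, reason)
    return report, cleaned[0], cleaned[1]
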