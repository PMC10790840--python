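"""Per-dyad coupled-oscillator estimation.

For each dyad the second derivative of each partner's detrended IBI
(estimated by GLLA) is regressed on that partner's position and
velocity and on the partner's position and velocity — 8 coefficients in
one stacked two-equation least-squares system with partner-indicator
coding and no constant term (the series are detrended and
mean-removed).  The embedding (tau, embed) is chosen per dyad by
maximizing the adjusted R^2 over a small grid, and an oscillation
period is reported for each partner whose own-position coefficient is
negative: period = 2*pi/sqrt(-eta_self) sample units, converted to
seconds by the sampling window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glla import DerivativeSeries, GllaConfig, estimate_derivatives
from .preprocess import SampledSeries

__all__ = ["CoFit", "fit_co", "co_grid_search", "oscillation_period", "summarize_co", "fits_to_frame"]

COEF_NAMES = (
    "eta_self_a", "zeta_self_a", "eta_cross_a", "zeta_cross_a",
    "eta_self_b", "zeta_self_b", "eta_cross_b", "zeta_cross_b",
)


@dataclass
class CoFit:
    """Estimated coupled-oscillator dynamics for one dyad."""

    dyad_id: int | str
    coefficients: dict[str, float]
    adj_r2: float
    tau: int
    embed: int
    delta: float
    n_rows: int
    window_s: float = 2.0
    period_a: float = math.nan
    period_b: float = math.nan
    period_a_s: float = math.nan
    period_b_s: float = math.nan
    grid: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if tuple(self.coefficients) != COEF_NAMES:
            raise ValueError(f"coefficients must be exactly {COEF_NAMES}")

    def coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in COEF_NAMES])


def oscillation_period(eta_self: float, window_s: float = 2.0) -> tuple[float, float]:
    """Oscillation period implied by an own-position coefficient.

    For eta_self < 0 the linear oscillator x'' = eta_self * x has
    angular frequency sqrt(-eta_self) per sample unit, hence period
    2*pi/sqrt(-eta_self) sample units (times window_s for seconds).
    A non-negative coefficient is non-oscillatory: (nan, nan).
    """
    if eta_self < 0:
        period_units = 2.0 * math.pi / math.sqrt(-eta_self)
        return period_units, period_units * window_s
    return math.nan, math.nan


def fit_co(
    derivs_a: DerivativeSeries,
    derivs_b: DerivativeSeries,
    dyad_id: int | str = 0,
    window_s: float = 2.0,
) -> CoFit:
    """Fit the 8-coefficient coupled-oscillator model to one dyad.

    The two partner equations are stacked into a single OLS system:
    partner A's rows regress x2_A on (x0_A, x1_A, x0_B, x1_B) and
    partner B's rows regress x2_B on (x0_B, x1_B, x0_A, x1_A), each
    equation with its own block of four coefficients and no intercept.
    """
    if derivs_a.config != derivs_b.config:
        raise ValueError("partners must share the same GLLA config")
    if len(derivs_a) != len(derivs_b) or not np.allclose(derivs_a.row_time, derivs_b.row_time):
        raise ValueError("partners' derivative rows are not aligned")
    m = len(derivs_a)
    block_a = np.column_stack([derivs_a.x0, derivs_a.x1, derivs_b.x0, derivs_b.x1])
    block_b = np.column_stack([derivs_b.x0, derivs_b.x1, derivs_a.x0, derivs_a.x1])
    design = np.zeros((2 * m, 8))
    design[:m, :4] = block_a
    design[m:, 4:] = block_b
    y = np.concatenate([derivs_a.x2, derivs_b.x2])

    rank = np.linalg.matrix_rank(design)
    if rank < 8:
        raise ValueError(
            f"rank-deficient coupled-oscillator design (rank {rank} < 8); "
            "constant or perfectly collinear series cannot be fit"
        )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)  # no intercept: uncentered total sum of squares
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n = 2 * m
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 8 - 1)

    coefficients = dict(zip(COEF_NAMES, coef))
    period_a, period_a_s = oscillation_period(coefficients["eta_self_a"], window_s)
    period_b, period_b_s = oscillation_period(coefficients["eta_self_b"], window_s)
    cfg = derivs_a.config
    return CoFit(
        dyad_id=dyad_id, coefficients=coefficients, adj_r2=adj_r2,
        tau=cfg.tau, embed=cfg.embed, delta=cfg.delta, n_rows=n,
        window_s=window_s,
        period_a=period_a, period_b=period_b,
        period_a_s=period_a_s, period_b_s=period_b_s,
    )


def co_grid_search(
    series_a: SampledSeries,
    series_b: SampledSeries,
    taus: tuple[int, ...] = (3, 4),
    embeds: tuple[int, ...] = (3, 4, 5),
    delta: float = 1.0,
    dyad_id: int | str | None = None,
) -> CoFit:
    """Fit the coupled-oscillator model over an embedding grid and keep
    the (tau, embed) combination maximizing adjusted R^2.

    Both partners use the same combination so their derivative rows stay
    aligned.  Ties break to the smaller embed, then the smaller tau
    (the grid is scanned in that order and only a strictly better fit
    replaces the incumbent).  Infeasible cells (series too short) are
    skipped; the full grid table is kept on the returned fit.
    """
    if dyad_id is None:
        dyad_id = series_a.dyad_id
    xa, xb = series_a.values, series_b.values
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise ValueError("series contain missing values; run QC/interpolation first")
    best: CoFit | None = None
    rows = []
    min_len_needed = None
    # a cell needs enough embedded rows for the 8-predictor stacked
    # regression to have positive residual degrees of freedom
    min_rows = 5
    for embed in sorted(embeds):
        for tau in sorted(taus):
            cfg = GllaConfig(tau=tau, embed=embed, delta=delta)
            needed = cfg.span + min_rows
            if len(xa) < needed:
                min_len_needed = needed if min_len_needed is None else min(min_len_needed, needed)
                rows.append({"tau": tau, "embed": embed, "adj_r2": math.nan, "feasible": False})
                continue
            try:
                fit = fit_co(
                    estimate_derivatives(xa, cfg), estimate_derivatives(xb, cfg),
                    dyad_id=dyad_id, window_s=series_a.window_s,
                )
            except ValueError:
                rows.append({"tau": tau, "embed": embed, "adj_r2": math.nan, "feasible": False})
                continue
            rows.append({"tau": tau, "embed": embed, "adj_r2": fit.adj_r2, "feasible": True})
            if best is None or fit.adj_r2 > best.adj_r2:
                best = fit
    if best is None:
        raise ValueError(
            f"no feasible (tau, embed) combination: series of length {len(xa)} "
            f"needs at least {min_len_needed} samples"
        )
    best.grid = pd.DataFrame(rows)
    return best


def fits_to_frame(fits: list[CoFit]) -> pd.DataFrame:
    """Per-dyad parameter table: the hand-off to latent-profile analysis."""
    rows = []
    for f in fits:
        row = {"dyad_id": f.dyad_id, **f.coefficients,
               "tau": f.tau, "embed": f.embed, "delta": f.delta,
               "adj_r2": f.adj_r2,
               "period_a": f.period_a, "period_b": f.period_b,
               "period_a_s": f.period_a_s, "period_b_s": f.period_b_s}
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_co(fits: list[CoFit]) -> pd.DataFrame:
    """Descriptive statistics of fit quality and oscillation periods.

    Mean, sample SD, min and max of the adjusted R^2 and of each
    partner's period in sample units (non-oscillatory fits excluded
    from the period rows; the count of contributing fits is reported).
    """
    if not fits:
        raise ValueError("no fits to summarize")
    frame = fits_to_frame(fits)
    rows = []
    for label, col in (("adj_r2", "adj_r2"), ("period_a", "period_a"), ("period_b", "period_b")):
        vals = frame[col].dropna().to_numpy()
        rows.append({
            "quantity": label,
            "mean": vals.mean() if vals.size else math.nan,
            "sd": vals.std(ddof=1) if vals.size > 1 else math.nan,
            "min": vals.min() if vals.size else math.nan,
            "max": vals.max() if vals.size else math.nan,
            "n": int(vals.size),
        })
    return pd.DataFrame(rows)
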