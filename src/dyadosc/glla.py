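"""Generalized Local Linear Approximation (GLLA) derivative estimation.

Derivatives of a noisy time series are estimated by regressing a
time-delay-embedded copy of the signal onto a local quadratic basis.
For an embedding of dimension ``embed`` with lag ``tau`` (in samples)
and sample spacing ``delta``, the lagged copies sit at centered times

    t_j = (j - (embed - 1) / 2) * tau * delta,   j = 0 .. embed - 1,

and the basis matrix L has columns (1, t_j, t_j^2 / 2).  The fixed
weight matrix W = L (L'L)^{-1} maps each embedded row onto estimates of
(position, first derivative, second derivative) at the row's center
time.  The t^2/2 column means the third output *is* the second
derivative — no trailing factor of two.  At embed=3, tau=delta=1 the
weights reduce to ordinary central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GllaConfig", "DerivativeSeries", "time_delay_embed", "glla_weights", "estimate_derivatives"]


@dataclass(frozen=True)
class GllaConfig:
    """Embedding parameters for GLLA derivative estimation.

    tau : lag between embedded copies, in samples (integer >= 1)
    embed : number of lagged copies (integer >= 3)
    delta : time per sample, in sample units (> 0); 1 when derivatives
        are expressed per sampling interval
    """

    tau: int
    embed: int
    delta: float = 1.0

    def __post_init__(self) -> None:
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"tau must be an integer >= 1, got {self.tau}")
        if int(self.embed) != self.embed or self.embed < 3:
            raise ValueError(f"embed must be an integer >= 3, got {self.embed}")
        if not (self.delta > 0):
            raise ValueError(f"delta must be positive, got {self.delta}")

    @property
    def span(self) -> int:
        """Samples consumed by the embedding: (embed - 1) * tau."""
        return (int(self.embed) - 1) * int(self.tau)


@dataclass
class DerivativeSeries:
    """Aligned GLLA estimates of position and first two derivatives.

    All arrays have length n - (embed - 1) * tau where n is the input
    length.  ``row_time`` is the center time (in sample indices of the
    original series) of each embedded row.
    """

    x0: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    row_time: np.ndarray
    config: GllaConfig

    def __len__(self) -> int:
        return len(self.x0)


def time_delay_embed(x: np.ndarray, embed: int, tau: int) -> np.ndarray:
    """Build the time-delay embedding matrix of ``x``.

    Row i is (x[i], x[i + tau], ..., x[i + (embed-1) * tau]); there are
    n - (embed - 1) * tau rows.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    span = (embed - 1) * tau
    n_rows = len(x) - span
    if n_rows < 1:
        raise ValueError(
            f"series of length {len(x)} too short for embed={embed}, tau={tau}; "
            f"needs length > {span}"
        )
    idx = np.arange(n_rows)[:, None] + tau * np.arange(embed)[None, :]
    return x[idx]


def glla_weights(config: GllaConfig) -> np.ndarray:
    """Fixed GLLA weight matrix W (embed x 3).

    ``embedded_row @ W`` yields (x0, x1, x2) estimates at the row's
    center time.
    """
    e, tau, delta = config.embed, config.tau, config.delta
    t = (np.arange(e) - (e - 1) / 2.0) * tau * delta
    basis = np.column_stack([np.ones(e), t, t**2 / 2.0])
    gram = basis.T @ basis
    if np.linalg.matrix_rank(gram) < 3:
        raise ValueError("singular GLLA basis; embed must give >= 3 distinct lag times")
    return basis @ np.linalg.inv(gram)


def estimate_derivatives(x: np.ndarray, config: GllaConfig) -> DerivativeSeries:
    """Estimate position, velocity and acceleration of ``x`` by GLLA."""
    emb = time_delay_embed(x, config.embed, config.tau)
    est = emb @ glla_weights(config)
    if not np.all(np.isfinite(est)):
        raise ValueError("non-finite derivative estimates; input contains NaN or inf")
    row_time = np.arange(emb.shape[0]) + config.span / 2.0
    return DerivativeSeries(
        x0=est[:, 0], x1=est[:, 1], x2=est[:, 2], row_time=row_time, config=config
    )
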