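"""Synthetic dyadic IBI data from known coupled-oscillator dynamics.

Each partner's detrended IBI is modeled as a damped, coupled linear
oscillator: the acceleration of partner A is

    x_A'' = eta_self_A * x_A + zeta_self_A * x_A'
          + eta_cross_A * x_B + zeta_cross_A * x_B'

and symmetrically for B.  A negative own-position coefficient
(eta_self) produces oscillation with period 2*pi/sqrt(-eta_self) sample
units; a negative own-velocity coefficient (zeta_self) damps the
envelope while a positive one amplifies it; the cross coefficients
couple the partners in frequency and in damping.

Three archetype regimes mirror qualitatively distinct linkage patterns
reported for stranger dyads: slow in-phase with one partner damping,
fast in-phase with one partner damping, and fast anti-phase.  A study
generator draws dyads from a mixture of these regimes, assigns a
balanced 2x2 condition design (talk/no-talk x cooperative/competitive),
and can plant multinomial log-odds effects of dyad-average and
within-dyad-difference covariates on regime membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .preprocess import SampledSeries

__all__ = [
    "TrueDynamics",
    "ArchetypeDyad",
    "CovariateEffect",
    "StudyDataset",
    "ARCHETYPES",
    "simulate_co_dyad",
    "make_archetype",
    "simulate_study",
    "write_study_csvs",
]

# Study-scale defaults: adult resting IBI around 800 ms, task-related
# oscillations of roughly 50 ms amplitude, 10 ms sampling noise.
DEFAULT_BASELINE_MS = 800.0
DEFAULT_AMPLITUDE_MS = 50.0
DEFAULT_NOISE_SD_MS = 10.0


@dataclass(frozen=True)
class TrueDynamics:
    """The 8 coupled-oscillator coefficients of one dyad.

    eta_self_* : own-position coefficient per sample-unit^2 (negative
        means oscillation at period 2*pi/sqrt(-eta_self))
    zeta_self_* : own-velocity coefficient per sample unit (negative
        damps, positive amplifies)
    eta_cross_* : partner-position (frequency) coupling
    zeta_cross_* : partner-velocity (damping) coupling
    """

    eta_self_a: float
    zeta_self_a: float
    eta_cross_a: float
    zeta_cross_a: float
    eta_self_b: float
    zeta_self_b: float
    eta_cross_b: float
    zeta_cross_b: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"dynamics coefficients must be finite, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def system_matrix(self) -> np.ndarray:
        """First-order form of the coupled system, state (x_A, v_A, x_B, v_B)."""
        return np.array(
            [
                [0.0, 1.0, 0.0, 0.0],
                [self.eta_self_a, self.zeta_self_a, self.eta_cross_a, self.zeta_cross_a],
                [0.0, 0.0, 0.0, 1.0],
                [self.eta_cross_b, self.zeta_cross_b, self.eta_self_b, self.zeta_self_b],
            ]
        )


def _rk4_step_matrix(m: np.ndarray, h: float) -> np.ndarray:
    """One-step propagator of the classical RK4 scheme for y' = M y.

    For a linear system RK4 collapses to the degree-4 Taylor polynomial
    of the matrix exponential.
    """
    hm = h * m
    eye = np.eye(m.shape[0])
    return eye + hm + hm @ hm / 2.0 + hm @ hm @ hm / 6.0 + hm @ hm @ hm @ hm / 24.0


def integrate_dynamics(
    dynamics: TrueDynamics,
    n_steps: int,
    init: tuple[float, float, float, float],
    step: float = 1.0,
) -> np.ndarray:
    """RK4 trajectory of the deterministic system; rows are time points,
    columns (x_A, v_A, x_B, v_B).  ``step`` is the integrator step in
    sample units (output is every accumulated unit step regardless)."""
    phi = _rk4_step_matrix(dynamics.system_matrix(), step)
    substeps = int(round(1.0 / step))
    if abs(substeps * step - 1.0) > 1e-12:
        raise ValueError("step must divide the unit sampling interval")
    out = np.empty((n_steps, 4))
    y = np.asarray(init, dtype=float)
    for i in range(n_steps):
        out[i] = y
        for _ in range(substeps):
            y = phi @ y
    return out


def simulate_co_dyad(
    dynamics: TrueDynamics,
    n_steps: int = 150,
    init: tuple[float, float, float, float] = (DEFAULT_AMPLITUDE_MS, 0.0, DEFAULT_AMPLITUDE_MS, 0.0),
    noise_sd: float = DEFAULT_NOISE_SD_MS,
    trend_slope: float = 0.0,
    baseline: float = DEFAULT_BASELINE_MS,
    seed: int | np.random.Generator | None = 0,
    dyad_id: int | str = 0,
    window_s: float = 2.0,
) -> tuple[SampledSeries, SampledSeries]:
    """Simulate one dyad's sampled IBI pair from known dynamics.

    The deterministic coupled system is integrated by fixed-step RK4 at
    the sampling step, then baseline, linear trend and independent
    Gaussian noise are added per sample.  Identical seed gives identical
    output.
    """
    if n_steps < 10:
        raise ValueError(f"n_steps must be >= 10, got {n_steps}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traj = integrate_dynamics(dynamics, n_steps, init)
    t = np.arange(n_steps)
    drift = baseline + trend_slope * t
    noise = rng.normal(0.0, noise_sd, size=(2, n_steps)) if noise_sd > 0 else np.zeros((2, n_steps))
    series_a = SampledSeries(traj[:, 0] + drift + noise[0], dyad_id=dyad_id, person=0, window_s=window_s)
    series_b = SampledSeries(traj[:, 2] + drift + noise[1], dyad_id=dyad_id, person=1, window_s=window_s)
    return series_a, series_b


@dataclass
class ArchetypeDyad:
    """A simulated dyad with its generating regime recorded."""

    name: str
    dynamics: TrueDynamics
    init: tuple[float, float, float, float]
    series_a: SampledSeries
    series_b: SampledSeries


def _archetype_presets() -> dict[str, tuple[TrueDynamics, tuple[float, float, float, float]]]:
    amp = DEFAULT_AMPLITUDE_MS
    slow = 2.0 * np.pi / 45.0   # period 45 samples (90 s at 2-s windows)
    fast = 2.0 * np.pi / 14.0   # period 14 samples (28 s)
    return {
        # slow in-phase, partner A's signal damps
        "slow_inphase_damping": (
            TrueDynamics(
                eta_self_a=-(slow**2), zeta_self_a=-0.020,
                eta_cross_a=0.004, zeta_cross_a=0.0,
                eta_self_b=-(slow**2), zeta_self_b=0.0,
                eta_cross_b=0.004, zeta_cross_b=0.0,
            ),
            (amp, 0.0, amp, 0.0),
        ),
        # fast in-phase, partner A's signal damps
        "fast_inphase_damping": (
            TrueDynamics(
                eta_self_a=-(fast**2), zeta_self_a=-0.050,
                eta_cross_a=0.020, zeta_cross_a=0.0,
                eta_self_b=-(fast**2), zeta_self_b=0.0,
                eta_cross_b=0.020, zeta_cross_b=0.0,
            ),
            (amp, 0.0, amp, 0.0),
        ),
        # fast anti-phase: opposite-sign starts, negative position coupling,
        # mild amplification on one partner (less stable over time)
        "fast_antiphase": (
            TrueDynamics(
                eta_self_a=-(fast**2), zeta_self_a=-0.015,
                eta_cross_a=-0.040, zeta_cross_a=0.0,
                eta_self_b=-(fast**2), zeta_self_b=0.008,
                eta_cross_b=-0.040, zeta_cross_b=0.0,
            ),
            (amp, 0.0, -amp, 0.0),
        ),
    }


ARCHETYPES = tuple(_archetype_presets().keys())


def make_archetype(
    name: str,
    n_steps: int = 150,
    seed: int | np.random.Generator | None = 0,
    noise_sd: float = DEFAULT_NOISE_SD_MS,
    jitter: float = 0.0,
    trend_slope: float = 0.0,
    dyad_id: int | str = 0,
) -> ArchetypeDyad:
    """Simulate a dyad from a named dynamic regime.

    ``jitter`` perturbs each nonzero preset coefficient by a uniform
    factor in [1 - jitter, 1 + jitter] so that repeated draws from one
    regime are not identical (within-profile variance for clustering).
    """
    presets = _archetype_presets()
    if name not in presets:
        raise ValueError(f"unknown archetype {name!r}; valid names: {sorted(presets)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dynamics, init = presets[name]
    if jitter > 0:
        coef = dynamics.as_array()
        factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=coef.size)
        names = [f.name for f in fields(TrueDynamics)]
        dynamics = TrueDynamics(**dict(zip(names, coef * factors)))
    series_a, series_b = simulate_co_dyad(
        dynamics, n_steps=n_steps, init=init, noise_sd=noise_sd,
        trend_slope=trend_slope, seed=rng, dyad_id=dyad_id,
    )
    return ArchetypeDyad(name=name, dynamics=dynamics, init=init,
                         series_a=series_a, series_b=series_b)


@dataclass(frozen=True)
class CovariateEffect:
    """Planted multinomial log-odds of one covariate on regime membership.

    Each tuple has one entry per non-reference regime (regimes 2..K vs
    regime 1): the log-odds change per unit of the dyad average and of
    the absolute within-dyad difference.
    """

    avg_log_odds: tuple[float, ...] = (0.0, 0.0)
    diff_log_odds: tuple[float, ...] = (0.0, 0.0)


@dataclass
class StudyDataset:
    """A full synthetic study: long-format series, dyad covariates, truth.

    series : columns dyad_id, person, t_index, ibi_ms
    covariates : one row per person with condition and scale columns
    truth : generator-only sidecar with the regime label and the true
        dynamics per dyad
    """

    series: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame

    @property
    def n_dyads(self) -> int:
        return self.truth.shape[0]


def simulate_study(
    n_dyads: int = 65,
    regime_mixture: tuple[float, float, float] = (0.42, 0.26, 0.32),
    covariate_spec: dict[str, CovariateEffect] | None = None,
    condition_log_odds: dict[str, tuple[float, ...]] | None = None,
    n_steps: int = 150,
    noise_sd: float = DEFAULT_NOISE_SD_MS,
    jitter: float = 0.10,
    seed: int | np.random.Generator | None = 0,
) -> StudyDataset:
    """Generate a synthetic study of coupled-oscillator dyads.

    Regime labels are drawn from a multinomial-logit model whose linear
    predictor combines baseline log-odds (matching ``regime_mixture``)
    with any planted covariate and condition effects; each dyad's series
    comes from its regime's archetype with per-dyad coefficient jitter.
    Covariates default to standard-normal person-level scores.
    """
    mixture = np.asarray(regime_mixture, dtype=float)
    if abs(mixture.sum() - 1.0) > 1e-8:
        raise ValueError(f"regime mixture must sum to 1, got sum {mixture.sum()}")
    if np.any(mixture < 0):
        raise ValueError("regime mixture proportions must be non-negative")
    if n_dyads < 12:
        raise ValueError("n_dyads must be >= 12")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covariate_spec = covariate_spec or {}
    cov_names = list(covariate_spec) or ["scale_1"]
    k = len(mixture)

    # balanced, randomly ordered 2x2 condition assignment
    cells = [("talk", "cooperative"), ("talk", "competitive"),
             ("no_talk", "cooperative"), ("no_talk", "competitive")]
    assignment = [cells[i % 4] for i in range(n_dyads)]
    rng.shuffle(assignment)

    person_scores = rng.normal(0.0, 1.0, size=(n_dyads, 2, len(cov_names)))
    avg = person_scores.mean(axis=1)
    diff = np.abs(person_scores[:, 0, :] - person_scores[:, 1, :])

    # baseline log-odds reproduce the mixture when all effects are null
    with np.errstate(divide="ignore"):
        base = np.where(mixture > 0, np.log(np.maximum(mixture, 1e-300)), -np.inf)
    logits = np.tile(base, (n_dyads, 1))
    for j, name in enumerate(cov_names):
        eff = covariate_spec.get(name, CovariateEffect((0.0,) * (k - 1), (0.0,) * (k - 1)))
        logits[:, 1:] += np.outer(avg[:, j], np.asarray(eff.avg_log_odds, dtype=float))
        logits[:, 1:] += np.outer(diff[:, j], np.asarray(eff.diff_log_odds, dtype=float))
    if condition_log_odds:
        for d in range(n_dyads):
            cell = f"{assignment[d][1]}/{assignment[d][0]}"
            if cell in condition_log_odds:
                logits[d, 1:] += np.asarray(condition_log_odds[cell], dtype=float)
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    labels = np.array([rng.choice(k, p=probs[d]) for d in range(n_dyads)])

    series_rows, cov_rows, truth_rows = [], [], []
    for d in range(n_dyads):
        regime = int(labels[d])
        dyad = make_archetype(
            ARCHETYPES[regime], n_steps=n_steps, seed=rng,
            noise_sd=noise_sd, jitter=jitter, dyad_id=d,
        )
        for s in (dyad.series_a, dyad.series_b):
            series_rows.append(pd.DataFrame({
                "dyad_id": d, "person": s.person,
                "t_index": np.arange(len(s)), "ibi_ms": s.values,
            }))
        talk, orient = assignment[d]
        for p in (0, 1):
            row = {"dyad_id": d, "person": p,
                   "social_interaction": talk, "orientation": orient}
            for j, name in enumerate(cov_names):
                row[name] = person_scores[d, p, j]
            cov_rows.append(row)
        truth = {"dyad_id": d, "regime": regime + 1, "archetype": dyad.name}
        truth.update({f.name: getattr(dyad.dynamics, f.name) for f in fields(TrueDynamics)})
        truth_rows.append(truth)

    return StudyDataset(
        series=pd.concat(series_rows, ignore_index=True),
        covariates=pd.DataFrame(cov_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_study_csvs(dataset: StudyDataset, out_dir) -> dict[str, str]:
    """Write the three study tables as CSV; returns name -> path."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("series", dataset.series),
                        ("covariates", dataset.covariates),
                        ("truth", dataset.truth)):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = str(p)
    return paths
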