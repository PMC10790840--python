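"""Latent-profile grouping of dyads by their oscillator dynamics.

The 8 coupled-oscillator coefficients per dyad are z-scored across
dyads and clustered with a diagonal-covariance Gaussian mixture (latent
profile analysis).  Solution selection follows substantive heuristics
rather than fit statistics: profiles holding fewer than a minimum
fraction of dyads are flagged, separation is summarized by the mean
maximal responsibility and pairwise Mahalanobis distances, and the
final choice of k is a recorded configuration decision.  Each profile's
typical dynamics can be integrated forward to render predicted
trajectory curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .co_model import COEF_NAMES, CoFit
from .synth import TrueDynamics, integrate_dynamics

__all__ = [
    "Standardization",
    "ProfileModel",
    "TrajectoryPrediction",
    "standardize_parameters",
    "fit_lpa",
    "select_profile_solution",
    "predict_profile_trajectories",
]

VARIANCE_FLOOR = 1e-6


@dataclass
class Standardization:
    """Per-coefficient centering/scaling used before mixture fitting."""

    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def inverse(self, z: np.ndarray) -> np.ndarray:
        """Back-transform standardized coordinates to the raw scale."""
        return np.asarray(z) * self.sds + self.means


@dataclass
class ProfileModel:
    """A fitted latent-profile (Gaussian mixture) solution."""

    k: int
    weights: np.ndarray
    means: np.ndarray            # (k, 8) on the standardized scale
    variances: np.ndarray        # (k, 8) diagonal covariances
    responsibilities: np.ndarray  # (n_dyads, k)
    assignment: np.ndarray       # modal profile per dyad, 1-based
    log_likelihood: float
    standardization: Standardization
    dyad_ids: np.ndarray

    @property
    def profile_counts(self) -> np.ndarray:
        return np.bincount(self.assignment - 1, minlength=self.k)

    @property
    def min_profile_frac(self) -> float:
        return float(self.profile_counts.min() / len(self.assignment))

    @property
    def mean_max_responsibility(self) -> float:
        return float(self.responsibilities.max(axis=1).mean())

    def profile_means_raw(self) -> np.ndarray:
        """Profile mean coefficient vectors on the raw (unstandardized) scale."""
        return self.standardization.inverse(self.means)


def standardize_parameters(
    fits: list[CoFit] | pd.DataFrame,
) -> tuple[np.ndarray, Standardization, np.ndarray]:
    """Z-score the 8 coefficients across dyads.

    Returns the standardized matrix, the standardization record needed
    to back-transform profile means, and the dyad ids.  A zero-variance
    coefficient is centered only (scale kept at 1) with a warning.
    """
    if isinstance(fits, pd.DataFrame):
        frame = fits
    else:
        from .co_model import fits_to_frame

        frame = fits_to_frame(fits)
    if frame.shape[0] < 2:
        raise ValueError("standardization needs at least 2 dyads")
    mat = frame[list(COEF_NAMES)].to_numpy(dtype=float)
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    degenerate = sds <= 0
    if degenerate.any():
        cols = [c for c, bad in zip(COEF_NAMES, degenerate) if bad]
        warnings.warn(f"zero-variance coefficients centered only: {cols}")
        sds = np.where(degenerate, 1.0, sds)
    z = (mat - means) / sds
    record = Standardization(columns=COEF_NAMES, means=means, sds=sds)
    return z, record, frame["dyad_id"].to_numpy()


def fit_lpa(
    matrix: np.ndarray,
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    standardization: Standardization | None = None,
    dyad_ids: np.ndarray | None = None,
) -> ProfileModel:
    """Fit a diagonal-covariance Gaussian mixture with random restarts.

    The best of ``n_starts`` EM runs by log-likelihood is kept; a small
    variance floor guards against degenerate components.  Deterministic
    given the seed.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.shape[0] < 5 * k:
        raise ValueError(f"need at least {5 * k} dyads for k={k} profiles")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        n_init=n_starts,
        reg_covar=VARIANCE_FLOOR,
        max_iter=500,
        random_state=seed,
    ).fit(matrix)
    resp = gm.predict_proba(matrix)
    assignment = resp.argmax(axis=1) + 1
    if standardization is None:
        standardization = Standardization(
            columns=tuple(f"x{i}" for i in range(matrix.shape[1])),
            means=np.zeros(matrix.shape[1]),
            sds=np.ones(matrix.shape[1]),
        )
    if dyad_ids is None:
        dyad_ids = np.arange(matrix.shape[0])
    return ProfileModel(
        k=k,
        weights=gm.weights_,
        means=gm.means_,
        variances=gm.covariances_,
        responsibilities=resp,
        assignment=assignment,
        log_likelihood=float(gm.score(matrix) * matrix.shape[0]),
        standardization=standardization,
        dyad_ids=np.asarray(dyad_ids),
    )


def _pairwise_separation(model: ProfileModel) -> float:
    """Minimum pairwise Mahalanobis distance between profile means,
    under the average of the two components' diagonal covariances."""
    if model.k < 2:
        return float("nan")
    dmin = np.inf
    for i in range(model.k):
        for j in range(i + 1, model.k):
            pooled = (model.variances[i] + model.variances[j]) / 2.0
            d = np.sqrt(np.sum((model.means[i] - model.means[j]) ** 2 / pooled))
            dmin = min(dmin, float(d))
    return dmin


def select_profile_solution(
    models: list[ProfileModel],
    min_frac: float = 0.10,
) -> pd.DataFrame:
    """Screen candidate profile solutions against substantive heuristics.

    Any solution with a profile holding fewer than ``min_frac`` of the
    dyads is flagged; separation is summarized by the mean maximal
    responsibility and the minimum pairwise Mahalanobis distance between
    profile means.  Admissible solutions are ranked by separation.  The
    final choice is a recorded configuration decision, not an automatic
    fit-statistic optimum.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 candidate solutions to compare")
    rows = []
    for m in models:
        counts = m.profile_counts
        flagged = m.min_profile_frac < min_frac
        rows.append({
            "k": m.k,
            "profile_counts": "/".join(str(c) for c in counts),
            "min_profile_frac": m.min_profile_frac,
            "small_profile_flag": bool(flagged),
            "mean_max_responsibility": m.mean_max_responsibility,
            "min_separation": _pairwise_separation(m),
            "log_likelihood": m.log_likelihood,
            "admissible": not flagged,
        })
    report = pd.DataFrame(rows).sort_values(
        ["admissible", "min_separation"], ascending=[False, False]
    ).reset_index(drop=True)
    report["rank"] = np.where(report["admissible"], np.arange(1, len(report) + 1), 0)
    return report


@dataclass
class TrajectoryPrediction:
    """Model-implied dyadic trajectory for one profile."""

    profile: int
    x_a: np.ndarray
    x_b: np.ndarray
    truncated: bool = False


def predict_profile_trajectories(
    model: ProfileModel,
    horizon: int = 150,
    inits: pd.DataFrame | None = None,
    default_amplitude: float = 50.0,
    divergence_limit: float = 1e6,
) -> list[TrajectoryPrediction]:
    """Integrate each profile's mean dynamics forward in time.

    Profile-mean coefficient vectors are back-transformed to the raw
    scale and integrated by fixed-step RK4 from profile-average initial
    conditions.  ``inits`` may supply per-dyad observed starts (columns
    dyad_id, x_a0, v_a0, x_b0, v_b0); otherwise both partners start at
    ``default_amplitude`` with zero velocity.  A trajectory that leaves
    ``divergence_limit`` (explosive amplification) is truncated and
    flagged.
    """
    raw_means = model.profile_means_raw()
    predictions = []
    for p in range(model.k):
        dynamics = TrueDynamics(**dict(zip(COEF_NAMES, raw_means[p])))
        if inits is not None:
            members = model.dyad_ids[model.assignment == p + 1]
            sub = inits[inits["dyad_id"].isin(members)]
            init = tuple(sub[["x_a0", "v_a0", "x_b0", "v_b0"]].mean().to_numpy()) if len(sub) else (
                default_amplitude, 0.0, default_amplitude, 0.0)
        else:
            init = (default_amplitude, 0.0, default_amplitude, 0.0)
        traj = integrate_dynamics(dynamics, horizon, init)
        bad = ~np.all(np.abs(traj) < divergence_limit, axis=1)
        truncated = bool(bad.any())
        if truncated:
            cut = int(np.argmax(bad))
            traj = traj[:max(cut, 2)]
        predictions.append(TrajectoryPrediction(
            profile=p + 1, x_a=traj[:, 0], x_b=traj[:, 2], truncated=truncated,
        ))
    return predictions
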