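"""Bayesian stage-2 models linking latent profiles to outcomes,
covariates, and condition.

Two model families are provided, mirroring the second analysis stage of
the pipeline:

* outcome models — a person-level outcome regressed on dyad-level
  profile membership (optionally crossed with the 4-level condition),
  with a dyad-varying intercept to respect the nesting of persons in
  dyads.  The dyad intercepts are integrated out analytically (the
  marginal likelihood of each dyad's two observations is bivariate
  normal with an exchangeable covariance), so only the fixed effects
  and the two variance scales are sampled.

* profile-membership models — multinomial-logit regression of dyad-level
  profile membership on one covariate's dyad average and within-dyad
  absolute difference (optionally crossed with condition), reference
  category = the largest profile.

Posteriors are sampled with an affine-invariant ensemble sampler
(emcee) under flat priors on regression coefficients and
weakly-informative half-Student-t priors on scales.  Every reported
parameter carries its posterior mean, 90% highest-density interval,
split R-hat and effective sample size; non-converged fits are re-run
once at escalated sampler settings (10 chains x 10,000 iterations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerSettings",
    "PosteriorSummary",
    "decompose_avg_diff",
    "hdi",
    "check_convergence",
    "fit_outcome_model",
    "fit_profile_model",
    "membership_probs",
    "DEFAULT_SETTINGS",
    "ESCALATED_SETTINGS",
]

RHAT_LIMIT = 1.1


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC budget: ``chains`` reported chains and ``draws`` iterations
    per chain.  Half of each chain is discarded as burn-in."""

    chains: int = 4
    draws: int = 2000

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.draws < 100:
            raise ValueError("draws must be >= 100")


DEFAULT_SETTINGS = SamplerSettings(chains=4, draws=2000)
ESCALATED_SETTINGS = SamplerSettings(chains=10, draws=10_000)


@dataclass
class PosteriorSummary:
    """Posterior summary for one stage-2 model."""

    model_id: str
    table: pd.DataFrame  # parameter, mean, hdi_low, hdi_high, rhat, ess
    mass: float
    converged: bool
    escalated: bool
    settings: SamplerSettings
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def parameter(self, name: str) -> pd.Series:
        row = self.table[self.table["parameter"] == name]
        if row.empty:
            raise KeyError(f"no parameter {name!r}; have {list(self.table['parameter'])}")
        return row.iloc[0]

    def excludes_zero(self, name: str) -> bool:
        row = self.parameter(name)
        return bool(row["hdi_low"] > 0 or row["hdi_high"] < 0)


def decompose_avg_diff(covariates: pd.DataFrame, covariate: str) -> pd.DataFrame:
    """Dyad-level average/difference decomposition of a person covariate.

    Returns one row per dyad with ``avg`` = mean of the two persons'
    scores (between-dyad variation) and ``diff`` = absolute difference
    (within-dyad variation); invariant to the arbitrary 0/1 person
    labels.  Dyads with a missing person score are dropped and logged.
    """
    if covariate not in covariates.columns:
        raise KeyError(f"covariate {covariate!r} not in table")
    rows = []
    for dyad_id, grp in covariates.groupby("dyad_id"):
        vals = grp[covariate].to_numpy(dtype=float)
        if len(vals) != 2:
            raise ValueError(f"dyad {dyad_id} has {len(vals)} persons; expected 2")
        if np.isnan(vals).any():
            logger.info("dyad %s dropped for %s: missing person score", dyad_id, covariate)
            continue
        rows.append({"dyad_id": dyad_id, "avg": vals.mean(), "diff": abs(vals[0] - vals[1])})
    return pd.DataFrame(rows)


def hdi(samples: np.ndarray, mass: float = 0.90) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Sorted-window method: among all windows of ceil(mass * n) sorted
    draws, return the narrowest.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"hdi needs at least 100 draws, got {n}")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _diagnostics(chains: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Split R-hat and effective sample size per parameter.

    ``chains`` has shape (n_chains, n_draws, n_params).
    """
    import arviz as az

    rows = []
    for i, name in enumerate(names):
        rows.append({
            "parameter": name,
            "rhat": float(az.rhat(chains[:, :, i])),
            "ess": float(az.ess(chains[:, :, i])),
        })
    return pd.DataFrame(rows)


def check_convergence(fit: "PosteriorSummary | np.ndarray", names: list[str] | None = None) -> pd.DataFrame:
    """Convergence diagnostics (R-hat < 1.1 rule, effective sample size).

    Accepts either a fitted :class:`PosteriorSummary` (returns its
    diagnostic columns) or a raw chains array (n_chains, n_draws,
    n_params) with parameter names.
    """
    if isinstance(fit, PosteriorSummary):
        out = fit.table[["parameter", "rhat", "ess"]].copy()
    else:
        chains = np.asarray(fit, dtype=float)
        if chains.ndim == 2:
            chains = chains[:, :, None]
        if names is None:
            names = [f"theta_{i}" for i in range(chains.shape[2])]
        out = _diagnostics(chains, names)
    out["converged"] = out["rhat"] < RHAT_LIMIT
    return out


def _run_sampler(
    log_prob,
    init: np.ndarray,
    init_scale: np.ndarray,
    settings: SamplerSettings,
    seed: int,
) -> np.ndarray:
    """Run the ensemble sampler; returns chains (n_chains, n_draws, ndim).

    The walker ensemble is sized as a multiple of ``settings.chains`` and
    at least twice the dimension; walkers are grouped into
    ``settings.chains`` chains for split-R-hat.
    """
    import emcee

    ndim = init.size
    per_chain = max(2, math.ceil((2 * ndim + 2) / settings.chains))
    n_walkers = settings.chains * per_chain
    rng = np.random.RandomState(seed & 0x7FFFFFFF)
    p0 = init[None, :] + init_scale[None, :] * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
    sampler._random = rng
    sampler.run_mcmc(p0, settings.draws, progress=False)
    burn = settings.draws // 2
    chain = sampler.get_chain(discard=burn)  # (draws-burn, n_walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (n_walkers, draws-burn, ndim)
    kept = chain.shape[1]
    return chain.reshape(settings.chains, per_chain * kept, ndim)


def _sample_with_escalation(
    log_prob,
    init: np.ndarray,
    init_scale: np.ndarray,
    names: list[str],
    settings: SamplerSettings,
    seed: int,
    escalated: SamplerSettings,
    mass: float,
    model_id: str,
    transforms: dict[str, object] | None = None,
) -> PosteriorSummary:
    chains = _run_sampler(log_prob, init, init_scale, settings, seed)
    diag = _diagnostics(chains, names)
    used, did_escalate = settings, False
    if (diag["rhat"] >= RHAT_LIMIT).any():
        logger.info("%s: R-hat >= %.2f, escalating to %s", model_id, RHAT_LIMIT, escalated)
        chains = _run_sampler(log_prob, init, init_scale, escalated, seed + 1)
        diag = _diagnostics(chains, names)
        used, did_escalate = escalated, True
    transforms = transforms or {}
    flat = {
        name: (transforms[name](chains[:, :, i].ravel()) if name in transforms
               else chains[:, :, i].ravel())
        for i, name in enumerate(names)
    }
    rows = []
    for i, name in enumerate(names):
        lo, hi = hdi(flat[name], mass)
        rows.append({
            "parameter": name,
            "mean": float(flat[name].mean()),
            "hdi_low": lo,
            "hdi_high": hi,
            "rhat": float(diag["rhat"].iloc[i]),
            "ess": float(diag["ess"].iloc[i]),
            "converged": bool(diag["rhat"].iloc[i] < RHAT_LIMIT),
        })
    table = pd.DataFrame(rows)
    return PosteriorSummary(
        model_id=model_id,
        table=table,
        mass=mass,
        converged=bool((table["rhat"] < RHAT_LIMIT).all()),
        escalated=did_escalate,
        settings=used,
        draws=flat,
    )


def _condition_design(condition: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies for the 4-level condition factor."""
    levels = sorted(condition.astype(str).unique())
    ref = levels[0]
    cols = [lvl for lvl in levels if lvl != ref]
    mat = np.column_stack([(condition.astype(str) == lvl).to_numpy(float) for lvl in cols]) \
        if cols else np.empty((len(condition), 0))
    return mat, [f"cond[{lvl}]" for lvl in cols]


def _half_t_logpdf(x: np.ndarray, scale: float, df: float = 3.0) -> np.ndarray:
    from scipy import stats

    return math.log(2.0) + stats.t.logpdf(x, df=df, scale=scale)


def fit_outcome_model(
    data: pd.DataFrame,
    outcome: str = "outcome",
    profile: str = "profile",
    dyad: str = "dyad_id",
    condition: str | None = None,
    include_interaction: bool = False,
    mass: float = 0.90,
    settings: SamplerSettings = DEFAULT_SETTINGS,
    escalated: SamplerSettings = ESCALATED_SETTINGS,
    seed: int = 0,
    model_id: str | None = None,
) -> PosteriorSummary:
    """Hierarchical normal model: person outcome ~ profile (x condition)
    with a dyad-varying intercept.

    outcome_ij = intercept + profile contrasts (+ condition terms)
    + u_j + e_ij, u_j ~ N(0, sigma_dyad^2), e_ij ~ N(0, sigma_resid^2).
    Profile contrasts are treatment-coded against the largest profile.
    Flat priors on the regression coefficients; half-Student-t(3) on the
    two scales.  The dyad intercepts are marginalized analytically.
    """
    df = data.sort_values([dyad, "person"] if "person" in data.columns else [dyad]).reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values")
    prof = df[profile].to_numpy()
    cats = np.unique(prof)
    if len(cats) < 2:
        raise ValueError("need at least 2 profiles present")
    counts = {c: int((prof == c).sum()) for c in cats}
    ref = max(cats, key=lambda c: (counts[c], -int(c) if np.issubdtype(type(c), np.integer) else 0))

    sizes = df.groupby(dyad).size()
    if not (sizes == 2).all():
        raise ValueError("every dyad must contribute exactly 2 persons")

    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for c in cats:
        if c == ref:
            continue
        cols.append((prof == c).astype(float))
        names.append(f"profile[{c}]")
    if condition is not None:
        cmat, cnames = _condition_design(df[condition])
        for j, nm in enumerate(cnames):
            cols.append(cmat[:, j])
            names.append(nm)
        if include_interaction:
            for c in cats:
                if c == ref:
                    continue
                pcol = (prof == c).astype(float)
                for j, nm in enumerate(cnames):
                    cols.append(pcol * cmat[:, j])
                    names.append(f"profile[{c}]:{nm}")
    design = np.column_stack(cols)
    p = design.shape[1]
    names = names + ["sigma_dyad", "sigma_resid"]
    ndim = p + 2

    sd_y = float(y.std(ddof=1)) or 1.0
    prior_scale = 2.5 * sd_y
    n_obs = len(y)
    n_dyads = n_obs // 2
    # the marginal likelihood grows without bound as the residual scale
    # approaches zero when persons within a dyad agree exactly; a small
    # relative floor keeps the posterior proper on such degenerate data
    log_s_floor = math.log(1e-4 * sd_y)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, :p]
        log_su, log_s = theta[:, p], theta[:, p + 1]
        out = np.full(theta.shape[0], -np.inf)
        ok = (np.abs(log_su) < 20) & (log_s >= log_s_floor) & (log_s < 20)
        if not ok.any():
            return out
        su2 = np.exp(2 * log_su[ok])
        s2 = np.exp(2 * log_s[ok])
        resid = y[None, :] - beta[ok] @ design.T
        r = resid.reshape(-1, n_dyads, 2)
        det = s2 * (s2 + 2 * su2)
        a = (s2 + su2)[:, None]
        quad = (a * (r[:, :, 0] ** 2 + r[:, :, 1] ** 2)
                - 2 * su2[:, None] * r[:, :, 0] * r[:, :, 1]) / det[:, None]
        ll = -0.5 * (n_obs * math.log(2 * math.pi)
                     + n_dyads * np.log(det) + quad.sum(axis=1))
        # half-t priors on the scales, with the log-scale Jacobian
        lp = (_half_t_logpdf(np.exp(log_su[ok]), prior_scale) + log_su[ok]
              + _half_t_logpdf(np.exp(log_s[ok]), prior_scale) + log_s[ok])
        out[ok] = ll + lp
        return out

    beta0, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid0 = y - design @ beta0
    s0 = max(float(resid0.std(ddof=1)), 1e-3)
    init = np.concatenate([beta0, [math.log(s0 / 2), math.log(s0)]])
    init_scale = np.concatenate([np.full(p, 0.1 * sd_y), [0.2, 0.2]])

    summary = _sample_with_escalation(
        log_prob, init, init_scale, names, settings, seed, escalated, mass,
        model_id or f"outcome:{outcome}~profile" + (f"x{condition}" if condition else ""),
        transforms={"sigma_dyad": np.exp, "sigma_resid": np.exp},
    )
    summary.extra.update({"reference_profile": ref, "design_columns": names[:p]})
    return summary


def fit_profile_model(
    assignments: pd.DataFrame,
    avg_diff: pd.DataFrame,
    condition: pd.DataFrame | None = None,
    include_interaction: bool = False,
    reference: int | str | None = None,
    mass: float = 0.90,
    settings: SamplerSettings = DEFAULT_SETTINGS,
    escalated: SamplerSettings = ESCALATED_SETTINGS,
    seed: int = 0,
    model_id: str | None = None,
) -> PosteriorSummary:
    """Multinomial-logit model of profile membership for one covariate.

    ``assignments`` has columns (dyad_id, profile); ``avg_diff`` is the
    output of :func:`decompose_avg_diff`; ``condition`` (optional) has
    columns (dyad_id, condition) with the 4-level factor.  The linear
    predictor for each non-reference profile contains an intercept, the
    dyad average and the dyad difference (plus condition terms and
    interactions when requested); the reference category defaults to the
    largest profile.  Flat priors throughout.
    """
    df = assignments.merge(avg_diff, on="dyad_id", how="inner")
    if condition is not None:
        df = df.merge(condition, on="dyad_id", how="inner")
    if df.empty:
        raise ValueError("no dyads left after merging assignments and covariates")
    prof = df["profile"].to_numpy()
    cats = list(np.unique(prof))
    if len(cats) < 2:
        raise ValueError("need at least 2 profiles present")
    counts = {c: int((prof == c).sum()) for c in cats}
    sparse = [c for c in cats if counts[c] < 3]
    if reference is None:
        reference = max(cats, key=lambda c: counts[c])
    elif reference not in cats:
        raise ValueError(f"reference {reference!r} is not an observed profile")
    others = [c for c in cats if c != reference]

    terms: list[np.ndarray] = [np.ones(len(df)), df["avg"].to_numpy(float), df["diff"].to_numpy(float)]
    term_names = ["intercept", "avg", "diff"]
    if condition is not None:
        cmat, cnames = _condition_design(df["condition"])
        for j, nm in enumerate(cnames):
            terms.append(cmat[:, j])
            term_names.append(nm)
        if include_interaction:
            for base, bname in (("avg", "avg"), ("diff", "diff")):
                bvals = df[base].to_numpy(float)
                for j, nm in enumerate(cnames):
                    terms.append(bvals * cmat[:, j])
                    term_names.append(f"{bname}:{nm}")
    design = np.column_stack(terms)
    n_terms = design.shape[1]
    k_other = len(others)
    ndim = k_other * n_terms
    names = [f"p{reference}_vs_p{c}:{t}" for c in others for t in term_names]
    y_idx = np.array([([reference] + others).index(c) for c in prof])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        b = theta.reshape(theta.shape[0], k_other, n_terms)
        logits = np.einsum("nt,bkt->bnk", design, b)  # (B, n, k_other)
        full = np.concatenate([np.zeros((*logits.shape[:2], 1)), logits], axis=2)
        mx = full.max(axis=2)
        lse = mx + np.log(np.exp(full - mx[..., None]).sum(axis=2))
        chosen = np.take_along_axis(full, y_idx[None, :, None], axis=2)[:, :, 0]
        ll = (chosen - lse).sum(axis=1)
        ll = np.where(np.all(np.abs(theta) < 50, axis=1), ll, -np.inf)
        return ll

    init = np.zeros(ndim)
    init_scale = np.full(ndim, 0.25)
    summary = _sample_with_escalation(
        log_prob, init, init_scale, names, settings, seed, escalated, mass,
        model_id or "profile~avg+diff" + (" x condition" if condition is not None else ""),
    )
    summary.extra.update({
        "reference_profile": reference,
        "categories": [reference] + others,
        "term_names": term_names,
        "design": design,
        "sparse_profiles": sparse,
    })
    if sparse:
        logger.warning("sparse profiles (<3 dyads): %s", sparse)
    return summary


def membership_probs(summary: PosteriorSummary) -> pd.DataFrame:
    """Fitted membership probabilities at the posterior mean, one row per
    dyad, columns ordered as summary.extra['categories']."""
    design = summary.extra["design"]
    cats = summary.extra["categories"]
    term_names = summary.extra["term_names"]
    ref = summary.extra["reference_profile"]
    b = np.array([
        [summary.parameter(f"p{ref}_vs_p{c}:{t}")["mean"] for t in term_names]
        for c in cats[1:]
    ])
    logits = design @ b.T
    full = np.column_stack([np.zeros(len(design)), logits])
    full -= full.max(axis=1, keepdims=True)
    probs = np.exp(full)
    probs /= probs.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, columns=[str(c) for c in cats])
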