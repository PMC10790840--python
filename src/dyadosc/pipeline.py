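"""End-to-end orchestration: simulate/load -> preprocess -> coupled-
oscillator fits -> latent profiles -> stage-2 models, with a manifest of
every artifact and reproducible seeding throughout."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import co_model, inference, preprocess, profiles, synth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_series", "preprocess_stage", "fit_stage",
           "profiles_stage", "models_stage"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``series_csv``/``covariates_csv`` point at existing input
    tables, or ``simulate`` is true and a synthetic study is generated.
    """

    out_dir: str = "pipeline_out"
    seed: int = 1
    simulate: bool = True
    n_dyads: int = 65
    regime_mixture: tuple[float, float, float] = (0.42, 0.26, 0.32)
    noise_sd: float = synth.DEFAULT_NOISE_SD_MS
    jitter: float = 0.10
    series_csv: str | None = None
    covariates_csv: str | None = None
    window_s: float = 2.0
    task_len_s: float = 300.0
    max_missing_frac: float = 0.10
    interp_gap_limit: int = 3
    taus: tuple[int, ...] = (3, 4)
    embeds: tuple[int, ...] = (3, 4, 5)
    delta: float = 1.0
    ks: tuple[int, ...] = (2, 3, 4)
    chosen_k: int = 3
    min_frac: float = 0.10
    n_starts: int = 20
    run_models: bool = True
    condition_models: bool = False
    hdi_mass: float = 0.90
    chains: int = 4
    draws: int = 2000
    escalate_chains: int = 10
    escalate_draws: int = 10_000
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("regime_mixture", "taus", "embeds", "ks"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for p in (self.series_csv, self.covariates_csv):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path missing or not found: {p}")
        if self.chosen_k not in self.ks:
            raise ValueError(f"chosen_k={self.chosen_k} not among candidate ks {self.ks}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_series(series: pd.DataFrame, window_s: float = 2.0) -> dict[int, tuple[preprocess.SampledSeries, preprocess.SampledSeries]]:
    """Long-format series table -> per-dyad pair of SampledSeries."""
    dyads = {}
    for dyad_id, grp in series.groupby("dyad_id"):
        pair = []
        for person in (0, 1):
            sub = grp[grp["person"] == person].sort_values("t_index")
            if sub.empty:
                raise ValueError(f"dyad {dyad_id} missing person {person}")
            pair.append(preprocess.SampledSeries(
                values=sub["ibi_ms"].to_numpy(float), dyad_id=dyad_id,
                person=person, window_s=window_s,
            ))
        dyads[dyad_id] = (pair[0], pair[1])
    return dyads


def preprocess_stage(
    series: pd.DataFrame, config: PipelineConfig
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """QC, interpolate, and detrend every dyad; returns the cleaned
    per-dyad series, a cleaned long table, and the QC report table."""
    dyads = load_series(series, config.window_s)
    cleaned, qc_rows, long_rows = {}, [], []
    for dyad_id, (a, b) in dyads.items():
        report, ca, cb = preprocess.qc_dyad(
            a, b, max_missing_frac=config.max_missing_frac,
            interp_gap_limit=config.interp_gap_limit,
        )
        qc_rows.append({
            "dyad_id": dyad_id, "include": report.include, "reason": report.reason,
            "n_missing_a": report.n_missing[0], "n_missing_b": report.n_missing[1],
            "longest_gap_a": report.longest_gap[0], "longest_gap_b": report.longest_gap[1],
            "n_interpolated_a": report.n_interpolated[0], "n_interpolated_b": report.n_interpolated[1],
        })
        if not report.include:
            continue
        da, db = preprocess.detrend_linear(ca), preprocess.detrend_linear(cb)
        cleaned[dyad_id] = (da, db)
        for s in (da, db):
            long_rows.append(pd.DataFrame({
                "dyad_id": dyad_id, "person": s.person,
                "t_index": s.t_index, "ibi_ms": s.values,
            }))
    cleaned_long = pd.concat(long_rows, ignore_index=True) if long_rows else pd.DataFrame()
    return cleaned, cleaned_long, pd.DataFrame(qc_rows)


def fit_stage(cleaned: dict, config: PipelineConfig) -> list[co_model.CoFit]:
    fits = []
    for dyad_id, (a, b) in cleaned.items():
        try:
            fits.append(co_model.co_grid_search(
                a, b, taus=config.taus, embeds=config.embeds, delta=config.delta,
            ))
        except ValueError as err:
            logger.warning("dyad %s: coupled-oscillator fit failed (%s)", dyad_id, err)
    if not fits:
        raise RuntimeError("coupled-oscillator stage produced no fits")
    return fits


def profiles_stage(
    fits: list[co_model.CoFit], config: PipelineConfig
) -> tuple[profiles.ProfileModel, pd.DataFrame, list[profiles.ProfileModel]]:
    z, record, dyad_ids = profiles.standardize_parameters(fits)
    models = [
        profiles.fit_lpa(z, k, n_starts=config.n_starts, seed=config.seed + 100 + k,
                         standardization=record, dyad_ids=dyad_ids)
        for k in config.ks
    ]
    report = profiles.select_profile_solution(models, min_frac=config.min_frac)
    chosen = models[list(config.ks).index(config.chosen_k)]
    return chosen, report, models


def models_stage(
    model: profiles.ProfileModel,
    covariates: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, inference.PosteriorSummary]:
    """Stage-2 models: for every scale column, (a) a profile-membership
    model on its dyad average/difference and (b) a person-outcome model
    predicted by profile with a dyad-varying intercept."""
    settings = inference.SamplerSettings(chains=config.chains, draws=config.draws)
    escalated = inference.SamplerSettings(chains=config.escalate_chains, draws=config.escalate_draws)
    assignments = pd.DataFrame({"dyad_id": model.dyad_ids, "profile": model.assignment})
    cond = (covariates.drop_duplicates("dyad_id")
            .assign(condition=lambda d: d["orientation"].astype(str) + "/" + d["social_interaction"].astype(str))
            [["dyad_id", "condition"]]) if {"orientation", "social_interaction"} <= set(covariates.columns) else None
    scale_cols = [c for c in covariates.columns
                  if c not in ("dyad_id", "person", "social_interaction", "orientation")]
    summaries: dict[str, inference.PosteriorSummary] = {}
    for i, cov in enumerate(scale_cols):
        avg_diff = inference.decompose_avg_diff(covariates, cov)
        summaries[f"profile~{cov}"] = inference.fit_profile_model(
            assignments, avg_diff,
            condition=cond if config.condition_models else None,
            include_interaction=config.condition_models,
            mass=config.hdi_mass, settings=settings, escalated=escalated,
            seed=config.seed + 200 + i, model_id=f"profile~{cov}",
        )
        person_data = covariates.merge(assignments, on="dyad_id")
        if cond is not None:
            person_data = person_data.merge(cond, on="dyad_id")
        summaries[f"{cov}~profile"] = inference.fit_outcome_model(
            person_data, outcome=cov,
            condition="condition" if (config.condition_models and cond is not None) else None,
            include_interaction=config.condition_models,
            mass=config.hdi_mass, settings=settings, escalated=escalated,
            seed=config.seed + 300 + i, model_id=f"{cov}~profile",
        )
    return summaries


def _plot_trajectories(preds, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for pred in preds:
        fig, ax = plt.subplots(figsize=(6, 3.2))
        t = np.arange(len(pred.x_a))
        ax.plot(t, pred.x_a, label="person 0", lw=1.5)
        ax.plot(t, pred.x_b, label="person 1", lw=1.5, ls="--")
        ax.set_xlabel("sample (2-s units)")
        ax.set_ylabel("detrended IBI (ms)")
        ax.set_title(f"Profile {pred.profile} predicted trajectory")
        ax.legend(frameon=False)
        fig.tight_layout()
        p = out_dir / f"profile_{pred.profile}_trajectory.png"
        fig.savefig(p, dpi=100, metadata={"Software": None})
        plt.close(fig)
        paths.append(p)
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write every artifact plus a checksum manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save(frame: pd.DataFrame, name: str) -> Path:
        p = out / name
        frame.to_csv(p, index=False, float_format="%.12g")
        artifacts.append(p)
        return p

    if config.simulate:
        study = synth.simulate_study(
            n_dyads=config.n_dyads, regime_mixture=config.regime_mixture,
            noise_sd=config.noise_sd, jitter=config.jitter, seed=config.seed,
        )
        series, covariates = study.series, study.covariates
        save(study.truth, "truth.csv")
    else:
        series = pd.read_csv(config.series_csv)
        covariates = pd.read_csv(config.covariates_csv)
    save(series, "series.csv")
    save(covariates, "covariates.csv")

    cleaned, cleaned_long, qc = preprocess_stage(series, config)
    save(cleaned_long, "cleaned_series.csv")
    save(qc, "qc_report.csv")

    fits = fit_stage(cleaned, config)
    save(co_model.fits_to_frame(fits), "co_parameters.csv")
    save(co_model.summarize_co(fits), "co_summary.csv")

    model, report, _ = profiles_stage(fits, config)
    save(report, "profile_selection.csv")
    assignments = pd.DataFrame({
        "dyad_id": model.dyad_ids, "profile": model.assignment,
        "max_responsibility": model.responsibilities.max(axis=1),
    })
    save(assignments, "assignments.csv")

    if config.make_plots:
        preds = profiles.predict_profile_trajectories(model, horizon=150)
        artifacts.extend(_plot_trajectories(preds, out))

    model_status = {}
    if config.run_models:
        summaries = models_stage(model, covariates, config)
        for name, summary in summaries.items():
            safe = name.replace("~", "_on_").replace("/", "-")
            save(summary.table, f"model_{safe}.csv")
            model_status[name] = {"converged": summary.converged, "escalated": summary.escalated}

    from . import __version__
    import numpy
    import sklearn

    manifest = {
        "versions": {"dyadosc": __version__, "numpy": numpy.__version__,
                     "sklearn": sklearn.__version__},
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "n_dyads_fit": len(fits),
        "chosen_k": config.chosen_k,
        "profile_counts": model.profile_counts.tolist(),
        "models": model_status,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
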