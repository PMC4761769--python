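"""End-to-end pipeline: simulate/load -> fit -> simplify -> envelope ->
classify -> report.

A single :class:`PipelineConfig` (typically loaded from YAML) drives every
stage; each run writes its artifacts plus a provenance record (config, seed,
package versions) so results are reproducible from the config alone.  Stage
failures abort with the stage name; record counts are logged after every
filter so the survey exclusions stay auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import envelope as env_mod
from . import glm, io, raster, synthetic, validation

logger = logging.getLogger("yeastclim")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with survey-scale defaults."""

    # inputs: either file paths or simulation parameters
    survey_path: str | None = None
    raster_path: str | None = None
    strains_path: str | None = None
    simulate_missing_inputs: bool = True
    # spans subtropical to boreal latitudes so that both species' envelopes
    # have in-range cells under the default temperature gradient
    raster_extent: tuple[float, float, float, float] = (0.0, 60.0, -10.0, 30.0)
    raster_resolution: float = 0.25
    raster_noise_sd_c: float = 1.0

    # model
    formula: str = ("n_sp_positive/n_samples ~ "
                    "girth_m * tmax_c * region * other_yeast_freq")
    alpha: float = 0.05

    # envelope
    envelope_policy: str = "paper"
    optimum_c: tuple[float, float] = env_mod.SP_OPTIMUM_C
    occurrence_c: tuple[float, float] = env_mod.SP_OCCURRENCE_C
    theta: float = 0.5
    species_offset_c: float = env_mod.DEFAULT_SPECIES_OFFSET_C

    seed: int = 0
    out_dir: str = "yeastclim_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        for key in ("raster_extent", "optimum_c", "occurrence_c"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@_stage("survey")
def _load_survey(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.survey_path:
        frame = io.read_survey(cfg.survey_path)
        logger.info("survey: read %d trees from %s", len(frame), cfg.survey_path)
    elif cfg.simulate_missing_inputs:
        frame = synthetic.simulate_survey(
            synthetic.SurveyParams(seed=cfg.seed)
        )
        logger.info("survey: simulated %d trees (seed %d)", len(frame), cfg.seed)
    else:
        raise PipelineError("stage 'survey' failed: no survey_path given and "
                            "simulation disabled")
    logger.info("survey: %d trees missing girth",
                int(frame["girth_m"].isna().sum()))
    return frame


@_stage("model")
def _fit_and_simplify(cfg: PipelineConfig, survey: pd.DataFrame):
    spec = glm.ModelSpec.from_formula(cfg.formula)
    final_spec, log = glm.stepwise_simplify(spec, survey, alpha=cfg.alpha)
    frame = survey.dropna(subset=list((spec.successes, spec.trials)
                                      + spec.variables))
    logger.info("model: fitted on %d complete-case trees; %d deletion tests",
                len(frame), len(log))
    model = glm.BinomialGLM(spec=final_spec).fit(frame)
    logger.info("model: final %s | residual deviance %.1f on %d df",
                final_spec.formula(), model.deviance_, model.df_residual_)
    return model, final_spec, log, frame


@_stage("envelope")
def _derive_envelopes(cfg: PipelineConfig, model, survey: pd.DataFrame):
    if cfg.envelope_policy == "paper":
        sp_env = env_mod.derive_ranges(
            [], policy="paper", optimum=tuple(cfg.optimum_c),
            occurrence=tuple(cfg.occurrence_c),
        )
    else:
        span = (float(survey["tmax_c"].min()), float(survey["tmax_c"].max()))
        grid = np.linspace(span[0], span[1], 201)
        q1, q2, q3 = survey["girth_m"].quantile([0.25, 0.5, 0.75])
        curves = []
        for girth in (q1, q2, q3):
            for region in sorted(survey["region"].unique()):
                curves.append(env_mod.predict_curve(model, girth, region, grid))
        sp_env = env_mod.derive_ranges(curves, policy="threshold",
                                       theta=cfg.theta, occurrence_span=span)
    sc_env = env_mod.shift_envelope(sp_env, cfg.species_offset_c,
                                    species="S. cerevisiae")
    logger.info("envelope: %s optimum %s occurrence %s -> %s occurrence %s",
                sp_env.species, sp_env.optimum, sp_env.occurrence,
                sc_env.species, sc_env.occurrence)
    return sp_env, sc_env


@_stage("raster")
def _load_raster(cfg: PipelineConfig) -> raster.RasterGrid:
    if cfg.raster_path:
        grid = raster.read_raster(cfg.raster_path)
        logger.info("raster: read %dx%d grid from %s", grid.n_rows,
                    grid.n_cols, cfg.raster_path)
    elif cfg.simulate_missing_inputs:
        grid = synthetic.simulate_raster(
            cfg.raster_extent, cfg.raster_resolution,
            noise_sd_c=cfg.raster_noise_sd_c, seed=cfg.seed + 1,
        )
        logger.info("raster: simulated %dx%d grid", grid.n_rows, grid.n_cols)
    else:
        raise PipelineError("stage 'raster' failed: no raster_path given and "
                            "simulation disabled")
    return grid


@_stage("classify")
def _classify(cfg: PipelineConfig, grid, sc_env) -> tuple[pd.DataFrame, pd.DataFrame]:
    if cfg.strains_path:
        strains = pd.read_csv(cfg.strains_path)
        logger.info("classify: read %d strains from %s", len(strains),
                    cfg.strains_path)
    elif cfg.simulate_missing_inputs:
        strains = synthetic.simulate_strains(
            grid, sc_env, synthetic.StrainSimParams(seed=cfg.seed + 2)
        )
        logger.info("classify: simulated %d strains", len(strains))
    else:
        raise PipelineError("stage 'classify' failed: no strains_path given "
                            "and simulation disabled")
    n0 = len(strains)
    strains = validation.filter_wine_associated(strains)
    logger.info("classify: %d strains retained after wine/vineyard filter "
                "(%d dropped)", len(strains), n0 - len(strains))
    classified = validation.classify_strains(strains, grid, sc_env.occurrence)
    return strains, classified


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incomplete = out / "INCOMPLETE"
    incomplete.write_text("run in progress\n")

    survey = _load_survey(config)
    io.write_survey(survey, out / "survey.csv")
    io.summarize_site(survey).to_csv(out / "site_summary.csv", index=False)

    model, final_spec, deletion_log, fit_frame = _fit_and_simplify(config, survey)
    deletion_log.to_csv(out / "deletion_log.csv", index=False)
    summary = model.result_.summary()
    summary.insert(0, "term", summary.index)
    summary.to_csv(out / "fit_summary.csv", index=False)

    sp_env, sc_env = _derive_envelopes(config, model, survey)
    (out / "envelope.json").write_text(json.dumps(
        {"S_paradoxus": json.loads(sp_env.to_json()),
         "S_cerevisiae": json.loads(sc_env.to_json()),
         "species_offset_c": config.species_offset_c}, indent=2) + "\n")

    grid = _load_raster(config)
    raster.write_raster(grid, out / "tmax.asc")

    strains, classified = _classify(config, grid, sc_env)
    classified.to_csv(out / "classified_strains.csv", index=False)
    report = validation.summarize_validation(classified)
    report.to_csv(out / "validation_report.csv", index=False)
    (out / "validation_report.txt").write_text(_text_report(
        model, final_spec, sp_env, sc_env, report))

    provenance = {
        "yeastclim_version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "final_model": final_spec.formula(),
        "n_trees_fit": int(model.result_.n_obs),
        "versions": _versions(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    incomplete.unlink()
    return out


def _text_report(model, final_spec, sp_env, sc_env, report) -> str:
    lines = [
        "yeastclim validation report",
        "===========================",
        f"final model: {final_spec.formula()}",
        f"residual deviance {model.deviance_:.1f} on {model.df_residual_} df "
        f"(null {model.null_deviance_:.1f})",
        f"deviance explained: "
        f"{glm.percent_deviance_explained(model.result_):.1f}%",
        "",
        f"{sp_env.species}: optimum {sp_env.optimum} degC, "
        f"occurrence {sp_env.occurrence} degC",
        f"{sc_env.species}: optimum {sc_env.optimum} degC, "
        f"occurrence {sc_env.occurrence} degC",
        "",
        report.to_string(index=False),
        "",
    ]
    return "\n".join(lines)


def _versions() -> dict:
    import scipy
    import sklearn

    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__}
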