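"""End-to-end pipeline orchestration.

Stages run in a fixed order — simulate -> kinematics -> scores ->
mass-univariate -> production-perception — and every artifact directory is
stamped with the config hash and seed.  Deterministic stages are
bit-identical under an identical config + seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .kinematics import recording_jerk
from .massuni import run_mass_univariate
from .perception import run_production_perception
from .scores import build_score_table, score_table_to_features
from .synthetic import (
    Dataset,
    ErLinkParams,
    SimulationConfig,
    generate_dataset,
    generate_er_ratings,
)

logger = logging.getLogger("facekin")


@dataclass
class PipelineArtifacts:
    out_dir: Path
    score_table: pd.DataFrame
    feature_table: pd.DataFrame
    massuni_summary: dict
    perception_summary: dict


def _simulation_config(config: fio.PipelineConfig) -> SimulationConfig:
    sim = config.simulation
    return SimulationConfig(
        n_per_group=sim.n_per_group, n_repetitions=sim.n_repetitions,
        emotions=tuple(config.emotions), conditions=tuple(config.conditions),
        frames_cued=sim.frames_cued,
        frames_spoken_mean=sim.frames_spoken_mean,
        frames_spoken_jitter=sim.frames_spoken_jitter,
        subject_sd=sim.subject_sd, repetition_sd=sim.repetition_sd,
        residual_sd=sim.residual_sd, seed=config.seed)


def run_pipeline(config: fio.PipelineConfig) -> PipelineArtifacts:
    """Run every stage on a freshly simulated dataset and write artifacts.

    Writes score tables (tidy CSV), per-family mass-univariate results
    (CSV + JSON summary), the production-perception report (JSON), a run
    manifest with the config hash and all derived sub-seeds, and a log.
    Any stage error aborts with a stage-named message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_log = out_dir / "run.log"
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    sub_seeds = {"simulate": config.seed, "er": config.seed + 1,
                 "massuni": config.seed + 2, "selection": config.seed + 3}
    try:
        try:
            sim_config = _simulation_config(config)
            dataset = generate_dataset(sim_config)
            logger.info("simulate: %d participants, %d recordings",
                        len(dataset.participants), dataset.n_recordings)
            fio.participants_frame(dataset.participants).to_csv(
                out_dir / "participants.csv", index=False)
            dataset.manifest.to_csv(out_dir / "manifest.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage simulate failed: {exc}") from exc

        try:
            jerk_dir = out_dir / "jerk"
            jerk_dir.mkdir(exist_ok=True)
            first = dataset.manifest.iloc[0]
            rec = dataset.get_recording(first.participant_id, first.condition,
                                        first.emotion, first.repetition)
            fio.write_jerk(recording_jerk(rec).values,
                           jerk_dir / "example_jerk.csv")
            logger.info("kinematics: jerk over %d valid frames "
                        "(from %d source frames)",
                        rec.n_frames - 4, rec.n_frames)
        except Exception as exc:
            raise RuntimeError(f"stage kinematics failed: {exc}") from exc

        try:
            ratings = generate_er_ratings(dataset.participants,
                                          ErLinkParams(), seed=sub_seeds["er"])
            score_table = build_score_table(dataset, er_ratings=ratings)
            score_table.to_csv(out_dir / "scores.csv", index=False)
            long = score_table.melt(
                id_vars=["participant_id", "group", "condition", "measure"],
                var_name="score", value_name="value")
            long.to_csv(out_dir / "scores_long.csv", index=False)
            logger.info("scores: %d rows", len(score_table))
        except Exception as exc:
            raise RuntimeError(f"stage scores failed: {exc}") from exc

        try:
            mu_opts = config.mass_univariate
            summaries = {}
            for emotion in config.emotions:
                result = run_mass_univariate(
                    dataset, measure="activation", condition="cued",
                    emotion=emotion, timing_mode=mu_opts.timing_mode,
                    n_permutations=mu_opts.n_permutations,
                    alpha=mu_opts.alpha, pooling=mu_opts.pooling,
                    engine=mu_opts.engine, seed=sub_seeds["massuni"])
                result.results.to_csv(
                    out_dir / f"massuni_activation_cued_{emotion}.csv",
                    index=False)
                summaries[f"activation_cued_{emotion}"] = {
                    "percent_significant": result.percent_significant,
                    "thresholds": {k: float(np.asarray(v).mean())
                                   for k, v in result.thresholds.items()},
                    "n_units": len(result.results),
                    "n_permutations": result.n_permutations,
                }
                logger.info(
                    "massuni %s: %d units, %d permutations, "
                    "%.2f%% significant (group)", emotion,
                    len(result.results), result.n_permutations,
                    result.percent_significant["group"])
            fio.write_json(summaries, out_dir / "massuni_summary.json")
        except Exception as exc:
            raise RuntimeError(f"stage mass-univariate failed: {exc}") from exc

        try:
            features = score_table_to_features(
                score_table,
                participants=fio.participants_frame(dataset.participants))
            features.to_csv(out_dir / "features.csv", index=False)
            report = {}
            counts = features["group"].value_counts()
            large_enough = features[features["group"].map(counts) >= 10]
            for group in counts[counts < 10].index:
                report[str(group)] = {
                    "skipped": f"only {int(counts[group])} participants; "
                               "feature screening needs >= 10"}
                logger.info("production-perception: skipped %s (n=%d)",
                            group, counts[group])
            analyses = {}
            if not large_enough.empty:
                analyses = run_production_perception(
                    large_enough,
                    n_iterations=config.selection.n_iterations,
                    n_estimators=config.selection.n_estimators,
                    alpha_entry=config.selection.alpha_entry,
                    seed=sub_seeds["selection"])
            for group, analysis in analyses.items():
                report[group] = {
                    "confirmed": analysis.selection.confirmed,
                    "tentative": analysis.selection.tentative,
                    "rejected": analysis.selection.rejected,
                    "shadow": analysis.selection.shadow_summary,
                }
                if analysis.regression is not None:
                    report[group]["regression"] = {
                        "entered": analysis.regression.entered,
                        "r2": analysis.regression.r2,
                        "steps": [vars(s) for s in analysis.regression.steps],
                    }
                if analysis.bayes is not None:
                    report[group]["bayes"] = {
                        "bf10": analysis.bayes.bf10,
                        "label": analysis.bayes.label,
                    }
            fio.write_json(report, out_dir / "perception_report.json")
            logger.info("production-perception: %s",
                        {g: r.get("confirmed") for g, r in report.items()})
        except Exception as exc:
            raise RuntimeError(
                f"stage production-perception failed: {exc}") from exc

        manifest = {
            "config_hash": fio.config_hash(config),
            "seed": config.seed,
            "sub_seeds": sub_seeds,
            "n_recordings": int(dataset.n_recordings),
            "elapsed_s": round(time.time() - t0, 2),
        }
        fio.write_json(manifest, out_dir / "run_manifest.json")
        return PipelineArtifacts(
            out_dir=out_dir, score_table=score_table,
            feature_table=features, massuni_summary=summaries,
            perception_summary=report)
    finally:
        logger.removeHandler(handler)
        handler.close()
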