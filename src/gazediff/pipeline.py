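"""End-to-end orchestration: simulate/load -> score -> frame stats -> classify.

A run writes a directory with frame statistics, per-video and per-category
summaries, the one-way category ANOVA, a descriptive full-cohort video
ranking, the repeated-holdout evaluation report and a provenance file
(config + seed + library versions), so every artefact is traceable to the
master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import EvalProtocol, repeated_protocol
from .features import FULL_COHORT, rank_videos, select_top_k, write_selection_manifest
from .framewise import (
    AnalysisConfig,
    UndefinedStatisticError,
    category_anova,
    category_summary,
    framewise_arrays,
    summarise,
    write_frame_stats_tsv,
    write_summary_tsv,
)
from .io_gaze import frame_matrices_from_table, read_video_manifest
from .questionnaire import read_questionnaire_csv, split_from_responses
from .simulate import Cohort, SimConfig, generate_cohort, write_cohort

logger = logging.getLogger("gazediff")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    protocol: EvalProtocol = field(default_factory=EvalProtocol)
    sim: SimConfig | None = field(default_factory=SimConfig)
    gaze_csv: str | None = None
    questionnaire_csv: str | None = None
    manifest_csv: str | None = None
    seed: int = 0
    write_cohort_files: bool = False
    write_frame_stats: bool = False


def _load_or_simulate(cfg: RunConfig) -> tuple[pd.DataFrame, list, dict, Cohort | None]:
    if cfg.gaze_csv is not None:
        gaze = pd.read_csv(cfg.gaze_csv, dtype={"participant_id": str, "video_id": str},
                       float_precision="round_trip")
        responses = read_questionnaire_csv(cfg.questionnaire_csv)
        manifest = read_video_manifest(cfg.manifest_csv)
        categories = dict(zip(manifest["video_id"], manifest["category"]))
        return gaze, responses, categories, None
    if cfg.sim is None:
        raise ValueError("either input CSV paths or a SimConfig is required")
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    cohort = generate_cohort(sim)
    return cohort.gaze, cohort.responses(), dict(sim.categories), cohort


def run_full_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Execute every stage and write the run directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        gaze, responses, categories, cohort = _load_or_simulate(cfg)
        if cohort is not None and cfg.write_cohort_files:
            write_cohort(cohort, out / "cohort")

        stage = "questionnaire"
        scores, groups = split_from_responses(responses)
        pd.DataFrame(
            [
                {
                    "participant_id": s.participant_id,
                    "total": s.total,
                    "anticipation": s.anticipation,
                    "desire": s.desire,
                    "relief": s.relief,
                    "group": groups.labels[s.participant_id],
                }
                for s in scores
            ]
        ).to_csv(out / "gacs_scores.tsv", sep="\t", index=False)
        logger.info(
            "median split at %.1f: low=%d high=%d",
            groups.split_value, groups.n_low, groups.n_high,
        )

        stage = "framewise"
        matrices = frame_matrices_from_table(gaze, fps=cfg.analysis.fps)
        summaries = []
        for video in sorted(matrices):
            res = framewise_arrays(matrices[video], groups, cfg.analysis)
            summaries.append(summarise(res, category=categories.get(video, "")))
            if cfg.write_frame_stats:
                write_frame_stats_tsv(res, out / f"frame_stats_{video}.tsv")
        write_summary_tsv(summaries, out / "video_summaries.tsv")

        stage = "category"
        cats = category_summary(summaries)
        try:
            anova = dataclasses.asdict(category_anova(summaries))
        except UndefinedStatisticError as exc:
            logger.warning("category ANOVA undefined: %s", exc)
            anova = None
        with open(out / "category_summary.json", "w") as fh:
            json.dump(
                {
                    "per_category": {c: {"mean_pct": m, "sem": s} for c, (m, s) in cats.items()},
                    "anova": anova,
                },
                fh,
                indent=2,
            )

        stage = "select"
        ranking = rank_videos(summaries, provenance=FULL_COHORT)
        selected = select_top_k(ranking, cfg.protocol.top_k)
        write_selection_manifest(ranking, selected, out / "selection_full_cohort.json")

        stage = "classify"
        protocol = dataclasses.replace(cfg.protocol, seed=cfg.seed)
        report = repeated_protocol(matrices, groups, cfg.analysis, protocol)
        report.to_json(out / "evaluation_report.json")
        report.summary().to_csv(out / "accuracy_summary.tsv", sep="\t", index=False)
        for rec in report.repetitions:
            logger.info(
                "repetition %d: selected=%s test_acc=%s",
                rec.repetition, rec.selected_videos, rec.test_accuracy,
            )

        stage = "provenance"
        import numpy, scipy, sklearn

        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {
                    "seed": cfg.seed,
                    "analysis": dataclasses.asdict(cfg.analysis),
                    "protocol": dataclasses.asdict(protocol),
                    "sim": _sim_dict(cfg.sim) if cfg.gaze_csv is None else None,
                    "inputs": {
                        "gaze_csv": cfg.gaze_csv,
                        "questionnaire_csv": cfg.questionnaire_csv,
                        "manifest_csv": cfg.manifest_csv,
                    },
                    "versions": {
                        "gazediff": __version__,
                        "numpy": numpy.__version__,
                        "scipy": scipy.__version__,
                        "sklearn": sklearn.__version__,
                    },
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _sim_dict(sim: SimConfig | None):
    if sim is None:
        return None
    d = dataclasses.asdict(sim)
    d["categories"] = dict(sim.categories)
    d["gacs_params"] = {k: list(v) for k, v in sim.gacs_params.items()}
    return d
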