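"""End-to-end orchestration of the morph-classification study.

One call (or one CLI invocation) runs every stage in order: load or
synthesize data → descriptive statistics → summer-morph allometry fit →
predictor selection → repeated 70/30 split evaluation per predictor of
interest → final threshold rules → morph density overlap → field
phenology.  All artifacts land in the output directory as plain CSV plus
a JSON run report that echoes the configuration, so identical
config + seed reproduces every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import RegressionFit, fit_summer_allometry
from .classifier import CANDIDATE_ORDER, Predictor, ThresholdRule, select_predictor
from .data_model import (
    ConfigurationError,
    InsufficientDataError,
    Morph,
    MorphometricDataset,
    Sex,
    Source,
    descriptive_stats,
    read_morphometrics,
    write_morphometrics,
)
from .phenology import evaluate_against_hidden_labels, monthly_morph_frequency
from .resampling import morph_density_overlap, repeated_split_evaluation
from .synthetic import (
    default_lab_specs,
    default_season_spec,
    generate_field_season,
    generate_lab_dataset,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger("suzukii_morphs")

_METRIC_KEYS = ("wing_length", "wing_width", "hind_tibia")


@dataclasses.dataclass
class RunConfig:
    """Flat-key configuration for one pipeline run (YAML-serializable)."""

    seed: int
    out_dir: str
    synthetic: bool = True
    lab_csv: Optional[str] = None
    field_csv: Optional[str] = None
    include_field: bool = True
    n_iterations: int = 500
    train_fraction: float = 0.7
    candidates: tuple[str, ...] = tuple(p.value for p in CANDIDATE_ORDER)
    predictors_of_interest: tuple[str, ...] = ("wing_length", "transformed_ratio")
    alpha_override: Optional[dict[str, float]] = None  # e.g. {"F": 1.008}
    stratified: bool = False
    with_replacement: bool = False
    pool_years: bool = True

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.synthetic and self.seed is None:
            raise ConfigurationError("synthetic runs require a seed")
        self.candidates = tuple(Predictor(c).value for c in self.candidates)
        self.predictors_of_interest = tuple(
            Predictor(p).value for p in self.predictors_of_interest
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidates"] = list(self.candidates)
        d["predictors_of_interest"] = list(self.predictors_of_interest)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclasses.dataclass
class RunReport:
    """Everything a run produced, with paths of the written artifacts."""

    config: RunConfig
    fits: dict[Sex, RegressionFit]
    selected: dict[Sex, tuple[Predictor, ThresholdRule]]
    summaries: list  # ResamplingSummary per (predictor, sex)
    final_rules: dict[tuple[str, str], ThresholdRule]  # (predictor, sex) -> rule
    overlaps: list
    phenology_paths: dict[str, str]
    field_evaluation: Optional[dict]
    artifact_paths: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "software_version": __version__,
            "config": self.config.to_dict(),
            "allometry_fits": {s.value: f.summary() for s, f in self.fits.items()},
            "selected_predictors": {
                s.value: {"predictor": p.value, **r.summary()}
                for s, (p, r) in self.selected.items()
            },
            "resampling_summaries": [s.to_row() for s in self.summaries],
            "final_rules": {
                f"{pred}/{sex}": rule.summary()
                for (pred, sex), rule in self.final_rules.items()
            },
            "density_overlaps": [o.summary() for o in self.overlaps],
            "phenology_tables": self.phenology_paths,
            "field_evaluation": self.field_evaluation,
            "artifacts": self.artifact_paths,
        }


def _load_or_synthesize(
    config: RunConfig, ss: np.random.SeedSequence
) -> tuple[MorphometricDataset, Optional[MorphometricDataset]]:
    lab_ss, field_ss = ss.spawn(2)
    if config.synthetic:
        lab = generate_lab_dataset(default_lab_specs(), lab_ss)
        field = (
            generate_field_season(default_season_spec(), field_ss)
            if config.include_field
            else None
        )
        return lab, field
    if not config.lab_csv:
        raise ConfigurationError("non-synthetic runs require lab_csv")
    lab = read_morphometrics(config.lab_csv)
    field = (
        read_morphometrics(config.field_csv)
        if (config.include_field and config.field_csv)
        else None
    )
    return lab, field


def _descriptives_frame(lab, field) -> pd.DataFrame:
    rows = []
    groups: list = [Morph.WINTER, Morph.SUMMER, Source.LAB, Source.FIELD]
    data = lab if field is None else lab + field
    for sex in Sex:
        for group in groups:
            for metric in _METRIC_KEYS:
                try:
                    st = descriptive_stats(data, sex, group, metric)
                except InsufficientDataError:
                    continue
                rows.append(
                    {
                        "sex": sex.value,
                        "group": st.group.value,
                        "metric": metric,
                        "n": st.n,
                        "mean_mm": round(st.mean, 4),
                        "sem_mm": round(st.sem, 4),
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write artifacts to ``config.out_dir``."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    data_ss, eval_ss = ss.spawn(2)
    artifacts: dict[str, str] = {}

    logger.info("stage=data seed=%s synthetic=%s", config.seed, config.synthetic)
    lab, field = _load_or_synthesize(config, data_ss)
    logger.info(
        "stage=data lab_n=%d field_n=%s", len(lab), len(field) if field else "none"
    )
    if config.synthetic:
        write_morphometrics(lab, out / "lab.csv")
        artifacts["lab_csv"] = str(out / "lab.csv")
        if field is not None:
            write_morphometrics(field, out / "field.csv")
            artifacts["field_csv"] = str(out / "field.csv")

    desc = _descriptives_frame(lab, field)
    desc.to_csv(out / "descriptive_stats.csv", index=False)
    artifacts["descriptive_stats"] = str(out / "descriptive_stats.csv")

    logger.info("stage=allometry")
    fits = {sex: fit_summer_allometry(lab, sex) for sex in Sex}
    if config.alpha_override:
        for sex_key, alpha in config.alpha_override.items():
            sex = Sex(sex_key)
            fits[sex] = fits[sex].with_alpha(alpha)
            logger.info("stage=allometry alpha_override sex=%s alpha=%s", sex.value, alpha)

    logger.info("stage=predictor_selection candidates=%s", config.candidates)
    selected = {
        sex: select_predictor(lab, sex, [Predictor(c) for c in config.candidates], fits)
        for sex in Sex
    }

    logger.info(
        "stage=resampling n_iterations=%d train_fraction=%s",
        config.n_iterations,
        config.train_fraction,
    )
    summaries = []
    final_rules: dict[tuple[str, str], ThresholdRule] = {}
    eval_children = eval_ss.spawn(len(config.predictors_of_interest) * len(Sex))
    k = 0
    for pred_name in config.predictors_of_interest:
        for sex in Sex:
            summary = repeated_split_evaluation(
                lab,
                sex,
                Predictor(pred_name),
                fits=fits,
                n_iterations=config.n_iterations,
                train_fraction=config.train_fraction,
                seed=eval_children[k],
                stratified=config.stratified,
                with_replacement=config.with_replacement,
            )
            k += 1
            summaries.append(summary)
            final_rules[(pred_name, sex.value)] = summary.final_rule
    pd.DataFrame([s.to_row() for s in summaries]).to_csv(
        out / "resampling_summary.csv", index=False
    )
    artifacts["resampling_summary"] = str(out / "resampling_summary.csv")

    logger.info("stage=overlap")
    overlaps = [
        morph_density_overlap(lab, sex, Predictor(pred_name), fits=fits)
        for pred_name in config.predictors_of_interest
        for sex in Sex
    ]

    phenology_paths: dict[str, str] = {}
    field_eval = None
    if field is not None:
        logger.info("stage=phenology pool_years=%s", config.pool_years)
        for pred_name in config.predictors_of_interest:
            rules = {
                sex: final_rules[(pred_name, sex.value)] for sex in Sex
            }
            table = monthly_morph_frequency(
                field, rules, fits=fits, pool_years=config.pool_years
            )
            path = out / f"phenology_{pred_name}.csv"
            table.to_csv(path)
            phenology_paths[pred_name] = str(path)
        if field.provenance.get("true_morphs"):
            ratio_rules = {
                sex: final_rules[(config.predictors_of_interest[-1], sex.value)]
                for sex in Sex
            }
            ev = evaluate_against_hidden_labels(field, ratio_rules, fits)
            field_eval = {
                "predictor": config.predictors_of_interest[-1],
                "n": ev.n,
                "accuracy_percent": round(ev.accuracy_percent, 4),
                "confusion": {f"{t}->{p}": c for (t, p), c in sorted(ev.confusion.items())},
            }

    report = RunReport(
        config=config,
        fits=fits,
        selected=selected,
        summaries=summaries,
        final_rules=final_rules,
        overlaps=overlaps,
        phenology_paths=phenology_paths,
        field_evaluation=field_eval,
        artifact_paths=artifacts,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["report"] = str(out / "report.json")
    logger.info("stage=done out_dir=%s", out)
    return report
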