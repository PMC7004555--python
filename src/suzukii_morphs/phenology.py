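"""Seasonal phenology of morph frequencies in field catches.

Field-trapped flies are classified with laboratory-trained threshold
rules (and laboratory-derived allometric intercepts — the application
direction is always lab → field), then aggregated per calendar month and
sex into counts and winter-morph frequencies.  Years are pooled by
default; months inside the observed span with zero catch are emitted
with n_total = 0 and an undefined frequency.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from typing import Optional

import pandas as pd

from .allometry import RegressionFit
from .classifier import ThresholdRule, classify
from .data_model import (
    ConfigurationError,
    InsufficientDataError,
    Morph,
    MorphometricDataset,
    Sex,
    ValidationError,
)

__all__ = [
    "PhenologyRow",
    "PhenologyTable",
    "FieldEvaluation",
    "monthly_morph_frequency",
    "evaluate_against_hidden_labels",
]


@dataclasses.dataclass(frozen=True)
class PhenologyRow:
    """Counts and winter-morph frequency for one (month, sex) cell.

    ``year`` is None when years are pooled.  ``winter_frequency`` is a
    percentage, or None for empty months (0/0 is undefined, not 0%).
    """

    year: Optional[int]
    month: int
    sex: Sex
    n_total: int
    n_winter: int
    n_summer: int
    winter_frequency: Optional[float]

    def __post_init__(self):
        if self.n_winter + self.n_summer != self.n_total:
            raise ValidationError("winter + summer counts must equal total")
        if self.n_total > 0:
            expected = 100.0 * self.n_winter / self.n_total
            if self.winter_frequency is None or abs(self.winter_frequency - expected) > 1e-9:
                raise ValidationError("frequency inconsistent with counts")
        elif self.winter_frequency is not None:
            raise ValidationError("empty month must have undefined frequency")


@dataclasses.dataclass(frozen=True)
class PhenologyTable:
    """Month × sex classification summary of a field season."""

    rows: tuple[PhenologyRow, ...]
    predictor: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "year": r.year if r.year is not None else "pooled",
                    "month": r.month,
                    "sex": r.sex.value,
                    "n_total": r.n_total,
                    "n_winter": r.n_winter,
                    "n_summer": r.n_summer,
                    "winter_frequency_pct": (
                        round(r.winter_frequency, 4) if r.winter_frequency is not None else ""
                    ),
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class FieldEvaluation:
    """Confusion of classified vs. hidden true morphs on synthetic field data."""

    n: int
    confusion: Mapping[tuple[str, str], int]  # (true, predicted) -> count
    accuracy_percent: float


def _month_span(keys: list[tuple[Optional[int], int]]) -> list[tuple[Optional[int], int]]:
    """All consecutive (year, month) cells between the first and last observed."""
    if not keys:
        return []
    if keys[0][0] is None:  # pooled: plain month range
        months = [k[1] for k in keys]
        return [(None, m) for m in range(min(months), max(months) + 1)]
    serial = [y * 12 + (m - 1) for y, m in keys]
    return [(s // 12, s % 12 + 1) for s in range(min(serial), max(serial) + 1)]


def monthly_morph_frequency(
    field_dataset: MorphometricDataset,
    rules: Mapping[Sex, ThresholdRule],
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
    pool_years: bool = True,
) -> PhenologyTable:
    """Classify field flies and tabulate winter-morph frequency per month.

    Frequencies are computed from pooled counts (pooling years then
    computing the frequency, not averaging yearly frequencies).
    """
    rules = {Sex(k): v for k, v in rules.items()}
    counts: dict[tuple[Optional[int], int, Sex], list[int]] = {}
    predictors = set()
    for rec in field_dataset:
        if rec.collection_date is None:
            raise ValidationError(f"field record {rec.id!r} has no collection date")
        if rec.sex not in rules:
            raise ConfigurationError(f"no threshold rule for sex {rec.sex.value}")
        rule = rules[rec.sex]
        predictors.add(rule.predictor.value)
        label = classify(rec, rule, fits)
        key = (
            None if pool_years else rec.collection_date.year,
            rec.collection_date.month,
            rec.sex,
        )
        cell = counts.setdefault(key, [0, 0])  # [winter, summer]
        cell[0 if label is Morph.WINTER else 1] += 1

    month_keys = sorted({(k[0], k[1]) for k in counts})
    rows: list[PhenologyRow] = []
    for year, month in _month_span(month_keys):
        for sex in sorted(rules, key=lambda s: s.value):
            n_w, n_s = counts.get((year, month, sex), (0, 0))
            total = n_w + n_s
            rows.append(
                PhenologyRow(
                    year=year,
                    month=month,
                    sex=sex,
                    n_total=total,
                    n_winter=n_w,
                    n_summer=n_s,
                    winter_frequency=(100.0 * n_w / total) if total else None,
                )
            )
    return PhenologyTable(rows=tuple(rows), predictor="/".join(sorted(predictors)))


def evaluate_against_hidden_labels(
    field_dataset: MorphometricDataset,
    rules: Mapping[Sex, ThresholdRule],
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
) -> FieldEvaluation:
    """Score classification against the generator's hidden true morphs.

    Only synthetic field datasets carry the truth (in provenance); real
    field data have no ground truth and raise.
    """
    truth = field_dataset.provenance.get("true_morphs")
    if not truth:
        raise ConfigurationError("dataset carries no hidden true morph labels")
    rules = {Sex(k): v for k, v in rules.items()}
    confusion: dict[tuple[str, str], int] = {}
    n = 0
    correct = 0
    for rec in field_dataset:
        if rec.id not in truth:
            raise ConfigurationError(f"record {rec.id!r} missing from hidden labels")
        if rec.sex not in rules:
            raise ConfigurationError(f"no threshold rule for sex {rec.sex.value}")
        predicted = classify(rec, rules[rec.sex], fits).value
        true = Morph(truth[rec.id]).value
        confusion[(true, predicted)] = confusion.get((true, predicted), 0) + 1
        n += 1
        correct += true == predicted
    if n == 0:
        raise InsufficientDataError("empty field dataset")
    return FieldEvaluation(n=n, confusion=confusion, accuracy_percent=100.0 * correct / n)
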