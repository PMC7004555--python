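"""Gini decision-stump morph classifier.

The classifier is the first (and only) split of a CART classification
tree: for one sex and one predictor it finds the cutoff maximizing the
Gini impurity decrease, with candidate cutoffs at midpoints between
consecutive distinct sorted values.  The decision direction is fixed by
the biology — winter morphs are the larger phenotype — so a record is
labelled winter iff its predictor value is ≥ the cutoff, and fitting
fails loudly if the training data contradict that orientation.

Candidate predictors are the three raw metrics plus the size-corrected
wing/tibia ratio (see :mod:`suzukii_morphs.allometry`).
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np

from .allometry import RegressionFit, transform_ratio
from .data_model import (
    ConfigurationError,
    DegenerateDataError,
    FlyRecord,
    InsufficientDataError,
    Metric,
    Morph,
    MorphometricDataset,
    MorphometricsError,
    Sex,
    ValidationError,
)

__all__ = [
    "Predictor",
    "CANDIDATE_ORDER",
    "NoSplitError",
    "ThresholdRule",
    "SplitResult",
    "gini_impurity",
    "best_split",
    "fit_threshold_rule",
    "select_predictor",
    "predictor_value",
    "classify",
    "misclassification_rate",
]


class NoSplitError(MorphometricsError):
    """No informative split exists (single class or constant values)."""


class Predictor(str, enum.Enum):
    WING_LENGTH = "wing_length"
    WING_WIDTH = "wing_width"
    HIND_TIBIA = "hind_tibia"
    TRANSFORMED_RATIO = "transformed_ratio"


# fixed tie-break order for predictor selection
CANDIDATE_ORDER: tuple[Predictor, ...] = (
    Predictor.WING_LENGTH,
    Predictor.WING_WIDTH,
    Predictor.HIND_TIBIA,
    Predictor.TRANSFORMED_RATIO,
)


@dataclasses.dataclass(frozen=True)
class ThresholdRule:
    """Per-sex decision stump: predictor value ≥ cutoff ⇒ winter morph.

    The boundary belongs to winter (inclusive ≥); the direction is fixed,
    not learned.
    """

    sex: Sex
    predictor: Predictor
    cutoff: float

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "predictor", Predictor(self.predictor))
        if not np.isfinite(self.cutoff):
            raise ValidationError("cutoff must be finite")

    def summary(self) -> dict:
        return {
            "sex": self.sex.value,
            "predictor": self.predictor.value,
            "cutoff": self.cutoff,
            "direction": ">= cutoff => winter",
        }


@dataclasses.dataclass(frozen=True)
class SplitResult:
    """Outcome of one optimal-threshold search."""

    cutoff: float
    gini_decrease: float
    left_counts: tuple[int, int]  # (winter, summer) with value < cutoff
    right_counts: tuple[int, int]  # (winter, summer) with value >= cutoff


def gini_impurity(n_winter: int, n_summer: int) -> float:
    """Gini impurity 1 − p_w² − p_s² of a two-class node; in [0, 0.5]."""
    total = n_winter + n_summer
    if total < 1:
        raise ValidationError("empty node has no impurity")
    p_w = n_winter / total
    p_s = n_summer / total
    return 1.0 - p_w * p_w - p_s * p_s


def best_split(values: Sequence[float], labels: Sequence[Morph]) -> SplitResult:
    """Gini-optimal threshold over midpoints of consecutive distinct values.

    Children are {value < cutoff} and {value ≥ cutoff}; the returned
    cutoff maximizes the weighted impurity decrease, ties broken toward
    the smaller cutoff.  Requires both classes present and at least two
    distinct values.
    """
    is_winter = np.array([Morph(l) is Morph.WINTER for l in labels], dtype=bool)
    return _best_split_arrays(np.asarray(values, dtype=float), is_winter)


def _best_split_arrays(v: np.ndarray, is_winter: np.ndarray) -> SplitResult:
    if v.size == 0:
        raise InsufficientDataError("no records to split")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite predictor value")
    if is_winter.size != v.size:
        raise ValidationError("values and labels length mismatch")
    n_w = int(is_winter.sum())
    n_s = int(v.size - n_w)
    if n_w == 0 or n_s == 0:
        raise NoSplitError("single-class node cannot be split")

    order = np.argsort(v, kind="stable")
    sv = v[order]
    sw = is_winter[order]
    distinct = np.nonzero(np.diff(sv) > 0)[0]  # boundary after index i
    if distinct.size == 0:
        raise NoSplitError("all predictor values identical")

    parent = gini_impurity(n_w, n_s)
    n = v.size
    cum_w = np.cumsum(sw)  # winter count among first i+1 sorted records
    left_n = distinct + 1
    left_w = cum_w[distinct]
    left_s = left_n - left_w
    right_n = n - left_n
    right_w = n_w - left_w
    right_s = n_s - left_s
    child = (
        left_n * (1.0 - (left_w / left_n) ** 2 - (left_s / left_n) ** 2)
        + right_n * (1.0 - (right_w / right_n) ** 2 - (right_s / right_n) ** 2)
    ) / n
    decrease = parent - child
    k = int(np.argmax(decrease))  # first max in ascending order: smallest cutoff wins ties
    i = int(distinct[k])
    return SplitResult(
        cutoff=float((sv[i] + sv[i + 1]) / 2.0),
        gini_decrease=float(decrease[k]),
        left_counts=(int(left_w[k]), int(left_s[k])),
        right_counts=(int(right_w[k]), int(right_s[k])),
    )


def _rule_values(
    records: Sequence[FlyRecord],
    predictor: Predictor,
    fits: Optional[Mapping[Sex, RegressionFit]],
) -> np.ndarray:
    return np.array([predictor_value(r, predictor, fits) for r in records])


def predictor_value(
    record: FlyRecord,
    predictor: Predictor,
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
) -> float:
    """The record's value of a predictor; computes the adjusted ratio on the fly."""
    predictor = Predictor(predictor)
    if predictor is Predictor.TRANSFORMED_RATIO:
        if fits is None or record.sex not in {Sex(k) for k in fits}:
            raise ConfigurationError(
                "transformed_ratio requires a regression fit for sex "
                f"{record.sex.value}"
            )
        fits = {Sex(k): f for k, f in fits.items()}
        return transform_ratio(record.wing_length, record.hind_tibia, fits[record.sex].alpha)
    value = record.metric(Metric(predictor.value))
    if value is None:
        raise ValidationError(
            f"record {record.id!r} lacks measurement {predictor.value}"
        )
    return value


def _check_direction(values: np.ndarray, is_winter: np.ndarray, predictor: Predictor):
    if values[is_winter].mean() < values[~is_winter].mean():
        raise DegenerateDataError(
            f"winter-class mean below summer-class mean for {predictor.value}: "
            "training data contradict the fixed 'winter is larger' direction"
        )


def fit_threshold_rule(
    dataset: MorphometricDataset,
    sex: Sex,
    predictor: Predictor,
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
) -> tuple[ThresholdRule, SplitResult]:
    """Fit the stump for one sex and predictor on labelled records."""
    sex = Sex(sex)
    predictor = Predictor(predictor)
    records = [r for r in dataset if r.sex is sex and r.morph is not Morph.UNKNOWN]
    if not records:
        raise InsufficientDataError(f"no labelled records for sex {sex.value}")
    values = _rule_values(records, predictor, fits)
    labels = [r.morph for r in records]
    is_winter = np.array([m is Morph.WINTER for m in labels])
    if is_winter.any() and (~is_winter).any():
        _check_direction(values, is_winter, predictor)
    split = best_split(values, labels)
    return ThresholdRule(sex=sex, predictor=predictor, cutoff=split.cutoff), split


def select_predictor(
    dataset: MorphometricDataset,
    sex: Sex,
    candidates: Sequence[Predictor] = CANDIDATE_ORDER,
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
) -> tuple[Predictor, ThresholdRule]:
    """Choose the candidate whose stump yields the largest Gini decrease.

    Ties break by the fixed candidate order (wing length, wing width,
    hind tibia, transformed ratio), then by smaller cutoff.  Candidates
    that cannot be split are skipped; if none can, the last error
    propagates.
    """
    ordered = [p for p in CANDIDATE_ORDER if p in {Predictor(c) for c in candidates}]
    if not ordered:
        raise ConfigurationError("no candidate predictors supplied")
    best: Optional[tuple[float, float, int, Predictor, ThresholdRule]] = None
    last_error: Optional[MorphometricsError] = None
    for rank, cand in enumerate(ordered):
        try:
            rule, split = fit_threshold_rule(dataset, sex, cand, fits)
        except (NoSplitError, ValidationError, ConfigurationError) as exc:
            last_error = exc
            continue
        key = (-split.gini_decrease, rank, split.cutoff)
        if best is None or key < best[:3]:
            best = (*key, cand, rule)
    if best is None:
        raise last_error if last_error is not None else NoSplitError(
            "no candidate predictor admits a split"
        )
    return best[3], best[4]


def classify(
    record: FlyRecord,
    rule: ThresholdRule,
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
) -> Morph:
    """Winter iff the record's predictor value is ≥ the rule's cutoff."""
    if record.sex is not rule.sex:
        raise ConfigurationError(
            f"rule is for sex {rule.sex.value}, record {record.id!r} is {record.sex.value}"
        )
    value = predictor_value(record, rule.predictor, fits)
    return Morph.WINTER if value >= rule.cutoff else Morph.SUMMER


def misclassification_rate(
    dataset: MorphometricDataset,
    rule: ThresholdRule,
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
) -> float:
    """Percent of labelled records the rule classifies incorrectly."""
    records = [r for r in dataset if r.sex is rule.sex]
    if not records:
        raise InsufficientDataError("no records to evaluate")
    wrong = 0
    for r in records:
        if r.morph is Morph.UNKNOWN:
            raise ValidationError(f"record {r.id!r} has no true morph label")
        if classify(r, rule, fits) is not r.morph:
            wrong += 1
    return 100.0 * wrong / len(records)
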