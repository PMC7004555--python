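"""Repeated train/validation evaluation and density overlap.

The threshold classifier is validated by Monte-Carlo cross-validation:
the labelled laboratory data are randomly partitioned 70/30 into
training and validation sets, the Gini stump is fitted on the training
set (refitting the allometric intercept on training summer morphs when
the predictor is the transformed ratio, so no validation information
leaks into the size correction), and the validation misclassification
rate recorded.  Over 500 such iterations the per-iteration cutoffs and
error percentages are summarized as mean/min/max; the final reported
rule uses the across-iteration mean cutoff.

Class separability is additionally quantified as the overlap coefficient
between the two morphs' Gaussian kernel density estimates,
100 · ∫ min(f̂_winter, f̂_summer) dx.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np
from scipy import stats as _scipy_stats

from .allometry import RegressionFit, fit_summer_allometry
from .classifier import (
    Predictor,
    ThresholdRule,
    fit_threshold_rule,
    misclassification_rate,
)
from .data_model import (
    DegenerateDataError,
    InsufficientDataError,
    Morph,
    MorphometricDataset,
    Sex,
    Source,
    ValidationError,
)

__all__ = [
    "ResamplingSummary",
    "OverlapResult",
    "partition",
    "repeated_split_evaluation",
    "density_overlap",
    "morph_density_overlap",
]


@dataclasses.dataclass(frozen=True)
class ResamplingSummary:
    """Mean/min/max cutoff and validation error over repeated splits.

    Per-iteration values are retained so alternative aggregations can be
    computed without rerunning.
    """

    sex: Sex
    predictor: Predictor
    n_iterations: int
    train_fraction: float
    cutoffs: tuple[float, ...]
    errors: tuple[float, ...]  # percent, in [0, 100]

    def __post_init__(self):
        if len(self.cutoffs) != self.n_iterations or len(self.errors) != self.n_iterations:
            raise ValidationError("per-iteration records must match n_iterations")

    @property
    def cutoff_mean(self) -> float:
        return float(np.mean(self.cutoffs))

    @property
    def cutoff_min(self) -> float:
        return float(np.min(self.cutoffs))

    @property
    def cutoff_max(self) -> float:
        return float(np.max(self.cutoffs))

    @property
    def error_mean(self) -> float:
        return float(np.mean(self.errors))

    @property
    def error_min(self) -> float:
        return float(np.min(self.errors))

    @property
    def error_max(self) -> float:
        return float(np.max(self.errors))

    @property
    def final_rule(self) -> ThresholdRule:
        """The reported rule: across-iteration mean cutoff."""
        return ThresholdRule(sex=self.sex, predictor=self.predictor, cutoff=self.cutoff_mean)

    def to_row(self) -> dict:
        """One row of the summary table (cutoff and error, mean/min/max)."""
        return {
            "sex": self.sex.value,
            "predictor": self.predictor.value,
            "n_iterations": self.n_iterations,
            "cutoff_mean": round(self.cutoff_mean, 4),
            "cutoff_min": round(self.cutoff_min, 4),
            "cutoff_max": round(self.cutoff_max, 4),
            "error_mean_pct": round(self.error_mean, 4),
            "error_min_pct": round(self.error_min, 4),
            "error_max_pct": round(self.error_max, 4),
        }


@dataclasses.dataclass(frozen=True)
class OverlapResult:
    """KDE overlap coefficient between the two morph densities, as percent."""

    sex: Sex
    predictor: Predictor
    overlap_percent: float
    bandwidth_winter: float
    bandwidth_summer: float
    bandwidth_rule: str = "silverman"

    def __post_init__(self):
        if not (0.0 <= self.overlap_percent <= 100.0):
            raise ValidationError("overlap_percent must lie in [0, 100]")

    def summary(self) -> dict:
        return {
            "sex": self.sex.value,
            "predictor": self.predictor.value,
            "overlap_percent": round(self.overlap_percent, 4),
            "bandwidth_winter": self.bandwidth_winter,
            "bandwidth_summer": self.bandwidth_summer,
            "bandwidth_rule": self.bandwidth_rule,
        }


def partition(
    dataset: MorphometricDataset,
    train_fraction: float,
    rng: np.random.Generator,
    stratified: bool = False,
    max_retries: int = 100,
) -> tuple[MorphometricDataset, MorphometricDataset]:
    """Random train/validation partition without replacement.

    Train size is round(train_fraction · n), clamped so both parts are
    non-empty.  Partitions leaving a single morph class in the training
    set are redrawn up to ``max_retries`` times before erroring.  With
    ``stratified`` the split is drawn within each morph class.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie strictly in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise InsufficientDataError("need at least 2 records to partition")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)

    labels = [r.morph for r in dataset]
    classes = {m for m in labels if m is not Morph.UNKNOWN}

    def draw() -> np.ndarray:
        if stratified and len(classes) > 1:
            picked: list[int] = []
            remaining = n_train
            class_idx = {
                m: [i for i, l in enumerate(labels) if l is m] for m in sorted(classes, key=lambda m: m.value)
            }
            items = list(class_idx.items())
            for j, (m, idx) in enumerate(items):
                # last class absorbs rounding so sizes are conserved
                take = remaining if j == len(items) - 1 else int(round(train_fraction * len(idx)))
                take = min(max(take, 1), len(idx) - 1, remaining)
                picked.extend(rng.choice(idx, size=take, replace=False))
                remaining -= take
            return np.array(sorted(picked))
        return np.sort(rng.choice(n, size=n_train, replace=False))

    for _ in range(max_retries):
        train_idx = draw()
        train_morphs = {labels[i] for i in train_idx} - {Morph.UNKNOWN}
        if len(classes) <= 1 or len(train_morphs) == len(classes):
            mask = np.zeros(n, dtype=bool)
            mask[train_idx] = True
            train = MorphometricDataset(
                [dataset[i] for i in range(n) if mask[i]], dataset.provenance
            )
            val = MorphometricDataset(
                [dataset[i] for i in range(n) if not mask[i]], dataset.provenance
            )
            return train, val
    raise DegenerateDataError(
        f"could not draw a two-class training set in {max_retries} attempts"
    )


def repeated_split_evaluation(
    dataset: MorphometricDataset,
    sex: Sex,
    predictor: Predictor,
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
    n_iterations: int = 500,
    train_fraction: float = 0.7,
    seed: int | np.random.SeedSequence = 0,
    stratified: bool = False,
    with_replacement: bool = False,
) -> ResamplingSummary:
    """Monte-Carlo cross-validation of the stump for one sex × predictor.

    Per iteration: partition the sex's labelled laboratory records
    70/30 (default); fit the Gini-optimal threshold on the training set
    (with a fresh training-only allometric fit when the predictor is the
    transformed ratio); score the validation misclassification rate.
    Iteration RNG streams are spawned from the seed, so iteration i is
    identical whatever ``n_iterations`` is.

    ``with_replacement`` switches to bootstrap resampling of the
    training set (validation = out-of-bag records), a sensitivity mode.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    sex = Sex(sex)
    predictor = Predictor(predictor)
    lab = dataset.filter(sex=sex, source=Source.LAB)
    if len({r.morph for r in lab}) < 2:
        raise InsufficientDataError(
            f"laboratory data for sex {sex.value} must contain both morphs"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_iterations)
    cutoffs: list[float] = []
    errors: list[float] = []
    if stratified or with_replacement:
        for child in children:
            rng = np.random.default_rng(child)
            if with_replacement:
                train, val = _bootstrap_partition(lab, train_fraction, rng)
            else:
                train, val = partition(lab, train_fraction, rng, stratified=stratified)
            iter_fits = fits
            if predictor is Predictor.TRANSFORMED_RATIO:
                iter_fits = {sex: fit_summer_allometry(train, sex)}
            rule, _ = fit_threshold_rule(train, sex, predictor, iter_fits)
            cutoffs.append(rule.cutoff)
            errors.append(misclassification_rate(val, rule, iter_fits))
    else:
        cutoffs, errors = _fast_simple_splits(
            lab, sex, predictor, fits, children, train_fraction
        )
    return ResamplingSummary(
        sex=sex,
        predictor=predictor,
        n_iterations=n_iterations,
        train_fraction=train_fraction,
        cutoffs=tuple(cutoffs),
        errors=tuple(errors),
    )


def _fast_simple_splits(
    lab: MorphometricDataset,
    sex: Sex,
    predictor: Predictor,
    fits: Optional[Mapping[Sex, RegressionFit]],
    children: Sequence[np.random.SeedSequence],
    train_fraction: float,
) -> tuple[list[float], list[float]]:
    """Array implementation of the simple-random iteration loop.

    Draw-for-draw equivalent to composing :func:`partition`,
    :func:`fit_summer_allometry`, the stump fit and
    :func:`misclassification_rate` per iteration (the reference path used
    for the stratified and bootstrap modes), just without per-record
    object churn.
    """
    from .classifier import _best_split_arrays, predictor_value

    n = len(lab)
    if n < 2:
        raise InsufficientDataError("need at least 2 records to partition")
    is_winter = np.array([r.morph is Morph.WINTER for r in lab])
    refit_alpha = predictor is Predictor.TRANSFORMED_RATIO
    if refit_alpha:
        wing = np.array([r.wing_length for r in lab])
        tibia = np.array([r.hind_tibia for r in lab])
        summer = np.array([r.morph is Morph.SUMMER for r in lab])
        values = np.empty(0)
    else:
        values = np.array([predictor_value(r, predictor, fits) for r in lab])
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    cutoffs: list[float] = []
    errors: list[float] = []
    for child in children:
        rng = np.random.default_rng(child)
        for _ in range(100):
            train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
            tw = is_winter[train_idx]
            if tw.any() and not tw.all():
                break
        else:
            raise DegenerateDataError(
                "could not draw a two-class training set in 100 attempts"
            )
        if refit_alpha:
            ts = train_idx[summer[train_idx]]
            if ts.size < 3:
                raise InsufficientDataError(
                    f"need >= 3 lab summer records for sex {sex.value}, got {ts.size}"
                )
            x = tibia[ts]
            y = wing[ts]
            if np.ptp(x) == 0.0:
                raise DegenerateDataError(
                    "zero variance in hind tibia length: OLS undefined"
                )
            xbar = x.mean()
            slope = float(((x - xbar) * y).sum() / ((x - xbar) ** 2).sum())
            alpha = float(y.mean() - slope * xbar)
            values = (wing - alpha) / tibia
        tv = values[train_idx]
        if tv[tw].mean() < tv[~tw].mean():
            raise DegenerateDataError(
                f"winter-class mean below summer-class mean for {predictor.value}: "
                "training data contradict the fixed 'winter is larger' direction"
            )
        split = _best_split_arrays(tv, tw)
        val_mask = np.ones(n, dtype=bool)
        val_mask[train_idx] = False
        wrong = (values[val_mask] >= split.cutoff) != is_winter[val_mask]
        cutoffs.append(split.cutoff)
        errors.append(100.0 * float(wrong.mean()))
    return cutoffs, errors


def _bootstrap_partition(
    dataset: MorphometricDataset, train_fraction: float, rng: np.random.Generator
) -> tuple[MorphometricDataset, MorphometricDataset]:
    """Bootstrap train sample; out-of-bag records form the validation set."""
    n = len(dataset)
    for _ in range(100):
        idx = rng.integers(0, n, size=int(round(train_fraction * n)))
        chosen = set(int(i) for i in idx)
        if len(chosen) == n:  # no out-of-bag records, redraw
            continue
        train_records = [
            dataclasses.replace(dataset[int(i)], id=f"{dataset[int(i)].id}#b{k}")
            for k, i in enumerate(idx)
        ]
        morphs = {r.morph for r in train_records} - {Morph.UNKNOWN}
        if len(morphs) < 2:
            continue
        val = MorphometricDataset(
            [dataset[i] for i in range(n) if i not in chosen], dataset.provenance
        )
        return MorphometricDataset(train_records, dataset.provenance), val
    raise DegenerateDataError("could not draw a usable bootstrap sample")


def density_overlap(
    values_winter: Sequence[float],
    values_summer: Sequence[float],
    grid_size: int = 1024,
    bw_method: str = "silverman",
) -> tuple[float, float, float]:
    """Overlap coefficient of two Gaussian KDEs, in percent.

    Each class gets its own Gaussian KDE (Silverman's bandwidth rule by
    default); the overlap is 100 · ∫ min(f̂₁, f̂₂) dx by the trapezoid
    rule on a shared grid spanning both samples padded by 3 bandwidths.
    Returns (overlap_percent, bandwidth_winter, bandwidth_summer).
    Symmetric in its two samples.
    """
    a = np.asarray(values_winter, dtype=float)
    b = np.asarray(values_summer, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each class needs >= 2 values for a KDE")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise DegenerateDataError("zero-variance sample: KDE bandwidth undefined")
    kde_a = _scipy_stats.gaussian_kde(a, bw_method=bw_method)
    kde_b = _scipy_stats.gaussian_kde(b, bw_method=bw_method)
    bw_a = float(kde_a.factor * np.std(a, ddof=1))
    bw_b = float(kde_b.factor * np.std(b, ddof=1))
    pad = 3.0 * max(bw_a, bw_b)
    lo = min(a.min(), b.min()) - pad
    hi = max(a.max(), b.max()) + pad
    grid = np.linspace(lo, hi, grid_size)
    overlap = float(np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid))
    return min(max(100.0 * overlap, 0.0), 100.0), bw_a, bw_b


def morph_density_overlap(
    dataset: MorphometricDataset,
    sex: Sex,
    predictor: Predictor,
    fits: Optional[Mapping[Sex, RegressionFit]] = None,
    grid_size: int = 1024,
    bw_method: str = "silverman",
) -> OverlapResult:
    """Density overlap between the two lab morphs on one predictor."""
    from .classifier import predictor_value  # local import avoids cycle at module load

    sex = Sex(sex)
    predictor = Predictor(predictor)
    lab = dataset.filter(sex=sex, source=Source.LAB)
    winter = [predictor_value(r, predictor, fits) for r in lab if r.morph is Morph.WINTER]
    summer = [predictor_value(r, predictor, fits) for r in lab if r.morph is Morph.SUMMER]
    pct, bw_w, bw_s = density_overlap(winter, summer, grid_size, bw_method)
    return OverlapResult(
        sex=sex,
        predictor=predictor,
        overlap_percent=pct,
        bandwidth_winter=bw_w,
        bandwidth_summer=bw_s,
        bandwidth_rule=str(bw_method),
    )
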