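"""Synthetic laboratory cohorts and field seasons.

No per-fly measurements are published for this system, only per-cohort
summary statistics (n, mean, SEM for each sex × morph) and the
summer-morph wing-on-tibia regression intercepts.  This module
regenerates data with exactly that statistical structure so every
pipeline stage is testable end to end:

* laboratory cohorts — hind tibia length drawn Normal(μ, σ) per cohort;
  wing length generated as ``intercept + slope × tibia + ε`` so the
  allometric coupling between wing and body size is real and the
  size-corrected ratio transform has something to correct; wing width an
  independent Normal.  Marginal SDs are reconstructed from printed SEMs
  as SEM·√n.
* field seasons — month-indexed mixtures of the winter and summer cohort
  distributions with configurable per-month catch sizes and winter-morph
  proportions.  True morph labels are hidden in dataset provenance so a
  classifier applied to synthetic field data cannot see them.

All draws are rejected-and-resampled while non-positive, never clipped,
so lengths stay strictly positive without point masses at a bound.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime
import math
from collections.abc import Mapping, Sequence
from typing import Optional, Union

import numpy as np

from .data_model import (
    FlyRecord,
    Morph,
    MorphometricDataset,
    Sex,
    Source,
    ValidationError,
)

__all__ = [
    "CohortSpec",
    "SeasonSpec",
    "TABLE1_SUMMARY",
    "SUMMER_INTERCEPTS",
    "default_lab_specs",
    "default_season_spec",
    "generate_lab_cohort",
    "generate_lab_dataset",
    "generate_field_season",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws with non-positive values rejected and redrawn."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0.0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0.0
    return out


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for one sex × morph laboratory cohort.

    Wing length is coupled to hind tibia length through a linear
    allometry ``wing = wing_intercept + wing_slope · tibia + ε`` with
    ``ε ~ Normal(0, wing_resid_sd)``, so the implied marginal wing mean
    is ``wing_intercept + wing_slope · tibia_mean``.  All lengths in mm.
    """

    sex: Sex
    morph: Morph
    n: int
    tibia_mean: float
    tibia_sd: float
    wing_slope: float
    wing_intercept: float
    wing_resid_sd: float
    width_mean: float
    width_sd: float

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "morph", Morph(self.morph))
        if self.n < 1:
            raise ValidationError("cohort n must be >= 1")
        for name in ("tibia_sd", "wing_resid_sd", "width_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("tibia_mean", "width_mean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def wing_mean(self) -> float:
        """Implied marginal mean wing length (mm)."""
        return self.wing_intercept + self.wing_slope * self.tibia_mean

    @property
    def wing_marginal_sd(self) -> float:
        """Implied marginal SD of wing length (mm)."""
        return math.sqrt(
            self.wing_resid_sd**2 + (self.wing_slope * self.tibia_sd) ** 2
        )


# Laboratory summary statistics: n, then (mean, SEM) in mm for wing
# length, wing width and hind tibia length, by sex and morph.
TABLE1_SUMMARY: dict[tuple[Sex, Morph], dict] = {
    (Sex.FEMALE, Morph.WINTER): dict(
        n=41, wing=(2.97, 0.020), width=(1.23, 0.011), tibia=(0.80, 0.005)
    ),
    (Sex.FEMALE, Morph.SUMMER): dict(
        n=56, wing=(2.39, 0.015), width=(0.99, 0.007), tibia=(0.73, 0.004)
    ),
    (Sex.MALE, Morph.WINTER): dict(
        n=42, wing=(2.69, 0.018), width=(1.08, 0.025), tibia=(0.75, 0.003)
    ),
    (Sex.MALE, Morph.SUMMER): dict(
        n=50, wing=(2.15, 0.015), width=(0.87, 0.006), tibia=(0.68, 0.004)
    ),
}

# Reported intercepts of the summer-morph wing-on-tibia regression (mm).
SUMMER_INTERCEPTS: dict[Sex, float] = {Sex.FEMALE: 1.003, Sex.MALE: 0.762}


def _marginal_sd(mean_sem: tuple[float, float], n: int) -> float:
    # printed tables give SEM; SD = SEM * sqrt(n)
    return mean_sem[1] * math.sqrt(n)


def default_lab_specs(
    summer_intercepts: Optional[Mapping[Sex, float]] = None,
) -> dict[tuple[Sex, Morph], CohortSpec]:
    """Cohort specs reproducing the published laboratory summary statistics.

    Per sex, the summer-morph wing–tibia slope is derived from the
    reported summer regression intercept and the summer marginal means:
    ``slope = (wing_mean − intercept) / tibia_mean``.  Winter cohorts
    share the sex's slope, with their intercept chosen so the marginal
    wing mean matches the printed value.  Residual wing SD is set so the
    implied marginal wing SD matches the printed SEM·√n, i.e.
    ``resid_sd² = marginal_sd² − slope²·tibia_sd²`` (floored at zero).
    """
    intercepts = dict(SUMMER_INTERCEPTS)
    if summer_intercepts:
        intercepts.update({Sex(k): float(v) for k, v in summer_intercepts.items()})
    specs: dict[tuple[Sex, Morph], CohortSpec] = {}
    for sex in Sex:
        summer = TABLE1_SUMMARY[(sex, Morph.SUMMER)]
        slope = (summer["wing"][0] - intercepts[sex]) / summer["tibia"][0]
        for morph in (Morph.WINTER, Morph.SUMMER):
            row = TABLE1_SUMMARY[(sex, morph)]
            n = row["n"]
            tibia_sd = _marginal_sd(row["tibia"], n)
            wing_sd = _marginal_sd(row["wing"], n)
            intercept = row["wing"][0] - slope * row["tibia"][0]
            resid_var = wing_sd**2 - (slope * tibia_sd) ** 2
            specs[(sex, morph)] = CohortSpec(
                sex=sex,
                morph=morph,
                n=n,
                tibia_mean=row["tibia"][0],
                tibia_sd=tibia_sd,
                wing_slope=slope,
                wing_intercept=intercept,
                wing_resid_sd=math.sqrt(max(resid_var, 0.0)),
                width_mean=row["width"][0],
                width_sd=_marginal_sd(row["width"], n),
            )
    return specs


def generate_lab_cohort(
    spec: CohortSpec, seed: SeedLike, id_prefix: Optional[str] = None
) -> MorphometricDataset:
    """Draw one laboratory cohort from its generating spec.

    Reproducible for a given seed: same spec + same seed give identical
    datasets.
    """
    rng = _rng(seed)
    prefix = id_prefix or f"lab-{spec.sex.value}-{spec.morph.value}"
    tibia = _positive_normal(rng, spec.tibia_mean, spec.tibia_sd, spec.n)
    wing = spec.wing_intercept + spec.wing_slope * tibia + rng.normal(
        0.0, spec.wing_resid_sd, size=spec.n
    )
    bad = wing <= 0.0
    while bad.any():  # redraw only the residual, keeping the tibia draw
        wing[bad] = spec.wing_intercept + spec.wing_slope * tibia[bad] + rng.normal(
            0.0, spec.wing_resid_sd, size=int(bad.sum())
        )
        bad = wing <= 0.0
    width = _positive_normal(rng, spec.width_mean, spec.width_sd, spec.n)
    records = [
        FlyRecord(
            id=f"{prefix}-{i:04d}",
            sex=spec.sex,
            source=Source.LAB,
            morph=spec.morph,
            wing_length=float(wing[i]),
            wing_width=float(width[i]),
            hind_tibia=float(tibia[i]),
        )
        for i in range(spec.n)
    ]
    return MorphometricDataset(
        records, provenance={"origin": "synthetic-lab", "spec": dataclasses.asdict(spec)}
    )


def generate_lab_dataset(
    specs: Mapping[tuple[Sex, Morph], CohortSpec], seed: SeedLike
) -> MorphometricDataset:
    """Generate all cohorts in a fixed (sex, morph) order from one seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    keys = sorted(specs, key=lambda k: (k[0].value, k[1].value))
    children = ss.spawn(len(keys))
    dataset = MorphometricDataset([], provenance={"origin": "synthetic-lab"})
    for key, child in zip(keys, children):
        dataset = dataset + generate_lab_cohort(specs[key], child)
    return dataset


@dataclasses.dataclass(frozen=True)
class SeasonSpec:
    """A field season as month-indexed mixtures of the two morphs.

    ``months`` are (year, month) pairs; ``counts`` gives per-sex catch
    totals per month; ``winter_props`` the per-month probability that a
    caught fly is a (hidden) winter morph.  Morphometrics for each hidden
    morph are drawn from ``cohorts`` — by default the laboratory cohort
    specs, since no separate field variance structure is published.
    """

    months: tuple[tuple[int, int], ...]
    counts: Mapping[Sex, tuple[int, ...]]
    winter_props: tuple[float, ...]
    cohorts: Mapping[tuple[Sex, Morph], CohortSpec]
    site: str = "synthetic-site"

    def __post_init__(self):
        object.__setattr__(self, "months", tuple((int(y), int(m)) for y, m in self.months))
        object.__setattr__(
            self,
            "counts",
            {Sex(k): tuple(int(c) for c in v) for k, v in dict(self.counts).items()},
        )
        object.__setattr__(self, "winter_props", tuple(float(p) for p in self.winter_props))
        k = len(self.months)
        if len(self.winter_props) != k:
            raise ValidationError("winter_props length must match months")
        for sex, row in self.counts.items():
            if len(row) != k:
                raise ValidationError(f"counts[{sex.value}] length must match months")
            if any(c < 0 for c in row):
                raise ValidationError("counts must be >= 0")
        if any(not (0.0 <= p <= 1.0) for p in self.winter_props):
            raise ValidationError("winter proportions must lie in [0, 1]")


def default_season_spec(
    cohorts: Optional[Mapping[tuple[Sex, Morph], CohortSpec]] = None,
) -> SeasonSpec:
    """A plausible single trapping season, June–October.

    Catch totals sum to the published field sample sizes (116 females,
    123 males); the winter-morph proportion starts high in June, dips in
    mid-summer and rises to 1.0 by October, the qualitative seasonal
    pattern reported for Minnesota trap catches.
    """
    return SeasonSpec(
        months=((2017, 6), (2017, 7), (2017, 8), (2017, 9), (2017, 10)),
        counts={
            Sex.FEMALE: (14, 28, 36, 24, 14),
            Sex.MALE: (14, 30, 40, 25, 14),
        },
        winter_props=(0.55, 0.15, 0.35, 0.80, 1.0),
        cohorts=cohorts or default_lab_specs(),
    )


def generate_field_season(spec: SeasonSpec, seed: SeedLike) -> MorphometricDataset:
    """Draw a field season; true morphs are hidden in provenance.

    Each fly's hidden morph is Bernoulli(month's winter proportion); its
    morphometrics come from the matching cohort spec; its collection date
    is uniform within the month.  Records carry ``source=field`` and
    ``morph=unknown`` — the truth lives only in
    ``provenance["true_morphs"]`` (id → "winter"/"summer").
    """
    rng = _rng(seed)
    records: list[FlyRecord] = []
    truth: dict[str, str] = {}
    counter = 0
    for mi, (year, month) in enumerate(spec.months):
        days = calendar.monthrange(year, month)[1]
        for sex in sorted(spec.counts, key=lambda s: s.value):
            n = spec.counts[sex][mi]
            if n == 0:
                continue
            is_winter = rng.random(n) < spec.winter_props[mi]
            for j in range(n):
                morph = Morph.WINTER if is_winter[j] else Morph.SUMMER
                cohort = spec.cohorts[(sex, morph)]
                tibia = float(_positive_normal(rng, cohort.tibia_mean, cohort.tibia_sd, 1)[0])
                wing = cohort.wing_intercept + cohort.wing_slope * tibia + float(
                    rng.normal(0.0, cohort.wing_resid_sd)
                )
                while wing <= 0.0:
                    wing = cohort.wing_intercept + cohort.wing_slope * tibia + float(
                        rng.normal(0.0, cohort.wing_resid_sd)
                    )
                width = float(_positive_normal(rng, cohort.width_mean, cohort.width_sd, 1)[0])
                rec_id = f"field-{counter:05d}"
                counter += 1
                records.append(
                    FlyRecord(
                        id=rec_id,
                        sex=sex,
                        source=Source.FIELD,
                        morph=Morph.UNKNOWN,
                        wing_length=wing,
                        wing_width=width,
                        hind_tibia=tibia,
                        collection_date=datetime.date(
                            year, month, int(rng.integers(1, days + 1))
                        ),
                        site=spec.site,
                    )
                )
                truth[rec_id] = morph.value
    return MorphometricDataset(
        records, provenance={"origin": "synthetic-field", "true_morphs": truth}
    )
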