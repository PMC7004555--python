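"""Domain types and delimited-text I/O for fly morphometric records.

The central object is the :class:`MorphometricDataset`, an ordered,
validated collection of :class:`FlyRecord` — one row per measured fly with
sex, rearing source (laboratory colony vs. field trap), seasonal morph
label (known only for laboratory-reared flies), and three linear
measurements in millimetres: wing length, wing width and hind tibia
length.  Field records additionally carry a collection date and site so
that downstream phenology can bin catches by calendar month.

Datasets round-trip through plain CSV with the documented default header::

    id,sex,source,morph,wing_length_mm,wing_width_mm,hind_tibia_mm,collection_date,site

Summary statistics (group mean ± SEM, pooled two-sample t) live here as
well because every later stage consumes them.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import math
from collections.abc import Iterable, Iterator, Mapping
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "Sex",
    "Source",
    "Morph",
    "Metric",
    "FlyRecord",
    "MorphometricDataset",
    "DescriptiveStats",
    "MorphometricsError",
    "SchemaError",
    "ValidationError",
    "InsufficientDataError",
    "DegenerateDataError",
    "ConfigurationError",
    "DEFAULT_DIALECT",
    "read_morphometrics",
    "write_morphometrics",
    "descriptive_stats",
    "pooled_t_test",
]


class MorphometricsError(Exception):
    """Base class for all package errors."""


class SchemaError(MorphometricsError):
    """An input file is missing a required column."""


class ValidationError(MorphometricsError):
    """A record violates a domain invariant (non-positive length, bad enum...)."""


class InsufficientDataError(MorphometricsError):
    """Too few records to perform the requested computation."""


class DegenerateDataError(MorphometricsError):
    """Data with no usable variation (zero variance, inverted class means...)."""


class ConfigurationError(MorphometricsError):
    """A required fit/rule/parameter is absent or mismatched."""


class Sex(str, enum.Enum):
    FEMALE = "F"
    MALE = "M"


class Source(str, enum.Enum):
    LAB = "lab"
    FIELD = "field"


class Morph(str, enum.Enum):
    WINTER = "winter"
    SUMMER = "summer"
    UNKNOWN = "unknown"


class Metric(str, enum.Enum):
    """The three measured morphometrics (all in mm)."""

    WING_LENGTH = "wing_length"
    WING_WIDTH = "wing_width"
    HIND_TIBIA = "hind_tibia"


def _coerce(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError:
        raise ValidationError(
            f"invalid {enum_cls.__name__} value {value!r}; "
            f"expected one of {[e.value for e in enum_cls]}"
        ) from None


def _check_positive(name: str, value: Optional[float], required: bool) -> Optional[float]:
    if value is None:
        if required:
            raise ValidationError(f"{name} is required")
        return None
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValidationError(f"{name} must be finite and > 0, got {value}")
    return value


@dataclasses.dataclass(frozen=True)
class FlyRecord:
    """One measured fly.

    Lengths are millimetres and must be strictly positive.  ``wing_width``
    is optional (a candidate predictor, never required); ``wing_length``
    and ``hind_tibia`` are mandatory.  Laboratory flies must carry a known
    morph; field flies enter the pipeline with ``morph = UNKNOWN`` and are
    only ever labelled by the classifier, never in place.
    """

    id: str
    sex: Sex
    source: Source
    wing_length: float
    hind_tibia: float
    morph: Morph = Morph.UNKNOWN
    wing_width: Optional[float] = None
    collection_date: Optional[datetime.date] = None
    site: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "sex", _coerce(self.sex, Sex))
        object.__setattr__(self, "source", _coerce(self.source, Source))
        object.__setattr__(self, "morph", _coerce(self.morph, Morph))
        object.__setattr__(
            self, "wing_length", _check_positive("wing_length", self.wing_length, True)
        )
        object.__setattr__(
            self, "hind_tibia", _check_positive("hind_tibia", self.hind_tibia, True)
        )
        object.__setattr__(
            self, "wing_width", _check_positive("wing_width", self.wing_width, False)
        )
        if self.source is Source.LAB and self.morph not in (Morph.WINTER, Morph.SUMMER):
            raise ValidationError(
                f"record {self.id!r}: laboratory flies must have a known morph "
                "(winter or summer)"
            )
        if self.source is Source.FIELD and self.morph is not Morph.UNKNOWN:
            raise ValidationError(
                f"record {self.id!r}: field flies enter with morph=unknown "
                "(labels are assigned by the classifier, not the input file)"
            )
        if self.collection_date is not None and not isinstance(
            self.collection_date, datetime.date
        ):
            raise ValidationError(
                f"record {self.id!r}: collection_date must be a datetime.date"
            )

    def metric(self, metric: Metric) -> Optional[float]:
        return {
            Metric.WING_LENGTH: self.wing_length,
            Metric.WING_WIDTH: self.wing_width,
            Metric.HIND_TIBIA: self.hind_tibia,
        }[Metric(metric)]


class MorphometricDataset:
    """Ordered collection of :class:`FlyRecord` with unique ids.

    Iteration order is stable (insertion order), which makes every
    downstream random sampling reproducible from a seed.  ``provenance``
    is free-form metadata; the synthetic generator stores hidden true
    morph labels for field flies there, outside the records themselves.
    """

    def __init__(self, records: Iterable[FlyRecord], provenance: Optional[Mapping] = None):
        self._records: tuple[FlyRecord, ...] = tuple(records)
        seen: set[str] = set()
        for rec in self._records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
        self.provenance: dict = dict(provenance or {})

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[FlyRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> FlyRecord:
        return self._records[i]

    @property
    def records(self) -> tuple[FlyRecord, ...]:
        return self._records

    def filter(
        self,
        sex: Optional[Sex] = None,
        source: Optional[Source] = None,
        morph: Optional[Morph] = None,
    ) -> "MorphometricDataset":
        recs = [
            r
            for r in self._records
            if (sex is None or r.sex is Sex(sex))
            and (source is None or r.source is Source(source))
            and (morph is None or r.morph is Morph(morph))
        ]
        return MorphometricDataset(recs, self.provenance)

    def values(self, metric: Metric) -> np.ndarray:
        """Metric values over all records; raises if any record lacks it."""
        out = []
        for r in self._records:
            v = r.metric(metric)
            if v is None:
                raise ValidationError(f"record {r.id!r} has no {Metric(metric).value}")
            out.append(v)
        return np.asarray(out, dtype=float)

    def __add__(self, other: "MorphometricDataset") -> "MorphometricDataset":
        prov = dict(self.provenance)
        for k, v in other.provenance.items():
            if k in prov and isinstance(prov[k], dict) and isinstance(v, dict):
                prov[k] = {**prov[k], **v}
            elif k not in prov:
                prov[k] = v
        return MorphometricDataset(self._records + other._records, prov)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MorphometricDataset):
            return NotImplemented
        return self._records == other._records


@dataclasses.dataclass(frozen=True)
class DescriptiveStats:
    """Group mean ± SEM for one metric, as printed in summary tables."""

    sex: Sex
    group: Union[Morph, Source]
    metric: Metric
    n: int
    mean: float
    sem: float

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError("descriptive stats need n >= 2")


# canonical field name -> default CSV column header
DEFAULT_DIALECT: dict[str, str] = {
    "id": "id",
    "sex": "sex",
    "source": "source",
    "morph": "morph",
    "wing_length": "wing_length_mm",
    "wing_width": "wing_width_mm",
    "hind_tibia": "hind_tibia_mm",
    "collection_date": "collection_date",
    "site": "site",
}

_REQUIRED_FIELDS = ("sex", "source", "wing_length", "hind_tibia")


def read_morphometrics(
    path, dialect: Optional[Mapping[str, str]] = None
) -> MorphometricDataset:
    """Read a delimited morphometrics file into a validated dataset.

    ``dialect`` maps canonical field names to the file's column headers,
    defaulting to :data:`DEFAULT_DIALECT`.  Rows violating record
    invariants are reported together, each diagnostic naming its 1-based
    data row.  Dates must be ISO-8601 (the dialect renames columns only).
    """
    cols = {**DEFAULT_DIALECT, **(dialect or {})}
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for field in _REQUIRED_FIELDS:
        if cols[field] not in frame.columns:
            raise SchemaError(
                f"missing required column {cols[field]!r} (field {field!r}) in {path}"
            )

    def cell(row, field):
        col = cols[field]
        if col not in frame.columns:
            return None
        raw = row[col].strip()
        return raw if raw else None

    records: list[FlyRecord] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            raw_date = cell(row, "collection_date")
            date = datetime.date.fromisoformat(raw_date) if raw_date else None
            rec_id = cell(row, "id") or f"row-{i}"

            def number(field, required):
                raw = cell(row, field)
                if raw is None:
                    if required:
                        raise ValidationError(f"{field} is required")
                    return None
                try:
                    return float(raw)
                except ValueError:
                    raise ValidationError(f"{field}={raw!r} is not numeric") from None

            records.append(
                FlyRecord(
                    id=rec_id,
                    sex=cell(row, "sex"),
                    source=cell(row, "source"),
                    morph=cell(row, "morph") or Morph.UNKNOWN,
                    wing_length=number("wing_length", True),
                    hind_tibia=number("hind_tibia", True),
                    wing_width=number("wing_width", False),
                    collection_date=date,
                    site=cell(row, "site"),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s) in {path}:\n  " + "\n  ".join(problems)
        )
    return MorphometricDataset(records, provenance={"origin": str(path)})


def write_morphometrics(dataset: MorphometricDataset, path) -> None:
    """Write a dataset as CSV readable by :func:`read_morphometrics`.

    Optional fields serialize as empty cells; floats keep 10 significant
    digits so the round-trip is lossless well past 6 significant digits.
    """

    def fmt(v: Optional[float]) -> str:
        return "" if v is None else format(v, ".10g")

    rows = [
        {
            "id": r.id,
            "sex": r.sex.value,
            "source": r.source.value,
            "morph": r.morph.value,
            "wing_length_mm": fmt(r.wing_length),
            "wing_width_mm": fmt(r.wing_width),
            "hind_tibia_mm": fmt(r.hind_tibia),
            "collection_date": r.collection_date.isoformat() if r.collection_date else "",
            "site": r.site or "",
        }
        for r in dataset
    ]
    frame = pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values()))
    frame.to_csv(path, index=False)


def descriptive_stats(
    dataset: MorphometricDataset,
    sex: Sex,
    group: Union[Morph, Source],
    metric: Metric,
) -> DescriptiveStats:
    """Mean ± SEM of one metric within a (sex, group) cell.

    ``group`` is either a morph (selects laboratory flies of that morph)
    or a source (selects all lab or all field flies), mirroring the four
    row types of the descriptive summary table.  SEM uses the sample
    (n−1) standard deviation.
    """
    if isinstance(group, Morph) or group in Morph._value2member_map_:
        sub = dataset.filter(sex=sex, source=Source.LAB, morph=Morph(group))
        group = Morph(group)
    else:
        sub = dataset.filter(sex=sex, source=Source(group))
        group = Source(group)
    if len(sub) < 2:
        raise InsufficientDataError(
            f"group (sex={Sex(sex).value}, {group.value}) has n={len(sub)} < 2"
        )
    vals = sub.values(metric)
    sd = float(np.std(vals, ddof=1))
    return DescriptiveStats(
        sex=Sex(sex),
        group=group,
        metric=Metric(metric),
        n=len(vals),
        mean=float(np.mean(vals)),
        sem=sd / math.sqrt(len(vals)),
    )


def pooled_t_test(a, b) -> tuple[float, int]:
    """Two-sample Student's t with pooled variance; returns (t, df).

    df = n_a + n_b − 2 (equal-variance Student's t, not Welch).  Identical
    degenerate samples (zero pooled variance, equal means) give t = 0;
    zero pooled variance with unequal means has no finite t and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    df = int(a.size + b.size - 2)
    pooled_var = (
        (a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)
    ) / df
    if pooled_var == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, df
        raise DegenerateDataError(
            "zero pooled variance with unequal means: t is undefined"
        )
    t, _ = _scipy_stats.ttest_ind(a, b, equal_var=True)
    return float(t), df
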