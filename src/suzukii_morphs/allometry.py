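"""Allometric size correction of the wing-length/tibia ratio.

A raw wing/tibia ratio does not remove the dependence of shape on body
size unless the wing-on-tibia regression passes through the origin.  The
Albrecht-style adjusted ratio subtracts the regression intercept first:

    ratio_adj = (wing_length − α) / hind_tibia

where α is the intercept of the ordinary least-squares regression of
wing length on hind tibia length fitted to laboratory-reared *summer*
morphs of the same sex.  α = 0 recovers the plain untransformed ratio.

Field flies are always transformed with the laboratory-derived α; the
regression is never refitted on field data.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from typing import NamedTuple

import numpy as np
from scipy import stats as _scipy_stats

from .data_model import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
    Morph,
    MorphometricDataset,
    Sex,
    Source,
    ValidationError,
)

__all__ = [
    "RegressionFit",
    "TransformedValue",
    "fit_summer_allometry",
    "transform_ratio",
    "transform_dataset",
]


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    """OLS fit of wing length on hind tibia length for one sex.

    ``alpha`` (the intercept, mm) is the only quantity the ratio
    transform consumes; slope, residuals and R² are retained for
    diagnostics (regression and residual plots).
    """

    sex: Sex
    alpha: float
    slope: float
    n: int
    residuals: tuple[float, ...]
    r_squared: float

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.n < 3:
            raise InsufficientDataError("regression fit needs n >= 3")
        if not np.isfinite(self.alpha):
            raise ValidationError("alpha must be finite")

    def with_alpha(self, alpha: float) -> "RegressionFit":
        """Copy of this fit with the intercept overridden (config option)."""
        return dataclasses.replace(self, alpha=float(alpha))

    def summary(self) -> dict:
        return {
            "sex": self.sex.value,
            "alpha": self.alpha,
            "slope": self.slope,
            "n": self.n,
            "r_squared": self.r_squared,
        }


class TransformedValue(NamedTuple):
    """Size-corrected ratio for one record."""

    record_id: str
    value: float


def fit_summer_allometry(dataset: MorphometricDataset, sex: Sex) -> RegressionFit:
    """OLS of wing length on hind tibia over lab summer morphs of one sex.

    Exactly the laboratory summer records define the fit — winter morphs
    and field flies are excluded by construction.
    """
    sub = dataset.filter(sex=Sex(sex), source=Source.LAB, morph=Morph.SUMMER)
    if len(sub) < 3:
        raise InsufficientDataError(
            f"need >= 3 lab summer records for sex {Sex(sex).value}, got {len(sub)}"
        )
    x = np.array([r.hind_tibia for r in sub])
    y = np.array([r.wing_length for r in sub])
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("zero variance in hind tibia length: OLS undefined")
    res = _scipy_stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    return RegressionFit(
        sex=Sex(sex),
        alpha=float(res.intercept),
        slope=float(res.slope),
        n=len(sub),
        residuals=tuple(float(v) for v in (y - fitted)),
        r_squared=float(res.rvalue**2),
    )


def transform_ratio(wing_length: float, hind_tibia: float, alpha: float) -> float:
    """Size-corrected ratio (wing_length − α) / hind_tibia.

    Strictly increasing in wing length; strictly decreasing in tibia
    length whenever wing_length > α.  With α = 0 this is the plain
    untransformed wing/tibia ratio.
    """
    if hind_tibia <= 0.0:
        raise ValidationError(f"hind_tibia must be > 0, got {hind_tibia}")
    return (wing_length - alpha) / hind_tibia


def transform_dataset(
    dataset: MorphometricDataset, fits: Mapping[Sex, RegressionFit]
) -> list[TransformedValue]:
    """Apply the sex-matched ratio transform to every record, in order."""
    fits = {Sex(k): v for k, v in fits.items()}
    missing = {r.sex for r in dataset} - set(fits)
    if missing:
        raise ConfigurationError(
            "no regression fit for sex(es): "
            + ", ".join(sorted(s.value for s in missing))
        )
    return [
        TransformedValue(r.id, transform_ratio(r.wing_length, r.hind_tibia, fits[r.sex].alpha))
        for r in dataset
    ]
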