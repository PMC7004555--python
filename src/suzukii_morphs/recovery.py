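"""Parameter-recovery experiments on synthetic cohorts.

The published per-fly measurements are not available, so the printed
classification cutoffs are checked by *recovery*: regenerate laboratory
cohorts at the published summary-statistic parameters, run the full
500-iteration 70/30 repeated-split procedure, and compare the resulting
mean cutoff with the printed one.

A single synthetic study is itself a random draw — for the transformed
ratio especially, the summer-morph regression intercept is weakly
identified from one cohort (the within-cohort tibia variance implied by
the printed SEMs is small), so the study-level mean cutoff carries
substantial dataset-level spread.  The recovery estimate therefore
averages the study-level mean cutoff over independent replicate studies;
``n_replicates`` controls the Monte-Carlo precision of that average.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .classifier import Predictor
from .data_model import Sex
from .synthetic import CohortSpec, Morph, default_lab_specs, generate_lab_dataset
from .resampling import repeated_split_evaluation

__all__ = ["RecoveryResult", "mean_cutoff_recovery"]


@dataclasses.dataclass(frozen=True)
class RecoveryResult:
    """Replicate-averaged mean cutoff for one sex × predictor."""

    sex: Sex
    predictor: Predictor
    n_replicates: int
    n_iterations: int
    per_replicate: tuple[float, ...]  # study-level mean cutoffs

    @property
    def value(self) -> float:
        """Grand mean cutoff over replicate studies."""
        return float(np.mean(self.per_replicate))

    @property
    def mc_standard_error(self) -> float:
        if self.n_replicates < 2:
            return float("nan")
        return float(np.std(self.per_replicate, ddof=1) / np.sqrt(self.n_replicates))


def mean_cutoff_recovery(
    sex: Sex,
    predictor: Predictor,
    n_replicates: int,
    n_iterations: int = 500,
    train_fraction: float = 0.7,
    seed: int | np.random.SeedSequence = 0,
    specs: Optional[dict[tuple[Sex, Morph], CohortSpec]] = None,
) -> RecoveryResult:
    """Average the study-level mean cutoff over replicate synthetic studies.

    Each replicate generates fresh laboratory cohorts at the default
    (published) parameters and runs the repeated-split evaluation for
    the given sex and predictor; the per-replicate values are the
    across-iteration mean cutoffs.
    """
    sex = Sex(sex)
    predictor = Predictor(predictor)
    specs = specs or default_lab_specs()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    means: list[float] = []
    for rep in range(n_replicates):
        lab_ss, eval_ss = ss.spawn(2)
        lab = generate_lab_dataset(specs, lab_ss)
        summary = repeated_split_evaluation(
            lab,
            sex,
            predictor,
            n_iterations=n_iterations,
            train_fraction=train_fraction,
            seed=eval_ss,
        )
        means.append(summary.cutoff_mean)
    return RecoveryResult(
        sex=sex,
        predictor=predictor,
        n_replicates=n_replicates,
        n_iterations=n_iterations,
        per_replicate=tuple(means),
    )
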