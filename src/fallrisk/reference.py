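"""Published reference values from the original laboratory cohort.

These printed numbers (recruitment accounting, the logistic coefficient
table, the classification confusion matrix and the component variance
percentages) serve as closed-form inputs for validation: the package's own
arithmetic must reproduce the derived quantities exactly from them. They are
inputs, never outputs — nothing in the pipeline reads them during a run.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluate import ConfusionMatrix

__all__ = [
    "RECRUITED",
    "COMPLETED",
    "ATYPICAL_FALL_EXCLUSIONS",
    "REFERENCE_CONFUSION",
    "REFERENCE_COEFFICIENTS",
    "REFERENCE_VARIANCE_PCT",
    "REFERENCE_TOTAL_VARIANCE_PCT",
    "CohortCounts",
    "apply_exclusions",
]

#: recruited community sample: (fallers, non-fallers) by 12-month fall history
RECRUITED = (42, 48)
#: subjects completing all three laboratory sessions
COMPLETED = (42, 42)
#: fallers removed post hoc (fall during sports/strenuous activity, not a
#: typical uncoordinated fall)
ATYPICAL_FALL_EXCLUSIONS = 4

#: classification table of the reference cohort (faller = positive)
REFERENCE_CONFUSION = ConfusionMatrix(tp=28, fn=10, fp=10, tn=32)

#: logistic coefficient table of the reference cohort:
#: component -> (beta, se, wald, p, exp_beta)
REFERENCE_COEFFICIENTS = {
    "static balance": (1.4, 0.97, 2.1, 0.15, 4.1),
    "temporal gait": (-0.01, 0.27, 0.002, 0.96, 0.99),
    "spatial gait": (-0.94, 0.34, 7.90, 0.005, 0.39),
    "temporal variability, right": (0.45, 0.27, 2.82, 0.093, 1.57),
    "temporal variability, left": (0.64, 0.28, 5.27, 0.022, 1.90),
    "spatial variability": (0.17, 0.26, 0.41, 0.52, 1.18),
    "dynamic balance": (0.21, 0.25, 0.71, 0.40, 1.23),
    "constant": (0.20, 0.26, 0.003, 0.96, 1.02),
}

#: predictors entering the reduced model at alpha = 0.1, in order of
#: significance
REFERENCE_SELECTED = (
    "spatial gait",
    "temporal variability, left",
    "temporal variability, right",
)

#: per-component variance explained (%) in the reference factor solution
REFERENCE_VARIANCE_PCT = (23, 15, 14, 13, 11, 7, 7)
#: stated total variance represented by the seven components
REFERENCE_TOTAL_VARIANCE_PCT = 90


@dataclass(frozen=True)
class CohortCounts:
    n_fallers: int
    n_nonfallers: int

    @property
    def n_total(self) -> int:
        return self.n_fallers + self.n_nonfallers


def apply_exclusions(
    recruited: tuple[int, int] = RECRUITED,
    completed: tuple[int, int] = COMPLETED,
    atypical_fallers: int = ATYPICAL_FALL_EXCLUSIONS,
) -> CohortCounts:
    """Recruitment accounting: completion attrition, then removal of fallers
    whose index fall was atypical (sports/strenuous activity)."""
    rec_f, rec_nf = recruited
    com_f, com_nf = completed
    if com_f > rec_f or com_nf > rec_nf:
        raise ValueError("completed counts cannot exceed recruited counts")
    if atypical_fallers > com_f:
        raise ValueError("cannot exclude more fallers than completed")
    return CohortCounts(
        n_fallers=com_f - atypical_fallers,
        n_nonfallers=com_nf,
    )
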