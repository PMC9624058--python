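"""Responses recorded each cycle: genetic mean and variance, selection
error bias and its decomposition, selection accuracy, and mean parental age.

Selection error bias is the ratio of the mean absolute criterion error
(criterion value minus true breeding value) in the selected parents to that
in all selection candidates. A ratio above 1 means selection preferentially
picked individuals whose criterion overstated their merit — the mechanism
by which overlapping generations degrade phenotypic selection, since those
inflated records persist across cycles. When the criterion is the true
breeding value itself every error is zero and the ratio is undefined (NaN),
preserving "error was zero" rather than inventing a value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founder_genomes import Individual
from .trait_architecture import TraitModel, true_breeding_values


@dataclass
class ErrorDecomposition:
    """Per-candidate criterion error split into its phenotype components.

    Only defined for phenotypic criteria, where
    total = year + gxy + plot exactly; a GEBV error has no such split.
    """

    total: np.ndarray
    year: np.ndarray | None = None
    gxy: np.ndarray | None = None
    plot: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.year is not None:
            recon = self.year + self.gxy + self.plot
            if not np.allclose(recon, self.total, atol=1e-9):
                raise ValueError("components do not reconstruct total error")


def selection_error_bias(selected_errors: np.ndarray,
                         all_errors: np.ndarray) -> float:
    """mean|error| in selected over mean|error| in all candidates.

    NaN when the denominator is zero (e.g. selection on true breeding
    value, where every error is zero by definition).
    """
    selected_errors = np.asarray(selected_errors, dtype=float)
    all_errors = np.asarray(all_errors, dtype=float)
    if selected_errors.size == 0 or all_errors.size == 0:
        raise ValueError("empty error vectors")
    denom = float(np.mean(np.abs(all_errors)))
    if denom == 0.0:
        return float("nan")
    return float(np.mean(np.abs(selected_errors))) / denom


def decompose_error_bias(selected: ErrorDecomposition,
                         all_candidates: ErrorDecomposition
                         ) -> tuple[float, float, float]:
    """Component-wise error bias (year, genotype-by-year, plot).

    Each component bias is `selection_error_bias` applied to that component.
    When all candidates share one identical year value the year bias is
    exactly 1.
    """
    if selected.year is None or all_candidates.year is None:
        raise ValueError("component decomposition requires phenotypic errors")
    return (
        selection_error_bias(selected.year, all_candidates.year),
        selection_error_bias(selected.gxy, all_candidates.gxy),
        selection_error_bias(selected.plot, all_candidates.plot),
    )


def selection_accuracy(criterion_values: np.ndarray,
                       tbvs: np.ndarray) -> float:
    """Pearson correlation of the selection criterion with TBV.

    NaN when either vector has zero variance (fewer than 2 pairs rejected).
    """
    x = np.asarray(criterion_values, dtype=float)
    y = np.asarray(tbvs, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need >= 2 paired values")
    if float(np.var(x)) == 0.0 or float(np.var(y)) == 0.0:
        return float("nan")
    if np.array_equal(x, y):
        return 1.0  # selection directly on TBV is exact by definition
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def mean_parental_age(selected: list[Individual], current_time: int) -> float:
    """Mean of (current_time - birth time) over the selected parents.

    ``current_time`` is the cycle/year stamped on the offspring the parents
    produce, so the value is the realized generation interval.
    """
    if not selected:
        raise ValueError("no selected parents")
    return float(np.mean([current_time - p.birth_cycle for p in selected]))


def genetic_stats(cohort: list[Individual],
                  trait: TraitModel) -> tuple[float, float]:
    """Sample mean and variance (ddof=1) of TBVs in a cohort."""
    if not cohort:
        raise ValueError("empty cohort")
    tbvs = true_breeding_values(cohort, trait)
    var = float(np.var(tbvs, ddof=1)) if len(cohort) > 1 else 0.0
    return float(np.mean(tbvs)), var
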