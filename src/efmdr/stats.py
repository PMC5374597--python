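"""Fuzzy confusion counts, accuracy measures, and the BA <-> chi-square bridge.

Weighting each sample's contribution by its cell's membership degrees gives
real-valued confusion pseudo-counts

    TP = sum_i n_i1 * mu_H(i),   FN = sum_i n_i1 * mu_L(i),
    TN = sum_i n_i0 * mu_L(i),   FP = sum_i n_i0 * mu_H(i),

from which sensitivity, specificity and balanced accuracy follow in the
usual way.  Under the empirical (MLE) membership the balanced accuracy is a
linear function of the Pearson chi-square statistic of the
case/control x genotype contingency table,

    X^2 = n_++ * (2 * BA - 1),

which turns the best-model score into a standard significance test: the
statistic is referred to a chi-square distribution with (number of observed
genotype combinations - 1) degrees of freedom, so no permutation test or
cross-validation is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .data import CellTable, GenotypeMatrix, count_cells
from .membership import MembershipAssignment, empirical_membership


class DegenerateModelError(ValueError):
    """Too few observed genotype combinations to report a model."""


class AccuracyError(ValueError):
    """Accuracy measures are undefined (a phenotype class is absent)."""


@dataclass(frozen=True)
class FuzzyConfusion:
    """Real-valued confusion pseudo-counts; TP+FN = n_+1 and TN+FP = n_+0."""

    tp: float
    fn: float
    tn: float
    fp: float


@dataclass(frozen=True)
class AccuracyResult:
    """Accuracy measures and significance of one SNP-combination model."""

    sen: float
    spe: float
    ba: float
    chi_square: float
    df: int
    p_value: float


def fuzzy_confusion(
    table: CellTable, assignment: MembershipAssignment
) -> FuzzyConfusion:
    """Membership-weighted confusion counts, summed over nonempty cells."""
    if assignment.n_cells != table.n_cells:
        raise ValueError(
            f"assignment has {assignment.n_cells} cells, table has {table.n_cells}"
        )
    if (assignment.empty != (table.n_total == 0)).any():
        raise ValueError("assignment empty-cell flags do not match the table")
    occ = ~assignment.empty
    n1 = table.n_case[occ].astype(float)
    n0 = table.n_control[occ].astype(float)
    mu_h = assignment.mu_h[occ]
    mu_l = 1.0 - mu_h
    return FuzzyConfusion(
        tp=float(n1 @ mu_h),
        fn=float(n1 @ mu_l),
        tn=float(n0 @ mu_l),
        fp=float(n0 @ mu_h),
    )


def fuzzy_accuracy(confusion: FuzzyConfusion) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy) from confusion counts."""
    n1 = confusion.tp + confusion.fn
    n0 = confusion.tn + confusion.fp
    if n1 <= 0 or n0 <= 0:
        raise AccuracyError(
            "both cases and controls must be present to define accuracy "
            f"(n_+1={n1}, n_+0={n0})"
        )
    sen = confusion.tp / n1
    spe = confusion.tn / n0
    return sen, spe, (sen + spe) / 2.0


def ba_to_chisq(ba: float, n: int, force: bool = False) -> float:
    """Chi-square statistic ``X^2 = n * (2 * ba - 1)``.

    The identity with the Pearson statistic holds under empirical
    membership, where ``ba >= 0.5``; for other engines the quantity is not
    a chi-square statistic and the conversion refuses unless ``force``.
    """
    if n < 0:
        raise ValueError(f"sample count must be nonnegative, got {n}")
    if not force and ba < 0.5 - 1e-12:
        raise ValueError(
            f"balanced accuracy {ba} < 0.5: not a chi-square statistic "
            "under this membership engine (pass force=True to convert anyway)"
        )
    return max(n * (2.0 * ba - 1.0), 0.0)


def model_pvalue(
    chi_square: float, table: CellTable, df_rule: str = "observed"
) -> tuple[int, float]:
    """Degrees of freedom and upper-tail p-value of the model statistic.

    The degrees of freedom are the number of genotype combinations minus
    one.  ``df_rule="observed"`` (default) counts observed (nonempty)
    cells, the reading under which the Pearson equivalence holds;
    ``df_rule="full"`` counts all 3**k cells.
    """
    if chi_square < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {chi_square}")
    if df_rule == "observed":
        n_genotypes = table.nonempty_cell_count
    elif df_rule == "full":
        n_genotypes = table.n_cells
    else:
        raise ValueError(f"unknown df_rule {df_rule!r}")
    if table.nonempty_cell_count < 2:
        raise DegenerateModelError(
            "fewer than two observed genotype combinations: model unreportable"
        )
    df = n_genotypes - 1
    return df, float(sps.chi2.sf(chi_square, df))


def evaluate_combination(
    data: GenotypeMatrix,
    snp_indices: Sequence[int],
    df_rule: str = "observed",
    max_order: int = 5,
) -> tuple[CellTable, AccuracyResult]:
    """Full EF-MDR chain for one SNP combination.

    count cells -> empirical membership -> fuzzy confusion -> accuracy ->
    chi-square -> p-value.
    """
    table = count_cells(data, snp_indices, max_order=max_order)
    assignment = empirical_membership(table)
    confusion = fuzzy_confusion(table, assignment)
    sen, spe, ba = fuzzy_accuracy(confusion)
    x2 = ba_to_chisq(ba, table.total_samples)
    df, p = model_pvalue(x2, table, df_rule=df_rule)
    return table, AccuracyResult(sen, spe, ba, x2, df, p)
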