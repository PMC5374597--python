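"""Risk-classification engines: per-cell high-risk membership degrees.

Classic MDR pools each multi-locus genotype into a crisp high-risk (H) or
low-risk (L) group by comparing the cell's case/control ratio to a
threshold.  The fuzzy generalisation assigns each cell a membership degree
``mu_H in [0, 1]`` of the high-risk set (with ``mu_L = 1 - mu_H``); the
empirical engine uses the maximum-likelihood case proportion
``n_i1 / (n_i1 + n_i0)`` and has no tuning parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .data import CellTable


class MembershipError(ValueError):
    """Invalid membership degrees or parameters."""


@dataclass(frozen=True)
class MembershipAssignment:
    """Per-cell high-risk membership degrees for one :class:`CellTable`.

    ``mu_h`` holds NaN at empty cells; ``empty`` flags them.  Empty cells
    carry no membership and contribute nothing downstream.
    """

    mu_h: np.ndarray
    empty: np.ndarray
    engine: str = "custom"

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_h, dtype=np.float64)
        empty = np.asarray(self.empty, dtype=bool)
        if mu.shape != empty.shape:
            raise MembershipError("mu_h and empty must have the same shape")
        with np.errstate(invalid="ignore"):
            bad = np.flatnonzero(~empty & ((mu < 0.0) | (mu > 1.0) | np.isnan(mu)))
        if bad.size:
            cell = int(bad[0])
            raise MembershipError(
                f"membership degree {mu[cell]} at cell {cell} is outside [0, 1]"
            )
        object.__setattr__(self, "mu_h", mu)
        object.__setattr__(self, "empty", empty)

    @property
    def mu_l(self) -> np.ndarray:
        return 1.0 - self.mu_h

    @property
    def n_cells(self) -> int:
        return self.mu_h.shape[0]


def empirical_membership(table: CellTable) -> MembershipAssignment:
    """MLE membership: ``mu_H(i) = n_i1 / n_i+`` for every nonempty cell.

    A cell holding six cases and four controls gets ``mu_H = 0.6`` and
    ``mu_L = 0.4``.  There are no tuning parameters.
    """
    tot = table.n_total
    empty = tot == 0
    mu = np.full(table.n_cells, np.nan)
    np.divide(table.n_case, tot, out=mu, where=~empty)
    return MembershipAssignment(mu, empty, engine="efmdr")


def binary_membership(
    table: CellTable, threshold: float | str = "auto"
) -> MembershipAssignment:
    """Crisp MDR rule: H iff the cell's case/control ratio >= threshold.

    ``threshold="auto"`` uses the table's case/control margin ratio
    ``n_+1 / n_+0`` (the balanced-accuracy convention).  Ties at the
    threshold classify H; a cell with controls absent but cases present is
    H.  Empty cells are assigned L (``mu_H = 0``) and flagged.
    """
    n1 = table.n_case
    n0 = table.n_control
    if threshold == "auto":
        # cross-multiplied form avoids dividing by zero-control cells
        high = n1 * table.total_controls >= table.total_cases * n0
    else:
        t = float(threshold)
        if t <= 0:
            raise MembershipError(f"threshold must be positive, got {t}")
        high = n1 >= t * n0
    empty = table.n_total == 0
    mu = np.where(high, 1.0, 0.0)
    mu[empty] = 0.0
    return MembershipAssignment(mu, empty, engine="mdr")


def custom_membership(
    table: CellTable, fn: Callable[[int, int], float], name: str = "custom"
) -> MembershipAssignment:
    """Build an assignment from ``fn(n_i1, n_i0) -> degree in [0, 1]``.

    The hook under which parametric fuzzy membership functions can be
    registered.  A returned degree outside [0, 1] is a contract violation
    naming the cell, never clamped.
    """
    empty = table.n_total == 0
    mu = np.full(table.n_cells, np.nan)
    for i in np.flatnonzero(~empty):
        d = float(fn(int(table.n_case[i]), int(table.n_control[i])))
        if not 0.0 <= d <= 1.0:
            raise MembershipError(
                f"membership function returned {d} at cell {i} "
                f"(genotype {table.genotype_tuple(int(i))}); must lie in [0, 1]"
            )
        mu[i] = d
    return MembershipAssignment(mu, empty, engine=name)


#: Membership engines selectable by name.
ENGINES: dict[str, Callable[[CellTable], MembershipAssignment]] = {
    "efmdr": empirical_membership,
    "mdr": binary_membership,
}


def register_engine(
    name: str, fn: Callable[[int, int], float]
) -> None:
    """Register a custom per-cell membership function under ``name``."""
    ENGINES[name] = lambda table: custom_membership(table, fn, name=name)


def assignment_frame(
    table: CellTable, assignment: MembershipAssignment
) -> pd.DataFrame:
    """Tabular export: cell index, genotype tuple, counts, mu_H."""
    cells = np.arange(table.n_cells)
    return pd.DataFrame(
        {
            "cell": cells,
            "genotype": [table.genotype_tuple(int(i)) for i in cells],
            "n_case": table.n_case,
            "n_control": table.n_control,
            "mu_h": assignment.mu_h,
        }
    )
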