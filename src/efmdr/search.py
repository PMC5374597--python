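"""Exhaustive k-locus model search: EF-MDR ranking and classic MDR with CV.

Both searches enumerate every SNP combination of each requested order.  The
EF-MDR path scores a combination by the p-value of its balanced-accuracy
chi-square statistic — a pure function of the data, needing neither
cross-validation nor permutation.  The classic MDR path scores
combinations by stratified m-fold cross-validation: crisp high/low-risk
pooling fit on the training folds, balanced testing accuracy, and
cross-validation consistency (CVC, the number of folds in which a
combination is the training-best).

Exposed as scikit-learn estimators (:class:`EFMDRSearch`,
:class:`MDRSearch`) with thin functional wrappers
(:func:`efmdr_search`, :func:`mdr_search`).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .data import CASE, MISSING, GenotypeMatrix, count_cells
from .membership import binary_membership
from .stats import (
    AccuracyError,
    DegenerateModelError,
    evaluate_combination,
)


class SearchError(ValueError):
    """Search-level parameter or data error."""


def enumerate_combinations(n_snps: int, k: int) -> Iterator[tuple[int, ...]]:
    """Yield all C(n_snps, k) index tuples in lexicographic order."""
    if k < 1:
        raise SearchError(f"order must be >= 1, got {k}")
    if k > n_snps:
        raise SearchError(f"order {k} exceeds SNP count {n_snps}")
    return itertools.combinations(range(n_snps), k)


@dataclass(frozen=True)
class ModelResult:
    """One evaluated SNP combination.

    The EF-MDR engine fills the accuracy/significance fields; the MDR
    engine fills the cross-validation fields.
    """

    snp_indices: tuple[int, ...]
    snp_names: tuple[str, ...]
    order: int
    engine: str
    sen: float | None = None
    spe: float | None = None
    ba: float | None = None
    chi_square: float | None = None
    df: int | None = None
    p_value: float | None = None
    cvc: int | None = None
    mean_train_ba: float | None = None
    mean_test_ba: float | None = None


@dataclass
class SearchReport:
    """Ranked search results with bookkeeping."""

    engine: str
    orders: tuple[int, ...]
    results: dict[int, list[ModelResult]]
    best_per_order: dict[int, ModelResult]
    best: ModelResult
    n_evaluated: dict[int, int]
    n_skipped: dict[int, int]
    config: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for order in self.orders:
            for rank, m in enumerate(self.results.get(order, []), start=1):
                rows.append(
                    {
                        "order": m.order,
                        "rank": rank,
                        "snps": ",".join(m.snp_names),
                        "snp_indices": ",".join(map(str, m.snp_indices)),
                        "engine": m.engine,
                        "sen": m.sen,
                        "spe": m.spe,
                        "ba": m.ba,
                        "chi_square": m.chi_square,
                        "df": m.df,
                        "p_value": m.p_value,
                        "cvc": m.cvc,
                        "mean_train_ba": m.mean_train_ba,
                        "mean_test_ba": m.mean_test_ba,
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _resolve_orders(orders, n_snps: int) -> tuple[int, ...]:
    if isinstance(orders, int):
        resolved = (orders,)
    elif isinstance(orders, tuple) and len(orders) == 2 and orders[0] <= orders[1]:
        resolved = tuple(range(orders[0], orders[1] + 1))
    else:
        resolved = tuple(sorted(set(int(k) for k in orders)))
    if not resolved:
        raise SearchError("no interaction orders requested")
    for k in resolved:
        if not 1 <= k <= n_snps:
            raise SearchError(f"order {k} invalid for {n_snps} SNPs")
    return resolved


def _as_genotype_matrix(X, y=None) -> GenotypeMatrix:
    if isinstance(X, GenotypeMatrix):
        if y is not None:
            raise SearchError("pass y=None when X is a GenotypeMatrix")
        return X
    if y is None:
        raise SearchError("y is required when X is an array")
    return GenotypeMatrix.from_arrays(np.asarray(X), np.asarray(y))


class _BaseSearch(BaseEstimator):
    """Shared fit plumbing and the column-selecting transform."""

    def _check_data(self, X, y) -> GenotypeMatrix:
        data = _as_genotype_matrix(X, y)
        if data.n_samples == 0:
            raise SearchError("empty dataset")
        if data.n_cases == 0 or data.n_controls == 0:
            raise SearchError("both cases and controls must be present")
        return data

    def transform(self, X):
        """Select the columns of the overall best SNP combination."""
        check_is_fitted(self, "best_model_")
        if isinstance(X, GenotypeMatrix):
            X = X.genotypes
        return np.asarray(X)[:, list(self.best_model_.snp_indices)]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class EFMDRSearch(_BaseSearch):
    """Exhaustive EF-MDR search ranked by chi-square p-value.

    For every SNP combination of each order in ``orders``, the empirical
    fuzzy balanced accuracy is converted to its chi-square statistic and
    p-value; the lowest p-value wins, per order and overall.  The result
    is a pure function of the data: no seed, no cross-validation, no
    permutation.

    Parameters
    ----------
    orders:
        Interaction orders to scan: an int, an inclusive ``(lo, hi)``
        pair, or an iterable of ints.
    top:
        Number of top-ranked models retained per order.
    df_rule:
        ``"observed"`` (nonempty cells - 1) or ``"full"`` (3**k - 1)
        degrees of freedom.

    Attributes
    ----------
    best_model_ : ModelResult
        Overall lowest-p-value model.
    best_per_order_ : dict[int, ModelResult]
    results_ : pandas.DataFrame
        Top models per order, ranked.
    report_ : SearchReport
    """

    def __init__(self, orders=(1, 2), top: int = 10, df_rule: str = "observed"):
        self.orders = orders
        self.top = top
        self.df_rule = df_rule

    def fit(self, X, y=None):
        data = self._check_data(X, y)
        orders = _resolve_orders(self.orders, data.n_snps)
        max_order = max(orders)
        results: dict[int, list[ModelResult]] = {}
        n_eval: dict[int, int] = {}
        n_skip: dict[int, int] = {}
        for k in orders:
            # heap keyed so that nsmallest == best: (p, -ba, indices)
            scored: list[tuple] = []
            evaluated = skipped = 0
            for combo in enumerate_combinations(data.n_snps, k):
                try:
                    table, acc = evaluate_combination(
                        data, combo, df_rule=self.df_rule, max_order=max_order
                    )
                except (DegenerateModelError, AccuracyError):
                    skipped += 1
                    continue
                evaluated += 1
                scored.append((acc.p_value, -acc.ba, combo, acc))
            picked = heapq.nsmallest(self.top, scored)
            results[k] = [
                ModelResult(
                    snp_indices=combo,
                    snp_names=tuple(data.snp_names[i] for i in combo),
                    order=k,
                    engine="efmdr",
                    sen=acc.sen,
                    spe=acc.spe,
                    ba=acc.ba,
                    chi_square=acc.chi_square,
                    df=acc.df,
                    p_value=acc.p_value,
                )
                for (_, _, combo, acc) in picked
            ]
            n_eval[k] = evaluated
            n_skip[k] = skipped
        best_per_order = {k: v[0] for k, v in results.items() if v}
        if not best_per_order:
            raise SearchError("all combinations degenerate: empty report")
        best = min(
            best_per_order.values(),
            key=lambda m: (m.p_value, -m.ba, m.snp_indices),
        )
        self.best_model_ = best
        self.best_per_order_ = best_per_order
        self.report_ = SearchReport(
            engine="efmdr",
            orders=orders,
            results=results,
            best_per_order=best_per_order,
            best=best,
            n_evaluated=n_eval,
            n_skipped=n_skip,
            config={"top": self.top, "df_rule": self.df_rule},
        )
        self.results_ = self.report_.to_dataframe()
        return self


def _binary_ba(n1: np.ndarray, n0: np.ndarray, high: np.ndarray) -> float:
    """Balanced accuracy of a crisp H/L pooling on a counted table."""
    total1 = n1.sum()
    total0 = n0.sum()
    if total1 == 0 or total0 == 0:
        return np.nan
    tp = n1[high].sum()
    tn = n0[~high].sum()
    return 0.5 * (tp / total1 + tn / total0)


class MDRSearch(_BaseSearch):
    """Classic MDR with stratified m-fold cross-validation.

    For each combination and fold, genotype cells are pooled into
    high/low risk on the training folds (H iff the cell case/control
    ratio is at least the training margin ratio; ties H; genotypes unseen
    in training are L), then scored by balanced accuracy on the held-out
    fold.  The per-order best model maximises cross-validation
    consistency, ties broken by mean testing balanced accuracy and then
    by lexicographic SNP tuple.

    Parameters
    ----------
    orders, top:
        As in :class:`EFMDRSearch`.
    n_folds:
        Number of stratified folds m (>= 2).
    random_state:
        Seed for the fold shuffle; fixing it makes the search
        deterministic.
    cv:
        Overrides the fold assignment: a splitter with a
        ``split(X, y)`` method, or an explicit iterable of
        ``(train_indices, test_indices)`` pairs.  ``None`` uses
        stratified ``n_folds``-fold CV.
    """

    def __init__(
        self,
        orders=(1, 2),
        n_folds: int = 10,
        random_state: int | None = None,
        top: int = 10,
        cv=None,
    ):
        self.orders = orders
        self.n_folds = n_folds
        self.random_state = random_state
        self.top = top
        self.cv = cv

    def _folds(self, g, yarr, n_cases: int, n_controls: int):
        if self.cv is not None:
            if hasattr(self.cv, "split"):
                return list(self.cv.split(g, yarr))
            return [(np.asarray(tr), np.asarray(te)) for tr, te in self.cv]
        if self.n_folds < 2:
            raise SearchError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_folds > min(n_cases, n_controls):
            raise SearchError(
                f"n_folds={self.n_folds} exceeds the smaller class count "
                f"{min(n_cases, n_controls)}"
            )
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        return list(skf.split(g, yarr))

    def fit(self, X, y=None):
        data = self._check_data(X, y)
        orders = _resolve_orders(self.orders, data.n_snps)
        g = data.genotypes
        yarr = data.phenotype
        folds = self._folds(g, yarr, data.n_cases, data.n_controls)

        results: dict[int, list[ModelResult]] = {}
        n_eval: dict[int, int] = {}
        n_skip: dict[int, int] = {}
        for k in orders:
            combos = list(enumerate_combinations(data.n_snps, k))
            radix = 3 ** np.arange(k - 1, -1, -1, dtype=np.int64)
            n_cells = 3**k
            # cell code per sample per combo; -1 marks incomplete rows
            codes = []
            for combo in combos:
                sub = g[:, combo].astype(np.int64)
                code = sub @ radix
                code[(sub == MISSING).any(axis=1)] = -1
                codes.append(code)

            train_ba = np.full((len(folds), len(combos)), np.nan)
            test_ba = np.full((len(folds), len(combos)), np.nan)
            for f, (tr, te) in enumerate(folds):
                tr_case = tr[yarr[tr] == CASE]
                tr_ctrl = tr[yarr[tr] != CASE]
                te_case = te[yarr[te] == CASE]
                te_ctrl = te[yarr[te] != CASE]
                for c, code in enumerate(codes):
                    c1 = code[tr_case]
                    c0 = code[tr_ctrl]
                    if (c1 < 0).any() or (c0 < 0).any():
                        c1 = c1[c1 >= 0]
                        c0 = c0[c0 >= 0]
                    n1t = np.bincount(c1, minlength=n_cells)
                    n0t = np.bincount(c0, minlength=n_cells)
                    total1, total0 = n1t.sum(), n0t.sum()
                    if total1 == 0 or total0 == 0:
                        continue
                    high = n1t * total0 >= total1 * n0t
                    high[(n1t + n0t) == 0] = False  # unseen genotypes -> L
                    train_ba[f, c] = _binary_ba(n1t, n0t, high)
                    s1 = code[te_case]
                    s0 = code[te_ctrl]
                    if (s1 < 0).any() or (s0 < 0).any():
                        s1 = s1[s1 >= 0]
                        s0 = s0[s0 >= 0]
                    n1s = np.bincount(s1, minlength=n_cells)
                    n0s = np.bincount(s0, minlength=n_cells)
                    test_ba[f, c] = _binary_ba(n1s, n0s, high)

            valid = ~np.isnan(train_ba).any(axis=0) & ~np.isnan(test_ba).any(axis=0)
            n_eval[k] = int(valid.sum())
            n_skip[k] = len(combos) - n_eval[k]
            if not valid.any():
                results[k] = []
                continue
            # per-fold training best among valid combos (nanargmax keeps
            # lexicographic tie-break: first max wins)
            masked = np.where(valid[None, :], train_ba, -np.inf)
            fold_best = masked.argmax(axis=1)
            cvc = np.bincount(fold_best, minlength=len(combos))
            mean_tr = np.nanmean(train_ba, axis=0)
            mean_te = np.nanmean(test_ba, axis=0)
            order_idx = sorted(
                np.flatnonzero(valid),
                key=lambda c: (-cvc[c], -mean_te[c], combos[c]),
            )[: self.top]
            results[k] = [
                ModelResult(
                    snp_indices=combos[c],
                    snp_names=tuple(data.snp_names[i] for i in combos[c]),
                    order=k,
                    engine="mdr",
                    cvc=int(cvc[c]),
                    mean_train_ba=float(mean_tr[c]),
                    mean_test_ba=float(mean_te[c]),
                )
                for c in order_idx
            ]

        best_per_order = {k: v[0] for k, v in results.items() if v}
        if not best_per_order:
            raise SearchError("all combinations degenerate: empty report")
        best = max(
            best_per_order.values(),
            key=lambda m: (m.cvc, m.mean_test_ba, tuple(-i for i in m.snp_indices)),
        )
        self.best_model_ = best
        self.best_per_order_ = best_per_order
        self.report_ = SearchReport(
            engine="mdr",
            orders=orders,
            results=results,
            best_per_order=best_per_order,
            best=best,
            n_evaluated=n_eval,
            n_skipped=n_skip,
            config={
                "n_folds": len(folds),
                "random_state": self.random_state,
                "top": self.top,
            },
        )
        self.results_ = self.report_.to_dataframe()
        # full-data pooling of the best model, for predict()
        table = count_cells(data, best.snp_indices, max_order=max(orders))
        assignment = binary_membership(table)
        self._predict_high_ = assignment.mu_h >= 0.5
        self._predict_high_[assignment.empty] = False
        return self

    def predict(self, X):
        """Crisp high-risk (1) / low-risk (0) label per sample.

        Uses the full-data H/L pooling of the fitted best model; samples
        in genotypes unseen at fit time (or with missing genotypes at the
        model's SNPs) are labelled low risk.
        """
        check_is_fitted(self, "best_model_")
        sub = np.asarray(
            X.genotypes if isinstance(X, GenotypeMatrix) else X, dtype=np.int64
        )[:, list(self.best_model_.snp_indices)]
        k = len(self.best_model_.snp_indices)
        radix = 3 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        code = sub @ radix
        ok = (sub != MISSING).all(axis=1)
        out = np.zeros(sub.shape[0], dtype=np.int8)
        out[ok] = self._predict_high_[code[ok]].astype(np.int8)
        return out


def efmdr_search(
    data: GenotypeMatrix,
    orders=(1, 2),
    top: int = 10,
    df_rule: str = "observed",
) -> SearchReport:
    """Run :class:`EFMDRSearch` and return its report."""
    return EFMDRSearch(orders=orders, top=top, df_rule=df_rule).fit(data).report_


def mdr_search(
    data: GenotypeMatrix,
    orders=(1, 2),
    n_folds: int = 10,
    random_state: int | None = None,
    top: int = 10,
) -> SearchReport:
    """Run :class:`MDRSearch` and return its report."""
    est = MDRSearch(
        orders=orders, n_folds=n_folds, random_state=random_state, top=top
    )
    return est.fit(data).report_
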