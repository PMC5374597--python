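"""Genotype/phenotype data model, contingency tables, and text-format I/O.

The universal input is a samples x SNPs matrix of biallelic genotype codes
(0 = homozygous major, 1 = heterozygous, 2 = homozygous minor; ``MISSING``
for an unobserved genotype) together with a binary case/control phenotype.
Every statistic downstream is computed from a :class:`CellTable`: the
case/control counts of each multi-locus genotype combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel code for a missing genotype.
MISSING: int = -1

#: Default cap on the interaction order of a contingency table.
DEFAULT_MAX_ORDER: int = 5

CASE: int = 1
CONTROL: int = 0


class DataError(ValueError):
    """Invalid genotype/phenotype data."""


class FormatError(ValueError):
    """Malformed input file."""


class InvalidCombinationError(ValueError):
    """A SNP combination violates the contingency-table preconditions."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Case-control genotype data.

    Parameters
    ----------
    genotypes:
        ``(n_samples, n_snps)`` integer array with codes in ``{0, 1, 2}``
        counting minor alleles, or :data:`MISSING`.
    phenotype:
        ``(n_samples,)`` array, 1 = case and 0 = control.
    snp_names:
        One unique identifier per SNP column.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: tuple[str, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        y = np.asarray(self.phenotype)
        if g.ndim != 2:
            raise DataError("genotypes must be a 2-D samples x SNPs array")
        if y.shape != (g.shape[0],):
            raise DataError(
                f"phenotype length {y.shape} does not match "
                f"{g.shape[0]} samples"
            )
        valid = (g == MISSING) | ((g >= 0) & (g <= 2))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise DataError(
                f"genotype code {g[tuple(bad)]} at sample {bad[0]}, "
                f"SNP {bad[1]} is not in {{0,1,2}} or missing"
            )
        if not np.isin(y, (CASE, CONTROL)).all():
            raise DataError("phenotype labels must be 1 (case) or 0 (control)")
        if len(self.snp_names) != g.shape[1]:
            raise DataError("one SNP name required per genotype column")
        if len(set(self.snp_names)) != len(self.snp_names):
            raise DataError("snp_names must be unique")
        object.__setattr__(self, "genotypes", np.ascontiguousarray(g, dtype=np.int8))
        object.__setattr__(self, "phenotype", np.ascontiguousarray(y, dtype=np.int8))
        object.__setattr__(self, "snp_names", tuple(self.snp_names))

    @classmethod
    def from_arrays(
        cls,
        genotypes: np.ndarray,
        phenotype: np.ndarray,
        snp_names: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        genotypes = np.asarray(genotypes)
        if snp_names is None:
            snp_names = tuple(f"SNP{j + 1}" for j in range(genotypes.shape[1]))
        return cls(genotypes, np.asarray(phenotype), tuple(snp_names))

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == CONTROL).sum())


@dataclass(frozen=True)
class CellTable:
    """Per-genotype-combination case/control counts for one SNP combination.

    Cells are indexed by the mixed-radix base-3 encoding of the genotype
    tuple, first listed SNP most significant: for order ``k`` the tuple
    ``(g_1, ..., g_k)`` maps to ``sum(g_j * 3**(k - j))``.
    """

    snp_indices: tuple[int, ...]
    n_case: np.ndarray
    n_control: np.ndarray
    snp_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        k = len(self.snp_indices)
        nc = np.asarray(self.n_case, dtype=np.int64)
        n0 = np.asarray(self.n_control, dtype=np.int64)
        if k < 1:
            raise InvalidCombinationError("order k must be >= 1")
        if nc.shape != (3**k,) or n0.shape != (3**k,):
            raise DataError(f"count arrays must have length 3**{k}")
        if (nc < 0).any() or (n0 < 0).any():
            raise DataError("cell counts must be nonnegative")
        object.__setattr__(self, "snp_indices", tuple(self.snp_indices))
        object.__setattr__(self, "n_case", nc)
        object.__setattr__(self, "n_control", n0)

    @property
    def k(self) -> int:
        return len(self.snp_indices)

    @property
    def n_cells(self) -> int:
        return 3**self.k

    @property
    def n_total(self) -> np.ndarray:
        """Per-cell margins n_i+ = n_i1 + n_i0."""
        return self.n_case + self.n_control

    @property
    def nonempty(self) -> np.ndarray:
        return self.n_total > 0

    @property
    def nonempty_cell_count(self) -> int:
        return int(self.nonempty.sum())

    @property
    def total_cases(self) -> int:
        return int(self.n_case.sum())

    @property
    def total_controls(self) -> int:
        return int(self.n_control.sum())

    @property
    def total_samples(self) -> int:
        return self.total_cases + self.total_controls

    def genotype_tuple(self, cell: int) -> tuple[int, ...]:
        """Decode a cell index into its genotype tuple."""
        out = []
        for _ in range(self.k):
            out.append(cell % 3)
            cell //= 3
        return tuple(reversed(out))


def count_cells(
    data: GenotypeMatrix,
    snp_indices: Sequence[int],
    max_order: int = DEFAULT_MAX_ORDER,
) -> CellTable:
    """Tabulate case and control counts per multi-locus genotype.

    Samples with a missing genotype at any of the selected SNPs are
    excluded from this table and its margins (complete-case analysis per
    combination).
    """
    idx = tuple(int(i) for i in snp_indices)
    k = len(idx)
    if k == 0:
        raise InvalidCombinationError("at least one SNP index is required")
    if k > max_order:
        raise InvalidCombinationError(f"order {k} exceeds max_order={max_order}")
    if len(set(idx)) != k:
        raise InvalidCombinationError(f"duplicate SNP indices in {idx}")
    for i in idx:
        if not 0 <= i < data.n_snps:
            raise InvalidCombinationError(
                f"SNP index {i} out of range for {data.n_snps} SNPs"
            )
    sub = data.genotypes[:, idx]
    keep = (sub != MISSING).all(axis=1)
    radix = 3 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    cell = sub[keep].astype(np.int64) @ radix
    y = data.phenotype[keep]
    n_case = np.bincount(cell[y == CASE], minlength=3**k)
    n_control = np.bincount(cell[y == CONTROL], minlength=3**k)
    names = tuple(data.snp_names[i] for i in idx)
    return CellTable(idx, n_case, n_control, snp_names=names)


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

_MDR_MISSING_TOKENS = {"NA"}


def _parse_genotype_tokens(
    tokens: np.ndarray, lineno: np.ndarray, permissive: bool
) -> np.ndarray:
    """Map an array of string tokens to genotype codes."""
    out = np.full(tokens.shape, MISSING, dtype=np.int8)
    for code in ("0", "1", "2"):
        out[tokens == code] = int(code)
    known = np.isin(tokens, ("0", "1", "2")) | np.isin(
        tokens, tuple(_MDR_MISSING_TOKENS)
    )
    if not known.all() and not permissive:
        r, c = np.argwhere(~known)[0]
        raise FormatError(
            f"line {lineno[r]}: unparseable genotype token "
            f"{tokens[r, c]!r} in column {c + 1} "
            "(pass permissive=True to treat it as missing)"
        )
    return out


def read_mdr_format(
    path: str | Path,
    class_column: str | None = None,
    permissive: bool = False,
) -> GenotypeMatrix:
    """Read the tab-delimited MDR text format.

    One header row of SNP names plus a class column (1 = case,
    0 = control), one row per sample; genotype columns coded 0/1/2 with
    ``NA`` for missing.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != width:
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {width}"
            )
        rows.append(fields)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    frame = pd.DataFrame(rows, columns=header)
    if class_column is None:
        class_column = header[-1]
    if class_column not in frame.columns:
        raise FormatError(f"{path}: class column {class_column!r} not found")
    labels = frame[class_column].to_numpy()
    if not np.isin(labels, ("0", "1")).all():
        bad = labels[~np.isin(labels, ("0", "1"))][0]
        raise FormatError(
            f"{path}: class label {bad!r} is not 0/1 "
            "(PLINK 1/2 coding must go through read_plink_raw)"
        )
    snp_cols = [c for c in header if c != class_column]
    tokens = frame[snp_cols].to_numpy(dtype=str)
    lineno = np.arange(2, 2 + len(rows))
    genotypes = _parse_genotype_tokens(tokens, lineno, permissive)
    phenotype = labels.astype(np.int8)
    return GenotypeMatrix(genotypes, phenotype, tuple(snp_cols))


def write_mdr_format(
    data: GenotypeMatrix, path: str | Path, class_name: str = "Class"
) -> None:
    """Write MDR tab-delimited text; missing genotypes become ``NA``."""
    frame = pd.DataFrame(data.genotypes, columns=list(data.snp_names), dtype=object)
    frame = frame.where(frame != MISSING, "NA")
    frame[class_name] = data.phenotype
    frame.to_csv(path, sep="\t", index=False)


_PLINK_LEADING = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_plink_raw(path: str | Path) -> GenotypeMatrix:
    """Read PLINK additive-coded ``.raw`` text.

    Columns FID IID PAT MAT SEX PHENOTYPE then one column per variant
    with minor-allele counts 0/1/2 or NA; PHENOTYPE 1 = control,
    2 = case.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if tuple(frame.columns[:6]) != _PLINK_LEADING:
        raise FormatError(
            f"{path}: header must start with {' '.join(_PLINK_LEADING)}"
        )
    if frame.shape[1] < 7:
        raise FormatError(f"{path}: no variant columns")
    pheno_raw = frame["PHENOTYPE"].to_numpy()
    if not np.isin(pheno_raw, (1, 2)).all():
        raise FormatError(
            f"{path}: PHENOTYPE must be 1 (control) or 2 (case); "
            "missing phenotypes are not supported"
        )
    phenotype = (pheno_raw == 2).astype(np.int8)
    snp_cols = list(frame.columns[6:])
    geno = frame[snp_cols].to_numpy(dtype=float)
    genotypes = np.full(geno.shape, MISSING, dtype=np.int8)
    obs = ~np.isnan(geno)
    if not np.isin(geno[obs], (0.0, 1.0, 2.0)).all():
        raise FormatError(f"{path}: additive genotype codes must be 0/1/2 or NA")
    genotypes[obs] = geno[obs].astype(np.int8)
    return GenotypeMatrix(genotypes, phenotype, tuple(snp_cols))
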