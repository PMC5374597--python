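"""Penetrance-model case-control simulator and study harnesses.

A k-way penetrance table ``f(g) = P(case | genotype g)`` together with
per-SNP minor allele frequencies (Hardy-Weinberg, independent loci)
defines the simulation ground truth.  Case-control data are drawn
retrospectively: causal genotypes from ``P(g | case)`` and
``P(g | control)`` via Bayes, noise SNPs as independent Hardy-Weinberg
draws.  Optionally a genotyped marker in linkage disequilibrium (D')
with each causal locus is emitted instead of the locus itself.

The module also provides the two study harnesses built on the simulator:
a type-I-error study (null SNP pairs, rejection rates at nominal levels)
and a power study (fraction of replicates in which a search engine
recovers the exact planted causal pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .data import GenotypeMatrix
from .search import EFMDRSearch, MDRSearch, SearchError


class FeasibilityError(ValueError):
    """Requested simulation model is infeasible."""


def _hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (0, 1, 2 minor alleles)."""
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


@dataclass(frozen=True)
class PenetranceModel:
    """k-way penetrance table plus per-locus minor allele frequencies."""

    penetrance: np.ndarray
    maf: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        pen = np.asarray(self.penetrance, dtype=float)
        k = len(self.maf)
        if pen.shape != (3,) * k:
            raise FeasibilityError(
                f"penetrance table shape {pen.shape} does not match "
                f"{k} loci (expected {(3,) * k})"
            )
        if ((pen < 0) | (pen > 1)).any():
            raise FeasibilityError("penetrances must lie in [0, 1]")
        for q in self.maf:
            if not 0 < q <= 0.5:
                raise FeasibilityError(f"MAF {q} must lie in (0, 0.5]")
        object.__setattr__(self, "penetrance", pen)
        object.__setattr__(self, "maf", tuple(float(q) for q in self.maf))

    @property
    def k(self) -> int:
        return len(self.maf)

    def genotype_probs(self) -> np.ndarray:
        """Joint genotype probabilities under HWE and independent loci."""
        probs = _hwe_probs(self.maf[0])
        for q in self.maf[1:]:
            probs = np.multiply.outer(probs, _hwe_probs(q))
        return probs

    @classmethod
    def null(
        cls, k: int = 2, maf: Sequence[float] = (0.3, 0.3), prevalence: float = 0.1
    ) -> "PenetranceModel":
        """Phenotype independent of genotype: constant penetrance."""
        return cls(np.full((3,) * k, prevalence), tuple(maf), name="null")

    @classmethod
    def pure_epistatic(
        cls,
        heritability: float,
        maf: Sequence[float] = (0.4, 0.4),
        prevalence: float = 0.1,
    ) -> "PenetranceModel":
        """Two-locus purely epistatic model at a target heritability.

        Penetrance ``f(g1, g2) = K + theta * (g1 - 2*q1) * (g2 - 2*q2)``:
        the product of centered minor-allele counts has zero mean given
        either single locus, so both marginal penetrances equal the
        prevalence K for any MAF, and

            h^2 = theta^2 * V1 * V2 / (K * (1 - K)),  V_j = 2*q_j*(1-q_j),

        which gives theta in closed form.
        """
        if not 0 <= heritability < 1:
            raise FeasibilityError(f"heritability {heritability} must be in [0, 1)")
        q1, q2 = (float(q) for q in maf)
        k_prev = float(prevalence)
        v1, v2 = 2 * q1 * (1 - q1), 2 * q2 * (1 - q2)
        theta = np.sqrt(heritability * k_prev * (1 - k_prev) / (v1 * v2))
        g = np.arange(3.0)
        pen = k_prev + theta * np.multiply.outer(g - 2 * q1, g - 2 * q2)
        if ((pen < 0) | (pen > 1)).any():
            raise FeasibilityError(
                f"heritability {heritability} at prevalence {k_prev}, "
                f"MAF ({q1}, {q2}) pushes penetrance outside [0, 1]"
            )
        return cls(pen, (q1, q2), name=f"epistatic(h2={heritability})")


def heritability(model: PenetranceModel) -> tuple[float, float]:
    """Population prevalence K and heritability h^2 of a penetrance model.

    ``h^2 = sum_g (f(g) - K)^2 P(g) / (K (1 - K))`` with K the
    probability-weighted mean penetrance.
    """
    probs = model.genotype_probs()
    pen = model.penetrance
    k_prev = float((pen * probs).sum())
    if k_prev <= 1e-12 or k_prev >= 1.0 - 1e-12:
        raise FeasibilityError(
            f"prevalence {k_prev} leaves heritability undefined"
        )
    h2 = float((((pen - k_prev) ** 2) * probs).sum() / (k_prev * (1 - k_prev)))
    return k_prev, h2


@dataclass(frozen=True)
class MarginalModelSpec:
    """Two-locus disease models with marginal effects.

    The odds of disease are ``b * theta ** score(g1, g2)`` where the
    exposure score depends on the family: ``additive`` uses the total
    minor-allele count g1 + g2, ``multiplicative`` the product g1 * g2,
    and ``threshold`` the indicator of carrying at least one minor
    allele at both loci.  The baseline odds ``b`` are solved so that the
    population prevalence hits ``prevalence``.  ``ld`` optionally gives a
    D' coefficient per causal locus; the generator then emits a marker in
    LD with the locus instead of the locus itself.
    """

    family: str
    theta: float
    maf: tuple[float, float] = (0.3, 0.3)
    prevalence: float = 0.1
    ld: tuple[float, float] | None = None
    marker_maf: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("additive", "multiplicative", "threshold"):
            raise FeasibilityError(f"unknown model family {self.family!r}")
        if self.theta <= 0:
            raise FeasibilityError(f"effect multiplier theta must be > 0")
        object.__setattr__(self, "maf", tuple(float(q) for q in self.maf))

    def score(self) -> np.ndarray:
        g = np.arange(3)
        if self.family == "additive":
            return np.add.outer(g, g).astype(float)
        if self.family == "multiplicative":
            return np.multiply.outer(g, g).astype(float)
        return np.multiply.outer(g >= 1, g >= 1).astype(float)

    def to_penetrance(self) -> PenetranceModel:
        """Convert to a penetrance table hitting the target prevalence."""
        score = self.score()
        probs = (
            np.multiply.outer(_hwe_probs(self.maf[0]), _hwe_probs(self.maf[1]))
        )

        def prev(log_b: float) -> float:
            odds = np.exp(log_b) * self.theta**score
            return float((odds / (1 + odds) * probs).sum()) - self.prevalence

        log_b = brentq(prev, -50.0, 50.0)
        odds = np.exp(log_b) * self.theta**score
        return PenetranceModel(
            odds / (1 + odds), self.maf, name=f"{self.family}(theta={self.theta})"
        )

    def odds_ratio(self) -> float:
        """Model odds ratio per unit of the exposure score."""
        return float(self.theta)


@dataclass(frozen=True)
class TruthManifest:
    """Ground truth of a simulated dataset, for power scoring."""

    causal_indices: tuple[int, ...]
    causal_names: tuple[str, ...]
    model: str
    seed: int | None
    n_case: int
    n_control: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "causal_index": self.causal_indices,
                "causal_name": self.causal_names,
                "model": self.model,
                "seed": self.seed,
                "n_case": self.n_case,
                "n_control": self.n_control,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _ld_conditionals(
    causal_maf: float, marker_maf: float, d_prime: float
) -> tuple[float, float]:
    """P(marker minor allele | causal minor) and (... | causal major).

    Haplotype frequencies follow from the two MAFs and D' (D scaled by
    its feasibility bound).  An out-of-range D' raises with the bound.
    """
    pa, pb = causal_maf, marker_maf
    if not -1.0 <= d_prime <= 1.0:
        raise FeasibilityError(
            f"D' = {d_prime} outside the feasible range [-1, 1] "
            f"for MAFs ({pa}, {pb})"
        )
    if d_prime >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d = d_prime * dmax
    h_minor_minor = pa * pb + d
    p_m_given_minor = h_minor_minor / pa
    p_m_given_major = (pb - h_minor_minor) / (1 - pa)
    return p_m_given_minor, p_m_given_major


def _draw_marker(
    causal_geno: np.ndarray,
    causal_maf: float,
    marker_maf: float,
    d_prime: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Marker genotypes given causal genotypes, haplotype by haplotype."""
    p_min, p_maj = _ld_conditionals(causal_maf, marker_maf, d_prime)
    g = causal_geno.astype(np.int64)
    # each of the 2 haplotypes carries the causal minor allele iff counted
    minor_alleles = rng.binomial(g, p_min)
    major_alleles = rng.binomial(2 - g, p_maj)
    return (minor_alleles + major_alleles).astype(np.int8)


def _decode(flat: np.ndarray, k: int) -> np.ndarray:
    """Mixed-radix base-3 decode; columns ordered most significant first."""
    out = np.empty((flat.shape[0], k), dtype=np.int8)
    for j in range(k - 1, -1, -1):
        out[:, j] = flat % 3
        flat = flat // 3
    return out


def generate_case_control(
    model: PenetranceModel | MarginalModelSpec,
    n_case: int,
    n_control: int,
    n_noise_snps: int = 18,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthManifest]:
    """Draw a retrospective case-control sample from a penetrance model.

    Causal genotype tuples are drawn from ``P(g | case)`` and
    ``P(g | control)``; noise SNPs are independent HWE draws with MAF
    uniform over ``noise_maf_range``.  Causal columns are placed at
    random positions among the noise and recorded in the manifest.
    Deterministic given the seed.
    """
    if n_case <= 0 and n_control <= 0:
        raise FeasibilityError("at least one of n_case, n_control must be > 0")
    spec_ld = None
    marker_maf = None
    if isinstance(model, MarginalModelSpec):
        spec_ld = model.ld
        marker_maf = model.marker_maf or model.maf
        pen_model = model.to_penetrance()
    else:
        pen_model = model
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    probs = pen_model.genotype_probs().ravel()
    pen = pen_model.penetrance.ravel()
    k_prev = float((pen * probs).sum())
    if not 0.0 < k_prev < 1.0:
        raise FeasibilityError(f"population prevalence {k_prev} is not in (0, 1)")
    p_case = pen * probs / k_prev
    p_ctrl = (1 - pen) * probs / (1 - k_prev)

    k = pen_model.k
    cells = np.arange(3**k)
    flat_case = rng.choice(cells, size=n_case, p=p_case)
    flat_ctrl = rng.choice(cells, size=n_control, p=p_ctrl)
    causal = np.vstack([_decode(flat_case, k), _decode(flat_ctrl, k)])

    if spec_ld is not None:
        emitted = np.empty_like(causal)
        for j in range(k):
            emitted[:, j] = _draw_marker(
                causal[:, j], pen_model.maf[j], marker_maf[j], spec_ld[j], rng
            )
        causal = emitted

    n = n_case + n_control
    noise_maf = rng.uniform(*noise_maf_range, size=n_noise_snps)
    noise = rng.binomial(2, noise_maf[None, :], size=(n, n_noise_snps)).astype(np.int8)

    s = k + n_noise_snps
    positions = rng.permutation(s)
    causal_pos = np.sort(positions[:k])
    genotypes = np.empty((n, s), dtype=np.int8)
    genotypes[:, causal_pos] = causal
    noise_pos = np.setdiff1d(np.arange(s), causal_pos)
    genotypes[:, noise_pos] = noise
    phenotype = np.concatenate(
        [np.ones(n_case, dtype=np.int8), np.zeros(n_control, dtype=np.int8)]
    )
    names = tuple(f"SNP{j + 1}" for j in range(s))
    data = GenotypeMatrix(genotypes, phenotype, names)
    manifest = TruthManifest(
        causal_indices=tuple(int(i) for i in causal_pos),
        causal_names=tuple(names[i] for i in causal_pos),
        model=pen_model.name,
        seed=seed_int,
        n_case=n_case,
        n_control=n_control,
    )
    return data, manifest


# ---------------------------------------------------------------------------
# Type I error study
# ---------------------------------------------------------------------------


def _simulate_null_pairs(
    rng: np.random.Generator,
    n_replicates: int,
    n_samples: int,
    maf_choices: Sequence[float],
) -> np.ndarray:
    """(replicates, samples, 2) null genotypes; each SNP's MAF drawn
    from ``maf_choices``."""
    mafs = rng.choice(np.asarray(maf_choices, dtype=float), size=(n_replicates, 2))
    return rng.binomial(2, mafs[:, None, :], size=(n_replicates, n_samples, 2)).astype(
        np.int8
    )


def _pair_pvalues(genotypes: np.ndarray, n_case: int) -> np.ndarray:
    """Vectorised EF-MDR p-value of the 2-SNP model, one per replicate.

    Same statistic chain as :func:`efmdr.stats.evaluate_combination`,
    computed on all replicates at once: per-cell counts, empirical
    balanced accuracy, X^2 = n (2 BA - 1), chi-square upper tail with
    (nonempty cells - 1) degrees of freedom.
    """
    reps, n, _ = genotypes.shape
    cell = (3 * genotypes[:, :, 0].astype(np.int64)) + genotypes[:, :, 1]
    offset = np.arange(reps, dtype=np.int64)[:, None] * 9
    n1 = np.bincount(
        (cell[:, :n_case] + offset).ravel(), minlength=reps * 9
    ).reshape(reps, 9)
    n0 = np.bincount(
        (cell[:, n_case:] + offset).ravel(), minlength=reps * 9
    ).reshape(reps, 9)
    tot = n1 + n0
    with np.errstate(invalid="ignore", divide="ignore"):
        sen = np.where(tot > 0, n1**2 / np.maximum(tot, 1), 0.0).sum(axis=1) / n_case
        spe = np.where(tot > 0, n0**2 / np.maximum(tot, 1), 0.0).sum(axis=1) / (
            n - n_case
        )
    ba = 0.5 * (sen + spe)
    x2 = np.maximum(n * (2 * ba - 1), 0.0)
    df = (tot > 0).sum(axis=1) - 1
    return sps.chi2.sf(x2, df)


@dataclass
class Type1Result:
    """Null-simulation rejection rates with Monte-Carlo standard errors."""

    table: pd.DataFrame
    p_values: np.ndarray
    n_samples: int
    n_replicates: int


def type1_error_study(
    n_samples: int = 1600,
    n_replicates: int = 7000,
    alpha_levels: Sequence[float] = (0.01, 0.05, 0.10),
    maf_choices: Sequence[float] = (0.2, 0.4),
    seed: int | None = None,
    chunk: int = 1000,
) -> Type1Result:
    """Type-I-error study on null SNP pairs.

    Per replicate: two phenotype-independent SNPs, balanced cases and
    controls totalling ``n_samples``; the EF-MDR p-value of the pair is
    computed and the rejection rate at each nominal level reported with a
    binomial standard error.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    rng = np.random.default_rng(seed)
    n_case = n_samples // 2
    pvals = []
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        g = _simulate_null_pairs(rng, m, n_samples, maf_choices)
        pvals.append(_pair_pvalues(g, n_case))
        done += m
    p = np.concatenate(pvals)
    rows = []
    for alpha in alpha_levels:
        rate = float((p < alpha).mean())
        rows.append(
            {
                "alpha": alpha,
                "rejection_rate": rate,
                "se": float(np.sqrt(rate * (1 - rate) / n_replicates)),
            }
        )
    return Type1Result(
        table=pd.DataFrame(rows),
        p_values=p,
        n_samples=n_samples,
        n_replicates=n_replicates,
    )


# ---------------------------------------------------------------------------
# Power study
# ---------------------------------------------------------------------------


def _efmdr_best(data: GenotypeMatrix, order: int, seed: int) -> tuple[int, ...]:
    est = EFMDRSearch(orders=order, top=1).fit(data)
    return est.best_per_order_[order].snp_indices


def _mdr_best(
    data: GenotypeMatrix, order: int, seed: int, n_folds: int = 5
) -> tuple[int, ...]:
    est = MDRSearch(orders=order, n_folds=n_folds, random_state=seed, top=1).fit(data)
    return est.best_per_order_[order].snp_indices


#: Search engines usable in the power study, by name.
SEARCH_METHODS = {"efmdr": _efmdr_best, "mdr": _mdr_best}


def power_study(
    models: Mapping[str, PenetranceModel | MarginalModelSpec],
    n_case: int = 400,
    n_control: int = 400,
    n_noise_snps: int = 18,
    n_replicates: int = 100,
    methods: Sequence[str] = ("efmdr", "mdr"),
    order: int = 2,
    seed: int | None = None,
    baseline: str | None = "mdr",
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
) -> pd.DataFrame:
    """Power of each search method on each simulation model.

    Power is the fraction of replicates in which the method's best model
    at the causal order is exactly the planted causal SNP set.  The
    ``power_ratio`` column divides each power by the baseline method's
    power on the same model (NaN where the baseline power is zero).
    """
    for m in methods:
        if m not in SEARCH_METHODS:
            raise SearchError(
                f"unknown search method {m!r}; registered: "
                f"{sorted(SEARCH_METHODS)}"
            )
    master = np.random.SeedSequence(seed)
    model_seeds = master.spawn(len(models))
    rows = []
    for (name, model), model_ss in zip(models.items(), model_seeds):
        rep_seeds = model_ss.spawn(n_replicates)
        hits = {m: 0 for m in methods}
        for rep_ss in rep_seeds:
            rng = np.random.default_rng(rep_ss)
            data, truth = generate_case_control(
                model,
                n_case=n_case,
                n_control=n_control,
                n_noise_snps=n_noise_snps,
                noise_maf_range=noise_maf_range,
                seed=rng,
            )
            fold_seed = int(rep_ss.generate_state(1)[0] % (2**31))
            for m in methods:
                best = SEARCH_METHODS[m](data, order, fold_seed)
                if set(best) == set(truth.causal_indices):
                    hits[m] += 1
        for m in methods:
            rows.append(
                {
                    "model": name,
                    "method": m,
                    "power": hits[m] / n_replicates,
                    "n_replicates": n_replicates,
                }
            )
    out = pd.DataFrame(rows)
    if baseline is not None and baseline in methods:
        base = out[out["method"] == baseline].set_index("model")["power"]
        with np.errstate(divide="ignore", invalid="ignore"):
            out["power_ratio"] = [
                row.power / base[row.model] if base[row.model] > 0 else np.nan
                for row in out.itertuples()
            ]
    return out
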