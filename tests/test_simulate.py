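"""Penetrance-model simulator and study harnesses."""

import numpy as np
import pytest
import scipy.stats as sps

from efmdr.data import GenotypeMatrix
from efmdr.search import SearchError
from efmdr.simulate import (
    FeasibilityError,
    MarginalModelSpec,
    PenetranceModel,
    _ld_conditionals,
    _pair_pvalues,
    _simulate_null_pairs,
    generate_case_control,
    heritability,
    power_study,
    type1_error_study,
)
from efmdr.stats import evaluate_combination


class TestHeritability:
    def test_constant_penetrance_is_zero(self):
        k_prev, h2 = heritability(PenetranceModel.null(maf=(0.3, 0.2), prevalence=0.1))
        assert k_prev == pytest.approx(0.1)
        assert h2 == pytest.approx(0.0)

    def test_deterministic_penetrance_is_one(self):
        pen = np.zeros((3, 3))
        pen[1, 1] = 1.0
        _, h2 = heritability(PenetranceModel(pen, (0.5, 0.5)))
        assert h2 == pytest.approx(1.0)

    def test_brute_force_summation(self):
        """Hand-built table at MAF 0.5: direct sum over the 9 genotypes."""
        pen = np.array([[0.1, 0.2, 0.3], [0.2, 0.4, 0.1], [0.3, 0.1, 0.5]])
        model = PenetranceModel(pen, (0.5, 0.5))
        hw = np.array([0.25, 0.5, 0.25])
        k_ref = sum(
            pen[a, b] * hw[a] * hw[b] for a in range(3) for b in range(3)
        )
        h2_ref = sum(
            (pen[a, b] - k_ref) ** 2 * hw[a] * hw[b]
            for a in range(3)
            for b in range(3)
        ) / (k_ref * (1 - k_ref))
        k_prev, h2 = heritability(model)
        assert k_prev == pytest.approx(k_ref)
        assert h2 == pytest.approx(h2_ref)

    def test_degenerate_prevalence_errors(self):
        with pytest.raises(FeasibilityError):
            heritability(PenetranceModel(np.ones((3, 3)), (0.3, 0.3)))


class TestPureEpistatic:
    def test_hits_target_heritability_with_no_marginal_effects(self):
        model = PenetranceModel.pure_epistatic(0.03, maf=(0.3, 0.4), prevalence=0.2)
        k_prev, h2 = heritability(model)
        assert k_prev == pytest.approx(0.2)
        assert h2 == pytest.approx(0.03)
        # marginal penetrance of each locus equals the prevalence
        probs = model.genotype_probs()
        for axis in (0, 1):
            marg = (model.penetrance * probs).sum(axis=axis) / probs.sum(axis=axis)
            assert np.allclose(marg, 0.2)

    def test_infeasible_heritability_errors(self):
        with pytest.raises(FeasibilityError):
            PenetranceModel.pure_epistatic(0.5, maf=(0.4, 0.4), prevalence=0.1)


class TestMarginalModels:
    @pytest.mark.parametrize("family", ["additive", "multiplicative", "threshold"])
    def test_prevalence_is_hit(self, family):
        spec = MarginalModelSpec(family, theta=2.0, maf=(0.3, 0.3), prevalence=0.1)
        k_prev, h2 = heritability(spec.to_penetrance())
        assert k_prev == pytest.approx(0.1, abs=1e-9)
        assert h2 > 0

    def test_threshold_exposure_odds_ratio(self):
        """The empirical odds ratio of the exposure indicator matches the
        model's theta within Monte-Carlo error (moment-matching oracle)."""
        theta = 3.0
        spec = MarginalModelSpec("threshold", theta=theta, maf=(0.3, 0.3))
        ors = []
        master = np.random.SeedSequence(41)
        for ss in master.spawn(50):
            data, truth = generate_case_control(
                spec, 2000, 2000, n_noise_snps=0, seed=np.random.default_rng(ss)
            )
            g = data.genotypes[:, list(truth.causal_indices)]
            exposed = (g >= 1).all(axis=1)
            y = data.phenotype == 1
            a = (exposed & y).sum()
            b = (exposed & ~y).sum()
            c = (~exposed & y).sum()
            d = (~exposed & ~y).sum()
            ors.append((a * d) / (b * c))
        assert np.mean(ors) == pytest.approx(theta, rel=0.05)

    def test_unknown_family_and_bad_theta(self):
        with pytest.raises(FeasibilityError):
            MarginalModelSpec("dominant", theta=2.0)
        with pytest.raises(FeasibilityError):
            MarginalModelSpec("additive", theta=0.0)


class TestGenerate:
    def test_deterministic_penetrance_degenerate(self):
        """Penetrance 1 on one genotype, 0 elsewhere: every case carries it."""
        pen = np.zeros((3, 3))
        pen[2, 1] = 1.0
        model = PenetranceModel(pen, (0.4, 0.4))
        data, truth = generate_case_control(model, 100, 100, n_noise_snps=3, seed=0)
        cases = data.genotypes[data.phenotype == 1][:, list(truth.causal_indices)]
        assert np.array_equal(np.unique(cases, axis=0), [[2, 1]])

    def test_reproducible_given_seed(self):
        model = PenetranceModel.pure_epistatic(0.02, prevalence=0.2)
        d1, t1 = generate_case_control(model, 50, 50, n_noise_snps=5, seed=9)
        d2, t2 = generate_case_control(model, 50, 50, n_noise_snps=5, seed=9)
        assert np.array_equal(d1.genotypes, d2.genotypes)
        assert t1 == t2

    def test_retrospective_sampling_frequencies(self):
        """Genotype frequencies among cases converge to P(g | case)."""
        model = PenetranceModel.pure_epistatic(0.05, maf=(0.4, 0.4), prevalence=0.2)
        probs = model.genotype_probs().ravel()
        pen = model.penetrance.ravel()
        k_prev = (pen * probs).sum()
        p_case = pen * probs / k_prev
        data, truth = generate_case_control(model, 100_000, 0, n_noise_snps=0, seed=13)
        g = data.genotypes[:, list(truth.causal_indices)].astype(int)
        cell = 3 * g[:, 0] + g[:, 1]
        obs = np.bincount(cell, minlength=9)
        res = sps.chisquare(obs, f_exp=p_case * obs.sum())
        assert res.pvalue > 1e-3

    def test_null_model_embeds_uniform_pvalues(self):
        """Under constant penetrance causal and noise SNPs are exchangeable:
        the causal-pair p-value is not systematically small."""
        model = PenetranceModel.null(maf=(0.3, 0.3), prevalence=0.2)
        pvals = []
        for seed in range(40):
            data, truth = generate_case_control(model, 200, 200, n_noise_snps=2, seed=seed)
            _, acc = evaluate_combination(data, truth.causal_indices)
            pvals.append(acc.p_value)
        assert np.mean(pvals) > 0.3

    def test_manifest_indices_valid(self):
        model = PenetranceModel.pure_epistatic(0.02, prevalence=0.2)
        data, truth = generate_case_control(model, 30, 30, n_noise_snps=8, seed=3)
        assert len(truth.causal_indices) == 2
        assert all(0 <= i < data.n_snps for i in truth.causal_indices)
        assert truth.causal_names == tuple(
            data.snp_names[i] for i in truth.causal_indices
        )


class TestLinkageDisequilibrium:
    def test_perfect_ld_copies_the_causal_locus(self):
        spec = MarginalModelSpec(
            "threshold", theta=4.0, maf=(0.3, 0.3), ld=(1.0, 1.0)
        )
        # with D'=1 and equal MAFs the marker haplotype tracks the causal one
        p_min, p_maj = _ld_conditionals(0.3, 0.3, 1.0)
        assert p_min == pytest.approx(1.0)
        assert p_maj == pytest.approx(0.0)
        data, truth = generate_case_control(spec, 500, 500, n_noise_snps=0, seed=21)
        g = data.genotypes[:, list(truth.causal_indices)]
        # markers keep the exposure association
        exposed = (g >= 1).all(axis=1)
        y = data.phenotype == 1
        assert exposed[y].mean() > exposed[~y].mean()

    def test_zero_ld_breaks_association(self):
        p_min, p_maj = _ld_conditionals(0.3, 0.4, 0.0)
        assert p_min == pytest.approx(0.4)
        assert p_maj == pytest.approx(0.4)

    def test_infeasible_ld_errors_with_bound(self):
        with pytest.raises(FeasibilityError, match=r"\[-1, 1\]"):
            _ld_conditionals(0.3, 0.3, 1.5)


class TestType1Study:
    def test_alpha_one_rejects_everything(self):
        res = type1_error_study(
            n_samples=200, n_replicates=200, alpha_levels=(1.0,), seed=5
        )
        assert res.table.loc[0, "rejection_rate"] == 1.0

    def test_vectorised_pvalues_match_statistic_chain(self):
        """The batched null p-values equal per-replicate evaluation."""
        rng = np.random.default_rng(17)
        g = _simulate_null_pairs(rng, 20, 100, (0.2, 0.4))
        p_fast = _pair_pvalues(g, 50)
        y = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
        for r in range(20):
            data = GenotypeMatrix.from_arrays(g[r], y)
            _, acc = evaluate_combination(data, (0, 1))
            assert p_fast[r] == pytest.approx(acc.p_value, abs=1e-12)

    def test_requires_enough_replicates(self):
        with pytest.raises(ValueError):
            type1_error_study(n_replicates=10)


class TestPowerStudy:
    def test_unknown_method_errors(self):
        models = {"null": PenetranceModel.null(prevalence=0.2)}
        with pytest.raises(SearchError, match="unknown search method"):
            power_study(models, methods=("efmdr", "nosuch"), n_replicates=100)

    def test_null_power_near_chance(self):
        """With no effect, recovering the labelled pair is ~1/C(s,2)."""
        models = {"null": PenetranceModel.null(maf=(0.3, 0.3), prevalence=0.2)}
        table = power_study(
            models,
            n_case=100,
            n_control=100,
            n_noise_snps=8,  # s = 10 -> chance 1/45
            n_replicates=100,
            methods=("efmdr",),
            baseline=None,
            seed=23,
        )
        assert table.loc[0, "power"] <= 0.15

    def test_saturates_at_strong_effect(self):
        models = {
            "strong": PenetranceModel.pure_epistatic(0.05, maf=(0.4, 0.4), prevalence=0.2)
        }
        table = power_study(
            models,
            n_case=200,
            n_control=200,
            n_noise_snps=8,
            n_replicates=20,
            methods=("efmdr",),
            baseline=None,
            seed=29,
        )
        assert table.loc[0, "power"] >= 0.9

    def test_reproducible_given_seed(self):
        models = {"m": PenetranceModel.pure_epistatic(0.02, prevalence=0.2)}
        kw = dict(
            n_case=100, n_control=100, n_noise_snps=5, n_replicates=10,
            methods=("efmdr", "mdr"), seed=31,
        )
        assert power_study(models, **kw).equals(power_study(models, **kw))
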