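"""Regression layer: admixture mapping, stratified association, scores."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ujat import simulate
from ujat.assoc import (
    CohortData,
    ScoreWeights,
    admixture_mapping_scan,
    conditional_association,
    genetic_score,
    joint_inputs,
    stratified_association,
    stratum_allele_freqs,
)
from ujat.joint_test import joint_statistic
from ujat.meta import inverse_variance_meta


def small_cohort(seed=0, n=600, **kw):
    cfg = simulate.CohortConfig(n_individuals=n, seed=seed, **kw)
    return simulate.simulate_admixed_cohort(cfg)


class TestAdmixtureMapping:
    def test_null_calibration_across_loci(self):
        # no ancestry or genotype effect: z scores standard normal
        cfg = simulate.CohortConfig(
            n_individuals=1000, n_loci=300, beta_ancestry=0.0,
            beta_genotype=0.0, freq_anc0=0.5, freq_anc2=0.5, seed=21,
        )
        cohort = simulate.simulate_admixed_cohort(cfg)
        # adjust for genome-wide ancestry so the 300 locus tests are
        # mutually independent given the shared admixture proportions
        scan = admixture_mapping_scan(
            cohort, covariates=("age", "sex", "admixture")
        )
        z = scan["z"].to_numpy()
        assert abs(z.mean()) < 3 / math.sqrt(len(z))
        rej = np.mean(scan["p"] < 0.05)
        assert abs(rej - 0.05) < 3 * math.sqrt(0.05 * 0.95 / len(z))

    def test_recovers_known_ancestry_effect(self):
        cfg = simulate.CohortConfig(
            n_individuals=5000, beta_ancestry=0.1, beta_genotype=0.0,
            noise_sd=1.0, seed=4,
        )
        cohort = simulate.simulate_admixed_cohort(cfg)
        scan = admixture_mapping_scan(cohort)
        row = scan.iloc[0]
        assert abs(row["beta"] - 0.1) < 3 * row["se"]

    def test_monomorphic_locus_flagged_not_estimated(self):
        cohort = small_cohort(seed=2)
        cohort.ancestry["var0000"] = 2  # force monomorphic ancestry
        scan = admixture_mapping_scan(cohort)
        assert not scan.loc["var0000", "estimable"]
        assert math.isnan(scan.loc["var0000", "beta"])

    def test_collinear_covariate_rejected(self):
        cohort = small_cohort(seed=3)
        cohort.individuals["age_copy"] = cohort.individuals["age"]
        with pytest.raises(ValueError, match="rank deficient"):
            admixture_mapping_scan(cohort, covariates=("age", "sex", "age_copy"))


class TestStratifiedAssociation:
    def test_equivalent_to_full_interaction_regression(self):
        """Per-stratum fits match one regression with stratum-interacted terms."""
        cohort = small_cohort(seed=5, n=900)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strata = stratified_association(cohort, "var0000",
                                            min_stratum_size=10)
        anc = cohort.ancestry["var0000"].to_numpy()
        y = cohort.individuals["phenotype"].to_numpy()
        blocks = []
        order = []
        for code in (0, 1, 2):
            mask = anc == code
            if mask.sum() < 10:
                continue
            dos = cohort.dosage.loc[mask, "var0000"].to_numpy()
            if len(np.unique(dos)) < 2:
                continue
            base = np.column_stack([
                np.ones(mask.sum()),
                dos,
                cohort.individuals.loc[mask, "age"],
                cohort.individuals.loc[mask, "sex"],
            ])
            block = np.zeros((len(y), base.shape[1]))
            block[mask] = base
            blocks.append(block)
            order.append(code)
        X = np.hstack(blocks)
        coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
        oracle_betas = [coefs[i * 4 + 1] for i in range(len(order))]
        assert len(strata) == len(order)
        for est_, oracle in zip(strata, oracle_betas):
            assert est_.beta == pytest.approx(oracle, abs=1e-8)

    def test_recovers_common_genotype_effect_with_homogeneity(self):
        cfg = simulate.CohortConfig(n_individuals=6000, beta_genotype=0.15,
                                    noise_sd=0.5, seed=6)
        cohort = simulate.simulate_admixed_cohort(cfg)
        strata = stratified_association(cohort, "var0000")
        assert len(strata) == 3
        for e in strata:
            assert abs(e.beta - 0.15) < 3 * e.se
        pooled = inverse_variance_meta(strata)
        assert pooled.het_p > 0.001  # homogeneous by construction

    def test_constant_dosage_stratum_omitted(self):
        cohort = small_cohort(seed=8, n=800)
        mask = cohort.ancestry["var0000"] == 0
        cohort.dosage.loc[mask, "var0000"] = 2.0
        with pytest.warns(UserWarning, match="no genotype variance"):
            strata = stratified_association(cohort, "var0000",
                                            min_stratum_size=5)
        assert all(e.label != "homozygous-0" for e in strata)

    def test_small_stratum_omitted_with_warning(self):
        # at n=400 the homozygous-0 stratum (~5% of the cohort) falls below
        # a minimum of 50 while the other two strata remain usable
        cohort = small_cohort(seed=9, n=400)
        with pytest.warns(UserWarning, match="omitted"):
            strata = stratified_association(cohort, "var0000",
                                            min_stratum_size=50)
        assert 1 <= len(strata) < 3


class TestConditionalAssociation:
    def test_conditioning_on_near_perfect_ld_shrinks_effect(self):
        cfg = simulate.CohortConfig(n_individuals=3000, beta_genotype=0.3,
                                    n_loci=2, noise_sd=0.5, seed=10)
        cohort = simulate.simulate_admixed_cohort(cfg)
        # make var0001 a near-perfect proxy of the causal var0000
        proxy = cohort.dosage["var0000"].copy()
        flip = np.random.default_rng(0).random(len(proxy)) < 0.01
        proxy[flip] = 2 - proxy[flip]
        cohort.dosage["var0001"] = proxy
        cohort.ancestry["var0001"] = cohort.ancestry["var0000"]
        strata = conditional_association(cohort, "var0000", ["var0001"])
        pooled = inverse_variance_meta(strata)
        unconditional = inverse_variance_meta(
            stratified_association(cohort, "var0000")
        )
        assert abs(pooled.z) < abs(unconditional.z) / 2

    def test_conditioning_on_null_variant_is_innocuous(self):
        cfg = simulate.CohortConfig(n_individuals=3000, beta_genotype=0.2,
                                    n_loci=2, noise_sd=0.5, seed=11)
        cohort = simulate.simulate_admixed_cohort(cfg)
        base = inverse_variance_meta(stratified_association(cohort, "var0000"))
        cond = inverse_variance_meta(
            conditional_association(cohort, "var0000", ["var0001"])
        )
        assert abs(cond.beta - base.beta) < 3 * base.se

    def test_test_variant_in_conditioning_set_rejected(self):
        cohort = small_cohort(seed=12)
        with pytest.raises(ValueError, match="conditioning"):
            conditional_association(cohort, "var0000", ["var0000"])


class TestStratumFrequencies:
    def test_fixed_dosage_gives_unit_frequency(self):
        cohort = small_cohort(seed=13)
        cohort.dosage["var0000"] = 2.0
        f0, f2 = stratum_allele_freqs(cohort, "var0000")
        assert f0 == 1.0 and f2 == 1.0

    def test_recovers_generator_frequencies(self):
        cfg = simulate.CohortConfig(n_individuals=10_000, seed=14)
        cohort = simulate.simulate_admixed_cohort(cfg)
        f0, f2 = stratum_allele_freqs(cohort, "var0000")
        n0 = int((cohort.ancestry["var0000"] == 0).sum())
        n2 = int((cohort.ancestry["var0000"] == 2).sum())
        se0 = math.sqrt(0.689 * 0.311 / (2 * n0))
        se2 = math.sqrt(0.429 * 0.571 / (2 * n2))
        assert abs(f0 - 0.689) < 3 * se0
        assert abs(f2 - 0.429) < 3 * se2

    def test_empty_stratum_yields_nan(self):
        cohort = small_cohort(seed=15)
        cohort.ancestry["var0000"] = cohort.ancestry["var0000"].clip(lower=1)
        f0, f2 = stratum_allele_freqs(cohort, "var0000")
        assert math.isnan(f0) and not math.isnan(f2)


class TestGeneticScore:
    def test_covariates_only(self):
        cohort = small_cohort(seed=16)
        w = ScoreWeights(intercept=1.0, beta_age=0.5, beta_sex=-0.2)
        s = genetic_score(cohort, w)
        expected = (1.0 + 0.5 * cohort.individuals["age"]
                    - 0.2 * cohort.individuals["sex"])
        pd.testing.assert_series_equal(s, expected.rename("score"))

    def test_linear_in_dosage(self):
        cohort = small_cohort(seed=17)
        cohort.dosage["var0000"] = np.resize([0.0, 1.0, 2.0], cohort.n)
        w = ScoreWeights(intercept=2.0,
                         variant_weights={"var0000": ("A", 0.5)})
        s = genetic_score(cohort, w)
        assert set(np.round(np.unique(s), 9)) == {2.0, 2.5, 3.0}

    def test_missing_variant_named_in_error(self):
        cohort = small_cohort(seed=18)
        w = ScoreWeights(variant_weights={"varXXXX": ("A", 0.5)})
        with pytest.raises(KeyError, match="varXXXX"):
            genetic_score(cohort, w)

    def test_generative_weights_predict_phenotype(self):
        cfg = simulate.CohortConfig(n_individuals=5000, seed=19)
        cohort = simulate.simulate_admixed_cohort(cfg)
        w = ScoreWeights(beta_age=cfg.beta_age, beta_sex=cfg.beta_sex,
                         variant_weights={"var0000": ("", cfg.beta_genotype)})
        s = genetic_score(cohort, w)
        r = np.corrcoef(s, cohort.individuals["phenotype"])[0, 1]
        assert r > 0.1


class TestJointInputsPipeline:
    def test_allele_flip_leaves_joint_statistic_unchanged(self, lpl_like_cohort):
        cohort = lpl_like_cohort
        record = joint_inputs(cohort, "var0000")
        flipped = CohortData(
            individuals=cohort.individuals.copy(),
            dosage=2.0 - cohort.dosage,
            ancestry=cohort.ancestry.copy(),
        )
        record_f = joint_inputs(flipped, "var0000")
        stat = joint_statistic(record.z_ancestry, record.z_assoc,
                               record.f0, record.f2)
        stat_f = joint_statistic(record_f.z_ancestry, record_f.z_assoc,
                                 record_f.f0, record_f.f2)
        assert record_f.z_assoc == pytest.approx(-record.z_assoc, abs=1e-8)
        assert record_f.f0 == pytest.approx(1 - record.f0)
        assert stat_f == pytest.approx(stat, rel=1e-8)

    def test_lpl_like_configuration_yields_consistent_signal(self, lpl_like_cohort):
        record = joint_inputs(lpl_like_cohort, "var0000")
        # effect allele commoner on the ancestry-0 background, positive
        # genotype effect, ancestry effect mediated through it
        assert record.f2 < record.f0
        assert record.z_assoc > 0
        stat = joint_statistic(record.z_ancestry, record.z_assoc,
                               record.f0, record.f2)
        assert stat > 0
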