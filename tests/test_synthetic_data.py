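"""Generator contracts: design structure, Mendelian transmission, HWE,
variance bookkeeping, artifact injection."""

import numpy as np
import pytest
from scipy import stats

from daughter_gwas.io_model import MISSING
from daughter_gwas.synthetic_data import (QtlEffect, SimulationConfig,
                                          inject_artifacts,
                                          simulate_daughter_design)


def test_design_counts_and_founders():
    cfg = SimulationConfig(n_sires=14, daughters_per_sire=150, n_snps=5,
                           traits=("MY",), seed=1)
    study = simulate_daughter_design(cfg)
    assert len(study.pedigree) == 14 + 14 * 150 == 2114
    assert len(study.pedigree.founders) == 14
    assert study.genotypes.n_individuals == 2114
    # every daughter has a genotyped sire and no dam
    for d in study.daughter_ids:
        assert study.pedigree.sire_of(d) in study.sire_ids
        assert study.pedigree.dam_of(d) is None


def test_same_seed_bit_identical():
    cfg = SimulationConfig(n_sires=2, daughters_per_sire=10, n_snps=50,
                           missing_rate=0.05, mendel_error_rate=0.01, seed=9)
    s1 = simulate_daughter_design(cfg)
    s2 = simulate_daughter_design(cfg)
    assert s1.genotypes.equals(s2.genotypes)
    assert s1.phenotypes.equals(s2.phenotypes)
    assert s1.pedigree.entries == s2.pedigree.entries
    for key in s1.truth:
        assert s1.truth[key].equals(s2.truth[key])


def test_degenerate_null_unit_variance():
    # no genetics, REL == 1: phenotypes are i.i.d. N(mu, sigma_e2)
    cfg = SimulationConfig(n_sires=10, daughters_per_sire=500, n_snps=2,
                           traits=("MY",), sigma_a2=0.0, sigma_e2=1.0,
                           reliability_range=(1.0, 1.0), trait_means=5.0,
                           seed=2)
    study = simulate_daughter_design(cfg)
    y = study.phenotypes.frame["ebv"].to_numpy()
    n = y.size
    assert n == 5000
    assert np.mean(y) == pytest.approx(5.0, abs=4 / np.sqrt(n))
    # sampling error of the variance of n normals ~ sqrt(2/n)
    assert np.var(y) == pytest.approx(1.0, abs=4 * np.sqrt(2 / n))


def test_paternal_transmission_frequency_half():
    # daughters of a heterozygous sire receive either paternal allele
    # with probability 1/2; with maf fixed at 0.5 the daughter dosage
    # mean is E[paternal] + maf, so E[paternal] should be 0.5
    cfg = SimulationConfig(n_sires=1, daughters_per_sire=1000, n_snps=30,
                           traits=("MY",), maf_range=(0.5, 0.5), seed=3)
    study = simulate_daughter_design(cfg)
    sire_row = study.genotypes.row("S01")
    het = np.flatnonzero(sire_row == 1)
    assert het.size > 0
    dau_rows = study.genotypes.codes[1:]
    three_sd = 3 * np.sqrt(0.5 / 1000)  # paternal + maternal binomial noise
    for j in het:
        transmitted_freq = dau_rows[:, j].mean() - 0.5
        assert abs(transmitted_freq - 0.5) < three_sd


def test_daughter_genotypes_in_hwe():
    # marginally each daughter dosage is Bern(p) + Bern(p); families of 2
    # keep within-family correlation negligible for the GOF test
    cfg = SimulationConfig(n_sires=2500, daughters_per_sire=2, n_snps=6,
                           traits=("MY",), maf_range=(0.1, 0.5), seed=4)
    study = simulate_daughter_design(cfg)
    p_true = study.truth["allele_freq"]["allele_b_freq"].to_numpy()
    dau_rows = study.genotypes.codes[2500:]
    n = dau_rows.shape[0]
    for j in range(6):
        p = p_true[j]
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        observed = np.array([(dau_rows[:, j] == c).sum() for c in (0, 1, 2)])
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=2) > 0.001


def test_phenotypic_variance_bookkeeping():
    # Var(y) ~= beta^2 * sigma_p^2 * 2pq + sigma_a2 + sigma_e2 * E[1/REL]
    cfg = SimulationConfig(n_sires=2000, daughters_per_sire=5, n_snps=3,
                           traits=("MY",), maf_range=(0.3, 0.3),
                           qtl=(QtlEffect(0, "MY", 0.5),),
                           sigma_a2=0.3, sigma_e2=0.7, seed=5)
    study = simulate_daughter_design(cfg)
    y = study.phenotypes.frame["ebv"].to_numpy()
    lo, hi = cfg.reliability_range
    mean_inv_rel = np.log(hi / lo) / (hi - lo)
    expected = (0.5 ** 2 * 1.0 * 2 * 0.3 * 0.7
                + 0.3 + 0.7 * mean_inv_rel)
    assert np.var(y) == pytest.approx(expected, rel=0.05)


def test_zero_daughters_rejected():
    with pytest.raises(ValueError, match="daughter"):
        SimulationConfig(n_sires=2, daughters_per_sire=0).validate()


def test_qtl_on_monomorphic_snp_rejected():
    # 1 sire + 1 daughter at maf 0.05: search a seed that fixes the SNP
    for seed in range(50):
        cfg = SimulationConfig(n_sires=1, daughters_per_sire=1, n_snps=1,
                               traits=("MY",), maf_range=(0.05, 0.05),
                               seed=seed)
        study = simulate_daughter_design(cfg)
        if np.unique(study.genotypes.codes[:, 0]).size == 1:
            cfg_qtl = SimulationConfig(
                n_sires=1, daughters_per_sire=1, n_snps=1, traits=("MY",),
                maf_range=(0.05, 0.05), qtl=(QtlEffect(0, "MY", 1.0),),
                seed=seed)
            with pytest.raises(ValueError, match="monomorphic"):
                simulate_daughter_design(cfg_qtl)
            return
    pytest.fail("no monomorphic draw found")


class TestInjectArtifacts:
    def test_zero_rates_identity(self, small_study):
        out = inject_artifacts(small_study, 0.0, 0.0, seed=1)
        assert out.genotypes.equals(small_study.genotypes)
        assert out.truth["injected_missing"].empty
        assert out.truth["injected_mendel"].empty

    def test_missing_rate_targets_individual(self, small_study):
        target = small_study.daughter_ids[0]
        out = inject_artifacts(small_study, 0.15, 0.0,
                               target_individuals=[target], seed=2)
        frac = np.mean(out.genotypes.row(target) == MISSING)
        assert frac > 0.10  # exceeds the individual-QC threshold
        others = [d for d in small_study.daughter_ids if d != target]
        for d in others[:5]:
            assert np.array_equal(out.genotypes.row(d),
                                  small_study.genotypes.row(d))

    def test_mendel_injection_is_opposite_homozygote(self, small_study):
        target = small_study.daughter_ids[1]
        out = inject_artifacts(small_study, 0.0, 0.5,
                               target_individuals=[target], seed=3)
        injected = out.truth["injected_mendel"]
        assert len(injected) > 0
        sire = small_study.pedigree.sire_of(target)
        snp_pos = {s: j for j, s in enumerate(out.genotypes.snp_ids)}
        for _, row in injected.iterrows():
            j = snp_pos[row["snp_id"]]
            s_code = out.genotypes.row(sire)[j]
            d_code = out.genotypes.row(target)[j]
            assert s_code in (0, 2) and d_code == 2 - s_code

    def test_bad_rate_rejected(self, small_study):
        with pytest.raises(ValueError):
            inject_artifacts(small_study, 1.5, 0.0)
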