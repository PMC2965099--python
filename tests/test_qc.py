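"""Quality control: metrics, Mendelian screen, staged filters, audit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from daughter_gwas.io_model import MISSING, GenotypeMatrix, Pedigree, SnpRecord
from daughter_gwas.qc import (SNP_CRITERIA, QcReport, QcThresholds,
                              compute_snp_metrics, hwe_exact_p,
                              mendelian_error_rate, run_individual_qc,
                              run_snp_qc)
from daughter_gwas.synthetic_data import (SimulationConfig, inject_artifacts,
                                          simulate_daughter_design)


def _matrix(codes, prefix="i"):
    codes = np.asarray(codes, dtype=np.int8)
    snps = [SnpRecord(f"s{j}", "1", 100 * (j + 1), "A", "B")
            for j in range(codes.shape[1])]
    ids = [f"{prefix}{k}" for k in range(codes.shape[0])]
    return GenotypeMatrix(ids, snps, codes)


class TestSnpMetrics:
    def test_exact_hwe_proportions(self):
        col = np.array([0] * 25 + [1] * 50 + [2] * 25)
        m = compute_snp_metrics(col)
        assert m.call_rate == 1.0
        assert m.maf == pytest.approx(0.5)
        assert m.hwe_p == pytest.approx(1.0)
        assert m.min_genotype_count == 25

    def test_hand_computed_chi2(self):
        # counts (2,2,2): expected (1.5,3,1.5) -> chi2 = 2/3, P ~ 0.414
        m = compute_snp_metrics(np.array([0, 0, 1, 1, 2, 2]))
        assert m.maf == pytest.approx(0.5)
        assert m.hwe_p == pytest.approx(0.4142, abs=2e-4)

    def test_all_missing_flagged_not_raised(self):
        m = compute_snp_metrics(np.full(10, MISSING))
        assert m.call_rate == 0.0
        assert np.isnan(m.maf) and np.isnan(m.hwe_p)

    def test_exact_test_matches_enumeration(self):
        # independent oracle: exact-integer conditional P(n_het | alleles)
        def oracle(n0, n1, n2):
            from math import factorial
            n = n0 + n1 + n2
            nb = 2 * n2 + n1
            rare = min(nb, 2 * n - nb)
            weights = {}
            for h in range(rare % 2, rare + 1, 2):
                hr = (rare - h) // 2
                hc = (2 * n - rare - h) // 2
                weights[h] = (factorial(n) * 2 ** h
                              // (factorial(hr) * factorial(hc)
                                  * factorial(h)))
            total = sum(weights.values())
            obs = weights[n1] / total
            return sum(w / total for w in weights.values()
                       if w / total <= obs * (1 + 1e-12))

        for counts in [(2, 2, 2), (5, 1, 4), (10, 0, 10), (3, 7, 2)]:
            assert hwe_exact_p(*counts) == pytest.approx(
                oracle(*counts), rel=1e-9)


class TestMendelianScreen:
    def test_opposite_homozygotes_counted(self):
        sire = np.array([2, 2, 0, 1, 2])
        dau = np.array([0, 2, 0, 0, MISSING])
        rate, n_inf = mendelian_error_rate(sire, dau, sample_size=100, seed=0)
        # informative loci: 0 (error), 1 (ok), 2 (ok); het sire and
        # missing daughter are not informative
        assert n_inf == 3
        assert rate == pytest.approx(1 / 3)

    def test_201_in_10000_exceeds_threshold(self):
        n = 12_000
        sire = np.full(n, 2, dtype=np.int8)
        dau = np.full(n, 2, dtype=np.int8)
        dau[:250] = 0  # 250 errors among 12,000 informative loci
        rates = [mendelian_error_rate(sire, dau, 10_000, seed=s)[0]
                 for s in range(5)]
        # expectation 250/12000 ~ 0.0208 > 0.02 on every subsample
        assert np.mean(rates) == pytest.approx(250 / 12_000, abs=0.003)

    def test_no_informative_loci(self):
        rate, n_inf = mendelian_error_rate(np.array([1, 1]),
                                           np.array([0, 2]), 10, seed=0)
        assert n_inf == 0 and np.isnan(rate)


class TestIndividualQc:
    def _study(self):
        sire = np.array([[1] * 6 + [2] * 14], dtype=np.int8)
        clean = np.array([1] * 6 + [2] * 14, dtype=np.int8)
        missing = clean.copy()
        missing[:3] = MISSING  # 15% missing
        mendel = clean.copy()
        mendel[6:] = 0  # opposite homozygote at every informative locus
        both = mendel.copy()
        both[:3] = MISSING  # fails both criteria
        codes = np.vstack([sire, clean, missing, mendel, both])
        gm = _matrix(codes)
        ped = Pedigree([("i0", None, None)]
                       + [(f"i{k}", "i0", None) for k in range(1, 5)])
        return gm, ped

    def test_removal_attribution_order(self):
        gm, ped = self._study()
        kept, report = run_individual_qc(gm, ped, QcThresholds(), seed=0)
        assert kept == ["i0", "i1"]
        assert report.removals == {"missingness": 2, "mendelian_error": 1}
        # i4 fails both but the missingness criterion claims it
        assert ("i4", "missingness") in report.removed
        assert report.conserves()

    def test_clean_study_zero_removals(self, small_study):
        kept, report = run_individual_qc(small_study.genotypes,
                                         small_study.pedigree,
                                         QcThresholds(), seed=0)
        assert report.counts_out == report.counts_in
        assert sum(report.removals.values()) == 0

    def test_below_threshold_kept(self):
        # 1.9% Mendelian error rate survives the 2% cut
        n = 1000
        sire = np.full((1, n), 2, dtype=np.int8)
        dau = np.full(n, 2, dtype=np.int8)
        dau[:19] = 0
        gm = _matrix(np.vstack([sire, dau[None, :]]))
        ped = Pedigree([("i0", None, None), ("i1", "i0", None)])
        kept, report = run_individual_qc(gm, ped, QcThresholds(), seed=0)
        assert "i1" in kept


class TestSnpQc:
    def test_sequential_attribution(self):
        n = 1000
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.4, n).astype(np.int8)
        low_call = good.copy()
        low_call[:110] = MISSING          # call rate 0.89 -> filter 1
        mono = np.zeros(n, dtype=np.int8)  # maf 0 -> filter 2
        rare = np.array([0] * 4 + [1] * 300 + [2] * 696, dtype=np.int8)
        codes = np.column_stack([good, low_call, mono, rare])
        gm = _matrix(codes)
        kept, report = run_snp_qc(gm, QcThresholds())
        assert list(kept) == [0]
        reasons = dict(report.removed)
        assert reasons["s1"] == "call_rate"
        assert reasons["s2"] == "maf"
        # (4, 300, 696): maf 0.154, HWE P ~ 1.7e-6 just passes, the
        # 4-individual minor genotype class fails filter 4
        assert reasons["s3"] == "min_genotype_count"
        assert report.conserves()

    def test_marginal_maf_fails(self):
        # maf 0.029 < 0.03
        col = np.array([1] * 29 + [0] * 471, dtype=np.int8)
        m = compute_snp_metrics(col)
        assert m.maf == pytest.approx(0.029)
        kept, report = run_snp_qc(_matrix(col[:, None]), QcThresholds())
        assert kept.size == 0
        assert report.removed[0][1] == "maf"

    @given(order=st.permutations(list(SNP_CRITERIA)),
           seed=st.integers(0, 10_000))
    def test_kept_set_independent_of_filter_order(self, order, seed):
        rng = np.random.default_rng(seed)
        codes = rng.choice([0, 1, 2, MISSING], size=(40, 8),
                           p=[0.3, 0.3, 0.3, 0.1]).astype(np.int8)
        gm = _matrix(codes)
        kept_ref, rep_ref = run_snp_qc(gm, QcThresholds())
        kept_perm, rep_perm = run_snp_qc(gm, QcThresholds(),
                                         filter_order=order)
        assert np.array_equal(kept_ref, kept_perm)
        assert sum(rep_ref.removals.values()) == sum(
            rep_perm.removals.values())
        assert rep_perm.conserves()

    def test_conservation_identity(self, small_study):
        kept, report = run_snp_qc(small_study.genotypes, QcThresholds())
        assert report.counts_in == small_study.genotypes.n_snps
        assert report.counts_in - sum(report.removals.values()) \
            == report.counts_out == kept.size


def test_injected_defects_recovered_exactly():
    """Precision = recall = 1 for unambiguous injected artifacts."""
    cfg = SimulationConfig(n_sires=2, daughters_per_sire=15, n_snps=2000,
                           traits=("MY",), seed=77)
    study = simulate_daughter_design(cfg)
    bad_missing = study.daughter_ids[:2]
    bad_mendel = study.daughter_ids[2:4]
    study = inject_artifacts(study, 0.2, 0.0,
                             target_individuals=bad_missing, seed=1)
    study = inject_artifacts(study, 0.0, 0.1,
                             target_individuals=bad_mendel, seed=2)
    kept, report = run_individual_qc(study.genotypes, study.pedigree,
                                     QcThresholds(), seed=0)
    removed_ids = {iid for iid, _ in report.removed}
    assert removed_ids == set(bad_missing) | set(bad_mendel)
    reasons = dict(report.removed)
    for iid in bad_missing:
        assert reasons[iid] == "missingness"
    for iid in bad_mendel:
        assert reasons[iid] == "mendelian_error"


def test_report_conservation_is_checkable():
    report = QcReport(stage="snp", counts_in=100, counts_out=90,
                      removals={"call_rate": 6, "maf": 4})
    assert report.conserves()
    bad = QcReport(stage="snp", counts_in=100, counts_out=91,
                   removals={"call_rate": 6, "maf": 4})
    assert not bad.conserves()
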