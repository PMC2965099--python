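import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """3 sires x 20 daughters, 200 SNPs, two traits, one planted QTL."""
    from daughter_gwas.synthetic_data import (QtlEffect, SimulationConfig,
                                              simulate_daughter_design)
    cfg = SimulationConfig(
        n_sires=3, daughters_per_sire=20, n_snps=200, traits=("MY", "FP"),
        maf_range=(0.2, 0.5), qtl=(QtlEffect(5, "MY", 1.0),), seed=1234)
    return simulate_daughter_design(cfg)


@pytest.fixture(scope="session")
def null_calibration_scan():
    """Shared full-scale null scan: 14 sires x 150 daughters, >10,000
    tested SNPs, polygenic background, no QTL; both methods' P values.

    Built once because it is by far the most expensive fixture.
    """
    from scipy import stats as sps

    from daughter_gwas.kinship import (build_a_inverse,
                                       build_numerator_relationship)
    from daughter_gwas.l1tdt import scan_l1tdt
    from daughter_gwas.mmra import MmraScanner, estimate_variance_components
    from daughter_gwas.synthetic_data import (SimulationConfig,
                                              simulate_daughter_design)

    cfg = SimulationConfig(n_sires=14, daughters_per_sire=150, n_snps=11_000,
                           traits=("MY",), sigma_a2=0.3, sigma_e2=0.7,
                           seed=20101)
    study = simulate_daughter_design(cfg)
    daughters = study.daughter_ids
    pheno = study.phenotypes.for_trait("MY")
    y = pheno.loc[daughters, "ebv"].to_numpy()
    rel = pheno.loc[daughters, "reliability"].to_numpy()
    a_matrix = build_numerator_relationship(study.pedigree)
    a_inv = build_a_inverse(study.pedigree)
    vc = estimate_variance_components(y, rel, a_matrix, sample_ids=daughters)
    rows = [study.genotypes.row_index(d) for d in daughters]
    codes = study.genotypes.codes[rows]
    scanner = MmraScanner(a_inv, daughters, rel, vc)
    mmra_p = np.array([scanner.fit(y, codes[:, j].astype(float)).raw_p
                       for j in range(codes.shape[1])])
    mmra_chi2 = sps.chi2.isf(mmra_p, df=1)
    l1_results, l1_info = scan_l1tdt(study.genotypes, study.pedigree,
                                     study.phenotypes, "MY")
    l1_p = np.array([r.raw_p for r in l1_results])
    return {"study": study, "vc": vc, "mmra_p": mmra_p,
            "mmra_chi2": mmra_chi2, "l1_p": l1_p, "l1_info": l1_info}
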