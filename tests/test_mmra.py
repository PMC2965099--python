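"""REML variance components and the mixed-model Wald test."""

import numpy as np
import pytest

from daughter_gwas.io_model import MISSING, Pedigree
from daughter_gwas.kinship import (build_a_inverse,
                                   build_numerator_relationship)
from daughter_gwas.mmra import (VarianceComponents,
                                estimate_variance_components, fit_mmra)
from daughter_gwas.synthetic_data import SimulationConfig, \
    simulate_daughter_design


def _random_instance(seed, n_sires=5, n_dau=45):
    rng = np.random.default_rng(seed)
    entries = [(f"S{i}", None, None) for i in range(n_sires)]
    entries += [(f"D{j}", f"S{rng.integers(n_sires)}", None)
                for j in range(n_dau)]
    ped = Pedigree(entries)
    ids = [f"D{j}" for j in range(n_dau)]
    rel = rng.uniform(0.41, 0.71, n_dau)
    y = rng.normal(0, 1, n_dau)
    x = rng.integers(0, 3, n_dau).astype(float)
    return ped, ids, y, x, rel


def _dense_gls(ped, ids, y, x, rel, sigma_a2, sigma_e2):
    """Independent oracle: direct GLS with V = A*sa2 + W*se2."""
    a = build_numerator_relationship(ped)
    add = a.submatrix(ids)
    v = add * sigma_a2 + np.diag(sigma_e2 / rel)
    vi = np.linalg.inv(v)
    design = np.column_stack([np.ones_like(x), x])
    cov = np.linalg.inv(design.T @ vi @ design)
    beta = cov @ design.T @ vi @ y
    return beta[1], cov[1, 1]


class TestRemlOracle:
    def test_grid_search_agreement(self):
        cfg = SimulationConfig(n_sires=8, daughters_per_sire=15, n_snps=2,
                               traits=("MY",), seed=31)
        study = simulate_daughter_design(cfg)
        dau = study.daughter_ids
        ph = study.phenotypes.for_trait("MY")
        y = ph.loc[dau, "ebv"].to_numpy()
        rel = ph.loc[dau, "reliability"].to_numpy()
        a = build_numerator_relationship(study.pedigree)
        vc = estimate_variance_components(y, rel, a, sample_ids=dau)
        kin = a.submatrix(dau)

        def reml_ll(sa2, se2):
            n = y.size
            v = kin * sa2 + np.diag(se2 / rel)
            design = np.ones((n, 1))
            vi = np.linalg.inv(v)
            xvx = design.T @ vi @ design
            beta = np.linalg.solve(xvx, design.T @ vi @ y)
            r = y - design @ beta
            _, ld = np.linalg.slogdet(v)
            _, ld2 = np.linalg.slogdet(xvx)
            return float(-0.5 * ((n - 1) * np.log(2 * np.pi)
                                 + ld + ld2 + r @ vi @ r))

        sa_grid = np.linspace(0.01, 1.5, 60)
        se_grid = np.linspace(0.05, 1.5, 60)
        lls = np.array([[reml_ll(sa, se) for se in se_grid]
                        for sa in sa_grid])
        k = np.unravel_index(np.argmax(lls), lls.shape)
        # profile optimum dominates the whole grid and sits on its argmax
        assert reml_ll(vc.sigma_a2, vc.sigma_e2) >= lls.max() - 1e-6
        assert vc.sigma_a2 == pytest.approx(sa_grid[k[0]],
                                            abs=np.diff(sa_grid)[0])
        assert vc.sigma_e2 == pytest.approx(se_grid[k[1]],
                                            abs=np.diff(se_grid)[0])
        assert vc.log_likelihood == pytest.approx(
            reml_ll(vc.sigma_a2, vc.sigma_e2), abs=1e-6)

    def test_boundary_recovery_when_no_genetics(self):
        medians = []
        for seed in range(6):
            cfg = SimulationConfig(n_sires=8, daughters_per_sire=25,
                                   n_snps=2, traits=("MY",), sigma_a2=0.0,
                                   sigma_e2=1.0, seed=400 + seed)
            study = simulate_daughter_design(cfg)
            dau = study.daughter_ids
            ph = study.phenotypes.for_trait("MY")
            a = build_numerator_relationship(study.pedigree)
            vc = estimate_variance_components(
                ph.loc[dau, "ebv"].to_numpy(),
                ph.loc[dau, "reliability"].to_numpy(), a, sample_ids=dau)
            medians.append(vc.sigma_a2 / vc.sigma_e2)
        assert np.median(medians) < 0.05

    def test_degenerate_reliability_rejected(self):
        ped = Pedigree([("A", None, None), ("B", None, None)])
        a = build_numerator_relationship(ped)
        with pytest.raises(ValueError, match="reliabilit"):
            estimate_variance_components(np.array([1.0, 2.0]),
                                         np.array([0.5, 1.5]), a)


class TestWaldFit:
    def test_closed_form_no_polygenics(self):
        ped = Pedigree([("a", None, None), ("b", None, None),
                        ("c", None, None)])
        ainv = build_a_inverse(ped)
        vc = VarianceComponents(0.0, 1.0, 0.0, 0)
        fit = fit_mmra(np.array([1.0, 2, 2]), np.array([0.0, 1, 2]),
                       np.ones(3), ainv, ["a", "b", "c"], vc)
        assert fit.b == pytest.approx(0.5, abs=1e-12)
        assert fit.var_b == pytest.approx(0.5, abs=1e-12)
        assert fit.wald == pytest.approx(0.5, abs=1e-12)
        assert fit.raw_p == pytest.approx(0.4795, abs=2e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_mme_equals_dense_gls(self, seed):
        ped, ids, y, x, rel = _random_instance(seed)
        ainv = build_a_inverse(ped)
        vc = VarianceComponents(0.3, 0.7, 0.0, 0)
        fit = fit_mmra(y, x, rel, ainv, ids, vc)
        b, var_b = _dense_gls(ped, ids, y, x, rel, 0.3, 0.7)
        assert fit.b == pytest.approx(b, abs=1e-8)
        assert fit.var_b == pytest.approx(var_b, abs=1e-8)

    def test_missing_dosages_dropped(self):
        ped, ids, y, x, rel = _random_instance(11)
        x[::5] = MISSING
        ainv = build_a_inverse(ped)
        vc = VarianceComponents(0.3, 0.7, 0.0, 0)
        fit = fit_mmra(y, x, rel, ainv, ids, vc)
        keep = x != MISSING
        b, var_b = _dense_gls(
            ped, [i for i, k in zip(ids, keep) if k],
            y[keep], x[keep], rel[keep], 0.3, 0.7)
        assert fit.n_used == int(keep.sum())
        assert fit.b == pytest.approx(b, abs=1e-8)
        assert fit.var_b == pytest.approx(var_b, abs=1e-8)

    def test_simple_regression_special_case(self):
        # sigma_a2 = 0, REL == 1: ordinary least squares
        ped, ids, y, x, rel = _random_instance(12)
        ainv = build_a_inverse(ped)
        vc = VarianceComponents(0.0, 2.5, 0.0, 0)
        fit = fit_mmra(y, x, np.ones_like(rel), ainv, ids, vc)
        design = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        cov = 2.5 * np.linalg.inv(design.T @ design)
        assert fit.b == pytest.approx(beta[1], rel=1e-12)
        assert fit.var_b == pytest.approx(cov[1, 1], rel=1e-12)

    def test_monomorphic_contract(self):
        ped, ids, y, x, rel = _random_instance(13)
        ainv = build_a_inverse(ped)
        vc = VarianceComponents(0.3, 0.7, 0.0, 0)
        fit = fit_mmra(y, np.full_like(x, 2.0), rel, ainv, ids, vc)
        assert fit.raw_p == 1.0


def test_polygenic_term_absorbs_family_structure():
    """Dropping the polygenic term on a structured null inflates the
    median Wald statistic; keeping it does not (the quantitative content
    of the Q-Q stratification diagnostic)."""
    from scipy import stats

    from daughter_gwas.mmra import MmraScanner
    cfg = SimulationConfig(n_sires=14, daughters_per_sire=60, n_snps=600,
                           traits=("MY",), sigma_a2=0.5, sigma_e2=0.5,
                           seed=55)
    study = simulate_daughter_design(cfg)
    dau = study.daughter_ids
    ph = study.phenotypes.for_trait("MY")
    y = ph.loc[dau, "ebv"].to_numpy()
    rel = ph.loc[dau, "reliability"].to_numpy()
    a = build_numerator_relationship(study.pedigree)
    ainv = build_a_inverse(study.pedigree)
    vc = estimate_variance_components(y, rel, a, sample_ids=dau)
    rows = [study.genotypes.row_index(d) for d in dau]
    codes = study.genotypes.codes[rows]

    scanner = MmraScanner(ainv, dau, rel, vc)
    with_poly = np.array(
        [scanner.fit(y, codes[:, j].astype(float)).wald
         for j in range(codes.shape[1])])
    vc_null = VarianceComponents(0.0, vc.sigma_e2, 0.0, 0)
    without_poly = np.array(
        [fit_mmra(y, codes[:, j].astype(float), rel, ainv, dau,
                  vc_null).wald for j in range(codes.shape[1])])
    median_chi2 = stats.chi2.ppf(0.5, df=1)
    assert np.median(without_poly) > median_chi2 * 1.3
    assert np.median(with_poly) == pytest.approx(median_chi2, rel=0.25)
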