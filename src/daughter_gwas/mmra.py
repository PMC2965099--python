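"""Mixed-model single-SNP regression association (MMRA).

For each SNP the daughters' EBVs are modeled as

    y = 1*mu + x*b + Z*a + e,
    a ~ N(0, A * sigma_a2),    e ~ N(0, W * sigma_e2),

where ``x`` is the allele-b dosage (0/1/2), ``a`` the residual polygenic
effects over the pedigree with numerator relationship matrix ``A``, and
``W = diag(1/REL)`` so low-reliability EBVs carry larger residual
variance.  The SNP effect ``b`` and its sampling variance come from
Henderson's mixed model equations with the polygenic block absorbed;
the test statistic is the Wald chi-square ``b^2 / var(b)`` on 1 df.

Variance components are estimated once by REML under the null
(no-SNP) model and reused across the scan.  The restricted likelihood
is profiled exactly on the eigendecomposition of the reliability-scaled
relationship matrix, reducing REML to a one-dimensional search in the
variance ratio ``gamma = sigma_a2 / sigma_e2``; a ``per_snp_reml`` flag
re-estimates under each SNP's null subset instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, sparse, stats
from scipy.sparse.linalg import splu

from .inference import bonferroni
from .io_model import (MISSING, METHOD_MMRA, AssociationResult,
                       GenotypeMatrix, Pedigree, PhenotypeTable)
from .kinship import RelationshipMatrix, build_numerator_relationship, \
    build_a_inverse

__all__ = ["VarianceComponents", "MmraFit", "estimate_variance_components",
           "fit_mmra", "MmraScanner", "scan_mmra"]

_TINY_P = float(np.finfo(float).tiny)


@dataclass
class VarianceComponents:
    """REML estimates of the polygenic and residual variances."""

    sigma_a2: float
    sigma_e2: float
    log_likelihood: float
    n_iterations: int
    converged: bool = True

    @property
    def lam(self) -> float:
        """Henderson's ratio sigma_e2 / sigma_a2 (inf at the boundary)."""
        if self.sigma_a2 <= 0.0:
            return float("inf")
        return self.sigma_e2 / self.sigma_a2


@dataclass
class MmraFit:
    """One SNP's mixed-model regression test."""

    b: float
    var_b: float
    wald: float
    raw_p: float
    n_used: int


def _reml_profile(y: np.ndarray, rel: np.ndarray, kin: np.ndarray
                  ) -> tuple[float, float, float, int, bool]:
    """Profile REML for y = 1*mu + a + e on the spectral scale.

    Returns (sigma_a2, sigma_e2, restricted log-likelihood, n_evals,
    converged).  ``kin`` is the relationship matrix restricted to the
    phenotyped individuals (same order as y).
    """
    n = y.size
    s = np.sqrt(rel)                      # W^{-1/2}, W = diag(1/rel)
    k_tilde = kin * np.outer(s, s)
    evals, evecs = np.linalg.eigh(k_tilde)
    evals = np.clip(evals, 0.0, None)
    y_star = evecs.T @ (s * y)
    x_star = evecs.T @ s                  # intercept column, scaled
    p = 1

    def neg_restricted_ll(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        v = 1.0 + gamma * evals
        xtvx = np.sum(x_star ** 2 / v)
        beta = np.sum(x_star * y_star / v) / xtvx
        resid = y_star - x_star * beta
        quad = np.sum(resid ** 2 / v)
        sigma_e2 = quad / (n - p)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + (n - p)
                     + (n - p) * np.log(sigma_e2) + np.sum(np.log(v))
                     + np.log(xtvx))
        return -ll

    # coarse bracket on log-gamma, then Brent refinement
    grid = np.linspace(-12.0, 12.0, 49)
    values = np.array([neg_restricted_ll(g) for g in grid])
    k = int(np.argmin(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    result = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10})
    n_evals = int(result.nfev) + grid.size
    best_log_gamma = float(result.x)
    best_nll = float(result.fun)
    converged = bool(result.success)

    # boundary check: sigma_a2 = 0 (gamma -> 0)
    boundary_nll = neg_restricted_ll(-40.0)
    if boundary_nll <= best_nll:
        gamma = 0.0
        best_nll = boundary_nll
    else:
        gamma = float(np.exp(best_log_gamma))
    v = 1.0 + gamma * evals
    xtvx = np.sum(x_star ** 2 / v)
    beta = np.sum(x_star * y_star / v) / xtvx
    quad = np.sum((y_star - x_star * beta) ** 2 / v)
    sigma_e2 = float(quad / (n - p))
    sigma_a2 = float(gamma * sigma_e2)
    if sigma_e2 <= 0.0:
        raise ValueError("degenerate REML likelihood: sigma_e2 -> 0")
    # undo the W^{-1/2} data transform (Jacobian) so the value reported
    # is the restricted log-likelihood of the original observations
    ll = float(-best_nll + 0.5 * np.sum(np.log(rel)))
    return sigma_a2, sigma_e2, ll, n_evals, converged


def estimate_variance_components(y: np.ndarray,
                                 rel: np.ndarray,
                                 relationship: RelationshipMatrix,
                                 sample_ids: Sequence[str] | None = None
                                 ) -> VarianceComponents:
    """REML variance components under the null model y = 1*mu + a + e.

    ``relationship`` is the numerator relationship matrix A; if
    ``sample_ids`` is given, A is restricted to those individuals in
    that order (they must index both y and rel).  Estimates are clamped
    at the sigma_a2 >= 0 boundary.
    """
    y = np.asarray(y, dtype=float)
    rel = np.asarray(rel, dtype=float)
    if y.shape != rel.shape:
        raise ValueError("y and rel lengths differ")
    if np.any(rel <= 0) or np.any(rel > 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    kin = (relationship.submatrix(list(sample_ids))
           if sample_ids is not None else relationship.dense())
    if kin.shape[0] != y.size:
        raise ValueError("relationship matrix does not match y")
    sigma_a2, sigma_e2, ll, n_iter, converged = _reml_profile(y, rel, kin)
    return VarianceComponents(sigma_a2=sigma_a2, sigma_e2=sigma_e2,
                              log_likelihood=ll, n_iterations=n_iter,
                              converged=converged)


def _wls_fit(y: np.ndarray, x: np.ndarray, rel: np.ndarray,
             sigma_e2: float) -> tuple[float, float]:
    """No-polygenic-term special case: weighted least squares."""
    w = rel
    design = np.column_stack([np.ones_like(x), x])
    xtwx = (design * w[:, None]).T @ design
    xtwy = (design * w[:, None]).T @ y
    coef = np.linalg.solve(xtwx, xtwy)
    cov = sigma_e2 * np.linalg.inv(xtwx)
    return float(coef[1]), float(cov[1, 1])


def fit_mmra(y: np.ndarray,
             x: np.ndarray,
             rel: np.ndarray,
             a_inverse: RelationshipMatrix,
             sample_ids: Sequence[str],
             vc: VarianceComponents) -> MmraFit:
    """Wald test of one SNP through the mixed model equations.

    ``sample_ids`` maps each element of y to its row in ``a_inverse``.
    Daughters with a missing dosage are dropped for this SNP; a dosage
    monomorphic among the remaining daughters leaves the test undefined
    and the contract value ``raw_p = 1`` is recorded.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    rel = np.asarray(rel, dtype=float)
    keep = x != MISSING
    y, x, rel = y[keep], x[keep], rel[keep]
    ids = [i for i, k in zip(sample_ids, keep) if k]
    n_used = int(y.size)
    if n_used == 0 or np.unique(x).size < 2:
        return MmraFit(b=0.0, var_b=float("nan"), wald=0.0, raw_p=1.0,
                       n_used=n_used)
    if vc.sigma_a2 <= 0.0:
        b, var_b = _wls_fit(y, x, rel, vc.sigma_e2)
    else:
        scanner = MmraScanner(a_inverse, ids, rel, vc)
        b, var_b = scanner._solve_one(y, x)
    if var_b <= 0 or not np.isfinite(var_b):
        return MmraFit(b=b, var_b=var_b, wald=0.0, raw_p=1.0, n_used=n_used)
    wald = b * b / var_b
    raw_p = max(float(stats.chi2.sf(wald, df=1)), _TINY_P)
    return MmraFit(b=b, var_b=var_b, wald=wald, raw_p=raw_p, n_used=n_used)


class MmraScanner:
    """Cached mixed-model-equation machinery for scanning many SNPs.

    The random-effect block ``Z' W^{-1} Z + lambda * A^{-1}`` does not
    depend on the SNP, so its sparse LU factorization is computed once
    and reused; each SNP then costs two sparse triangular solves.
    """

    def __init__(self,
                 a_inverse: RelationshipMatrix,
                 sample_ids: Sequence[str],
                 rel: np.ndarray,
                 vc: VarianceComponents) -> None:
        if vc.sigma_a2 <= 0.0:
            raise ValueError("MmraScanner requires sigma_a2 > 0; "
                             "use the WLS path otherwise")
        self.vc = vc
        self.rel = np.asarray(rel, dtype=float)
        self.sample_ids = list(sample_ids)
        lookup = {iid: k for k, iid in enumerate(a_inverse.ids)}
        self.z_index = np.array([lookup[i] for i in self.sample_ids], int)
        q = len(a_inverse.ids)
        ztrz = sparse.coo_matrix(
            (self.rel, (self.z_index, self.z_index)), shape=(q, q)).tocsc()
        self._a_inv_csc = sparse.csc_matrix(a_inverse.values)
        m = (ztrz + vc.lam * self._a_inv_csc).tocsc()
        self._factor = splu(m)
        self._q = q

    def _ztr(self, vec: np.ndarray) -> np.ndarray:
        out = np.zeros(self._q)
        np.add.at(out, self.z_index, self.rel * vec)
        return out

    def _solve_one(self, y: np.ndarray, x: np.ndarray
                   ) -> tuple[float, float]:
        """Absorbed-MME solution: returns (b_hat, var_b)."""
        w = self.rel
        ones = np.ones_like(x)
        design = np.column_stack([ones, x])           # X
        ztrx = np.column_stack([self._ztr(ones), self._ztr(x)])
        m_inv_ztrx = self._factor.solve(ztrx)
        xtwx = (design * w[:, None]).T @ design
        s = xtwx - ztrx.T @ m_inv_ztrx                # absorbed fixed block
        ztry = self._ztr(y)
        xtwy = (design * w[:, None]).T @ y
        c = xtwy - ztrx.T @ self._factor.solve(ztry)
        s_inv = np.linalg.inv(s)
        beta = s_inv @ c
        var_b = self.vc.sigma_e2 * s_inv[1, 1]
        return float(beta[1]), float(var_b)

    def fit(self, y: np.ndarray, x: np.ndarray) -> MmraFit:
        x = np.asarray(x, dtype=float)
        if np.any(x == MISSING) :
            # subset changes the random-effect block; rebuild for this SNP
            keep = x != MISSING
            ids = [i for i, k in zip(self.sample_ids, keep) if k]
            sub = MmraScanner.__new__(MmraScanner)
            sub.vc = self.vc
            sub.rel = self.rel[keep]
            sub.sample_ids = ids
            sub.z_index = self.z_index[keep]
            q = self._q
            ztrz = sparse.coo_matrix(
                (sub.rel, (sub.z_index, sub.z_index)), shape=(q, q)).tocsc()
            m = (ztrz + self.vc.lam * self._a_inv_csc).tocsc()
            sub._factor = splu(m)
            sub._q = q
            sub._a_inv_csc = self._a_inv_csc
            y, x = np.asarray(y, float)[keep], x[keep]
            scanner = sub
        else:
            y = np.asarray(y, float)
            scanner = self
        n_used = int(y.size)
        if np.unique(x).size < 2:
            return MmraFit(b=0.0, var_b=float("nan"), wald=0.0, raw_p=1.0,
                           n_used=n_used)
        b, var_b = scanner._solve_one(y, x)
        if var_b <= 0 or not np.isfinite(var_b):
            return MmraFit(b=b, var_b=var_b, wald=0.0, raw_p=1.0,
                           n_used=n_used)
        wald = b * b / var_b
        raw_p = max(float(stats.chi2.sf(wald, df=1)), _TINY_P)
        return MmraFit(b=b, var_b=var_b, wald=wald, raw_p=raw_p,
                       n_used=n_used)


def scan_mmra(genotypes: GenotypeMatrix,
              pedigree: Pedigree,
              phenotypes: PhenotypeTable,
              trait: str,
              vc: VarianceComponents | None = None,
              per_snp_reml: bool = False,
              alpha: float = 0.05
              ) -> tuple[list[AssociationResult], VarianceComponents, dict]:
    """Run the mixed-model regression across a panel for one trait.

    Variance components are REML-estimated once under the null model
    (unless supplied, or ``per_snp_reml`` requests re-estimation on each
    SNP's complete-dosage subset).  Raw P values are Bonferroni-adjusted
    with N = number of SNPs tested.
    """
    pheno = phenotypes.for_trait(trait)
    daughters = [i for i in genotypes.individual_ids
                 if i in pedigree and pedigree.sire_of(i) is not None
                 and i in pheno.index]
    if not daughters:
        raise ValueError(f"no phenotyped, genotyped daughters for {trait!r}")
    y = pheno.loc[daughters, "ebv"].to_numpy()
    rel = pheno.loc[daughters, "reliability"].to_numpy()

    a_matrix = build_numerator_relationship(pedigree)
    a_inv = build_a_inverse(pedigree)
    if vc is None:
        vc = estimate_variance_components(y, rel, a_matrix,
                                          sample_ids=daughters)

    d_rows = np.array([genotypes.row_index(i) for i in daughters], int)
    codes = genotypes.codes[d_rows]
    n_tests = genotypes.n_snps
    results = []
    if vc.sigma_a2 > 0 and not per_snp_reml:
        scanner = MmraScanner(a_inv, daughters, rel, vc)
        fits = [scanner.fit(y, codes[:, j].astype(float))
                for j in range(n_tests)]
    else:
        fits = []
        for j in range(n_tests):
            x = codes[:, j].astype(float)
            vc_j = vc
            if per_snp_reml:
                keep = x != MISSING
                ids_j = [i for i, k in zip(daughters, keep) if k]
                vc_j = estimate_variance_components(
                    y[keep], rel[keep], a_matrix, sample_ids=ids_j)
            fits.append(fit_mmra(y, x, rel, a_inv, daughters, vc_j))
    for j, fit in enumerate(fits):
        adj, _, _ = bonferroni(fit.raw_p, n_tests, alpha)
        results.append(AssociationResult(
            snp_id=genotypes.snps[j].snp_id, trait=trait,
            method=METHOD_MMRA, effect_estimate=fit.b,
            standard_error=float(np.sqrt(fit.var_b))
            if fit.var_b > 0 else float("nan"),
            statistic=fit.wald, raw_p=fit.raw_p, adjusted_p=adj,
            n_used=fit.n_used))
    info = {"n_tested": n_tests, "n_daughters": len(daughters),
            "trait": trait, "sigma_a2": vc.sigma_a2,
            "sigma_e2": vc.sigma_e2}
    return results, vc, info
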