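"""Single-parent transmission-disequilibrium regression (L1-TDT).

For each SNP, each daughter receives a transmission indicator TDS in
{-1, 0, +1} describing which paternal allele she inherited.  With only
the sire genotyped, Mendelian logic forces the score exactly when the
sire is heterozygous and the daughter homozygous:

* sire Aa, daughter bb  -> +1  (the sire must have transmitted b)
* sire Aa, daughter aa  -> -1
* sire Aa, daughter ab  ->  0  (ambiguous without the dam's genotype)
* sire homozygous       ->  0  (uninformative)
* daughter missing      ->  excluded from that SNP's regression

The daughter's EBV is then regressed on the indicator with the sire as a
fixed factor,

    y_ij = mu + s_i + beta * TDS_ij + e_ij,

by weighted least squares, and the SNP effect beta is tested with an
F(1, n - rank) test.  SNPs at which no sire is heterozygous carry no
transmission information and are excluded from the scan up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .inference import bonferroni
from .io_model import (MISSING, METHOD_L1TDT, AssociationResult,
                       GenotypeMatrix, Pedigree, PhenotypeTable)

__all__ = ["EXCLUDED", "TdsMatrix", "L1tdtFit", "determine_tds",
           "build_tds_matrix", "exclude_uninformative_snps", "fit_l1tdt",
           "scan_l1tdt"]

#: Return value of :func:`determine_tds` for a missing daughter genotype.
EXCLUDED = "excluded"

_TINY_P = float(np.finfo(float).tiny)


def determine_tds(sire_code: int, daughter_code: int) -> int | str:
    """Score one sire-daughter genotype pair; see the module docstring.

    The mapping for ambiguous heterozygous daughters (scored 0) is the
    conservative default; ``build_tds_matrix`` accepts a custom rule for
    experimentation.
    """
    if daughter_code == MISSING:
        return EXCLUDED
    if sire_code != 1:
        return 0
    if daughter_code == 2:
        return +1
    if daughter_code == 0:
        return -1
    return 0


@dataclass
class TdsMatrix:
    """Daughters x SNPs transmission scores with an exclusion mask.

    ``values`` holds {-1, 0, +1} (0 where excluded); ``excluded`` marks
    daughter-SNP cells dropped from that SNP's regression (missing
    daughter genotype).
    """

    daughter_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray  # int8
    excluded: np.ndarray  # bool


def build_tds_matrix(genotypes: GenotypeMatrix,
                     pedigree: Pedigree,
                     daughter_ids: Sequence[str] | None = None,
                     rule: Callable[[int, int], int | str] | None = None
                     ) -> TdsMatrix:
    """Vectorized TDS scores for every daughter against her own sire.

    A sire genotype that is itself missing at a SNP scores 0 for his
    daughters (no transmission information, like a homozygous sire).
    """
    if daughter_ids is None:
        daughter_ids = [i for i in genotypes.individual_ids
                        if i in pedigree and pedigree.sire_of(i) is not None]
    daughter_ids = list(daughter_ids)
    d_rows = np.array([genotypes.row_index(i) for i in daughter_ids], int)
    s_rows = np.array([genotypes.row_index(pedigree.sire_of(i))
                       for i in daughter_ids], int)
    dau = genotypes.codes[d_rows]
    sire = genotypes.codes[s_rows]
    excluded = dau == MISSING
    if rule is not None:
        values = np.zeros(dau.shape, dtype=np.int8)
        it = np.nditer(dau, flags=["multi_index"])
        for cell in it:
            i, j = it.multi_index
            score = rule(int(sire[i, j]), int(cell))
            values[i, j] = 0 if score == EXCLUDED else score
    else:
        values = np.zeros(dau.shape, dtype=np.int8)
        het = sire == 1
        values[het & (dau == 2)] = 1
        values[het & (dau == 0)] = -1
        values[excluded] = 0
    return TdsMatrix(daughter_ids, genotypes.snp_ids, values, excluded)


def exclude_uninformative_snps(genotypes: GenotypeMatrix,
                               sire_ids: Sequence[str]
                               ) -> tuple[np.ndarray, int]:
    """Keep SNPs at which at least one sire is (called) heterozygous."""
    rows = np.array([genotypes.row_index(s) for s in sire_ids], int)
    informative = (genotypes.codes[rows] == 1).any(axis=0)
    kept = np.flatnonzero(informative)
    return kept, int(genotypes.n_snps - kept.size)


@dataclass
class L1tdtFit:
    """One SNP's weighted least-squares transmission test."""

    beta: float
    se: float
    f_statistic: float
    df1: int
    df2: int
    raw_p: float
    n_informative: int
    n_used: int
    intercept: float
    sire_effects: dict[str, float]


def fit_l1tdt(y: np.ndarray,
              rel: np.ndarray,
              family: Sequence[str] | np.ndarray,
              tds: np.ndarray,
              excluded: np.ndarray | None = None,
              weight_mode: str = "reliability") -> L1tdtFit:
    """Weighted least squares of EBV on {intercept, sire factors, TDS}.

    ``weight_mode="reliability"`` uses weights equal to REL, matching a
    residual variance proportional to 1/REL (the same residual model the
    mixed-model analysis assumes); ``"literal"`` uses weights 1/REL.
    Daughters with an excluded (missing-genotype) cell are dropped;
    daughters with TDS = 0 are retained -- they still inform the mean
    and the sire effects.  With no nonzero TDS at all the test is
    undefined and the contract value ``raw_p = 1`` is recorded.
    """
    y = np.asarray(y, dtype=float)
    rel = np.asarray(rel, dtype=float)
    family = np.asarray(family)
    tds = np.asarray(tds, dtype=float)
    keep = np.ones(y.size, dtype=bool) if excluded is None else ~np.asarray(
        excluded, dtype=bool)
    y, rel, family, tds = y[keep], rel[keep], family[keep], tds[keep]
    n_used = int(y.size)
    n_informative = int(np.count_nonzero(tds))

    if weight_mode == "reliability":
        w = rel
    elif weight_mode == "literal":
        w = 1.0 / rel
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    fams, fam_codes = np.unique(family, return_inverse=True)
    if n_informative == 0 or n_used < 3:
        return L1tdtFit(beta=0.0, se=float("nan"), f_statistic=0.0,
                        df1=1, df2=max(n_used - len(fams) - 1, 0),
                        raw_p=1.0, n_informative=n_informative,
                        n_used=n_used, intercept=float("nan"),
                        sire_effects={})

    # design: intercept, sire dummies (first family as baseline), tds
    n_fam = len(fams)
    design = np.zeros((n_used, 1 + (n_fam - 1) + 1))
    design[:, 0] = 1.0
    for k in range(1, n_fam):
        design[fam_codes == k, k] = 1.0
    design[:, -1] = tds

    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y * sw,
                                       rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient L1-TDT design; aliased columns "
                      "resolved by the minimum-norm solution", stacklevel=2)
    fitted = design @ coef
    rss = float(np.sum(w * (y - fitted) ** 2))
    df2 = n_used - int(rank)
    if df2 <= 0:
        return L1tdtFit(beta=float(coef[-1]), se=float("nan"),
                        f_statistic=0.0, df1=1, df2=0, raw_p=1.0,
                        n_informative=n_informative, n_used=n_used,
                        intercept=float(coef[0]),
                        sire_effects={})
    sigma2 = rss / df2
    xtwx_inv = np.linalg.pinv((design * w[:, None]).T @ design)
    var_beta = sigma2 * xtwx_inv[-1, -1]
    beta = float(coef[-1])
    if var_beta <= 0:
        f_stat, raw_p, se = 0.0, 1.0, float("nan")
    else:
        se = float(np.sqrt(var_beta))
        f_stat = (beta / se) ** 2
        raw_p = max(float(stats.f.sf(f_stat, 1, df2)), _TINY_P)
    sire_effects = {str(fams[0]): float(coef[0])}
    for k in range(1, n_fam):
        sire_effects[str(fams[k])] = float(coef[0] + coef[k])
    return L1tdtFit(beta=beta, se=se, f_statistic=float(f_stat), df1=1,
                    df2=df2, raw_p=raw_p, n_informative=n_informative,
                    n_used=n_used, intercept=float(coef[0]),
                    sire_effects=sire_effects)


def scan_l1tdt(genotypes: GenotypeMatrix,
               pedigree: Pedigree,
               phenotypes: PhenotypeTable,
               trait: str,
               weight_mode: str = "reliability",
               alpha: float = 0.05
               ) -> tuple[list[AssociationResult], dict]:
    """Run the transmission test across a panel for one trait.

    Uninformative SNPs (no heterozygous sire) are excluded first, as in
    the design's QC; raw P values are Bonferroni-adjusted with N equal
    to the number of SNPs actually tested.  Returns the results plus a
    scan-info dict (tested/excluded counts).
    """
    pheno = phenotypes.for_trait(trait)
    daughters = [i for i in genotypes.individual_ids
                 if i in pedigree and pedigree.sire_of(i) is not None
                 and i in pheno.index]
    if not daughters:
        raise ValueError(f"no phenotyped, genotyped daughters for {trait!r}")
    sires = sorted({pedigree.sire_of(d) for d in daughters})
    kept, n_excluded = exclude_uninformative_snps(genotypes, sires)
    tds = build_tds_matrix(genotypes, pedigree, daughter_ids=daughters)
    y = pheno.loc[daughters, "ebv"].to_numpy()
    rel = pheno.loc[daughters, "reliability"].to_numpy()
    family = np.array([pedigree.sire_of(d) for d in daughters])

    n_tests = int(kept.size)
    results = []
    for j in kept:
        fit = fit_l1tdt(y, rel, family, tds.values[:, j],
                        excluded=tds.excluded[:, j],
                        weight_mode=weight_mode)
        adj, _, _ = bonferroni(fit.raw_p, n_tests, alpha)
        results.append(AssociationResult(
            snp_id=genotypes.snps[j].snp_id, trait=trait,
            method=METHOD_L1TDT, effect_estimate=fit.beta,
            standard_error=fit.se, statistic=fit.f_statistic,
            raw_p=fit.raw_p, adjusted_p=adj, n_used=fit.n_used))
    info = {"n_tested": n_tests, "n_excluded_uninformative": n_excluded,
            "n_daughters": len(daughters), "trait": trait,
            "weight_mode": weight_mode}
    return results, info
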