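"""Two-stage genotype quality control for the daughter design.

Stage 1 excludes daughters (never sires): first any daughter with more
than 10% missing genotypes, then any daughter whose Mendelian error rate
against her sire exceeds 2%.  The Mendelian rate is measured on a random
sample of up to 10,000 loci at which sire and daughter are both
homozygous and called; opposite homozygotes at such a locus are
impossible under Mendelian transmission when the dam is unobserved.

Stage 2 removes SNPs by four filters applied in a fixed order -- call
rate < 90%, MAF < 3%, Hardy-Weinberg equilibrium P < 1e-6, minor
genotype class observed in fewer than 5 individuals -- with each SNP
attributed to the first filter it fails.  SNP metrics are computed on
the individuals kept by stage 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import MISSING, DataFormatError, GenotypeMatrix, Pedigree

__all__ = ["QcThresholds", "QcReport", "SnpMetrics", "compute_snp_metrics",
           "hwe_chi2_p", "hwe_exact_p", "mendelian_error_rate",
           "run_individual_qc", "run_snp_qc",
           "INDIVIDUAL_CRITERIA", "SNP_CRITERIA"]

INDIVIDUAL_CRITERIA = ("missingness", "mendelian_error")
SNP_CRITERIA = ("call_rate", "maf", "hwe", "min_genotype_count")


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds; defaults are the classical 50K-chip settings."""

    ind_missing_max: float = 0.10
    mendel_rate_max: float = 0.02
    mendel_sample_size: int = 10_000
    snp_call_min: float = 0.90
    maf_min: float = 0.03
    hwe_p_min: float = 1e-6
    min_genotype_count: int = 5
    hwe_test: str = "chi2"  # "chi2" (Pearson 1 df) or "exact"

    def __post_init__(self) -> None:
        for name, lo, hi in (("ind_missing_max", 0, 1),
                             ("mendel_rate_max", 0, 1),
                             ("snp_call_min", 0, 1),
                             ("maf_min", 0, 0.5),
                             ("hwe_p_min", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.mendel_sample_size < 1 or self.min_genotype_count < 0:
            raise ValueError("invalid count threshold")
        if self.hwe_test not in ("chi2", "exact"):
            raise ValueError(f"unknown hwe_test {self.hwe_test!r}")


@dataclass
class QcReport:
    """Audit record of one QC stage.

    ``counts_in`` minus the per-criterion removal counts must equal
    ``counts_out`` (checked by :meth:`conserves`); ``removed`` itemizes
    every excluded identifier with the criterion that claimed it, in
    removal order.  ``flagged`` lists identifiers needing manual review
    (e.g. a daughter with zero informative Mendelian loci), which are
    kept, not removed.
    """

    stage: str
    counts_in: int
    counts_out: int
    removals: dict[str, int]
    removed: list[tuple[str, str]] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    def conserves(self) -> bool:
        return self.counts_in - sum(self.removals.values()) == self.counts_out

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.stage, crit, n) for crit, n in self.removals.items()]
        rows.append((self.stage, "kept", self.counts_out))
        return pd.DataFrame(rows, columns=["stage", "criterion", "count"])

    def summary(self) -> str:
        lines = [f"[{self.stage}] in: {self.counts_in}"]
        for crit, n in self.removals.items():
            lines.append(f"[{self.stage}] removed ({crit}): {n}")
        lines.append(f"[{self.stage}] out: {self.counts_out}")
        if self.flagged:
            lines.append(f"[{self.stage}] flagged for review: "
                         + ", ".join(self.flagged))
        return "\n".join(lines)


class SnpMetrics(NamedTuple):
    call_rate: float
    maf: float
    hwe_p: float
    min_genotype_count: int
    genotype_counts: tuple[int, int, int]


def hwe_chi2_p(n0: int, n1: int, n2: int) -> float:
    """Pearson 1-df chi-square HWE P from genotype class counts.

    Expected counts come from the sample allele-b frequency; no
    continuity correction.  Monomorphic columns return P = 1.
    """
    n = n0 + n1 + n2
    if n == 0:
        return float("nan")
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n0, n1, n2], dtype=float)
    mask = expected > 0
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2
                        / expected[mask]))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test: sum of heterozygote-count probabilities no larger
    than the observed one, conditional on the allele counts."""
    n = n0 + n1 + n2
    if n == 0:
        return float("nan")
    nb = 2 * n2 + n1  # copies of allele b
    na = 2 * n0 + n1
    rare = min(na, nb)
    # log-probability of each feasible heterozygote count
    hets = [h for h in range(rare % 2, rare + 1, 2)]
    logp = []
    for h in hets:
        hom_rare = (rare - h) // 2
        hom_common = (max(na, nb) - h) // 2
        lp = (math.lgamma(n + 1)
              - math.lgamma(hom_rare + 1) - math.lgamma(hom_common + 1)
              - math.lgamma(h + 1)
              + h * math.log(2)
              + math.lgamma(na + 1) + math.lgamma(nb + 1)
              - math.lgamma(2 * n + 1))
        logp.append(lp)
    logp = np.array(logp)
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets.index(n1)]
    return float(prob[prob <= obs * (1 + 1e-12)].sum())


def compute_snp_metrics(column: np.ndarray,
                        hwe_test: str = "chi2") -> SnpMetrics:
    """Per-SNP QC metrics from one genotype-code column.

    An all-missing column yields call_rate 0 and NaN MAF/HWE -- the SNP
    is flagged for removal by the call-rate filter, not an exception.
    """
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty genotype column")
    n0 = int(np.sum(column == 0))
    n1 = int(np.sum(column == 1))
    n2 = int(np.sum(column == 2))
    n = n0 + n1 + n2
    call_rate = n / column.size
    if n == 0:
        return SnpMetrics(0.0, float("nan"), float("nan"), 0, (0, 0, 0))
    p = (2 * n2 + n1) / (2 * n)
    maf = min(p, 1.0 - p)
    hwe_p = (hwe_exact_p if hwe_test == "exact" else hwe_chi2_p)(n0, n1, n2)
    return SnpMetrics(call_rate, maf, hwe_p, min(n0, n1, n2), (n0, n1, n2))


def mendelian_error_rate(sire_column: np.ndarray,
                         daughter_column: np.ndarray,
                         sample_size: int = 10_000,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None
                         ) -> tuple[float, int]:
    """Opposite-homozygote rate on a random sample of informative loci.

    Informative loci are those where sire and daughter are both called
    homozygous.  Up to ``sample_size`` of them are drawn uniformly
    without replacement (all, if fewer exist).  Returns ``(rate,
    n_informative)``; with zero informative loci the rate is NaN.
    """
    sire_column = np.asarray(sire_column)
    daughter_column = np.asarray(daughter_column)
    if sire_column.shape != daughter_column.shape:
        raise ValueError("sire and daughter columns are not aligned")
    hom = np.isin(sire_column, (0, 2)) & np.isin(daughter_column, (0, 2))
    informative = np.flatnonzero(hom)
    n_informative = informative.size
    if n_informative == 0:
        return float("nan"), 0
    if rng is None:
        rng = np.random.default_rng(seed)
    k = min(sample_size, n_informative)
    chosen = rng.choice(informative, size=k, replace=False)
    errors = int(np.sum(sire_column[chosen] != daughter_column[chosen]))
    return errors / k, n_informative


def run_individual_qc(genotypes: GenotypeMatrix,
                      pedigree: Pedigree,
                      thresholds: QcThresholds = QcThresholds(),
                      seed: int = 0) -> tuple[list[str], QcReport]:
    """Exclude daughters by missingness, then by Mendelian error rate.

    A daughter failing both criteria is counted under missingness (the
    Mendelian screen is never evaluated for her).  Sires are exempt:
    removing one would orphan a whole half-sib family.  Returns the kept
    individual ids (sires first, then surviving daughters in file order)
    and the stage report, whose counts cover daughters only.
    """
    daughters = []
    sires_in_matrix = []
    for iid in genotypes.individual_ids:
        if iid not in pedigree:
            raise DataFormatError(f"genotyped individual {iid} not in pedigree")
        sire = pedigree.sire_of(iid)
        if sire is None:
            sires_in_matrix.append(iid)
        else:
            if sire not in genotypes._row_index:
                raise DataFormatError(
                    f"daughter {iid}: sire {sire} is not genotyped")
            daughters.append(iid)

    removed: list[tuple[str, str]] = []
    flagged: list[str] = []
    kept_daughters: list[str] = []
    removals = {crit: 0 for crit in INDIVIDUAL_CRITERIA}
    for j, iid in enumerate(daughters):
        row = genotypes.row(iid)
        miss_frac = float(np.mean(row == MISSING))
        if miss_frac > thresholds.ind_missing_max:
            removed.append((iid, "missingness"))
            removals["missingness"] += 1
            continue
        sire_row = genotypes.row(pedigree.sire_of(iid))
        rate, n_inf = mendelian_error_rate(
            sire_row, row, thresholds.mendel_sample_size,
            rng=np.random.default_rng([seed, j]))
        if n_inf == 0:
            flagged.append(iid)  # undefined rate: keep, ask for review
            kept_daughters.append(iid)
            continue
        if rate > thresholds.mendel_rate_max:
            removed.append((iid, "mendelian_error"))
            removals["mendelian_error"] += 1
            continue
        kept_daughters.append(iid)

    report = QcReport(stage="individual",
                      counts_in=len(daughters),
                      counts_out=len(kept_daughters),
                      removals=removals,
                      removed=removed,
                      flagged=flagged)
    return sires_in_matrix + kept_daughters, report


def _snp_metric_arrays(codes: np.ndarray, hwe_test: str
                       ) -> tuple[np.ndarray, ...]:
    """Vectorized per-column metrics; mirrors compute_snp_metrics."""
    n0 = (codes == 0).sum(axis=0)
    n1 = (codes == 1).sum(axis=0)
    n2 = (codes == 2).sum(axis=0)
    n = n0 + n1 + n2
    call_rate = n / codes.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, (2 * n2 + n1) / np.maximum(2 * n, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    if hwe_test == "exact":
        hwe_p = np.array([hwe_exact_p(int(a), int(b), int(c)) if tot else np.nan
                          for a, b, c, tot in zip(n0, n1, n2, n)])
    else:
        q = 1.0 - p
        exp0, exp1, exp2 = n * q * q, 2 * n * p * q, n * p * p
        chi2 = np.zeros(codes.shape[1])
        for obs, exp in ((n0, exp0), (n1, exp1), (n2, exp2)):
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(exp > 0, (obs - exp) ** 2 / np.where(
                    exp > 0, exp, 1.0), 0.0)
            chi2 += term
        hwe_p = np.where(n > 0, stats.chi2.sf(chi2, df=1), np.nan)
    min_count = np.minimum(np.minimum(n0, n1), n2)
    return call_rate, maf, hwe_p, min_count


def run_snp_qc(genotypes: GenotypeMatrix,
               thresholds: QcThresholds = QcThresholds(),
               filter_order: Sequence[str] = SNP_CRITERIA
               ) -> tuple[np.ndarray, QcReport]:
    """Apply the four SNP filters sequentially on kept individuals.

    Each SNP is attributed to the first filter it fails; the kept set is
    order-independent (a SNP failing any filter is removed), only the
    attribution counts depend on ``filter_order``.  Returns the kept SNP
    indices (into ``genotypes.snps``) and the stage report.
    """
    if sorted(filter_order) != sorted(SNP_CRITERIA):
        raise ValueError(f"filter_order must permute {SNP_CRITERIA}")
    codes = genotypes.codes
    call_rate, maf, hwe_p, min_count = _snp_metric_arrays(
        codes, thresholds.hwe_test)
    with np.errstate(invalid="ignore"):
        fails = {
            "call_rate": call_rate < thresholds.snp_call_min,
            # NaN metrics (all-missing column) fail call_rate, pass the rest
            "maf": np.nan_to_num(maf, nan=1.0) < thresholds.maf_min,
            "hwe": np.nan_to_num(hwe_p, nan=1.0) < thresholds.hwe_p_min,
            "min_genotype_count":
                min_count < thresholds.min_genotype_count,
        }
    removed_by = np.full(codes.shape[1], "", dtype=object)
    for crit in filter_order:
        newly = fails[crit] & (removed_by == "")
        removed_by[newly] = crit
    kept = np.flatnonzero(removed_by == "")
    removals = {crit: int(np.sum(removed_by == crit))
                for crit in filter_order}
    removed = [(genotypes.snps[j].snp_id, removed_by[j])
               for j in np.flatnonzero(removed_by != "")]
    report = QcReport(stage="snp",
                      counts_in=codes.shape[1],
                      counts_out=kept.size,
                      removals=removals,
                      removed=removed)
    return kept, report
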