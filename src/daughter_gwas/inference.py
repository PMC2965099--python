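"""Genome-wise significance, Q-Q diagnostics and cross-method summaries.

Multiple testing uses the Bonferroni rule with a method-specific N: a
SNP is genome-wise significant when its raw P value falls below
``alpha / N`` where N counts the SNPs that method actually tested (the
transmission test typically tests fewer SNPs than the mixed-model scan
because SNPs with no heterozygous sire are uninformative for it).

Q-Q diagnostics compare observed test statistics (or P values) with
their null quantiles at plotting positions ``(i - 0.5) / n`` and report
the median-based inflation factor, median observed chi-square over the
chi-square(1) median 0.4549: values near 1 indicate no systematic
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import METHOD_L1TDT, METHOD_MMRA, AssociationResult

__all__ = ["SignificanceConfig", "BonferroniResult", "bonferroni",
           "QqResult", "qq_points", "SummaryTable", "cross_method_summary",
           "CHI2_1DF_MEDIAN"]

#: Median of the chi-square distribution with one degree of freedom.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class SignificanceConfig:
    """Genome-wise significance settings for one method."""

    alpha: float = 0.05
    n_tests: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests


def bonferroni(raw_p: float, n_tests: int, alpha: float = 0.05
               ) -> tuple[float, float, bool]:
    """Bonferroni adjustment: ``(adjusted_p, threshold, significant)``.

    ``adjusted_p = min(1, raw_p * n_tests)``; a SNP is significant iff
    ``raw_p < alpha / n_tests`` (equivalently ``adjusted_p < alpha``).
    """
    if not (0.0 < raw_p <= 1.0):
        raise ValueError(f"raw_p {raw_p} outside (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    adjusted = min(1.0, raw_p * n_tests)
    threshold = alpha / n_tests
    return adjusted, threshold, raw_p < threshold


#: Convenience alias keeping dataclass-style access available.
BonferroniResult = tuple


@dataclass
class QqResult:
    """Ordered (expected, observed) quantile pairs plus the inflation factor."""

    expected: np.ndarray
    observed: np.ndarray
    inflation_factor: float


def qq_points(values: np.ndarray | Iterable[float],
              reference: str = "uniform",
              df: int = 1) -> QqResult:
    """Quantile-quantile pairs against a Uniform(0,1) or chi-square null.

    ``reference="uniform"`` treats ``values`` as P values; the observed
    axis is the sorted P values and the expected axis the uniform
    quantiles at plotting positions ``(i - 0.5) / n``.  The inflation
    factor is always computed on the chi-square(1) scale (P values are
    back-transformed), so a well-calibrated scan gives ~1 either way.
    ``reference="chi2"`` treats ``values`` as chi-square statistics.
    """
    values = np.asarray(list(values) if not isinstance(values, np.ndarray)
                        else values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("qq_points requires at least one finite value")
    n = values.size
    positions = (np.arange(1, n + 1) - 0.5) / n
    observed = np.sort(values)
    if reference == "uniform":
        expected = positions
        chi2_obs = stats.chi2.isf(observed, df=df)
    elif reference == "chi2":
        expected = stats.chi2.ppf(positions, df=df)
        chi2_obs = observed
    else:
        raise ValueError(f"unknown reference {reference!r}")
    inflation = float(np.median(chi2_obs) / stats.chi2.ppf(0.5, df=df))
    return QqResult(expected=expected, observed=observed,
                    inflation_factor=inflation)


@dataclass
class SummaryTable:
    """Cross-method accounting of significant SNPs.

    ``per_trait`` has one row per trait with the counts detected by each
    method, their overlap and their union; the global fields count
    *distinct* SNPs across all traits, splitting them into those found
    by both methods (for any trait), and those found solely by one.
    """

    per_trait: pd.DataFrame
    n_distinct: int
    n_both: int
    n_l1tdt_only: int
    n_mmra_only: int

    def union_identity_holds(self) -> bool:
        t = self.per_trait
        return bool(((t["n_l1tdt"] + t["n_mmra"] - t["n_overlap"])
                     == t["n_union"]).all())


def cross_method_summary(results: Iterable[AssociationResult],
                         configs: Mapping[str, SignificanceConfig]
                         ) -> SummaryTable:
    """Tabulate significant SNPs per trait and method, and globally.

    ``configs`` maps method name to its :class:`SignificanceConfig`
    (method-specific N); a result is significant when its raw P is below
    that method's genome-wise threshold.
    """
    hits: dict[tuple[str, str], set[str]] = {}
    traits: list[str] = []
    for r in results:
        cfg = configs[r.method]
        if r.raw_p < cfg.threshold:
            hits.setdefault((r.trait, r.method), set()).add(r.snp_id)
        if r.trait not in traits:
            traits.append(r.trait)

    rows = []
    for trait in traits:
        l1 = hits.get((trait, METHOD_L1TDT), set())
        mm = hits.get((trait, METHOD_MMRA), set())
        rows.append((trait, len(l1), len(mm), len(l1 & mm), len(l1 | mm)))
    per_trait = pd.DataFrame(
        rows, columns=["trait", "n_l1tdt", "n_mmra", "n_overlap", "n_union"])

    all_l1: set[str] = set()
    all_mm: set[str] = set()
    for (_, method), snps in hits.items():
        (all_l1 if method == METHOD_L1TDT else all_mm).update(snps)
    return SummaryTable(per_trait=per_trait,
                        n_distinct=len(all_l1 | all_mm),
                        n_both=len(all_l1 & all_mm),
                        n_l1tdt_only=len(all_l1 - all_mm),
                        n_mmra_only=len(all_mm - all_l1))
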