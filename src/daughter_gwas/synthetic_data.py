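"""Simulation of daughter-design GWAS datasets.

The generator emulates the statistical structure the association models
assume: unrelated sires, paternal half-sib daughter families, independent
biallelic SNPs in Hardy-Weinberg proportions, Mendelian paternal
transmission, an additive polygenic background transmitted through the
pedigree, optional pleiotropic QTL, and EBV-like phenotypes whose noise
variance scales with the inverse of a per-record reliability.

Dams are unknown and unrelated: each daughter receives one allele from her
sire (uniformly chosen when the sire is heterozygous) and one maternal
allele drawn from the population allele frequency.  The daughter's
polygenic value is half the sire's plus an independent Mendelian-sampling
deviation with variance ``0.75 * sigma_a2``, so half-sib covariance is
``0.25 * sigma_a2`` exactly as the numerator relationship matrix encodes.

EBV phenotypes are emulated as true-genetic-value-plus-noise,

    y = mu + sum_q x_q * beta_q + a + eps,   eps ~ N(0, sigma_e2 / REL),

with ``REL`` uniform on the configured reliability range per
daughter-trait.  QTL effect sizes are specified in phenotypic-SD units
(``sqrt(sigma_a2 + sigma_e2)``) per copy of allele b.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (MISSING, TRAITS, GenotypeMatrix, Pedigree,
                       PhenotypeTable, SnpRecord)

__all__ = ["QtlEffect", "SimulationConfig", "SimulatedStudy",
           "simulate_daughter_design", "inject_artifacts"]


@dataclass(frozen=True)
class QtlEffect:
    """One QTL: additive effect (phenotypic-SD units per allele-b copy)."""

    snp_index: int
    trait: str
    effect_sd: float


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the daughter-design generator.

    Defaults reflect the design this package targets: 14 unrelated sires
    with ~150 daughters each, a uniform MAF spectrum on (0.05, 0.5),
    reliabilities uniform on (0.41, 0.71), and a 30/70 split of additive
    to residual variance on the standardized trait scale.
    """

    n_sires: int = 14
    daughters_per_sire: int | Sequence[int] = 150
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    traits: tuple[str, ...] = TRAITS
    trait_means: Mapping[str, float] | float = 0.0
    qtl: tuple[QtlEffect, ...] = ()
    sigma_a2: float = 0.3
    sigma_e2: float = 0.7
    reliability_range: tuple[float, float] = (0.41, 0.71)
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0
    seed: int = 20101027

    def daughter_counts(self) -> list[int]:
        if isinstance(self.daughters_per_sire, int):
            return [self.daughters_per_sire] * self.n_sires
        counts = list(self.daughters_per_sire)
        if len(counts) != self.n_sires:
            raise ValueError(
                f"daughters_per_sire has {len(counts)} entries "
                f"for {self.n_sires} sires")
        return counts

    def mean_of(self, trait: str) -> float:
        if isinstance(self.trait_means, Mapping):
            return float(self.trait_means.get(trait, 0.0))
        return float(self.trait_means)

    def validate(self) -> None:
        if self.n_sires < 1:
            raise ValueError("need at least one sire")
        counts = self.daughter_counts()
        if any(c < 0 for c in counts):
            raise ValueError("negative daughter count")
        if sum(counts) == 0:
            raise ValueError("simulation requires at least one daughter")
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")
        rlo, rhi = self.reliability_range
        if not (0.0 < rlo <= rhi <= 1.0):
            raise ValueError(
                f"reliability_range {self.reliability_range} outside (0, 1]")
        for rate in (self.missing_rate, self.mendel_error_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"artifact rate {rate} outside [0, 1]")
        for q in self.qtl:
            if not (0 <= q.snp_index < self.n_snps):
                raise ValueError(f"QTL snp_index {q.snp_index} out of range")
            if q.trait not in self.traits:
                raise ValueError(f"QTL trait {q.trait!r} not simulated")


@dataclass
class SimulatedStudy:
    """A complete simulated dataset plus its ground truth.

    ``truth`` holds DataFrames: ``"qtl"`` (planted effects), ``"genetic"``
    (per daughter-trait polygenic and QTL values), ``"allele_freq"``
    (per-SNP allele-b frequency used for the draws), and after artifact
    injection also ``"injected_missing"`` / ``"injected_mendel"``
    (individual id, snp_id of each corrupted cell).
    """

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    phenotypes: PhenotypeTable
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def sire_ids(self) -> list[str]:
        return self.pedigree.founders

    @property
    def daughter_ids(self) -> list[str]:
        founders = set(self.pedigree.founders)
        return [i for i in self.pedigree.ids if i not in founders]


def _snp_panel(n_snps: int) -> list[tuple[str, str, int]]:
    """Spread SNPs over 29 autosomes in contiguous blocks, 1-based bp."""
    sites = []
    per_chrom: dict[str, int] = {}
    for j in range(n_snps):
        chrom = str(1 + (j * 29) // n_snps)
        k = per_chrom.get(chrom, 0) + 1
        per_chrom[chrom] = k
        sites.append((f"SNP{j + 1:06d}", chrom, 60_000 * k))
    return sites


def simulate_daughter_design(config: SimulationConfig) -> SimulatedStudy:
    """Draw one complete study dataset; bit-reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.daughter_counts()
    n_sires, n_snps = config.n_sires, config.n_snps
    n_dau = sum(counts)
    n_traits = len(config.traits)

    p = rng.uniform(*config.maf_range, size=n_snps)  # allele-b frequency
    sire_codes = rng.binomial(2, p[None, :], size=(n_sires, n_snps)
                              ).astype(np.int8)

    sire_idx = np.repeat(np.arange(n_sires), counts)
    sc = sire_codes[sire_idx]  # sire genotype per daughter
    coin = rng.integers(0, 2, size=(n_dau, n_snps)).astype(np.int8)
    paternal = np.where(sc == 1, coin, sc // 2).astype(np.int8)
    maternal = rng.binomial(1, p[None, :], size=(n_dau, n_snps)).astype(np.int8)
    dau_codes = paternal + maternal

    codes = np.vstack([sire_codes, dau_codes])
    sire_ids = [f"S{i + 1:02d}" for i in range(n_sires)]
    dau_ids = [f"{sire_ids[s]}D{k + 1:03d}"
               for s in range(n_sires) for k in range(counts[s])]
    sites = _snp_panel(n_snps)
    snps = [SnpRecord(sid, chrom, pos, "A", "B")
            for sid, chrom, pos in sites]
    genotypes = GenotypeMatrix(sire_ids + dau_ids, snps, codes)

    for q in config.qtl:
        if len(np.unique(codes[:, q.snp_index])) < 2:
            raise ValueError(
                f"QTL on monomorphic SNP {snps[q.snp_index].snp_id}")

    entries = [(iid, None, None) for iid in sire_ids]
    entries += [(dau_ids[j], sire_ids[sire_idx[j]], None)
                for j in range(n_dau)]
    pedigree = Pedigree(entries)

    # polygenic values, per trait, independent across traits
    u_sire = rng.normal(0.0, np.sqrt(config.sigma_a2),
                        size=(n_sires, n_traits))
    mendelian = rng.normal(0.0, np.sqrt(0.75 * config.sigma_a2),
                           size=(n_dau, n_traits))
    a_dau = 0.5 * u_sire[sire_idx] + mendelian

    rel = rng.uniform(*config.reliability_range, size=(n_dau, n_traits))
    eps = rng.normal(0.0, 1.0, size=(n_dau, n_traits)) \
        * np.sqrt(config.sigma_e2 / rel)

    sigma_p = float(np.sqrt(config.sigma_a2 + config.sigma_e2))
    qtl_value = np.zeros((n_dau, n_traits))
    trait_pos = {t: k for k, t in enumerate(config.traits)}
    for q in config.qtl:
        x = dau_codes[:, q.snp_index].astype(float)
        qtl_value[:, trait_pos[q.trait]] += x * q.effect_sd * sigma_p

    mu = np.array([config.mean_of(t) for t in config.traits])
    y = mu[None, :] + qtl_value + a_dau + eps

    records = []
    for j, iid in enumerate(dau_ids):
        for k, t in enumerate(config.traits):
            records.append((iid, t, float(y[j, k]), float(rel[j, k])))
    phenotypes = PhenotypeTable.from_records(records)

    truth = {
        "qtl": pd.DataFrame(
            [(snps[q.snp_index].snp_id, q.trait, q.effect_sd,
              q.effect_sd * sigma_p, float(p[q.snp_index]))
             for q in config.qtl],
            columns=["snp_id", "trait", "effect_sd", "effect_units",
                     "allele_b_freq"]),
        "genetic": pd.DataFrame(
            [(dau_ids[j], t, float(a_dau[j, k]), float(qtl_value[j, k]))
             for j in range(n_dau)
             for k, t in enumerate(config.traits)],
            columns=["id", "trait", "polygenic", "qtl_value"]),
        "allele_freq": pd.DataFrame(
            {"snp_id": [s.snp_id for s in snps], "allele_b_freq": p}),
    }
    study = SimulatedStudy(genotypes, pedigree, phenotypes, truth)

    if config.missing_rate > 0 or config.mendel_error_rate > 0:
        study = inject_artifacts(
            study, config.missing_rate, config.mendel_error_rate,
            seed=int(rng.integers(2 ** 31 - 1)))
    return study


def inject_artifacts(study: SimulatedStudy,
                     missing_rate: float,
                     mendel_error_rate: float,
                     target_individuals: Sequence[str] | None = None,
                     seed: int = 0) -> SimulatedStudy:
    """Corrupt genotype cells to exercise the QC stage.

    Missing calls are injected first (uniformly over target cells), then
    Mendelian errors: at loci where the target daughter's sire is
    homozygous, the daughter's call is flipped to the *opposite*
    homozygote, a guaranteed Mendelian inconsistency.  Both kinds of
    injected cells are recorded in ``truth``.  Rates of zero return a
    study with identical genotype codes.
    """
    for rate in (missing_rate, mendel_error_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"artifact rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    genotypes = study.genotypes
    codes = genotypes.codes.copy()
    targets = list(target_individuals) if target_individuals is not None \
        else study.daughter_ids
    snp_ids = genotypes.snp_ids
    injected_missing: list[tuple[str, str]] = []
    injected_mendel: list[tuple[str, str]] = []

    for iid in targets:
        i = genotypes.row_index(iid)
        if missing_rate > 0:
            hit = rng.random(codes.shape[1]) < missing_rate
            for j in np.flatnonzero(hit):
                injected_missing.append((iid, snp_ids[j]))
            codes[i, hit] = MISSING
        if mendel_error_rate > 0:
            sire = study.pedigree.sire_of(iid)
            if sire is None:
                continue
            s_row = codes[genotypes.row_index(sire)]
            eligible = ((s_row == 0) | (s_row == 2)) & (codes[i] != MISSING)
            hit = (rng.random(codes.shape[1]) < mendel_error_rate) & eligible
            for j in np.flatnonzero(hit):
                injected_mendel.append((iid, snp_ids[j]))
            codes[i, hit] = 2 - s_row[hit]

    truth = {k: v.copy() for k, v in study.truth.items()}
    truth["injected_missing"] = pd.DataFrame(
        injected_missing, columns=["id", "snp_id"])
    truth["injected_mendel"] = pd.DataFrame(
        injected_mendel, columns=["id", "snp_id"])
    new_geno = GenotypeMatrix(genotypes.individual_ids, genotypes.snps, codes)
    return SimulatedStudy(new_geno, copy.deepcopy(study.pedigree),
                          PhenotypeTable(study.phenotypes.frame.copy()), truth)
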