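"""Core data model and text I/O for daughter-design GWAS.

A daughter design genotypes a set of sires and their paternal half-sib
daughters; phenotypes are estimated breeding values (EBVs) with per-record
reliabilities, recorded on the daughters.  Every statistic in this package
consumes allele-b dosage codes: 0, 1 or 2 copies of ``allele_b`` at a SNP,
with :data:`MISSING` (-1) marking failed calls.

Supported on-disk dialects are all plain text:

* PLINK PED/MAP (whitespace-delimited, two allele characters per SNP,
  ``0 0`` = missing genotype, unknown parents coded ``0``),
* a native genotype TSV (rows = individuals, columns = SNPs, codes
  ``0/1/2/NA``) whose commented header carries the SNP metadata so that
  write-then-read is lossless,
* pedigree CSV (``id,sire,dam``), phenotype TSV
  (``id, trait, ebv, reliability``) and a results TSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in integer code matrices.
MISSING: int = -1

#: File encoding of an unknown parent (PLINK convention).
UNKNOWN_PARENT: str = "0"

#: The five milk production traits of the daughter design.
TRAITS: tuple[str, ...] = ("MY", "FY", "PY", "FP", "PP")

#: Column order of the association results TSV.
RESULT_COLUMNS: tuple[str, ...] = (
    "snp_id", "chrom", "pos", "trait", "method",
    "effect", "se", "statistic", "raw_p", "adjusted_p", "n_used",
)

METHOD_L1TDT = "L1TDT"
METHOD_MMRA = "MMRA"


class DataFormatError(ValueError):
    """An input file violates the expected dialect or an invariant."""


class PedigreeCycleError(DataFormatError):
    """The pedigree contains an individual that is its own ancestor."""


@dataclass(frozen=True)
class SnpRecord:
    """Identity and genomic placement of one biallelic SNP.

    ``chromosome`` is a string label (autosomes ``"1"``-``"29"``, ``"X"``,
    or ``"0"`` for unassigned markers); ``position_bp`` is 1-based.
    ``allele_b`` is the allele whose copies the dosage codes count.
    """

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise DataFormatError(
                f"SNP {self.snp_id}: allele_a and allele_b must differ")
        if self.position_bp < 0:
            raise DataFormatError(f"SNP {self.snp_id}: negative position")


class GenotypeMatrix:
    """Individuals x SNPs matrix of allele-b dosage codes.

    Codes are stored as ``int8`` with values in ``{0, 1, 2, MISSING}``.
    Row order is meaningful (it follows the source file) and preserved by
    all round-trips.
    """

    def __init__(self,
                 individual_ids: Sequence[str],
                 snps: Sequence[SnpRecord],
                 codes: np.ndarray) -> None:
        self.individual_ids: list[str] = list(individual_ids)
        self.snps: list[SnpRecord] = list(snps)
        codes = np.ascontiguousarray(codes, dtype=np.int8)
        if codes.shape != (len(self.individual_ids), len(self.snps)):
            raise DataFormatError(
                f"code matrix shape {codes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snps)} SNPs")
        bad = ~np.isin(codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataFormatError(
                f"invalid genotype code {codes[i, j]} for individual "
                f"{self.individual_ids[i]} at SNP {self.snps[j].snp_id}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise DataFormatError("duplicate individual ids in genotype matrix")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise DataFormatError("duplicate SNP ids in genotype matrix")
        self.codes = codes
        self._row_index = {iid: i for i, iid in enumerate(self.individual_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def row(self, individual_id: str) -> np.ndarray:
        return self.codes[self._row_index[individual_id]]

    def row_index(self, individual_id: str) -> int:
        return self._row_index[individual_id]

    def column(self, j: int) -> np.ndarray:
        return self.codes[:, j]

    # -- derived matrices ----------------------------------------------------
    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self._row_index[i] for i in ids]
        return GenotypeMatrix(list(ids), self.snps, self.codes[rows])

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(self.individual_ids,
                              [self.snps[j] for j in idx],
                              self.codes[:, idx])

    def swap_allele_labels(self) -> "GenotypeMatrix":
        """Relabel allele_a <-> allele_b at every SNP (code -> 2 - code)."""
        codes = self.codes.copy()
        obs = codes != MISSING
        codes[obs] = 2 - codes[obs]
        snps = [SnpRecord(s.snp_id, s.chromosome, s.position_bp,
                          s.allele_b, s.allele_a) for s in self.snps]
        return GenotypeMatrix(self.individual_ids, snps, codes)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (self.individual_ids == other.individual_ids
                and self.snps == other.snps
                and np.array_equal(self.codes, other.codes))


class Pedigree:
    """Ordered list of ``(individual, sire, dam)`` records.

    Unknown parents are ``None`` in memory and ``"0"`` on disk.  Every
    referenced parent must itself appear as a record (founders carry two
    unknown parents), which keeps the relationship-matrix construction
    well defined.
    """

    def __init__(self, entries: Iterable[tuple[str, str | None, str | None]]):
        norm: list[tuple[str, str | None, str | None]] = []
        for iid, sire, dam in entries:
            sire = None if sire in (None, "", UNKNOWN_PARENT) else str(sire)
            dam = None if dam in (None, "", UNKNOWN_PARENT) else str(dam)
            iid = str(iid)
            if iid in (sire, dam):
                raise PedigreeCycleError(f"{iid} is its own parent")
            norm.append((iid, sire, dam))
        self.entries = norm
        self._sire = {i: s for i, s, _ in norm}
        self._dam = {i: d for i, _, d in norm}
        if len(self._sire) != len(norm):
            raise DataFormatError("duplicate individual ids in pedigree")
        known = set(self._sire)
        for iid, sire, dam in norm:
            for parent in (sire, dam):
                if parent is not None and parent not in known:
                    raise DataFormatError(
                        f"parent {parent} of {iid} has no pedigree record")

    @property
    def ids(self) -> list[str]:
        return [i for i, _, _ in self.entries]

    def __contains__(self, iid: str) -> bool:
        return iid in self._sire

    def __len__(self) -> int:
        return len(self.entries)

    def sire_of(self, iid: str) -> str | None:
        return self._sire[iid]

    def dam_of(self, iid: str) -> str | None:
        return self._dam[iid]

    @property
    def founders(self) -> list[str]:
        return [i for i, s, d in self.entries if s is None and d is None]

    def offspring_by_sire(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for iid, sire, _ in self.entries:
            if sire is not None:
                out.setdefault(sire, []).append(iid)
        return out

    def topological_order(self) -> list[str]:
        """Parents-before-offspring order: founders in file order first,
        then non-founders in file order as their parents become available.

        Raises :class:`PedigreeCycleError` naming the cycle if the pedigree
        contains one.
        """
        placed: set[str] = set()
        order: list[str] = []
        pending = list(self.entries)
        while pending:
            progressed = False
            remaining = []
            for iid, sire, dam in pending:
                ok = all(p is None or p in placed for p in (sire, dam))
                if ok:
                    placed.add(iid)
                    order.append(iid)
                    progressed = True
                else:
                    remaining.append((iid, sire, dam))
            if not progressed:
                cycle = self._find_cycle({i for i, _, _ in remaining})
                raise PedigreeCycleError(
                    "pedigree cycle: " + " -> ".join(cycle))
            pending = remaining
        return order

    def _find_cycle(self, candidates: set[str]) -> list[str]:
        start = next(iter(sorted(candidates)))
        seen: list[str] = []
        node = start
        while node not in seen:
            seen.append(node)
            nxt = self._sire.get(node) or self._dam.get(node)
            if nxt is None:  # pragma: no cover - defensive
                return seen
            node = nxt
        return seen[seen.index(node):] + [node]


class PhenotypeTable:
    """Per-daughter, per-trait EBV phenotypes with reliabilities.

    One row per ``(individual, trait)``; ``reliability`` must lie in
    ``(0, 1]`` because both association models weight residuals by it.
    """

    COLUMNS = ("id", "trait", "ebv", "reliability")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise DataFormatError(f"phenotype table lacks columns {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        frame["id"] = frame["id"].astype(str)
        frame["trait"] = frame["trait"].astype(str)
        frame["ebv"] = frame["ebv"].astype(float)
        frame["reliability"] = frame["reliability"].astype(float)
        bad = (frame["reliability"] <= 0) | (frame["reliability"] > 1)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataFormatError(
                f"phenotype row {row + 1}: reliability "
                f"{frame['reliability'].iloc[row]} outside (0, 1]")
        dup = frame.duplicated(subset=["id", "trait"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise DataFormatError(
                f"duplicate (id, trait) pair at phenotype row {row + 1}: "
                f"{frame['id'].iloc[row]}/{frame['trait'].iloc[row]}")
        self.frame = frame

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float, float]]
                     ) -> "PhenotypeTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.frame)

    def traits(self) -> list[str]:
        return sorted(self.frame["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        """``ebv``/``reliability`` indexed by individual id for one trait."""
        sub = self.frame[self.frame["trait"] == trait]
        return sub.set_index("id")[["ebv", "reliability"]]

    def equals(self, other: "PhenotypeTable") -> bool:
        return self.frame.equals(other.frame)


@dataclass(frozen=True)
class AssociationResult:
    """Per-SNP association outcome for one trait and one method."""

    snp_id: str
    trait: str
    method: str
    effect_estimate: float
    standard_error: float
    statistic: float
    raw_p: float
    adjusted_p: float
    n_used: int

    def __post_init__(self) -> None:
        if self.method not in (METHOD_L1TDT, METHOD_MMRA):
            raise ValueError(f"unknown method {self.method!r}")
        if not (0.0 < self.raw_p <= 1.0):
            raise ValueError(f"raw_p {self.raw_p} outside (0, 1]")
        if not (0.0 < self.adjusted_p <= 1.0):
            raise ValueError(f"adjusted_p {self.adjusted_p} outside (0, 1]")
        if self.adjusted_p < self.raw_p - 1e-15:
            raise ValueError("adjusted_p below raw_p")
        if not np.isnan(self.statistic) and self.statistic < 0:
            raise ValueError("negative test statistic")
        if not np.isnan(self.standard_error) and self.standard_error < 0:
            raise ValueError("negative standard error")


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    """Parse a PLINK MAP file into ``(chromosome, snp_id, position)`` rows."""
    out = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 4:
            raise DataFormatError(
                f"{map_path}: MAP row {ln} has {len(fields)} fields, expected 4")
        chrom, snp_id, _gdist, pos = fields[:4]
        out.append((chrom, snp_id, int(pos)))
    return out


def read_genotypes(ped_path: str | Path,
                   map_path: str | Path,
                   allele_b: Mapping[str, str] | None = None
                   ) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    Allele-b at each SNP is the lexicographically later observed allele
    unless overridden through ``allele_b`` (mapping snp_id -> allele
    character).  ``0 0`` allele pairs become :data:`MISSING`.  Row order
    follows the PED file.
    """
    sites = read_map(map_path)
    n_snps = len(sites)
    individual_ids: list[str] = []
    allele_rows: list[list[str]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * n_snps:
            raise DataFormatError(
                f"{ped_path}: PED row {ln} has {len(fields)} fields, expected "
                f"{6 + 2 * n_snps} for {n_snps} MAP SNPs")
        individual_ids.append(fields[1])
        allele_rows.append(fields[6:])

    n_ind = len(individual_ids)
    codes = np.full((n_ind, n_snps), MISSING, dtype=np.int8)
    snps: list[SnpRecord] = []
    alleles = np.array(allele_rows, dtype=object).reshape(n_ind, n_snps, 2) \
        if n_ind else np.empty((0, n_snps, 2), dtype=object)
    for j, (chrom, snp_id, pos) in enumerate(sites):
        col = alleles[:, j, :] if n_ind else np.empty((0, 2), dtype=object)
        observed = sorted({a for pair in col for a in pair if a != "0"})
        if len(observed) > 2:
            raise DataFormatError(
                f"SNP {snp_id}: more than 2 distinct alleles {observed}")
        if len(observed) == 2:
            a_a, a_b = observed
        elif len(observed) == 1:
            a_a, a_b = "0", observed[0]
        else:
            a_a, a_b = "0", "N"
        if allele_b is not None and snp_id in allele_b:
            forced = allele_b[snp_id]
            if forced not in observed and observed:
                raise DataFormatError(
                    f"SNP {snp_id}: forced allele_b {forced!r} never observed")
            other = [a for a in observed if a != forced]
            a_b = forced
            a_a = other[0] if other else "0"
        snps.append(SnpRecord(snp_id, chrom, pos, a_a, a_b))
        for i in range(n_ind):
            a1, a2 = col[i]
            if a1 == "0" or a2 == "0":
                continue
            codes[i, j] = (a1 == a_b) + (a2 == a_b)
    return GenotypeMatrix(individual_ids, snps, codes)


def write_plink(genotypes: GenotypeMatrix,
                ped_path: str | Path,
                map_path: str | Path,
                pedigree: Pedigree | None = None) -> None:
    """Write PED/MAP.  Parent columns are filled from ``pedigree`` if given."""
    with open(map_path, "w") as fh:
        for s in genotypes.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(genotypes.individual_ids):
            sire = dam = UNKNOWN_PARENT
            if pedigree is not None and iid in pedigree:
                sire = pedigree.sire_of(iid) or UNKNOWN_PARENT
                dam = pedigree.dam_of(iid) or UNKNOWN_PARENT
            fields = [iid, iid, sire, dam, "0", "-9"]
            row = genotypes.codes[i]
            for j, s in enumerate(genotypes.snps):
                c = row[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [s.allele_a, s.allele_a]
                elif c == 1:
                    fields += [s.allele_a, s.allele_b]
                else:
                    fields += [s.allele_b, s.allele_b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Native genotype TSV (lossless dialect)
# ---------------------------------------------------------------------------

def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV with SNP metadata in commented header lines."""
    with open(path, "w") as fh:
        for s in genotypes.snps:
            fh.write(f"#snp\t{s.snp_id}\t{s.chromosome}\t{s.position_bp}"
                     f"\t{s.allele_a}\t{s.allele_b}\n")
        fh.write("individual_id\t" + "\t".join(genotypes.snp_ids) + "\n")
        for i, iid in enumerate(genotypes.individual_ids):
            cells = ["NA" if c == MISSING else str(int(c))
                     for c in genotypes.codes[i]]
            fh.write(iid + "\t" + "\t".join(cells) + "\n")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    snps: list[SnpRecord] = []
    header: list[str] | None = None
    ids: list[str] = []
    rows: list[list[int]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#snp\t"):
            _, snp_id, chrom, pos, a_a, a_b = line.split("\t")
            snps.append(SnpRecord(snp_id, chrom, int(pos), a_a, a_b))
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            if header[1:] != [s.snp_id for s in snps]:
                raise DataFormatError(
                    f"{path}: column header does not match #snp metadata")
            continue
        if len(fields) != len(header):
            raise DataFormatError(
                f"{path}: row {ln} has {len(fields)} fields, "
                f"expected {len(header)}")
        ids.append(fields[0])
        rows.append([MISSING if c == "NA" else int(c) for c in fields[1:]])
    codes = (np.array(rows, dtype=np.int8) if rows
             else np.empty((0, len(snps)), dtype=np.int8))
    return GenotypeMatrix(ids, snps, codes)


# ---------------------------------------------------------------------------
# Pedigree CSV
# ---------------------------------------------------------------------------

def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sire", "dam"])
        for iid, sire, dam in pedigree.entries:
            writer.writerow([iid, sire or UNKNOWN_PARENT, dam or UNKNOWN_PARENT])


def read_pedigree(path: str | Path) -> Pedigree:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["id", "sire", "dam"]:
            raise DataFormatError(f"{path}: expected header id,sire,dam")
        entries = [(r[0], r[1], r[2]) for r in reader if r]
    return Pedigree(entries)


# ---------------------------------------------------------------------------
# Phenotype TSV
# ---------------------------------------------------------------------------

def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    phenotypes.frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t", dtype={"id": str, "trait": str})
    if frame.empty and list(frame.columns) != list(PhenotypeTable.COLUMNS):
        raise DataFormatError(f"{path}: expected header id/trait/ebv/reliability")
    return PhenotypeTable(frame)


# ---------------------------------------------------------------------------
# Results TSV
# ---------------------------------------------------------------------------

def results_to_frame(results: Iterable[AssociationResult],
                     snp_info: Mapping[str, SnpRecord]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = snp_info[r.snp_id]
        rows.append((r.snp_id, s.chromosome, s.position_bp, r.trait, r.method,
                     r.effect_estimate, r.standard_error, r.statistic,
                     r.raw_p, r.adjusted_p, r.n_used))
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Iterable[AssociationResult],
                  snp_info: Mapping[str, SnpRecord],
                  path: str | Path) -> None:
    results_to_frame(results, snp_info).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t",
                        dtype={"snp_id": str, "chrom": str, "trait": str,
                               "method": str})
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: results file lacks columns {missing}")
    return frame
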