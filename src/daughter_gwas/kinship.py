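"""Pedigree numerator relationship matrix A and its inverse.

The numerator relationship matrix holds expected additive genetic
relationships: twice the kinship coefficient between two individuals.
It is built by the tabular method -- processing individuals in an order
where parents precede offspring,

    a_ii = 1 + 0.5 * a(sire_i, dam_i)
    a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))   for j processed before i,

with unknown parents contributing zero.  A-inverse is assembled sparsely
by Henderson's rules for non-inbred pedigrees, which is the path the
mixed-model equations use at design scale (2,000+ individuals); a dense
inverse of the tabular A is the fallback when inbreeding is detected.

A gene-dropping Monte Carlo estimator of A is included as an
independent simulation-based cross-check for small pedigrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io_model import Pedigree, PedigreeCycleError

__all__ = ["RelationshipMatrix", "build_numerator_relationship",
           "build_a_inverse", "gene_drop_relationship",
           "write_sparse_triplets"]


@dataclass
class RelationshipMatrix:
    """Symmetric additive-relationship (or inverse) matrix with row ids."""

    ids: list[str]
    values: np.ndarray | sparse.spmatrix

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return self.values.toarray()
        return self.values

    def index_of(self, iid: str) -> int:
        try:
            return self.ids.index(iid)
        except ValueError:
            raise KeyError(iid) from None

    def submatrix(self, ids: list[str]) -> np.ndarray:
        lookup = {iid: i for i, iid in enumerate(self.ids)}
        idx = np.array([lookup[i] for i in ids])
        return self.dense()[np.ix_(idx, idx)]


def _ordering(pedigree: Pedigree) -> list[str]:
    """Founders first (file order), then non-founders topologically."""
    topo = pedigree.topological_order()
    founders = [i for i in pedigree.ids
                if pedigree.sire_of(i) is None and pedigree.dam_of(i) is None]
    founder_set = set(founders)
    return founders + [i for i in topo if i not in founder_set]


def build_numerator_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Dense A by the tabular method.

    Raises :class:`PedigreeCycleError` (from the topological sort) if the
    pedigree contains a cycle.
    """
    order = _ordering(pedigree)
    index = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for i, iid in enumerate(order):
        s = pedigree.sire_of(iid)
        d = pedigree.dam_of(iid)
        si = index[s] if s is not None else None
        di = index[d] if d is not None else None
        a_sd = a[si, di] if (si is not None and di is not None) else 0.0
        a[i, i] = 1.0 + 0.5 * a_sd
        if i == 0:
            continue
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * a[:i, si]
        if di is not None:
            row += 0.5 * a[:i, di]
        a[i, :i] = row
        a[:i, i] = row
    return RelationshipMatrix(order, a)


def _is_inbred(pedigree: Pedigree) -> bool:
    """True if any individual's known parents share a known ancestor."""
    ancestors: dict[str, frozenset[str]] = {}

    def anc(iid: str) -> frozenset[str]:
        if iid not in ancestors:
            acc: set[str] = set()
            for p in (pedigree.sire_of(iid), pedigree.dam_of(iid)):
                if p is not None:
                    acc.add(p)
                    acc |= anc(p)
            ancestors[iid] = frozenset(acc)
        return ancestors[iid]

    for iid in pedigree.topological_order():
        s, d = pedigree.sire_of(iid), pedigree.dam_of(iid)
        if s is not None and d is not None:
            if s == d or s in anc(d) or d in anc(s) or (anc(s) & anc(d)):
                return True
    return False


def build_a_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules (non-inbred pedigrees).

    Per-individual contributions use the unknown-parent residual weights
    1 (both parents unknown), 4/3 (one known), 2 (both known).  If the
    pedigree is inbred these rules are invalid; the function then warns
    and falls back to densely inverting the tabular A.
    """
    order = _ordering(pedigree)
    if _is_inbred(pedigree):
        warnings.warn("inbred pedigree: dense inversion of tabular A used "
                      "instead of Henderson's rules", stacklevel=2)
        a = build_numerator_relationship(pedigree)
        return RelationshipMatrix(a.ids, sparse.csr_matrix(
            np.linalg.inv(a.values)))
    index = {iid: k for k, iid in enumerate(order)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for iid in order:
        i = index[iid]
        parents = [index[p] for p in (pedigree.sire_of(iid),
                                      pedigree.dam_of(iid)) if p is not None]
        alpha = {0: 1.0, 1: 4.0 / 3.0, 2: 2.0}[len(parents)]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -alpha / 2.0)
            add(p, i, -alpha / 2.0)
        for p in parents:
            for q in parents:
                add(p, q, alpha / 4.0)
    n = len(order)
    ainv = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    ainv.sum_duplicates()
    return RelationshipMatrix(order, ainv)


def gene_drop_relationship(pedigree: Pedigree,
                           n_replicates: int = 10_000,
                           seed: int = 0) -> RelationshipMatrix:
    """Monte Carlo estimate of A by gene dropping.

    Founders receive unique allele labels; each offspring inherits one
    uniformly chosen allele from each known parent (unknown parents
    contribute fresh unique alleles).  The additive relationship is
    estimated as twice the average fraction of allele pairs identical by
    descent.  Intended as an independent cross-check on small pedigrees.
    """
    order = _ordering(pedigree)
    index = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    rng = np.random.default_rng(seed)
    acc = np.zeros((n, n))
    for _ in range(n_replicates):
        alleles = np.zeros((n, 2), dtype=np.int64)
        next_label = 1
        for iid in order:
            i = index[iid]
            for slot, parent in enumerate((pedigree.sire_of(iid),
                                           pedigree.dam_of(iid))):
                if parent is None:
                    alleles[i, slot] = next_label
                    next_label += 1
                else:
                    alleles[i, slot] = alleles[index[parent],
                                               rng.integers(0, 2)]
        match = np.zeros((n, n))
        for k in range(2):
            for m in range(2):
                match += alleles[:, k][:, None] == alleles[:, m][None, :]
        acc += match / 2.0
    return RelationshipMatrix(order, acc / n_replicates)


def write_sparse_triplets(matrix: RelationshipMatrix, path: str) -> None:
    """TSV dump of nonzero entries as (id_i, id_j, value) for inspection."""
    coo = sparse.coo_matrix(matrix.values)
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{matrix.ids[i]}\t{matrix.ids[j]}\t{v:.12g}\n")
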