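"""Pedigree (A) and genomic (G) relationship matrices.

The numerator relationship matrix A is built with the tabular (recursive)
method in a topological ordering of the pedigree:

    A[i, j] = 0.5 * (A[sire(i), j] + A[dam(i), j])        for j before i
    A[i, i] = 1 + 0.5 * A[sire(i), dam(i)]

with unknown parents contributing 0.  Diagonal entries therefore equal
1 + F_i, twice the self-kinship of an inbred animal.

The genomic relationship matrix follows VanRaden's first method:

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),   Z = M - 2p

with M the allele-dosage matrix (0/1/2 copies of the counted allele) and
p_j the allele frequency of SNP j, by default estimated from the supplied
genotypes.  Monomorphic SNPs carry no information and are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import SnpMap, SnpSet

log = logging.getLogger(__name__)

__all__ = [
    "PedigreeError",
    "Pedigree",
    "RelationshipMatrix",
    "Grm",
    "Genotypes",
    "build_a_matrix",
    "build_grm",
    "augment_snp_set",
]


class PedigreeError(ValueError):
    """Invalid pedigree structure."""


class Pedigree:
    """A validated, topologically sortable pedigree.

    Parameters
    ----------
    animals, sires, dams
        Parallel sequences of identifiers.  Unknown parents use the
        ``unknown`` marker ("0" by livestock convention).  Every known
        parent must itself appear as an animal.
    """

    def __init__(
        self,
        animals: Sequence[str],
        sires: Sequence[str],
        dams: Sequence[str],
        unknown: str = "0",
    ) -> None:
        ids = [str(a) for a in animals]
        if len(set(ids)) != len(ids):
            dupes = sorted({a for a in ids if ids.count(a) > 1})
            raise PedigreeError(f"duplicate animal ids {dupes[:5]}")
        index = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        parent = np.full((n, 2), -1, dtype=np.intp)
        for i, (s, d) in enumerate(zip(sires, dams)):
            for k, p in enumerate((str(s), str(d))):
                if p == unknown:
                    continue
                if p not in index:
                    raise PedigreeError(
                        f"animal {ids[i]!r} references parent {p!r} "
                        "which has no pedigree row"
                    )
                parent[i, k] = index[p]
        self.ids = ids
        self.index = index
        self.parent = parent
        self.unknown = unknown
        self.topo_order = self._toposort()

    def __len__(self) -> int:
        return len(self.ids)

    def _toposort(self) -> np.ndarray:
        n = len(self.ids)
        n_pending = np.zeros(n, dtype=np.intp)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in self.parent[i]:
                if p >= 0:
                    n_pending[i] += 1
                    children[p].append(i)
        order = [i for i in range(n) if n_pending[i] == 0]
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for c in children[i]:
                n_pending[c] -= 1
                if n_pending[c] == 0:
                    order.append(c)
        if len(order) < n:
            stuck = next(self.ids[i] for i in range(n) if n_pending[i] > 0)
            raise PedigreeError(f"pedigree cycle involving animal {stuck!r}")
        return np.asarray(order, dtype=np.intp)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unknown: str = "0") -> "Pedigree":
        return cls(
            df["animal"].astype(str).tolist(),
            df["sire"].astype(str).tolist(),
            df["dam"].astype(str).tolist(),
            unknown=unknown,
        )

    @classmethod
    def from_csv(cls, path, unknown: str = "0") -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str, comment="#"), unknown)

    def to_frame(self) -> pd.DataFrame:
        sire = [self.ids[p] if p >= 0 else self.unknown for p in self.parent[:, 0]]
        dam = [self.ids[p] if p >= 0 else self.unknown for p in self.parent[:, 1]]
        return pd.DataFrame({"animal": self.ids, "sire": sire, "dam": dam})


@dataclass
class RelationshipMatrix:
    """Dense symmetric matrix of expected additive relationships."""

    ids: list[str]
    values: np.ndarray

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.ids)}
        idx = np.asarray([index[str(a)] for a in ids], dtype=np.intp)
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class Grm(RelationshipMatrix):
    """Genomic relationship matrix with provenance of SNPs and frequencies."""

    snp_ids: tuple[str, ...] = ()
    freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dropped_monomorphic: int = 0


class Genotypes:
    """Allele-dosage matrix (animals x SNPs) with id bookkeeping."""

    def __init__(
        self,
        animal_ids: Sequence[str],
        snp_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        values = np.asarray(values)
        if values.shape != (len(animal_ids), len(snp_ids)):
            raise ValueError(
                f"dosage matrix shape {values.shape} does not match "
                f"{len(animal_ids)} animals x {len(snp_ids)} SNPs"
            )
        self.animal_ids = [str(a) for a in animal_ids]
        self.snp_ids = [str(s) for s in snp_ids]
        self.values = values
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}
        self._animal_index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dosages(
        self,
        snp_ids: Iterable[str] | None = None,
        animal_ids: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Float dosage submatrix in the requested id orders."""
        rows = (
            slice(None)
            if animal_ids is None
            else np.asarray([self._animal_index[str(a)] for a in animal_ids], np.intp)
        )
        cols = (
            slice(None)
            if snp_ids is None
            else np.asarray([self._snp_index[str(s)] for s in snp_ids], np.intp)
        )
        out = self.values[rows]
        out = out[:, cols]
        return np.asarray(out, dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.animal_ids, columns=self.snp_ids)


def build_a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Rows/columns are returned in the pedigree's input order.  The matrix is
    exact for arbitrarily inbred pedigrees (validated elsewhere against
    Monte-Carlo gene dropping).
    """
    n = len(ped)
    order = ped.topo_order
    pos = np.empty(n, dtype=np.intp)  # animal index -> topo position
    pos[order] = np.arange(n)
    sire = np.asarray([pos[p] if p >= 0 else -1 for p in ped.parent[order, 0]])
    dam = np.asarray([pos[p] if p >= 0 else -1 for p in ped.parent[order, 1]])
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    out = A[np.ix_(pos, pos)]  # back to pedigree input order
    return RelationshipMatrix(list(ped.ids), out)


def build_grm(
    genotypes: np.ndarray | Genotypes,
    snp_ids: Sequence[str] | None = None,
    freqs: np.ndarray | str = "estimate",
    animal_ids: Sequence[str] | None = None,
) -> Grm:
    """VanRaden method-1 GRM from a dosage matrix.

    Parameters
    ----------
    genotypes
        Animals x SNPs dosage matrix in [0, 2] (or a :class:`Genotypes`).
    freqs
        Per-SNP frequency of the counted allele, or ``"estimate"`` to use
        the observed frequencies (the default; base-population frequencies
        may be supplied instead).
    """
    if isinstance(genotypes, Genotypes):
        animal_ids = animal_ids or genotypes.animal_ids
        snp_ids = snp_ids or genotypes.snp_ids
        M = np.asarray(genotypes.values, dtype=np.float64)
    else:
        M = np.asarray(genotypes, dtype=np.float64)
    n, m = M.shape
    if snp_ids is not None and len(snp_ids) != m:
        raise ValueError(f"{len(snp_ids)} snp_ids for {m} genotype columns")
    if animal_ids is None:
        animal_ids = [f"i{k}" for k in range(n)]
    if isinstance(freqs, str):
        if freqs != "estimate":
            raise ValueError("freqs must be an array or 'estimate'")
        p = M.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if p.shape != (m,):
            raise ValueError("freqs length does not match SNP count")
    poly = M.std(axis=0) > 0
    n_dropped = int(m - poly.sum())
    if poly.sum() == 0:
        raise ValueError("all SNPs monomorphic; GRM undefined")
    if n_dropped:
        log.info("build_grm: dropped %d monomorphic SNPs", n_dropped)
    Mp, pp = M[:, poly], p[poly]
    Z = Mp - 2.0 * pp
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    G = (Z @ Z.T) / denom
    kept = (
        tuple(np.asarray(snp_ids, dtype=object)[poly]) if snp_ids is not None else ()
    )
    return Grm(
        ids=[str(a) for a in animal_ids],
        values=G,
        snp_ids=kept,
        freqs=pp,
        n_dropped_monomorphic=n_dropped,
    )


def augment_snp_set(
    pathway_snps: SnpSet,
    all_snps: SnpMap,
    n_random: int,
    seed: int | np.random.Generator,
) -> SnpSet:
    """Add ``n_random`` genome-wide random SNPs to a pathway SNP set.

    The random SNPs are drawn uniformly without replacement from the SNPs
    not already in the set.  This mirrors the device of padding a
    positionally clustered SNP set with random genome-wide SNPs so that the
    resulting GRM is well conditioned.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    in_set = np.asarray([s in pathway_snps for s in all_snps.snp_id])
    candidates = all_snps.snp_id[~in_set]
    if n_random > len(candidates):
        raise ValueError(
            f"requested {n_random} random SNPs but only {len(candidates)} "
            "non-pathway SNPs are available"
        )
    if n_random == 0:
        return pathway_snps
    extra = rng.choice(candidates, size=n_random, replace=False)
    ids = sorted(set(pathway_snps.snp_ids) | set(extra))
    return SnpSet(f"{pathway_snps.pathway_name}+{n_random}rand", tuple(ids))
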