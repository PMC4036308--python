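"""Gene tables, pathways and windowed SNP sets.

Gene coordinates are 1-based and inclusive at both ends (NCBI-style), and
the window of a gene is ``[max(1, start - window_bp), stop + window_bp]``,
again inclusive at both ends.  A pathway's SNP set is the union over its
member genes' windows: a SNP shared by two overlapping gene windows (for
instance the STAT5A/STAT5B pair, whose bodies overlap) contributes exactly
once to any set-level statistic.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "GeneRecord",
    "Pathway",
    "SnpMap",
    "SnpSet",
    "load_gene_table",
    "load_pathways_gmt",
    "load_snp_map",
    "snps_in_window",
    "pathway_snp_set",
    "gene_pair_distances",
    "exclude_chromosome",
    "pathway_overlap",
    "packaged_gene_table",
    "packaged_pathways",
    "packaged_gene_universe",
]

_SUMMARY_ROW = re.compile(r"^\s*N\s*=", re.IGNORECASE)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: symbol plus a 1-based inclusive genomic interval."""

    symbol: str
    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError(f"gene {self.symbol!r}: empty chromosome")
        if self.start > self.stop:
            raise AnnotationError(
                f"gene {self.symbol!r}: start {self.start} > stop {self.stop}"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def window(self, window_bp: int) -> tuple[int, int]:
        """Inclusive window bounds, truncated at position 1."""
        if window_bp < 0:
            raise AnnotationError("window_bp must be >= 0")
        return max(1, self.start - window_bp), self.stop + window_bp


@dataclass(frozen=True)
class Pathway:
    """A named, ordered set of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise AnnotationError(f"pathway {self.name!r}: duplicate genes {dupes}")

    def __len__(self) -> int:
        return len(self.genes)


def _chrom_key(c: str) -> tuple[int, int | str]:
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


class SnpMap:
    """Ordered SNP identifiers with chromosome and 1-based position.

    SNPs are stored sorted by (chromosome, position); lookups of the SNPs
    falling in a genomic interval use binary search per chromosome.
    """

    def __init__(
        self,
        snp_ids: Sequence[str],
        chroms: Sequence[str],
        positions: Sequence[int],
    ) -> None:
        ids = np.asarray(snp_ids, dtype=object)
        chrom = np.asarray([str(c) for c in chroms], dtype=object)
        pos = np.asarray(positions, dtype=np.int64)
        if not (len(ids) == len(chrom) == len(pos)):
            raise AnnotationError("snp_ids, chroms, positions must have equal length")
        if np.any(pos < 0):
            raise AnnotationError("SNP positions must be non-negative")
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate SNP identifiers in map")
        order = sorted(range(len(ids)), key=lambda i: (_chrom_key(chrom[i]), pos[i]))
        order = np.asarray(order, dtype=np.intp)
        self.snp_id = ids[order]
        self.chrom = chrom[order]
        self.pos = pos[order]
        self._index: dict[str, int] = {s: i for i, s in enumerate(self.snp_id)}
        self._chrom_slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                self._chrom_slices[self.chrom[start]] = slice(start, i)
                start = i

    def __len__(self) -> int:
        return len(self.snp_id)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def index_of(self, snp_id: str) -> int:
        return self._index[snp_id]

    def chrom_slice(self, chrom: str) -> slice:
        """Row slice of a chromosome's SNPs (empty slice if absent)."""
        return self._chrom_slices.get(str(chrom), slice(0, 0))

    def indices_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        return np.asarray([self._index[s] for s in snp_ids], dtype=np.intp)

    def indices_in_window(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """Row indices of SNPs on ``chrom`` with lo <= pos <= hi (inclusive)."""
        sl = self._chrom_slices.get(str(chrom))
        if sl is None:
            return np.empty(0, dtype=np.intp)
        pos = self.pos[sl]
        a = int(np.searchsorted(pos, lo, side="left"))
        b = int(np.searchsorted(pos, hi, side="right"))
        return np.arange(sl.start + a, sl.start + b, dtype=np.intp)

    def ids_in_window(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        return self.snp_id[self.indices_in_window(chrom, lo, hi)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpMap":
        return cls(df["snp_id"].tolist(), df["chrom"].tolist(), df["pos"].tolist())


@dataclass(frozen=True)
class SnpSet:
    """A deduplicated SNP set attributed to a pathway (or gene)."""

    pathway_name: str
    snp_ids: tuple[str, ...]
    _members: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        members = frozenset(self.snp_ids)
        if len(members) != len(self.snp_ids):
            raise AnnotationError(
                f"SnpSet {self.pathway_name!r}: duplicate SNP identifiers"
            )
        object.__setattr__(self, "_members", members)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._members

    def union(self, other: "SnpSet", name: str | None = None) -> "SnpSet":
        ids = sorted(self._members | other._members)
        return SnpSet(name or f"{self.pathway_name}|{other.pathway_name}", tuple(ids))


# ---------------------------------------------------------------------------
# file parsing


def _norm_cols(cols: Sequence[str]) -> list[str]:
    aliases = {"gene": "symbol", "chr": "chrom", "chromosome": "chrom", "end": "stop"}
    out = []
    for c in cols:
        c = str(c).strip().lower()
        out.append(aliases.get(c, c))
    return out


def load_gene_table(path) -> list[GeneRecord]:
    """Parse a TSV gene table (symbol, chrom, start, stop).

    Summary rows (blank coordinates, or a symbol like ``N = 64``) are
    skipped.  Malformed coordinates raise a parse error naming the line;
    start > stop and duplicate symbols raise validation errors.
    """
    records: list[GeneRecord] = []
    seen: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise AnnotationError(f"{path}: empty gene table")
        cols = _norm_cols(header.rstrip("\n").split("\t"))
        try:
            i_sym = cols.index("symbol")
            i_chr = cols.index("chrom")
            i_start = cols.index("start")
            i_stop = cols.index("stop")
        except ValueError as exc:
            raise AnnotationError(
                f"{path}: header must contain symbol/chrom/start/stop, got {cols}"
            ) from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(i_sym, i_chr, i_start, i_stop):
                fields += [""] * 4
            symbol = fields[i_sym].strip()
            raw_start, raw_stop = fields[i_start].strip(), fields[i_stop].strip()
            if _SUMMARY_ROW.match(symbol) or (not raw_start and not raw_stop):
                continue  # printed-table summary row
            try:
                start, stop = int(raw_start), int(raw_stop)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path} line {lineno}: non-integer coordinate "
                    f"({raw_start!r}, {raw_stop!r})"
                ) from exc
            if symbol in seen:
                raise AnnotationError(
                    f"{path} line {lineno}: duplicate gene symbol {symbol!r} "
                    f"(first seen on line {seen[symbol]})"
                )
            seen[symbol] = lineno
            try:
                records.append(GeneRecord(symbol, fields[i_chr].strip(), start, stop))
            except AnnotationError as exc:
                raise AnnotationError(f"{path} line {lineno}: {exc}") from exc
    if not records:
        raise AnnotationError(f"{path}: no gene records parsed")
    return records


def load_pathways_gmt(path) -> list[Pathway]:
    """Parse a GMT-like pathway file (name, optional description, genes)."""
    pathways = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 2:
                raise AnnotationError(f"{path} line {lineno}: need name and genes")
            genes = [g for g in fields[2:] if g] or [fields[1]]
            pathways.append(Pathway(fields[0], tuple(genes)))
    if not pathways:
        raise AnnotationError(f"{path}: no pathways parsed")
    return pathways


def load_snp_map(path) -> SnpMap:
    """Parse a bim-like TSV SNP map.

    Three columns are read as (chrom, snp_id, pos); four or more columns are
    treated as plink bim layout (chrom, snp_id, genetic distance, pos) and
    the genetic-distance column is ignored.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise AnnotationError(f"{path}: SNP map needs >= 3 columns")
    pos_col = 2 if df.shape[1] == 3 else 3
    return SnpMap(
        df[1].tolist(), df[0].tolist(), df[pos_col].astype(np.int64).tolist()
    )


# ---------------------------------------------------------------------------
# windowed SNP sets


def snps_in_window(gene: GeneRecord, snps: SnpMap, window_bp: int) -> SnpSet:
    """SNPs within the gene body extended by ``window_bp`` on each side."""
    lo, hi = gene.window(window_bp)
    if str(gene.chrom) not in snps._chrom_slices:
        log.warning(
            "chromosome %s of gene %s absent from SNP map; empty set",
            gene.chrom,
            gene.symbol,
        )
        return SnpSet(gene.symbol, ())
    ids = snps.ids_in_window(gene.chrom, lo, hi)
    return SnpSet(gene.symbol, tuple(ids))


def pathway_snp_set(
    pathway: Pathway,
    gene_table: Sequence[GeneRecord],
    snps: SnpMap,
    window_bp: int,
) -> SnpSet:
    """Union of member-gene windows; each SNP counted once."""
    if len(pathway) == 0:
        raise AnnotationError(f"pathway {pathway.name!r} is empty")
    by_symbol = {g.symbol: g for g in gene_table}
    missing = [g for g in pathway.genes if g not in by_symbol]
    if missing:
        raise AnnotationError(
            f"pathway {pathway.name!r}: unresolvable gene symbols {missing}"
        )
    idx_arrays = []
    for sym in pathway.genes:
        gene = by_symbol[sym]
        lo, hi = gene.window(window_bp)
        idx_arrays.append(snps.indices_in_window(gene.chrom, lo, hi))
    idx = np.unique(np.concatenate(idx_arrays)) if idx_arrays else np.empty(0, int)
    return SnpSet(pathway.name, tuple(snps.snp_id[idx]))


def gene_pair_distances(
    genes: Sequence[GeneRecord],
) -> list[tuple[str, int]]:
    """Gap between intervals for every same-chromosome gene pair.

    Overlapping intervals have distance 0; cross-chromosome pairs are
    omitted.  Used as a spacing diagnostic comparing candidate pathways to
    random control gene sets.
    """
    if len(genes) < 1:
        raise AnnotationError("need at least one gene")
    out: list[tuple[str, int]] = []
    for a, b in itertools.combinations(genes, 2):
        if a.chrom != b.chrom:
            continue
        gap = max(a.start, b.start) - min(a.stop, b.stop) - 1
        out.append((a.chrom, max(0, gap)))
    return out


def exclude_chromosome(items, chrom: str, snps: SnpMap | None = None):
    """Drop all entries on ``chrom``; other entries are untouched.

    Works on a list of :class:`GeneRecord` or on a :class:`SnpSet` (the
    latter requires the SNP map to resolve chromosomes).  An absent
    chromosome leaves the input unchanged.
    """
    chrom = str(chrom)
    if isinstance(items, SnpSet):
        if snps is None:
            raise AnnotationError("excluding a chromosome from a SnpSet needs a SnpMap")
        kept = tuple(
            s for s in items.snp_ids if snps.chrom[snps.index_of(s)] != chrom
        )
        return SnpSet(items.pathway_name, kept)
    return [g for g in items if str(g.chrom) != chrom]


def pathway_overlap(
    pathways: Sequence[Pathway],
) -> dict[frozenset[str], list[str]]:
    """Venn-style exclusive membership regions over >= 2 pathways.

    Returns a mapping from the set of pathway names containing a gene to
    the sorted genes in exactly that combination; regions partition the
    union of all pathway gene sets.
    """
    if len(pathways) < 2:
        raise AnnotationError("pathway_overlap needs >= 2 pathways")
    regions: dict[frozenset[str], list[str]] = {}
    union = sorted({g for p in pathways for g in p.genes})
    for gene in union:
        key = frozenset(p.name for p in pathways if gene in p.genes)
        regions.setdefault(key, []).append(gene)
    return regions


# ---------------------------------------------------------------------------
# packaged fixtures: the three lactation pathway gene tables

_PATHWAY_FILES = {
    "mammary_development": "mammary_development.tsv",
    "prolactin_signalling": "prolactin_signalling.tsv",
    "involution": "involution.tsv",
}


def _data_path(name: str):
    return resources.files("lactpath.data").joinpath(name)


def packaged_gene_table(pathway: str) -> list[GeneRecord]:
    """Gene table for one packaged lactation pathway.

    ``pathway`` is one of ``mammary_development`` (64 genes),
    ``prolactin_signalling`` (27) or ``involution`` (40).
    """
    try:
        fname = _PATHWAY_FILES[pathway]
    except KeyError as exc:
        raise AnnotationError(
            f"unknown packaged pathway {pathway!r}; choose from {list(_PATHWAY_FILES)}"
        ) from exc
    return load_gene_table(_data_path(fname))


def packaged_pathways() -> list[Pathway]:
    """The three packaged lactation pathways as gene-symbol sets."""
    return load_pathways_gmt(_data_path("lactation_pathways.gmt"))


def packaged_gene_universe() -> list[GeneRecord]:
    """Deduplicated union of the three packaged gene tables (105 genes)."""
    seen: dict[str, GeneRecord] = {}
    for name in _PATHWAY_FILES:
        for rec in packaged_gene_table(name):
            if rec.symbol in seen and seen[rec.symbol] != rec:
                raise AnnotationError(
                    f"inconsistent coordinates for {rec.symbol} across tables"
                )
            seen.setdefault(rec.symbol, rec)
    return list(seen.values())
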