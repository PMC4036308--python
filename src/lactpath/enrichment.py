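"""PropSig and its experiment-wise permutation test against random gene sets.

The pathway statistic is the proportion of the pathway's SNPs whose
single-SNP association p-value is at or below a per-SNP level alpha
(PropSig).  Its null distribution is built by repeatedly drawing a random
gene set of the same gene count from an annotation universe, forming that
set's windowed SNP union, and recomputing PropSig from the same per-SNP
p-values.  The experiment-wise critical value at level alpha is the
ceil(alpha * n_perm)-th largest null value — with 10,000 permutations at
alpha = 0.05, the 500th highest.  A pathway is declared significant when
its observed PropSig strictly exceeds the critical value.

Random sets are matched on gene count only (not SNP count, chromosome or
spacing); the spacing mismatch can be quantified with
:func:`lactpath.annotation.gene_pair_distances` but no correction is
applied.  Draws whose windowed SNP union is empty are redrawn (dropping
them would bias the null toward zero); the redraw count is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationError, GeneRecord, Pathway, SnpMap

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "NullDistribution",
    "prop_sig",
    "sample_random_gene_set",
    "build_null_distribution",
    "enrichment_test",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed PropSig of one pathway/trait against its permutation null."""

    pathway_name: str
    trait: str
    n_snps: int
    n_sig: int
    propsig: float
    threshold: float
    significant: bool
    empirical_p: float


@dataclass(frozen=True)
class NullDistribution:
    """Sorted permutation PropSig values with the experiment-wise threshold."""

    values: np.ndarray
    n_perm: int
    alpha: float
    threshold: float
    threshold_rank: int  # 1-based from the top
    seed: int | None
    k_genes: int
    window_bp: int
    n_redraws: int
    excluded_chroms: tuple[str, ...] = ()


def prop_sig(pvalues: Sequence[float], alpha: float) -> tuple[int, float]:
    """Count and proportion of p-values significant at p <= alpha."""
    p = np.asarray(pvalues, dtype=np.float64)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no (finite) p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n_sig = int(np.sum(p <= alpha))
    return n_sig, n_sig / p.size


def sample_random_gene_set(
    universe: Sequence[GeneRecord],
    k: int,
    seed: int | np.random.Generator,
    excluded_chroms: Sequence[str] | None = None,
    name: str = "random",
) -> Pathway:
    """Draw k distinct genes uniformly without replacement."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    excl = {str(c) for c in (excluded_chroms or ())}
    pool = [g for g in universe if str(g.chrom) not in excl]
    if k > len(pool):
        raise ValueError(
            f"cannot draw {k} genes from a universe of {len(pool)} "
            f"(after excluding chromosomes {sorted(excl)})"
        )
    idx = rng.choice(len(pool), size=k, replace=False)
    return Pathway(name, tuple(pool[i].symbol for i in idx))


def _pvalue_array(snps: SnpMap, pvalues) -> np.ndarray:
    """Per-SNP p-values aligned to the map order; missing SNPs become NaN."""
    arr = np.full(len(snps), np.nan)
    if isinstance(pvalues, pd.DataFrame):
        pvalues = pvalues.set_index("snp_id")["pvalue"]
    if isinstance(pvalues, pd.Series):
        items = pvalues.items()
    elif isinstance(pvalues, Mapping):
        items = pvalues.items()
    else:
        raise TypeError("pvalues must be a mapping, Series or association frame")
    for snp_id, p in items:
        if snp_id in snps:
            arr[snps.index_of(snp_id)] = p
    return arr


def build_null_distribution(
    universe: Sequence[GeneRecord],
    k: int,
    snps: SnpMap,
    pvalues,
    n_perm: int,
    alpha: float = 0.05,
    window_bp: int = 100_000,
    seed: int | None = 0,
    excluded_chroms: Sequence[str] | None = None,
) -> NullDistribution:
    """Permutation null of PropSig from random k-gene sets.

    ``pvalues`` maps snp_id -> association p-value (dict, Series, or an
    association DataFrame with snp_id/pvalue columns).  SNPs without a
    p-value do not contribute to any set.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    excl = {str(c) for c in (excluded_chroms or ())}
    pool = [g for g in universe if str(g.chrom) not in excl]
    if k > len(pool):
        raise ValueError(f"k={k} exceeds usable universe of {len(pool)} genes")

    p_arr = _pvalue_array(snps, pvalues)
    valid = np.isfinite(p_arr)
    sig = valid & (p_arr <= alpha)

    gene_snp_idx = []
    for g in pool:
        lo, hi = g.window(window_bp)
        gene_snp_idx.append(snps.indices_in_window(g.chrom, lo, hi))

    values = np.empty(n_perm)
    n_redraws = 0
    max_attempts = 100 * n_perm + 1000
    attempts = 0
    i = 0
    while i < n_perm:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("too many empty gene-set redraws; check inputs")
        choice = rng.choice(len(pool), size=k, replace=False)
        idx = np.unique(np.concatenate([gene_snp_idx[c] for c in choice]))
        idx = idx[valid[idx]]
        if idx.size == 0:
            n_redraws += 1
            continue
        values[i] = sig[idx].sum() / idx.size
        i += 1
    if n_redraws:
        log.info("null distribution: %d empty gene-set redraws", n_redraws)

    rank = math.ceil(alpha * n_perm)  # 1-based from the top
    rank = min(rank, n_perm)
    threshold = float(np.sort(values)[n_perm - rank])
    return NullDistribution(
        values=values,
        n_perm=n_perm,
        alpha=alpha,
        threshold=threshold,
        threshold_rank=rank,
        seed=seed if isinstance(seed, int) else None,
        k_genes=k,
        window_bp=window_bp,
        n_redraws=n_redraws,
        excluded_chroms=tuple(sorted(excl)),
    )


def enrichment_test(
    pathway_name: str,
    trait: str,
    pvalues: Sequence[float],
    null: NullDistribution,
    alpha: float | None = None,
) -> EnrichmentResult:
    """Compare a pathway's observed PropSig with its permutation null.

    ``pvalues`` are the association p-values of the pathway's own SNP set.
    Significance requires the observed PropSig to strictly exceed the
    experiment-wise threshold; the empirical p-value uses the add-one
    estimator (1 + #{null >= observed}) / (n_perm + 1).
    """
    if alpha is not None and not np.isclose(alpha, null.alpha):
        raise ValueError(
            f"alpha mismatch: requested {alpha}, null built at {null.alpha}"
        )
    n_sig, propsig = prop_sig(pvalues, null.alpha)
    emp_p = (1 + int(np.sum(null.values >= propsig))) / (null.n_perm + 1)
    return EnrichmentResult(
        pathway_name=pathway_name,
        trait=trait,
        n_snps=int(np.sum(np.isfinite(np.asarray(pvalues, dtype=float)))),
        n_sig=n_sig,
        propsig=propsig,
        threshold=null.threshold,
        significant=bool(propsig > null.threshold),
        empirical_p=emp_p,
    )
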