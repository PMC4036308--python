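"""Stage orchestration: gwas, enrichment and variance partitioning runs.

Thin glue over the library modules operating on a :class:`lactpath.io.Dataset`:
each stage aligns phenotype records, genotypes and relationship matrices by
animal id, runs the corresponding analysis, and returns plain DataFrames
ready to be written with a provenance header.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import Pathway, exclude_chromosome, pathway_snp_set
from .enrichment import build_null_distribution, enrichment_test
from .io import Dataset
from .lmm import design_matrix, fit_null_model, snp_association
from .relatedness import build_a_matrix
from .varcomp import run_partitioning

log = logging.getLogger(__name__)

__all__ = ["gwas_inputs", "run_gwas", "run_enrichment", "run_varcomp"]


def gwas_inputs(ds: Dataset, trait: str):
    """Aligned (records, y, X, weights, dosage matrix) for one trait."""
    rec = ds.phenotypes[ds.phenotypes["trait"] == trait].reset_index(drop=True)
    if rec.empty:
        raise ValueError(
            f"unknown trait {trait!r}; dataset has {ds.traits}"
        )
    if rec["animal"].duplicated().any():
        raise ValueError(f"trait {trait!r}: multiple records per animal")
    y = rec["value"].to_numpy(dtype=np.float64)
    X = design_matrix(rec)
    w = rec["weight"].to_numpy(dtype=np.float64)
    W = ds.genotypes.dosages(animal_ids=rec["animal"])
    return rec, y, X, w, W


def run_gwas(ds: Dataset, trait: str, mode: str = "fast") -> pd.DataFrame:
    """Weighted mixed-model association of every SNP with one trait."""
    rec, y, X, w, W = gwas_inputs(ds, trait)
    A = build_a_matrix(ds.pedigree).submatrix(rec["animal"])
    null = fit_null_model(y, X, A, w)
    log.info(
        "null model for %s: sigma_a2=%.4f sigma_e2=%.4f (identifiable=%s)",
        trait,
        null.sigma_a2,
        null.sigma_e2,
        null.identifiable,
    )
    res = snp_association(
        W, y, X, A, w, mode=mode, null=null, snp_ids=list(ds.genotypes.snp_ids)
    )
    res.insert(1, "chrom", [ds.snps.chrom[ds.snps.index_of(s)] for s in res.snp_id])
    res.insert(2, "pos", [ds.snps.pos[ds.snps.index_of(s)] for s in res.snp_id])
    res["trait"] = trait
    return res


def run_enrichment(
    ds: Dataset,
    assoc: pd.DataFrame,
    pathways: Sequence[Pathway] | None = None,
    *,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    window_bp: int = 100_000,
    seed: int = 0,
    exclude_chroms: Sequence[str] = (),
) -> pd.DataFrame:
    """Permutation enrichment test of each pathway for one association run.

    When ``exclude_chroms`` is given, the excluded chromosomes are removed
    from the gene universe, from every pathway SNP set and from the
    permutation draws (the chromosome-exclusion re-analysis).
    """
    pathways = list(pathways) if pathways is not None else list(ds.pathways)
    trait = str(assoc["trait"].iloc[0]) if "trait" in assoc else ""
    pvals = assoc.set_index("snp_id")["pvalue"].dropna()
    universe = ds.genes
    for c in exclude_chroms:
        universe = exclude_chromosome(universe, c)
    rows = []
    nulls: dict[int, object] = {}
    for i, pw in enumerate(pathways):
        genes_in = [
            g
            for g in pw.genes
            if any(r.symbol == g for r in universe)
        ]
        pw_used = Pathway(pw.name, tuple(genes_in))
        if len(pw_used) == 0:
            raise ValueError(
                f"pathway {pw.name!r} has no genes left after exclusions"
            )
        pset = pathway_snp_set(pw_used, universe, ds.snps, window_bp)
        k = len(pw_used)
        if k not in nulls:
            nulls[k] = build_null_distribution(
                universe,
                k,
                ds.snps,
                pvals,
                n_perm=n_perm,
                alpha=alpha,
                window_bp=window_bp,
                seed=seed + i,
                excluded_chroms=exclude_chroms,
            )
        null = nulls[k]
        obs_p = pvals.reindex(list(pset.snp_ids)).dropna().to_numpy()
        res = enrichment_test(pw.name, trait, obs_p, null)
        rows.append(
            {
                "pathway": res.pathway_name,
                "trait": res.trait,
                "n_genes": k,
                "n_snps": res.n_snps,
                "n_sig": res.n_sig,
                "propsig": res.propsig,
                "null_mean": float(np.mean(null.values)),
                "threshold": res.threshold,
                "threshold_rank": null.threshold_rank,
                "significant": res.significant,
                "empirical_p": res.empirical_p,
                "n_perm": n_perm,
                "alpha": alpha,
                "window_bp": window_bp,
                "excluded_chroms": ",".join(str(c) for c in exclude_chroms),
            }
        )
    return pd.DataFrame(rows)


def run_varcomp(
    ds: Dataset,
    trait: str,
    pathway: str | Pathway,
    *,
    window_bp: int = 100_000,
    n_random: int = 4000,
    n_replicates: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additional-variance partitioning for one pathway and trait."""
    if isinstance(pathway, str):
        match = [p for p in ds.pathways if p.name == pathway]
        if not match:
            raise ValueError(
                f"pathway {pathway!r} not in dataset "
                f"({[p.name for p in ds.pathways]})"
            )
        pathway = match[0]
    rec, y, X, w, _ = gwas_inputs(ds, trait)
    result, details = run_partitioning(
        y,
        X,
        w,
        ds.genotypes,
        pathway,
        ds.genes,
        ds.snps,
        trait=trait,
        window_bp=window_bp,
        n_random=n_random,
        n_replicates=n_replicates,
        seed=seed,
        animal_ids=list(rec["animal"]),
    )
    summary = pd.DataFrame(
        [
            {
                "pathway": result.pathway_name,
                "trait": trait,
                "delta_pct": result.delta,
                "se_pct": result.se,
                "n_replicates": result.n_replicates,
                "pathway_prop_g": result.pathway_prop_g,
                "baseline_mean_prop_g": float(np.mean(result.baseline_prop_g)),
                "n_random": n_random,
                "window_bp": window_bp,
                "seed": seed,
            }
        ]
    )
    return summary, details
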