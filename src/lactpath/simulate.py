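"""Synthetic two-breed dairy population generator.

Emulates, at desk scale, the design of a pathway GWAS in dairy cattle: a
gene universe with positional clustering, LD-structured SNP genotypes
transmitted through a multi-generation two-breed pedigree, candidate
pathways drawn from the universe, and phenotype records of two kinds —
cows carry the mean deviation over their lactations (heritability h2,
repeatability r2), bulls carry the mean deviation of their simulated
daughters.  Causal variants can be concentrated inside the windows of a
target pathway (``enrichment_fraction``) or spread genome-wide.

Design notes
------------
* LD: founder haplotypes are mosaics of a small per-breed pool of
  ancestral block haplotypes.  Within a block LD is strong; across blocks
  it vanishes.  This reproduces the clustered-SNP redundancy that makes a
  pathway-only GRM ill conditioned, without coalescent machinery.
* Bull records are built by actually averaging simulated daughter
  deviations (each daughter: half the sire breeding value, a random dam
  contribution, Mendelian sampling, one lactation's residual), so the
  variance structure assumed by the bull weighting formula is emergent,
  not imposed.
* Two breeds are separate founder pools with Fst-like divergent allele
  frequencies; breed enters records as a fixed shift (removed again by
  within-breed standardisation, exactly as in the emulated design).
* Everything is driven by one master seed through named child streams, so
  all outputs are byte-identical given the seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, Pathway, SnpMap, pathway_snp_set
from .lmm import TraitParams, record_weights, standardise_records
from .relatedness import Genotypes, Pedigree

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_map_and_genes",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_dataset",
    "SimulatedDataset",
    "default_traits",
]

RECOMB_RATE_PER_BP = 1e-8  # 1 cM/Mb


def default_traits() -> tuple[TraitParams, ...]:
    """The five milk production traits with their customary parameters."""
    return (
        TraitParams("milk", h2=0.33, r2=0.56),
        TraitParams("fat", h2=0.33, r2=0.56),
        TraitParams("protein", h2=0.33, r2=0.56),
        TraitParams("fat_pct", h2=0.5, r2=0.56, weight_bulls=False),
        TraitParams("protein_pct", h2=0.5, r2=0.56, weight_bulls=False),
    )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the desk-scale preset.

    The preset (2,000 animals, 5,000 SNPs, 1,500 genes, one 40-gene
    pathway on 10 x 30 Mb chromosomes) keeps every full-pipeline run in
    minutes while roughly preserving the design ratios of a dense-chip
    two-breed cattle study: the candidate pathway is a small fraction of
    the gene universe (2.7% here) so random control gene sets rarely touch
    it, as in a genome-wide annotation.
    """

    seed: int
    # genome
    n_chromosomes: int = 10
    chrom_length_bp: int = 30_000_000
    n_snps: int = 5_000
    n_genes: int = 1_500
    gene_length_log_mean: float = np.log(20_000.0)
    gene_length_log_sd: float = 0.6
    cluster_fraction: float = 0.3  # fraction of inter-gene gaps drawn short
    cluster_gap_bp: float = 30_000.0
    # pathways
    pathway_sizes: tuple[int, ...] = (40,)
    window_bp: int = 100_000
    # population
    n_founders: int = 200
    n_generations: int = 3
    n_animals: int = 2_000
    breeds: tuple[tuple[str, float], ...] = (("holstein", 0.65), ("jersey", 0.35))
    sex_ratio_male: float = 0.25  # bull share of genotyped animals
    fst: float = 0.05
    n_ancestral_haplotypes: int = 16
    ld_block_bp: int = 250_000  # 0 => every SNP independent
    maf_low: float = 0.05
    maf_high: float = 0.95
    # traits / causal architecture
    traits: tuple[TraitParams, ...] = field(
        default_factory=lambda: (TraitParams("milk", h2=0.33, r2=0.56),)
    )
    n_causal: int = 50
    enrichment_fraction: float = 0.0
    target_pathway: str | None = None
    shared_causal: bool = False  # share causal loci (not effects) across traits
    # record counts
    bull_daughters_mean: float = 40.0
    cow_lactations_mean: float = 2.2
    max_lactations: int = 8
    breed_effects: tuple[tuple[str, float], ...] = (
        ("holstein", 0.0),
        ("jersey", -0.25),
    )

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_snps <= 0 or self.n_founders < 2 or self.n_animals < 2:
            raise ValueError("counts must be positive (and >= 2 animals/founders)")
        if not 0.0 <= self.enrichment_fraction <= 1.0:
            raise ValueError("enrichment_fraction must be in [0, 1]")
        props = [p for _, p in self.breeds]
        if abs(sum(props) - 1.0) > 1e-6 or min(props) <= 0:
            raise ValueError("breed proportions must be positive and sum to 1")
        for t in self.traits:
            if t.r2 is not None and t.h2 > t.r2:
                raise ValueError(f"trait {t.name}: h2 > r2")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset (for recovery tests)."""

    causal_ids: dict[str, tuple[str, ...]]
    causal_effects: dict[str, np.ndarray]
    breeding_values: dict[str, np.ndarray]  # aligned with animal order
    h2: dict[str, float]
    r2: dict[str, float | None]
    record_counts: pd.DataFrame
    animal_ids: list[str]


@dataclass
class SimulatedDataset:
    """Everything one analysis run needs, in memory."""

    config: SimulationConfig
    genes: list[GeneRecord]
    pathways: list[Pathway]
    snps: SnpMap
    pedigree: Pedigree
    genotypes: Genotypes
    animals: pd.DataFrame  # animal, sex, breed, generation
    phenotypes: pd.DataFrame  # animal, sex, breed, trait, value, n, weight
    truth: SimTruth


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# genome


def simulate_map_and_genes(
    cfg: SimulationConfig,
) -> tuple[SnpMap, list[GeneRecord], list[Pathway]]:
    """Gene universe with clustered placement, uniform SNPs, pathways."""
    rng_genes, rng_snps, rng_paths = _streams(cfg.seed, 3)

    counts = rng_genes.multinomial(
        cfg.n_genes, np.full(cfg.n_chromosomes, 1.0 / cfg.n_chromosomes)
    )
    genes: list[GeneRecord] = []
    gi = 0
    for c in range(cfg.n_chromosomes):
        n_c = int(counts[c])
        if n_c == 0:
            continue
        lengths = np.exp(
            rng_genes.normal(cfg.gene_length_log_mean, cfg.gene_length_log_sd, n_c)
        ).astype(np.int64)
        lengths = np.clip(lengths, 1_000, None)
        if lengths.sum() >= cfg.chrom_length_bp:
            raise ValueError(
                f"infeasible gene packing on chromosome {c + 1}: "
                f"{lengths.sum()} bp of genes in {cfg.chrom_length_bp} bp"
            )
        short = rng_genes.random(n_c + 1) < cfg.cluster_fraction
        raw_gaps = np.where(
            short,
            rng_genes.exponential(cfg.cluster_gap_bp, n_c + 1),
            rng_genes.exponential(10.0 * cfg.cluster_gap_bp, n_c + 1),
        )
        free = cfg.chrom_length_bp - int(lengths.sum())
        gaps = np.floor(raw_gaps / raw_gaps.sum() * free).astype(np.int64)
        pos = 1
        for j in range(n_c):
            pos += int(gaps[j])
            start = max(1, pos)
            stop = start + int(lengths[j]) - 1
            genes.append(GeneRecord(f"G{gi:04d}", str(c + 1), start, stop))
            pos = stop + 1
            gi += 1

    # SNPs uniform over the genome, deduplicated positions per chromosome
    snp_counts = rng_snps.multinomial(
        cfg.n_snps, np.full(cfg.n_chromosomes, 1.0 / cfg.n_chromosomes)
    )
    ids, chroms, positions = [], [], []
    k = 0
    for c in range(cfg.n_chromosomes):
        want = int(snp_counts[c])
        pos = np.unique(rng_snps.integers(1, cfg.chrom_length_bp + 1, size=want))
        while pos.size < want:  # rare collisions
            extra = rng_snps.integers(1, cfg.chrom_length_bp + 1, size=want - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = pos[:want]
        for p in pos:
            ids.append(f"s{k:06d}")
            chroms.append(str(c + 1))
            positions.append(int(p))
            k += 1
    snpmap = SnpMap(ids, chroms, positions)

    pathways = []
    for pi, size in enumerate(cfg.pathway_sizes, start=1):
        if size > len(genes):
            raise ValueError(f"pathway size {size} exceeds {len(genes)} genes")
        idx = rng_paths.choice(len(genes), size=size, replace=False)
        pathways.append(
            Pathway(f"pathway_{pi}", tuple(genes[i].symbol for i in sorted(idx)))
        )
    return snpmap, genes, pathways


# ---------------------------------------------------------------------------
# population


def _founder_haplotypes(
    cfg: SimulationConfig, snpmap: SnpMap, n_hap: int, breed_freqs: np.ndarray,
    block_of_snp: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Founder haplotypes as mosaics of ancestral block haplotypes."""
    n_snps = len(snpmap)
    n_anc = cfg.n_ancestral_haplotypes
    anc = (rng.random((n_anc, n_snps)) < breed_freqs).astype(np.int8)
    n_blocks = int(block_of_snp.max()) + 1
    choice = rng.integers(0, n_anc, size=(n_hap, n_blocks))
    return anc[choice[:, block_of_snp], np.arange(n_snps)]


def _meiosis(
    haps: np.ndarray, chrom_slices: list[slice], chrom_pos: list[np.ndarray],
    rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a (2, n_snps) parental haplotype pair."""
    gamete = np.empty(haps.shape[1], dtype=np.int8)
    for sl, pos in zip(chrom_slices, chrom_pos):
        span = int(pos[-1] - pos[0]) if pos.size > 1 else 0
        n_x = rng.poisson(span * RECOMB_RATE_PER_BP)
        phase = int(rng.integers(0, 2))
        if n_x == 0:
            gamete[sl] = haps[phase, sl]
            continue
        xpos = np.sort(rng.integers(pos[0], pos[-1] + 1, size=n_x))
        seg = np.searchsorted(xpos, pos, side="right")
        cols = np.arange(sl.start, sl.stop)
        gamete[sl] = haps[(phase + seg) % 2, cols]
    return gamete


def simulate_population(
    cfg: SimulationConfig, snpmap: SnpMap
) -> tuple[Pedigree, Genotypes, pd.DataFrame]:
    """Two-breed pedigree with gene-dropped, recombining genotypes.

    Returns the pedigree, the dosage matrix and an animal table with sex,
    breed and generation.
    """
    rng_freq, rng_found, rng_ped, rng_meio = _streams(cfg.seed + 1, 4)
    n_snps = len(snpmap)

    # block structure by physical position
    if cfg.ld_block_bp > 0:
        block_parts = []
        offset = 0
        for chrom in snpmap.chromosomes:
            sl = snpmap.chrom_slice(chrom)
            blk = np.unique(snpmap.pos[sl] // cfg.ld_block_bp, return_inverse=True)[1]
            blk = blk + offset
            block_parts.append(blk)
            offset = int(blk.max()) + 1 if blk.size else offset
        block_of_snp = np.concatenate(block_parts)
    else:
        block_of_snp = np.arange(n_snps)

    # breed allele frequencies around a shared ancestral frequency
    p0 = rng_freq.uniform(cfg.maf_low, cfg.maf_high, size=n_snps)
    breed_names = [b for b, _ in cfg.breeds]
    freqs = {}
    for b in breed_names:
        if cfg.fst > 0:
            a = p0 * (1.0 - cfg.fst) / cfg.fst
            bb = (1.0 - p0) * (1.0 - cfg.fst) / cfg.fst
            pb = rng_freq.beta(np.maximum(a, 1e-3), np.maximum(bb, 1e-3))
        else:
            pb = p0.copy()
        freqs[b] = np.clip(pb, 0.01, 0.99)

    # founders
    props = np.asarray([p for _, p in cfg.breeds])
    founder_counts = np.maximum(
        np.round(props * cfg.n_founders).astype(int), 2
    )
    founder_counts[-1] = max(2, cfg.n_founders - int(founder_counts[:-1].sum()))
    n_founders = int(founder_counts.sum())

    animal_ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    sexes: list[str] = []
    breeds_out: list[str] = []
    gens: list[int] = []
    haplo = np.empty((max(cfg.n_animals, n_founders) + 2, 2, n_snps), dtype=np.int8)

    idx = 0
    by_breed_gen: dict[tuple[str, int, str], list[int]] = {}
    for b, n_b in zip(breed_names, founder_counts):
        H = _founder_haplotypes(
            cfg, snpmap, 2 * int(n_b), freqs[b], block_of_snp, rng_found
        )
        for j in range(int(n_b)):
            aid = f"A{idx:05d}"
            if j < 2 and cfg.n_generations > 0:
                sex = "M" if j == 0 else "F"  # breeding needs both sexes
            else:
                sex = "M" if rng_ped.random() < cfg.sex_ratio_male else "F"
            animal_ids.append(aid)
            sires.append("0")
            dams.append("0")
            sexes.append(sex)
            breeds_out.append(b)
            gens.append(0)
            haplo[idx] = H[2 * j : 2 * j + 2]
            by_breed_gen.setdefault((b, 0, sex), []).append(idx)
            idx += 1

    chrom_slices = [snpmap.chrom_slice(c) for c in snpmap.chromosomes]
    chrom_pos = [snpmap.pos[sl] for sl in chrom_slices]

    n_off_total = cfg.n_animals - n_founders
    if n_off_total < 0:
        raise ValueError("n_animals smaller than the founder count")
    if cfg.n_generations == 0:
        if n_off_total:
            raise ValueError("n_generations=0 requires n_animals == n_founders")
        per_gen: list[int] = []
    else:
        per_gen = [n_off_total // cfg.n_generations] * cfg.n_generations
        per_gen[-1] += n_off_total - sum(per_gen)
    for g in range(1, cfg.n_generations + 1):
        breed_draw = rng_ped.choice(len(breed_names), size=per_gen[g - 1], p=props)
        for j, bi in enumerate(breed_draw):
            b = breed_names[bi]
            sire_pool = by_breed_gen.get((b, g - 1, "M")) or by_breed_gen[(b, 0, "M")]
            dam_pool = by_breed_gen.get((b, g - 1, "F")) or by_breed_gen[(b, 0, "F")]
            si = sire_pool[int(rng_ped.integers(0, len(sire_pool)))]
            di = dam_pool[int(rng_ped.integers(0, len(dam_pool)))]
            aid = f"A{idx:05d}"
            if j < 2:
                sex = "M" if j == 0 else "F"
            else:
                sex = "M" if rng_ped.random() < cfg.sex_ratio_male else "F"
            animal_ids.append(aid)
            sires.append(animal_ids[si])
            dams.append(animal_ids[di])
            sexes.append(sex)
            breeds_out.append(b)
            gens.append(g)
            haplo[idx, 0] = _meiosis(haplo[si], chrom_slices, chrom_pos, rng_meio)
            haplo[idx, 1] = _meiosis(haplo[di], chrom_slices, chrom_pos, rng_meio)
            by_breed_gen.setdefault((b, g, sex), []).append(idx)
            idx += 1

    dosage = haplo[:idx, 0].astype(np.int8) + haplo[:idx, 1].astype(np.int8)
    ped = Pedigree(animal_ids, sires, dams)
    geno = Genotypes(animal_ids, list(snpmap.snp_id), dosage)
    animals = pd.DataFrame(
        {"animal": animal_ids, "sex": sexes, "breed": breeds_out, "generation": gens}
    )
    return ped, geno, animals


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    cfg: SimulationConfig,
    genotypes: Genotypes,
    animals: pd.DataFrame,
    pathways: Sequence[Pathway],
    snps: SnpMap,
    genes: Sequence[GeneRecord],
) -> tuple[pd.DataFrame, SimTruth]:
    """Cow and bull records plus ground truth for every configured trait.

    Cows (females) get the mean of ``l`` lactation deviations sharing a
    permanent-environment effect; bulls (males) get the mean deviation of
    ``n`` simulated daughters.  Records are standardised within breed and
    carry the appropriate residual weight.
    """
    rng_master = np.random.SeedSequence(cfg.seed + 2)
    M = np.asarray(genotypes.values, dtype=np.float64)
    n_animals, n_snps = M.shape
    sex = animals["sex"].to_numpy()
    breed = animals["breed"].to_numpy()
    is_f = sex == "F"
    is_m = ~is_f

    target_idx: np.ndarray | None = None
    if cfg.enrichment_fraction > 0:
        name = cfg.target_pathway or (pathways[0].name if pathways else None)
        pw = next((p for p in pathways if p.name == name), None)
        if pw is None:
            raise ValueError(f"enrichment target pathway {name!r} not found")
        pset = pathway_snp_set(pw, genes, snps, cfg.window_bp)
        if pset.n_snps == 0:
            raise ValueError(f"enrichment target pathway {name!r} has no SNPs")
        target_idx = snps.indices_of(pset.snp_ids)

    breed_shift = dict(cfg.breed_effects)
    rows = []
    causal_ids: dict[str, tuple[str, ...]] = {}
    causal_eff: dict[str, np.ndarray] = {}
    bvs: dict[str, np.ndarray] = {}
    counts_rows = []

    # record counts shared across traits (one dataset, several traits)
    rng_counts = np.random.default_rng(rng_master.spawn(1)[0])
    lact = 1 + rng_counts.poisson(max(cfg.cow_lactations_mean - 1.0, 0.0), n_animals)
    lact = np.minimum(lact, cfg.max_lactations)
    ndau = 1 + rng_counts.poisson(max(cfg.bull_daughters_mean - 1.0, 0.0), n_animals)
    shared_loci: np.ndarray | None = None

    for t_i, trait in enumerate(cfg.traits):
        rng = np.random.default_rng(rng_master.spawn(1)[0])
        h2, r2 = trait.h2, trait.r2 if trait.r2 is not None else trait.h2
        # causal loci
        n_causal = min(cfg.n_causal, n_snps)
        n_in = int(round(cfg.enrichment_fraction * n_causal))
        if target_idx is not None and n_in > 0:
            n_in = min(n_in, target_idx.size)
            inside = rng.choice(target_idx, size=n_in, replace=False)
            pool = np.setdiff1d(np.arange(n_snps), target_idx, assume_unique=False)
            outside = rng.choice(pool, size=n_causal - n_in, replace=False)
            loci = np.sort(np.concatenate([inside, outside]))
        else:
            if cfg.shared_causal and shared_loci is not None:
                loci = shared_loci
            else:
                loci = np.sort(rng.choice(n_snps, size=n_causal, replace=False))
        if cfg.shared_causal and shared_loci is None:
            shared_loci = loci
        effects = rng.normal(0.0, 1.0, size=loci.size)

        if h2 > 0:
            raw = (M[:, loci] - M[:, loci].mean(axis=0)) @ effects
            sd_raw = raw.std()
            if sd_raw == 0:
                raise ValueError("degenerate genetic values; increase n_causal/MAF")
            scale = np.sqrt(h2) / sd_raw
            u = raw * scale
            effects = effects * scale
        else:
            u = np.zeros(n_animals)
            effects = np.zeros(loci.size)

        value = np.empty(n_animals)
        nrec = np.empty(n_animals, dtype=int)
        # cows: mean of l lactations, shared permanent environment
        pe = rng.normal(0.0, np.sqrt(max(r2 - h2, 0.0)), n_animals)
        eps = rng.normal(0.0, 1.0, n_animals) * np.sqrt((1.0 - r2) / lact)
        value[is_f] = u[is_f] + pe[is_f] + eps[is_f]
        nrec[is_f] = lact[is_f]
        # bulls: mean of n daughter deviations
        # daughter = 0.5 u_sire + 0.5 u_dam + mendelian + residual;
        # averaging n of them leaves 0.5 u_sire + noise of var (1 - h2/4)/n
        n_d = ndau[is_m]
        noise_var = (0.25 * h2 + 0.5 * h2 + (1.0 - h2)) / n_d
        dau = rng.normal(0.0, 1.0, int(is_m.sum())) * np.sqrt(noise_var)
        value[is_m] = 0.5 * u[is_m] + dau
        nrec[is_m] = n_d

        value = value + np.asarray([breed_shift.get(b, 0.0) for b in breed])
        value = standardise_records(value, breed)

        df = pd.DataFrame(
            {
                "animal": animals["animal"],
                "sex": np.where(is_f, "cow", "bull"),
                "breed": breed,
                "trait": trait.name,
                "value": value,
                "n": nrec,
            }
        )
        df["weight"] = record_weights(df, trait)
        rows.append(df)
        causal_ids[trait.name] = tuple(np.asarray(genotypes.snp_ids)[loci])
        causal_eff[trait.name] = effects
        bvs[trait.name] = u
        counts_rows.append(
            pd.DataFrame(
                {
                    "animal": animals["animal"],
                    "trait": trait.name,
                    "n": nrec,
                    "sex": df["sex"],
                }
            )
        )

    phenos = pd.concat(rows, ignore_index=True)
    truth = SimTruth(
        causal_ids=causal_ids,
        causal_effects=causal_eff,
        breeding_values=bvs,
        h2={t.name: t.h2 for t in cfg.traits},
        r2={t.name: t.r2 for t in cfg.traits},
        record_counts=pd.concat(counts_rows, ignore_index=True),
        animal_ids=list(animals["animal"]),
    )
    return phenos, truth


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full synthetic dataset: genome, population and phenotypes."""
    snpmap, genes, pathways = simulate_map_and_genes(cfg)
    ped, geno, animals = simulate_population(cfg, snpmap)
    phenos, truth = simulate_phenotypes(cfg, geno, animals, pathways, snpmap, genes)
    return SimulatedDataset(
        config=cfg,
        genes=genes,
        pathways=pathways,
        snps=snpmap,
        pedigree=ped,
        genotypes=geno,
        animals=animals,
        phenotypes=phenos,
        truth=truth,
    )
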