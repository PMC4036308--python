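"""Reading and writing the dataset directory layout.

A dataset directory holds plain-text files:

    genes.tsv       symbol/chrom/start/stop gene table
    pathways.gmt    GMT pathway membership
    snps.bim        plink-bim-like SNP map (chrom, id, 0, pos)
    genotypes.tsv   animals x SNPs dosage matrix (first column: animal)
    pedigree.csv    animal,sire,dam ("0" = unknown)
    phenotypes.csv  animal,sex,breed,trait,value,n,weight
    truth.json      simulation ground truth (synthetic datasets only)
    manifest.json   config snapshot, seeds, file digests
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    GeneRecord,
    Pathway,
    SnpMap,
    load_gene_table,
    load_pathways_gmt,
    load_snp_map,
)
from .relatedness import Genotypes, Pedigree
from .simulate import SimulatedDataset, SimulationConfig

__all__ = ["Dataset", "write_dataset", "read_dataset", "file_digest", "write_manifest"]

DATA_FILES = (
    "genes.tsv",
    "pathways.gmt",
    "snps.bim",
    "genotypes.tsv",
    "pedigree.csv",
    "phenotypes.csv",
)


@dataclass
class Dataset:
    """An analysis-ready dataset loaded from disk (or built in memory)."""

    genes: list[GeneRecord]
    pathways: list[Pathway]
    snps: SnpMap
    genotypes: Genotypes
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: dict | None = None
    manifest: dict | None = None

    @property
    def traits(self) -> list[str]:
        return sorted(self.phenotypes["trait"].unique())


def file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: Path, config: dict, seed: int, files: list[str]
) -> dict:
    manifest = {
        "tool": "lactpath",
        "version": __version__,
        "master_seed": seed,
        "config": config,
        "files": {f: file_digest(outdir / f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_dataset(sim: SimulatedDataset, outdir: str | Path) -> dict:
    """Write a simulated dataset to a directory; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = pd.DataFrame(
        [(g.symbol, g.chrom, g.start, g.stop) for g in sim.genes],
        columns=["symbol", "chrom", "start", "stop"],
    )
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)

    with open(outdir / "pathways.gmt", "w") as fh:
        for p in sim.pathways:
            fh.write(p.name + "\tsimulated pathway\t" + "\t".join(p.genes) + "\n")

    bim = pd.DataFrame(
        {
            "chrom": sim.snps.chrom,
            "snp_id": sim.snps.snp_id,
            "cm": 0,
            "pos": sim.snps.pos,
        }
    )
    bim.to_csv(outdir / "snps.bim", sep="\t", index=False, header=False)

    geno = pd.DataFrame(
        sim.genotypes.values,
        index=pd.Index(sim.genotypes.animal_ids, name="animal"),
        columns=sim.genotypes.snp_ids,
    )
    geno.to_csv(outdir / "genotypes.tsv", sep="\t")

    sim.pedigree.to_frame().to_csv(outdir / "pedigree.csv", index=False)
    sim.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)

    truth = {
        "causal_ids": {t: list(v) for t, v in sim.truth.causal_ids.items()},
        "causal_effects": {
            t: np.asarray(v).tolist() for t, v in sim.truth.causal_effects.items()
        },
        "breeding_values": {
            t: np.asarray(v).tolist() for t, v in sim.truth.breeding_values.items()
        },
        "h2": sim.truth.h2,
        "r2": sim.truth.r2,
        "animal_ids": sim.truth.animal_ids,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True)
        fh.write("\n")

    cfg = dataclasses.asdict(sim.config)
    cfg["traits"] = [dataclasses.asdict(t) for t in sim.config.traits]
    return write_manifest(
        outdir, cfg, sim.config.seed, list(DATA_FILES) + ["truth.json"]
    )


def read_dataset(path: str | Path) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    for f in DATA_FILES:
        if not (path / f).exists():
            raise FileNotFoundError(f"dataset {path} is missing {f}")
    genes = load_gene_table(path / "genes.tsv")
    pathways = load_pathways_gmt(path / "pathways.gmt")
    snps = load_snp_map(path / "snps.bim")
    geno_df = pd.read_csv(path / "genotypes.tsv", sep="\t", index_col=0)
    genotypes = Genotypes(
        [str(a) for a in geno_df.index],
        [str(s) for s in geno_df.columns],
        geno_df.to_numpy(dtype=np.int8),
    )
    pedigree = Pedigree.from_csv(path / "pedigree.csv")
    phenotypes = pd.read_csv(
        path / "phenotypes.csv", dtype={"animal": str}, comment="#"
    )
    truth = None
    if (path / "truth.json").exists():
        with open(path / "truth.json") as fh:
            truth = json.load(fh)
    manifest = None
    if (path / "manifest.json").exists():
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
    return Dataset(
        genes=genes,
        pathways=pathways,
        snps=snps,
        genotypes=genotypes,
        pedigree=pedigree,
        phenotypes=phenotypes,
        truth=truth,
        manifest=manifest,
    )
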