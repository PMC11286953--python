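"""VCF 4.2 and tab-separated input/output.

Datasets are written as plain-text VCF with one ``##contig`` line per target
region (carrying the region length) and ``CHROM``/``POS`` holding the region
id and the 1-based within-region position.  Reading goes through cyvcf2 and
round-trips the genotype matrix losslessly (missing genotypes as ``./.``).
Stand assignments and correspondence tables travel as tab-separated files.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .dataset import MISSING, SLOPE_OF, GenotypeDataset

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(data: GenotypeDataset, path: str | os.PathLike) -> None:
    """Write a dataset as an uncompressed VCF 4.2 file."""
    if data.n_sites == 0 or data.n_samples == 0:
        raise ValueError("refusing to write an empty dataset")
    sample_ids = list(data.samples["sample_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=demoscan\n")
        fh.write(
            '##INFO=<ID=RID,Number=1,Type=String,Description="Target region id">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for region, row in data.regions.iterrows():
            fh.write(f"##contig=<ID={region},length={int(row['length'])}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for i in range(data.n_sites):
            region = data.sites["region"].iat[i]
            pos = int(data.sites["pos"].iat[i])
            gts = "\t".join(_GT_STRING[int(g)] for g in data.genotypes[i])
            fh.write(
                f"{region}\t{pos}\t{region}:{pos}\tA\tT\t.\tPASS\t"
                f"RID={region}\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | os.PathLike,
    stand_table: pd.DataFrame | str | os.PathLike,
) -> GenotypeDataset:
    """Read a VCF written by :func:`write_vcf` (or any biallelic VCF).

    ``stand_table`` assigns each sample to a stand (and optionally a slope);
    it may be a data frame or a path to a tab-separated file with columns
    ``sample_id``, ``stand`` [, ``slope``].
    """
    if not isinstance(stand_table, pd.DataFrame):
        stand_table = read_stand_table(stand_table)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens))

    geno_rows = []
    site_rows = []
    for var in vcf:
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        row = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        geno_rows.append(row.astype(np.int8))
        site_rows.append((var.CHROM, var.POS))
    vcf.close()

    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.zeros((0, len(sample_ids)), np.int8)
    )
    sites = pd.DataFrame(site_rows, columns=["region", "pos"])
    # keep every header contig so SNP-less regions survive the round trip
    regions = pd.DataFrame(
        {"length": [int(lengths[r]) for r in vcf_seqnames(lengths, sites)]},
        index=pd.Index(vcf_seqnames(lengths, sites), name="region"),
    )
    by_id = stand_table.set_index("sample_id")
    stands = [by_id.loc[s, "stand"] for s in sample_ids]
    slopes = [
        by_id.loc[s, "slope"] if "slope" in by_id.columns else SLOPE_OF.get(st, "?")
        for s, st in zip(sample_ids, stands)
    ]
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "stand": stands, "slope": slopes}
    )
    return GenotypeDataset(
        genotypes=genotypes, samples=samples, sites=sites, regions=regions
    )


def vcf_seqnames(lengths: Mapping[str, int], sites: pd.DataFrame) -> list[str]:
    """Header contigs first (header order), then any extra site regions."""
    names = list(lengths)
    extra = [r for r in dict.fromkeys(sites["region"]) if r not in lengths]
    if extra:
        raise ValueError(f"VCF records reference contigs missing from header: {extra[:3]}")
    return names


def write_stand_table(data: GenotypeDataset, path: str | os.PathLike) -> None:
    data.samples.to_csv(path, sep="\t", index=False)


def read_stand_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "sample_id" not in table.columns or "stand" not in table.columns:
        raise ValueError("stand table needs 'sample_id' and 'stand' columns")
    return table
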