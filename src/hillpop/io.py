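"""Reading and writing the pipeline's on-disk formats.

VCF v4.2 is the genotype interchange format (GT genotypes; QD, MQ, FS,
MQRankSum, ReadPosRankSum and DP carried in INFO; site QUAL in the QUAL
column). Gene annotations are BED (0-based half-open); population maps and
reports are plain TSV. Reading uses cyvcf2; writing emits VCF text directly
since records are simple biallelic SNPs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    ANNOTATION_FIELDS,
    MISSING,
    GeneIntervals,
    GenotypeMatrix,
    PopulationMap,
)

_INFO_FIELDS = tuple(f for f in ANNOTATION_FIELDS if f != "QUAL")

_VCF_HEADER_META = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum z">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum z">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Mean depth of coverage across samples">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _fmt(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(round(float(x), 6))


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 file."""
    path = Path(path)
    sites = genotypes.sites
    lines = ["##fileformat=VCFv4.2", "##source=hillpop"]
    for chrom, grp in sites.groupby("chrom", sort=False):
        lines.append(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>")
    lines.extend(_VCF_HEADER_META)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.samples)
    )
    has = {f: f in sites.columns for f in ANNOTATION_FIELDS}
    for j in range(genotypes.n_sites):
        row = sites.iloc[j]
        qual = "."
        if has["QUAL"] and not pd.isna(row["QUAL"]):
            qual = _fmt(row["QUAL"])
        info_parts = [
            f"{f}={_fmt(row[f])}"
            for f in _INFO_FIELDS
            if has[f] and not pd.isna(row[f])
        ]
        info = ";".join(info_parts) if info_parts else "."
        gts = "\t".join(_GT_STRINGS[int(g)] for g in genotypes.dosages[:, j])
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t.\t{row.get('ref', 'A')}\t"
            f"{row.get('alt', 'C')}\t{qual}\tPASS\t{info}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a GenotypeMatrix.

    Multi-allelic or non-SNP records raise, matching the pipeline's
    biallelic-SNP contract. Missing INFO annotations become NaN.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    quals = []
    infos: dict[str, list[float]] = {f: [] for f in _INFO_FIELDS}
    dosage_rows = []
    for record in vcf:
        if len(record.ALT) != 1 or not record.is_snp:
            raise ValueError(
                f"non-biallelic-SNP record at {record.CHROM}:{record.POS}"
            )
        chroms.append(record.CHROM)
        poss.append(record.POS)
        refs.append(record.REF)
        alts.append(record.ALT[0])
        quals.append(np.nan if record.QUAL is None else record.QUAL)
        for f in _INFO_FIELDS:
            v = record.INFO.get(f)
            infos[f].append(np.nan if v is None else float(v))
        gt = np.asarray(record.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 encodes an uncalled genotype
        dosage_rows.append(gt)
    vcf.close()
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "QUAL": quals}
    )
    for f in _INFO_FIELDS:
        sites[f] = infos[f]
    dosages = (
        np.stack(dosage_rows, axis=1)
        if dosage_rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(dosages=dosages, samples=samples, sites=sites)


def write_bed(intervals: GeneIntervals, path: str | Path) -> Path:
    path = Path(path)
    intervals.table[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )
    return path


def read_bed(path: str | Path) -> GeneIntervals:
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
    )
    return GeneIntervals(table)


def write_pop_map(pop_map: PopulationMap, path: str | Path) -> Path:
    path = Path(path)
    pop_map.table.to_csv(path, sep="\t", index=False)
    return path


def read_pop_map(path: str | Path) -> PopulationMap:
    return PopulationMap(pd.read_csv(path, sep="\t"))
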