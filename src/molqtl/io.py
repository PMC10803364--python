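"""Readers and writers for the formats the pipeline exchanges.

Genotypes travel as VCF 4.2 with phased ``GT`` fields; molecular phenotypes
as a BED dialect (0-based half-open interval, column 4 phenotype id, column 5
group id, column 6 strand, one column per sample after that); covariates as a
TSV with covariates in rows and samples in columns. All writers round-trip
losslessly through the matching readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHENOTYPE_BED_COLUMNS = ["#chr", "start", "end", "pid", "gid", "strand"]


@dataclass
class GenotypeData:
    """In-memory phased genotypes for one cohort.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per variant: ``chrom``, ``pos`` (1-based, as in VCF),
        ``id``, ``ref``, ``alt``, ``maf``.
    haplotypes : numpy.ndarray
        ``(2 * n_samples, n_variants)`` int8 array; rows ``2i`` and
        ``2i + 1`` are the two haplotypes of sample ``i``.
    samples : list of str
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray
    samples: list

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def dosages(self) -> np.ndarray:
        """Alternative-allele dosage matrix, shape (n_samples, n_variants)."""
        return (
            self.haplotypes[0::2].astype(np.float64)
            + self.haplotypes[1::2].astype(np.float64)
        )

    def subset_samples(self, index) -> "GenotypeData":
        index = np.asarray(index)
        hap_index = np.empty(2 * len(index), dtype=int)
        hap_index[0::2] = 2 * index
        hap_index[1::2] = 2 * index + 1
        return GenotypeData(
            variants=self.variants.copy(),
            haplotypes=self.haplotypes[hap_index],
            samples=[self.samples[i] for i in index],
        )


def write_vcf(genotypes: GenotypeData, path: str) -> None:
    """Write phased genotypes as an uncompressed VCF 4.2 file."""
    var = genotypes.variants
    hap = genotypes.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=molqtl\n")
        for chrom in var["chrom"].unique():
            length = int(var.loc[var["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        a = hap[0::2]
        b = hap[1::2]
        for j in range(len(var)):
            row = var.iloc[j]
            gts = "\t".join(f"{a[i, j]}|{b[i, j]}" for i in range(a.shape[0]))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeData:
    """Read phased genotypes from a VCF file via :mod:`cyvcf2`."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    haps = []
    for v in vcf:
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "id": v.ID if v.ID is not None else f"{v.CHROM}:{v.POS}",
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
            }
        )
        g = np.array(v.genotypes, dtype=np.int8)  # (n, 3): hapA, hapB, phased
        haps.append(g[:, :2])
    variants = pd.DataFrame(rows)
    hap_arr = np.empty((2 * len(samples), len(variants)), dtype=np.int8)
    for j, g in enumerate(haps):
        hap_arr[0::2, j] = g[:, 0]
        hap_arr[1::2, j] = g[:, 1]
    dos = hap_arr[0::2] + hap_arr[1::2]
    af = dos.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(af, 1.0 - af)
    return GenotypeData(variants=variants, haplotypes=hap_arr, samples=samples)


def write_phenotype_bed(
    meta: pd.DataFrame, values: pd.DataFrame, path: str
) -> None:
    """Write a phenotype table in the BED dialect.

    Parameters
    ----------
    meta : DataFrame with columns ``#chr, start, end, pid, gid, strand``
        (start/end 0-based half-open anchors).
    values : DataFrame indexed like ``meta`` with one column per sample.
    """
    if list(meta.columns) != PHENOTYPE_BED_COLUMNS:
        raise ValueError(f"meta must have columns {PHENOTYPE_BED_COLUMNS}")
    out = pd.concat(
        [meta.reset_index(drop=True), values.reset_index(drop=True)], axis=1
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotype_bed(path: str):
    """Read a phenotype BED table; returns ``(meta, values)``."""
    df = pd.read_csv(path, sep="\t")
    meta = df[PHENOTYPE_BED_COLUMNS].copy()
    values = df.drop(columns=PHENOTYPE_BED_COLUMNS)
    return meta, values


def write_covariates(covariates: pd.DataFrame, path: str) -> None:
    """Write covariates (rows = covariates, columns = samples)."""
    covariates.to_csv(path, sep="\t", index=True, index_label="id")


def read_covariates(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
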