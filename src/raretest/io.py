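"""Readers and writers for the formats the toolkit touches.

Genotypes come from VCF (biallelic SNVs, GT fields; parsed with cyvcf2) or
from a plain sample x variant TSV of 0/1/2 counts. Gene definitions are
two-column set files (``gene<TAB>variant``), phenotypes two-column TSVs
(``sample<TAB>value``), pedigrees whitespace-delimited FAM-style files.
Results go out as TSV with a seeded header comment.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assoc_unrelated import AssocResult
from .core_types import GenotypeMatrix, GeneSet, Pedigree, Phenotype, minor_allele_orient

logger = logging.getLogger("raretest")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_setfile",
    "write_setfile",
    "read_pedigree",
    "write_fam",
    "read_phenotype",
    "write_phenotype",
    "write_results",
]

_GT_CODE = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}


def read_vcf(path: str, skip_multiallelic: bool = True) -> tuple:
    """Load a VCF into a minor-allele-count matrix.

    Biallelic records are converted to ALT counts and then re-oriented so
    the counted allele is the minor one. Returns ``(matrix, flipped)``
    where ``flipped`` lists the variants whose ALT allele was the major
    allele. Multi-allelic records are skipped with a warning (or rejected
    when ``skip_multiallelic`` is False). Missing GT -> missing entry.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    variants, columns = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if not skip_multiallelic:
                raise ValueError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS}; split it first"
                )
            warnings.warn(f"skipping multi-allelic record {rec.CHROM}:{rec.POS}")
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        col = np.empty(len(samples))
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            col[i] = np.nan if (a < 0 or b < 0) else _GT_CODE[(min(a, 1), min(b, 1))]
        variants.append(vid)
        columns.append(col)
    counts = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    matrix, flipped = minor_allele_orient(GenotypeMatrix(samples, variants, counts))
    if flipped:
        logger.info("re-oriented %d ALT-major variant(s): %s", len(flipped),
                    ", ".join(flipped[:5]))
    return matrix, flipped


def write_vcf(matrix: GenotypeMatrix, path: str, header_note: str = "") -> None:
    """Write counts as a minimal single-chromosome VCF (A/T placeholder alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if header_note:
            fh.write(f"##source={header_note}\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, vid in enumerate(matrix.variants):
            col = matrix.counts[:, j]
            gts = "\t".join(
                "./." if np.isnan(c) else gt_of[c] for c in col
            )
            fh.write(f"1\t{j + 1}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_matrix_tsv(path: str) -> GenotypeMatrix:
    """Sample x variant TSV of 0/1/2 counts (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    matrix, _ = minor_allele_orient(
        GenotypeMatrix(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))
    )
    return matrix


def write_matrix_tsv(matrix: GenotypeMatrix, path: str) -> None:
    pd.DataFrame(matrix.counts, index=matrix.samples, columns=matrix.variants).to_csv(
        path, sep="\t", index_label="sample", float_format="%g"
    )


def read_setfile(path: str, matrix: GenotypeMatrix | None = None) -> GeneSet:
    """Two-column gene/variant set file -> GeneSet.

    Duplicate lines collapse to one entry; variants absent from the matrix
    (when one is given) are skipped with a warning.
    """
    genes: dict[str, list[str]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need 'gene<TAB>variant'")
            gene, variant = parts[0], parts[1]
            if matrix is not None and variant not in matrix._variant_index:
                warnings.warn(f"{path}:{lineno}: unknown variant {variant!r}, skipped")
                continue
            genes.setdefault(gene, []).append(variant)
            n_lines += 1
    if n_lines == 0:
        raise ValueError(f"set file {path} contains no usable entries")
    genes = {g: v for g, v in genes.items() if v}
    return GeneSet(genes, matrix)


def write_setfile(geneset: GeneSet, path: str) -> None:
    with open(path, "w") as fh:
        for gene in geneset:
            for variant in geneset[gene]:
                fh.write(f"{gene}\t{variant}\n")


def read_pedigree(path: str) -> Pedigree:
    """FAM-style file: fid iid father mother sex [phenotype...]; '0' = no parent."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: need >= 5 FAM columns")
            fid, iid, father, mother, sex = parts[:5]
            rows.append((fid, iid,
                         None if father == "0" else father,
                         None if mother == "0" else mother,
                         int(sex) if sex.isdigit() else 0))
    return Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"]))


def write_fam(ped: Pedigree, path: str) -> None:
    with open(path, "w") as fh:
        for _, r in ped.records.iterrows():
            fh.write(f"{r.fid}\t{r.iid}\t{r.father or 0}\t{r.mother or 0}\t{r.sex}\n")


def read_phenotype(path: str) -> Phenotype:
    """Two-column TSV sample<TAB>value (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"phenotype file {path} needs two columns")
    first = df.iloc[0, 1]
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    return Phenotype(list(df.iloc[:, 0]), df.iloc[:, 1].astype(float).to_numpy())


def write_phenotype(pheno: Phenotype, path: str, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for s, v in zip(pheno.samples, pheno.values):
            fh.write(f"{s}\t{v:.10g}\n")


def write_results(
    results: Iterable[AssocResult],
    path: str,
    seed=None,
    extra_header: Sequence[str] = (),
) -> None:
    """Results TSV: gene, method, statistic, df, p, n_perm, status."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# raretest {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        fh.write("\n")
        for line in extra_header:
            fh.write(f"# {line}\n")
        fh.write("gene\tmethod\tstatistic\tdf\tp\tn_perm\tstatus\n")
        for r in results:
            stat = "" if r.statistic is None else f"{r.statistic:.6g}"
            p = "" if r.p is None else f"{r.p:.6g}"
            df = "" if r.df is None else str(r.df)
            nperm = "" if r.n_permutations is None else str(r.n_permutations)
            fh.write(f"{r.gene}\t{r.method}\t{stat}\t{df}\t{p}\t{nperm}\t{r.status}\n")
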