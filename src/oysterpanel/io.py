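"""Reading and writing the pipeline's on-disk formats.

VCF 4.2 (GT-only), fam-style pedigree TSV and reference FASTA.  VCF input
goes through cyvcf2; reference sequence access goes through pyfaidx.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, SITE_COLUMNS, GenomeLayout, GenotypeMatrix, Pedigree

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike,
              layout: GenomeLayout | None = None) -> Path:
    """Write a GT-only VCF 4.2 file (uncompressed text, 1-based positions)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    if layout is not None:
        for name, length in zip(layout.names, layout.lengths):
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"]
    lines.append("\t".join(header + list(matrix.individuals)))
    dos = matrix.dosages
    for j, site in enumerate(matrix.sites.itertuples(index=False)):
        gts = "\t".join(_GT_STRINGS[int(d)] for d in dos[:, j])
        lines.append(
            f"{site.chrom}\t{site.pos}\t{site.id}\t{site.ref}\t{site.alt}"
            f"\t.\t.\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | os.PathLike) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Read a VCF into a GenotypeMatrix.

    Returns the matrix and, when every record carries INFO/DP, the per-site
    total-depth vector (else None).  Multiallelic records are rejected.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows = []
    dosages = []
    depths: list[int] = []
    have_depth = True
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"site {var.ID or var.POS} is not biallelic")
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0]))
        gts = np.asarray(var.genotype.array())[:, :2]
        dose = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        dosages.append(dose.astype(np.int8))
        dp = var.INFO.get("DP")
        if dp is None:
            have_depth = False
        else:
            depths.append(int(dp))
    vcf.close()
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    matrix = GenotypeMatrix(
        individuals, sites,
        np.column_stack(dosages) if dosages else
        np.zeros((len(individuals), 0), np.int8),
    )
    depth = np.asarray(depths) if (have_depth and depths) else None
    return matrix, depth


def write_pedigree(pedigree: Pedigree, path: str | os.PathLike) -> Path:
    path = Path(path)
    cols = ["id", "sire", "dam", "generation"]
    extra = [c for c in pedigree.table.columns if c not in cols]
    pedigree.table[cols + extra].to_csv(path, sep="\t", index=False)
    return path


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return Pedigree(table)


def write_fasta(sequences: dict[str, str], path: str | os.PathLike,
                width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start:start + width] + "\n")
    return path
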