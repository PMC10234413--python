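"""Discovery-stage site filtering on a called-genotype table.

Retains biallelic SNPs with minor allele frequency strictly above a floor,
data from a minimum fraction of individuals, and (when depth is known)
total depth below a cap.  Allele frequencies are computed from called
genotypes; read-level quality criteria are upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteSummary:
    """Per-site summary used by the downstream probe-selection stage."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    n_called: int
    maf: float
    total_depth: int | None = None


def compute_maf(matrix: GenotypeMatrix, site: int) -> float:
    """Minor allele frequency at site index ``site``: min(f, 1-f) with
    f = (sum of dosages) / (2 x called individuals)."""
    dose = matrix.dosages[:, site]
    called = dose != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError(f"site index {site} has no called genotypes")
    f = dose[called].sum() / (2 * n)
    return float(min(f, 1.0 - f))


def site_summaries(
    matrix: GenotypeMatrix, depth: np.ndarray | None = None
) -> list[SiteSummary]:
    """SiteSummary rows for every site, in matrix order."""
    if depth is not None and len(depth) != matrix.n_sites:
        raise ValueError("depth vector length does not match site count")
    out = []
    called = matrix.called()
    n_called = called.sum(axis=0)
    for j, site in enumerate(matrix.sites.itertuples(index=False)):
        out.append(SiteSummary(
            id=site.id, chrom=site.chrom, pos=int(site.pos),
            ref=site.ref, alt=site.alt,
            n_called=int(n_called[j]),
            maf=compute_maf(matrix, j) if n_called[j] else float("nan"),
            total_depth=int(depth[j]) if depth is not None else None,
        ))
    return out


def filter_candidates(
    matrix: GenotypeMatrix,
    min_maf: float = 0.01,
    min_called_fraction: float = 0.5,
    max_total_depth: int | None = None,
    depth: np.ndarray | None = None,
) -> list[SiteSummary]:
    """Apply the discovery filters; returns retained sites in input order.

    A site is retained iff it is biallelic (two distinct single-base
    alleles), ``maf > min_maf`` (strict), called in at least
    ``min_called_fraction`` of individuals, and — when a depth vector is
    supplied — ``total_depth < max_total_depth`` (strict).  Without depth
    information the depth criterion passes.
    """
    if matrix.n_individuals == 0 or matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")
    retained = []
    for s in site_summaries(matrix, depth):
        biallelic = (s.ref in _BASES and s.alt in _BASES and s.ref != s.alt)
        if not biallelic:
            continue
        if s.n_called == 0 or not (s.maf > min_maf):
            continue
        if s.n_called / matrix.n_individuals < min_called_fraction:
            continue
        if (max_total_depth is not None and s.total_depth is not None
                and not (s.total_depth < max_total_depth)):
            continue
        retained.append(s)
    return retained


def summaries_to_frame(summaries: list[SiteSummary]) -> pd.DataFrame:
    cols = ["id", "chrom", "pos", "ref", "alt", "n_called", "maf", "total_depth"]
    return pd.DataFrame([[getattr(s, c) for c in cols] for s in summaries],
                        columns=cols)
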