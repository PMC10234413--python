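"""Probe selection for a custom genotyping array.

The selection procedure grades every candidate SNP against a grid of
stringency criteria — all combinations of a MAF floor, a flanking-window
size, and a cap on the number of other SNPs inside that window — and ranks
candidates by how many of those criteria they satisfy (their
*membership count*).  A candidate passing the most stringent combination
passes all of them, so membership count is a graded stringency score.
Ranked candidates receive priority numbers 1..N (1 = best), are allocated
to chromosomes proportionally to chromosome length, and exported with
reference flanking sequence for probe synthesis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .core import GenomeLayout

DEFAULT_MAF_LEVELS = (0.05, 0.1)
DEFAULT_FLANK_LEVELS = (20, 25, 30)
DEFAULT_NEIGHBOR_LEVELS = (0, 1, 2)


@dataclass(frozen=True)
class StringencyCriterion:
    """One combination of the selection-stringency grid."""

    min_maf: float
    flank_bp: int
    max_neighbors: int

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive")
        if self.max_neighbors < 0:
            raise ValueError("max_neighbors must be >= 0")


@dataclass(frozen=True)
class ProbeRecord:
    """A selected SNP with its reference flanks, ready for synthesis."""

    id: str
    chrom: str
    pos: int
    left_flank: str
    right_flank: str
    ref: str
    alt: str
    priority: int


def enumerate_criteria(
    maf_levels=DEFAULT_MAF_LEVELS,
    flank_levels=DEFAULT_FLANK_LEVELS,
    neighbor_levels=DEFAULT_NEIGHBOR_LEVELS,
) -> list[StringencyCriterion]:
    """Full Cartesian product of the stringency levels.

    Deterministic order: MAF descending, flank descending, neighbor cap
    ascending — most stringent first.  The default levels give the
    18-combination grid.
    """
    if not (len(maf_levels) and len(flank_levels) and len(neighbor_levels)):
        raise ValueError("level lists must be non-empty")
    return [
        StringencyCriterion(m, f, k)
        for m, f, k in product(
            sorted(maf_levels, reverse=True),
            sorted(flank_levels, reverse=True),
            sorted(neighbor_levels),
        )
    ]


def count_neighbors(pos: int, positions: np.ndarray, flank_bp: int) -> int:
    """Number of *other* SNPs within ``flank_bp`` of ``pos`` on one
    chromosome (both sides, boundary inclusive).

    ``positions`` must be sorted and contain all discovered SNPs on the
    chromosome; if the focal position itself is present it is excluded.
    """
    positions = np.asarray(positions)
    lo = np.searchsorted(positions, pos - flank_bp, side="left")
    hi = np.searchsorted(positions, pos + flank_bp, side="right")
    inside = int(hi - lo)
    focal = int(np.searchsorted(positions, pos, side="right")
                - np.searchsorted(positions, pos, side="left"))
    return inside - min(focal, 1)


def neighbor_counts(
    candidates: pd.DataFrame, all_sites: pd.DataFrame, flank_bp: int
) -> np.ndarray:
    """Vectorised ``count_neighbors`` for every candidate row.

    ``all_sites`` is the full discovered SNP list (chrom, pos): a probe is
    disrupted by any real polymorphism near it, not only by co-candidates.
    """
    by_chrom = {
        chrom: np.sort(group["pos"].to_numpy())
        for chrom, group in all_sites.groupby("chrom")
    }
    out = np.zeros(len(candidates), dtype=int)
    for i, (chrom, pos) in enumerate(zip(candidates["chrom"], candidates["pos"])):
        positions = by_chrom.get(chrom)
        out[i] = (count_neighbors(int(pos), positions, flank_bp)
                  if positions is not None else 0)
    return out


def build_neighbor_index(
    candidates: pd.DataFrame,
    all_sites: pd.DataFrame,
    flank_levels=DEFAULT_FLANK_LEVELS,
) -> dict[int, np.ndarray]:
    """Neighbor counts per flank level, aligned with ``candidates`` rows."""
    return {f: neighbor_counts(candidates, all_sites, f) for f in flank_levels}


def membership_and_rank(
    candidates: pd.DataFrame,
    criteria: list[StringencyCriterion],
    neighbor_index: dict[int, np.ndarray],
) -> pd.DataFrame:
    """Score candidates by criteria membership and assign priority numbers.

    A candidate belongs to a criterion when ``maf >= min_maf`` and its
    neighbor count within ``flank_bp`` is ``<= max_neighbors``.  Candidates
    are ordered by (membership count desc, maf desc, chrom, pos) and given
    priority numbers 1..N.  Ranking on membership before MAF is what lets
    a clean low-MAF site outrank a crowded high-MAF one.
    """
    maf = candidates["maf"].to_numpy()
    membership = np.zeros(len(candidates), dtype=int)
    for crit in criteria:
        if crit.flank_bp not in neighbor_index:
            raise KeyError(f"no neighbor counts for flank {crit.flank_bp} bp")
        membership += ((maf >= crit.min_maf)
                       & (neighbor_index[crit.flank_bp] <= crit.max_neighbors))
    ranked = candidates.copy()
    ranked["membership_count"] = membership
    ranked = ranked.sort_values(
        ["membership_count", "maf", "chrom", "pos"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ranked["priority"] = np.arange(1, len(ranked) + 1)
    return ranked


def largest_remainder_quotas(lengths: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` seats proportionally to ``lengths`` (Hamilton
    method): floor the exact quotas, then hand leftover seats to the
    largest fractional remainders (ties to the longer chromosome)."""
    lengths = np.asarray(lengths, dtype=float)
    exact = total * lengths / lengths.sum()
    quotas = np.floor(exact).astype(int)
    remainder = exact - quotas
    leftover = total - quotas.sum()
    order = np.lexsort((-lengths, -remainder))
    quotas[order[:leftover]] += 1
    return quotas


def allocate_by_chromosome(
    ranked: pd.DataFrame, layout: GenomeLayout, total: int
) -> pd.DataFrame:
    """Pick ``total`` SNPs spread over chromosomes by length.

    Per-chromosome quotas come from largest-remainder apportionment of
    ``total`` over chromosome lengths; within a chromosome the best
    priority numbers fill the quota.  Quota slots a chromosome cannot fill
    are redistributed to the remaining candidates by global priority, so
    the output always has exactly ``total`` rows.
    """
    if total > len(ranked):
        raise ValueError(f"requested {total} SNPs but only {len(ranked)} ranked")
    quotas = largest_remainder_quotas(np.asarray(layout.lengths), total)
    selected_parts = []
    for name, quota in zip(layout.names, quotas):
        on_chrom = ranked[ranked["chrom"] == name].nsmallest(quota, "priority")
        selected_parts.append(on_chrom)
    selected = pd.concat(selected_parts) if selected_parts else ranked.iloc[:0]
    shortfall = total - len(selected)
    if shortfall > 0:
        rest = ranked[~ranked["priority"].isin(selected["priority"])]
        selected = pd.concat([selected, rest.nsmallest(shortfall, "priority")])
    return selected.sort_values("priority").reset_index(drop=True)


def extract_flanks(
    selected: pd.DataFrame,
    fasta_path: str | os.PathLike,
    probe_flank_bp: int = 35,
) -> tuple[list[ProbeRecord], pd.DataFrame]:
    """Pull left/right reference flanks for each selected SNP.

    Flanks are ``probe_flank_bp`` bases on the forward strand, uppercased,
    1-based inclusive coordinates.  Sites whose flanks would run off a
    chromosome end or contain an N are excluded and returned in the
    flagged table with a reason.
    """
    fasta = Fasta(str(fasta_path))
    probes: list[ProbeRecord] = []
    flagged: list[tuple[str, str]] = []
    for row in selected.itertuples(index=False):
        if row.chrom not in fasta:
            raise KeyError(f"chromosome {row.chrom!r} absent from FASTA")
        chrom_len = len(fasta[row.chrom])
        pos = int(row.pos)
        if pos - probe_flank_bp < 1:
            flagged.append((row.id, "insufficient left flank"))
            continue
        if pos + probe_flank_bp > chrom_len:
            flagged.append((row.id, "insufficient right flank"))
            continue
        left = str(fasta[row.chrom][pos - probe_flank_bp - 1:pos - 1]).upper()
        right = str(fasta[row.chrom][pos:pos + probe_flank_bp]).upper()
        if "N" in left or "N" in right:
            flagged.append((row.id, "flank contains N"))
            continue
        probes.append(ProbeRecord(
            id=row.id, chrom=row.chrom, pos=pos,
            left_flank=left, right_flank=right,
            ref=row.ref, alt=row.alt, priority=int(row.priority),
        ))
    return probes, pd.DataFrame(flagged, columns=["id", "reason"])


def export_submission_table(
    probes: list[ProbeRecord], path: str | os.PathLike
) -> Path:
    """Write the vendor submission TSV.

    One row per probe with the sequence rendered as ``LEFT[R/A]RIGHT``
    (ref allele first in the bracket).
    """
    ids = [p.id for p in probes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate probe ids in submission")
    path = Path(path)
    rows = [{
        "id": p.id,
        "chromosome": p.chrom,
        "position": p.pos,
        "priority": p.priority,
        "sequence": f"{p.left_flank}[{p.ref}/{p.alt}]{p.right_flank}",
    } for p in probes]
    pd.DataFrame(rows, columns=["id", "chromosome", "position", "priority",
                                "sequence"]).to_csv(path, sep="\t", index=False)
    return path
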