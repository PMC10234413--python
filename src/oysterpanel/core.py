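"""Shared containers: genome layout, genotype matrix, pedigree.

Genotypes are stored as alt-allele dosages (0, 1, 2) in a dense
individuals × sites integer matrix, with ``MISSING`` (-1) as the
no-call sentinel.  Site metadata (id, chromosome, 1-based position,
ref/alt alleles) travels alongside as a DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

SITE_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp) of a reference assembly."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def n_chromosomes(self) -> int:
        return len(self.names)

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, name: str) -> int:
        return self.lengths[self.names.index(name)]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))


def default_layout(scale: float = 0.01) -> GenomeLayout:
    """Ten chromosomes with the Eastern oyster assembly's relative lengths.

    The true assembly spans ~685 Mbp; ``scale`` shrinks every chromosome
    proportionally (default 1/100, ~6.9 Mbp total) so that simulated data
    remain desk-sized while preserving the uneven length distribution that
    the chromosome-proportional probe allocation has to handle.
    """
    mbp = (65.7, 61.8, 77.1, 59.6, 98.7, 51.3, 57.8, 75.9, 104.2, 32.6)
    names = tuple(f"chr{i}" for i in range(1, 11))
    lengths = tuple(int(round(m * 1e6 * scale)) for m in mbp)
    return GenomeLayout(names, lengths)


@dataclass
class GenotypeMatrix:
    """Dense individuals × sites alt-allele dosage matrix.

    Parameters
    ----------
    individuals
        Sample identifiers, one per row.
    sites
        DataFrame with columns ``id, chrom, pos, ref, alt`` (1-based
        positions), one row per column of ``dosages``.
    dosages
        ``(n_individuals, n_sites)`` integer array with values in
        ``{0, 1, 2, MISSING}``.
    """

    individuals: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites table lacks columns {missing_cols}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages outside {0,1,2,missing}")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids must be unique")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosages != MISSING

    def individual_call_rates(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_individuals)
        return self.called().mean(axis=1)

    def site_call_rates(self) -> np.ndarray:
        if self.n_individuals == 0:
            return np.zeros(self.n_sites)
        return self.called().mean(axis=0)

    def row_index(self, individual: str) -> int:
        try:
            return self.individuals.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual id {individual!r}") from None

    def subset(
        self,
        individual_mask: np.ndarray | None = None,
        site_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        ind = np.asarray(individual_mask if individual_mask is not None
                         else np.ones(self.n_individuals, bool))
        sit = np.asarray(site_mask if site_mask is not None
                         else np.ones(self.n_sites, bool))
        return GenotypeMatrix(
            [s for s, keep in zip(self.individuals, ind) if keep],
            self.sites.loc[sit].reset_index(drop=True),
            self.dosages[np.ix_(ind, sit)],
        )


#: Pedigree sentinel for an unknown parent.
UNKNOWN_PARENT = "0"

GENERATIONS = ("founder", "F1", "F2")


@dataclass
class Pedigree:
    """Offspring → (sire, dam) links with generation labels.

    ``table`` has columns ``id, sire, dam, generation`` (sire/dam ``"0"``
    when unknown) and may carry extra columns such as the founder
    population or the cross/family an offspring came from.
    """

    table: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        req = ["id", "sire", "dam", "generation"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree lacks columns {missing}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        self._index = {i: r for r, i in enumerate(ids)}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Parents must appear earlier in the table than their offspring;
        # this is stronger than acyclicity and cheap to verify.
        for row in self.table.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent == UNKNOWN_PARENT:
                    continue
                if parent not in self._index:
                    raise ValueError(f"parent {parent!r} of {row.id!r} not in pedigree")
                if self._index[parent] >= self._index[row.id]:
                    raise ValueError(
                        f"parent {parent!r} does not precede offspring {row.id!r}"
                    )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def generation(self, label: str) -> pd.DataFrame:
        return self.table[self.table["generation"] == label]

    def offspring_with_parents(self) -> pd.DataFrame:
        """Records with at least one known parent (trio or duo)."""
        t = self.table
        return t[(t["sire"] != UNKNOWN_PARENT) | (t["dam"] != UNKNOWN_PARENT)]

    def ancestors(self, individual: str) -> set[str]:
        out: set[str] = set()
        stack = [individual]
        while stack:
            current = stack.pop()
            row = self.table.iloc[self._index[current]]
            for parent in (row["sire"], row["dam"]):
                if parent != UNKNOWN_PARENT and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out
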