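"""Synthetic multi-generation cross data for panel design and validation.

Emulates the breeding design behind an aquaculture SNP panel: differentiated
wild founder populations, F1 families from interpopulation crosses, F2
families from F1×F1 crosses, and genotyping with three controlled artefact
channels — segregating null alleles, symmetric genotyping error and random
missingness.

Null alleles are the mechanism of interest.  At a designated subset of loci
a third, assay-invisible allele ``n`` segregates in the founders and is
transmitted Mendelianly.  A true ``A/n`` genotype is rendered as the
homozygote ``A/A``, ``B/n`` as ``B/B``, and ``n/n`` as a missing call — the
rendering that produces both the heterozygote deficit (positive F_IS) and
the homozygous-opposite-child Mendelian errors that flag such loci in real
panels.

All randomness flows from ``SimulationConfig.seed``; identical configs give
identical outputs, file-for-file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import (
    MISSING,
    UNKNOWN_PARENT,
    GenomeLayout,
    GenotypeMatrix,
    Pedigree,
    default_layout,
)

# Internal allele codes in the *true* (pre-rendering) genotypes.
_REF, _ALT, _NULL = 0, 1, 2

# Unordered biallelic SNP types with on-chip proportions matching a typical
# bivalve panel manifest (transitions dominate).
_SNP_TYPES = ["A/G", "C/T", "G/T", "A/C", "A/T", "C/G"]
_SNP_TYPE_PROBS = [0.28, 0.28, 0.11, 0.11, 0.16, 0.06]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic breeding design.

    Defaults mirror the strain the package targets: 11 wild founder
    populations (464 founders total), 39 interpopulation F1 crosses and
    82 F1×F1 crosses, with moderate founder differentiation.
    """

    n_founder_pops: int = 11
    founders_per_pop: int = 42
    fst: float = 0.1
    n_f1_crosses: int = 39
    n_f2_crosses: int = 82
    offspring_per_cross: int = 14
    n_sites: int = 1000
    null_locus_fraction: float = 0.1
    null_allele_freq: float = 0.2
    genotyping_error_rate: float = 0.005
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst", "null_locus_fraction", "null_allele_freq",
                     "genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.fst < 1.0:
            raise ValueError("fst must be < 1")
        for name in ("n_founder_pops", "founders_per_pop",
                     "offspring_per_cross", "n_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_f1_crosses", "n_f2_crosses"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimulationConfig(**current)


@dataclass
class FounderFrequencies:
    """Per-population alt-allele frequencies at simulated site positions."""

    sites: pd.DataFrame          # id, chrom, pos, ref, alt, ancestral_freq
    freqs: np.ndarray            # (n_pops, n_sites) in [0, 1]
    pop_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        for k, name in enumerate(self.pop_names):
            out[name] = self.freqs[k]
        return out


@dataclass
class NullAlleleTruth:
    """Ground truth of the null-allele channel, kept for oracle tests."""

    null_site_ids: list[str]
    carriers: pd.DataFrame       # individual, site_id, n_null_alleles


def _rng(seed: int, stream: int) -> np.random.Generator:
    # Distinct, order-independent substream per operation.
    return np.random.default_rng(np.random.SeedSequence([stream, seed]))


def simulate_founder_frequencies(
    layout: GenomeLayout, cfg: SimulationConfig
) -> FounderFrequencies:
    """Draw site positions and divergent founder allele frequencies.

    The divergence mechanism is the Balding–Nichols model: an ancestral
    frequency ``p ~ Uniform(0.05, 0.95)`` per site, and each population's
    frequency drawn from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` so that
    ``Var(p_pop) = F * p * (1-p)``.  ``fst = 0`` is the divergence-free
    limit where every population keeps the ancestral frequency.
    """
    if cfg.n_sites > layout.total_bp:
        raise ValueError(
            f"{cfg.n_sites} sites cannot fit in a {layout.total_bp} bp genome"
        )
    rng = _rng(cfg.seed, 1)
    # Uniform distinct offsets in the concatenated genome => positions
    # uniform per chromosome, at least 1 bp apart.
    offsets = np.sort(rng.choice(layout.total_bp, size=cfg.n_sites, replace=False))
    bounds = np.cumsum([0] + list(layout.lengths))
    chrom_idx = np.searchsorted(bounds, offsets, side="right") - 1
    pos = offsets - bounds[chrom_idx] + 1  # 1-based
    chroms = np.asarray(layout.names)[chrom_idx]

    type_idx = rng.choice(len(_SNP_TYPES), size=cfg.n_sites, p=_SNP_TYPE_PROBS)
    swap = rng.random(cfg.n_sites) < 0.5
    ref, alt = [], []
    for t, s in zip(type_idx, swap):
        a, b = _SNP_TYPES[t].split("/")
        ref.append(b if s else a)
        alt.append(a if s else b)

    ancestral = rng.uniform(0.05, 0.95, size=cfg.n_sites)
    if cfg.fst == 0.0:
        freqs = np.tile(ancestral, (cfg.n_founder_pops, 1))
    else:
        f = cfg.fst
        a = ancestral * (1 - f) / f
        b = (1 - ancestral) * (1 - f) / f
        freqs = rng.beta(a, b, size=(cfg.n_founder_pops, cfg.n_sites))

    sites = pd.DataFrame({
        "id": [f"{c}_{p}" for c, p in zip(chroms, pos)],
        "chrom": chroms,
        "pos": pos.astype(int),
        "ref": ref,
        "alt": alt,
        "ancestral_freq": ancestral,
    })
    pop_names = [f"pop{k + 1}" for k in range(cfg.n_founder_pops)]
    return FounderFrequencies(sites, freqs, pop_names)


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Build the three-generation pedigree of the breeding design.

    Every F1 cross pairs founders from two *different* populations; every
    F2 cross pairs F1 individuals from two different F1 families.  Parents
    may sire several crosses, as in a real hatchery.
    """
    if cfg.n_f1_crosses >= 1 and cfg.n_founder_pops < 2:
        raise ValueError("interpopulation F1 crosses need at least 2 founder populations")
    if cfg.n_f2_crosses >= 1 and cfg.n_f1_crosses < 2:
        raise ValueError("F2 crosses between distinct F1 families need at least 2 F1 crosses")
    rng = _rng(cfg.seed, 2)
    rows: list[tuple[str, str, str, str, str, str]] = []

    founders: list[list[str]] = []
    for k in range(cfg.n_founder_pops):
        pop = f"pop{k + 1}"
        members = []
        for i in range(cfg.founders_per_pop):
            ident = f"{pop}_f{i + 1}"
            members.append(ident)
            rows.append((ident, UNKNOWN_PARENT, UNKNOWN_PARENT, "founder", pop, ""))
        founders.append(members)

    f1_families: list[list[str]] = []
    for c in range(cfg.n_f1_crosses):
        pa, pb = rng.choice(cfg.n_founder_pops, size=2, replace=False)
        sire = founders[pa][rng.integers(len(founders[pa]))]
        dam = founders[pb][rng.integers(len(founders[pb]))]
        fam = f"F1c{c + 1}"
        members = []
        for k in range(cfg.offspring_per_cross):
            ident = f"{fam}_o{k + 1}"
            members.append(ident)
            rows.append((ident, sire, dam, "F1", "", fam))
        f1_families.append(members)

    for c in range(cfg.n_f2_crosses):
        fa, fb = rng.choice(cfg.n_f1_crosses, size=2, replace=False)
        sire = f1_families[fa][rng.integers(len(f1_families[fa]))]
        dam = f1_families[fb][rng.integers(len(f1_families[fb]))]
        fam = f"F2c{c + 1}"
        for k in range(cfg.offspring_per_cross):
            rows.append((f"{fam}_o{k + 1}", sire, dam, "F2", "", fam))

    table = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "generation", "population", "family"]
    )
    return Pedigree(table)


def simulate_genotypes(
    pedigree: Pedigree,
    freqs: FounderFrequencies,
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, NullAlleleTruth]:
    """Drop genotypes down the pedigree and render observed dosages.

    Founders draw two alleles independently from their population's
    frequencies (Hardy–Weinberg within populations); at null loci the
    invisible allele ``n`` takes frequency ``null_allele_freq`` and the
    visible alleles share the remainder in proportion to the population
    frequency.  Offspring receive one uniformly chosen allele per parent;
    sites segregate independently (no linkage map).

    Rendering and artefacts, in order: null rendering (``X/n`` → ``X/X``
    homozygote, ``n/n`` → missing), then symmetric genotyping error
    (an observed dosage is replaced by one of the other two, uniformly,
    with probability ``genotyping_error_rate``), then additional missing
    calls at ``missing_rate``.
    """
    rng = _rng(cfg.seed, 3)
    n_sites = len(freqs.sites)
    table = pedigree.table
    n_ind = len(table)
    pop_index = {name: k for k, name in enumerate(freqs.pop_names)}
    row_of = {ident: r for r, ident in enumerate(table["id"])}

    n_null = int(round(cfg.null_locus_fraction * n_sites))
    null_sites = np.sort(rng.choice(n_sites, size=n_null, replace=False))
    nu = np.zeros(n_sites)
    nu[null_sites] = cfg.null_allele_freq

    alleles = np.empty((n_ind, 2, n_sites), dtype=np.int8)
    for r, rec in enumerate(table.itertuples(index=False)):
        if rec.sire == UNKNOWN_PARENT and rec.dam == UNKNOWN_PARENT:
            if rec.generation != "founder":
                raise ValueError(f"non-founder {rec.id!r} lacks parents")
            try:
                p = freqs.freqs[pop_index[rec.population]]
            except KeyError:
                raise ValueError(
                    f"founder {rec.id!r} population {rec.population!r} "
                    "absent from frequency table"
                ) from None
            u = rng.random((2, n_sites))
            alleles[r] = np.where(
                u < nu, _NULL, np.where(u < nu + (1 - nu) * p, _ALT, _REF)
            )
        else:
            for slot, parent in enumerate((rec.sire, rec.dam)):
                if parent not in row_of:
                    raise ValueError(f"unknown parent id {parent!r} for {rec.id!r}")
                pick = rng.integers(0, 2, size=n_sites)
                alleles[r, slot] = alleles[row_of[parent], pick, np.arange(n_sites)]

    n_null_alleles = (alleles == _NULL).sum(axis=1)
    alt_count = (alleles == _ALT).sum(axis=1)
    observed = np.where(
        n_null_alleles == 2, MISSING,
        np.where(n_null_alleles == 1, 2 * alt_count, alt_count),
    ).astype(np.int8)

    carrier_rows, carrier_cols = np.nonzero(n_null_alleles > 0)
    site_ids = freqs.sites["id"].to_numpy()
    truth = NullAlleleTruth(
        null_site_ids=[site_ids[j] for j in null_sites],
        carriers=pd.DataFrame({
            "individual": table["id"].to_numpy()[carrier_rows],
            "site_id": site_ids[carrier_cols],
            "n_null_alleles": n_null_alleles[carrier_rows, carrier_cols],
        }),
    )

    if cfg.genotyping_error_rate > 0:
        err = (observed != MISSING) & (rng.random(observed.shape) < cfg.genotyping_error_rate)
        r = rng.integers(0, 2, size=observed.shape).astype(np.int8)
        replacement = np.where(observed == 0, 1 + r,
                               np.where(observed == 1, 2 * r, r)).astype(np.int8)
        observed = np.where(err, replacement, observed)
    if cfg.missing_rate > 0:
        observed = np.where(rng.random(observed.shape) < cfg.missing_rate,
                            np.int8(MISSING), observed)

    matrix = GenotypeMatrix(
        list(table["id"]),
        freqs.sites[["id", "chrom", "pos", "ref", "alt"]].copy(),
        observed,
    )
    return matrix, truth


def simulate_dataset(
    cfg: SimulationConfig, layout: GenomeLayout | None = None
) -> tuple[GenotypeMatrix, Pedigree, FounderFrequencies, NullAlleleTruth]:
    """Run the full generator: frequencies → pedigree → genotypes."""
    layout = layout or default_layout()
    freqs = simulate_founder_frequencies(layout, cfg)
    pedigree = simulate_pedigree(cfg)
    matrix, truth = simulate_genotypes(pedigree, freqs, cfg)
    return matrix, pedigree, freqs, truth


def write_outputs(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    layout: GenomeLayout,
    outdir: str | os.PathLike,
    reference_seed: int = 0,
) -> dict[str, Path]:
    """Serialise a simulated dataset: VCF, pedigree TSV and reference FASTA.

    The FASTA holds random sequence of the declared chromosome lengths,
    patched so the base at every site position equals that site's ref
    allele — probe flanks extracted from it are internally consistent.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([4, reference_seed]))
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sequences: dict[str, str] = {}
    for name, length in zip(layout.names, layout.lengths):
        seq = rng.choice(bases, size=length).astype("U1")
        on_chrom = matrix.sites[matrix.sites["chrom"] == name]
        seq[on_chrom["pos"].to_numpy() - 1] = on_chrom["ref"].to_numpy()
        sequences[name] = "".join(seq)
    return {
        "vcf": io.write_vcf(matrix, outdir / "genotypes.vcf", layout),
        "pedigree": io.write_pedigree(pedigree, outdir / "pedigree.tsv"),
        "fasta": io.write_fasta(sequences, outdir / "reference.fa"),
    }
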