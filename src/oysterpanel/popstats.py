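"""Panel validation statistics.

Call-rate QC, per-locus MAF / heterozygosity / F_IS, an exact
Hardy–Weinberg test with Bonferroni screening, genotype-dosage LD decay,
SNP-type conversion summaries and the chromosome-density correlation.

Conventions: He = 2p(1-p) with no small-sample correction;
F_IS = (He - Ho)/He, undefined (NaN) at monomorphic loci; the HWE test is
the exact conditional test that enumerates heterozygote counts compatible
with the observed allele counts and sums the probabilities of
configurations no more likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import pearsonr

from .core import MISSING, GenomeLayout, GenotypeMatrix

# ---------------------------------------------------------------------------
# call-rate QC


@dataclass
class QCReport:
    removed_individuals: list[str]
    removed_sites: list[str]
    n_individuals_before: int
    n_sites_before: int
    n_individuals_after: int
    n_sites_after: int


def qc_call_rates(
    matrix: GenotypeMatrix,
    min_individual_cr: float = 0.9,
    min_snp_cr: float = 0.9,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop low-call-rate individuals, then low-call-rate SNPs.

    Individuals are filtered first; SNP call rates are then recomputed on
    the retained individuals, mirroring the usual array-QC order.
    """
    ind_keep = matrix.individual_call_rates() >= min_individual_cr
    trimmed = matrix.subset(individual_mask=ind_keep)
    site_keep = trimmed.site_call_rates() >= min_snp_cr
    result = trimmed.subset(site_mask=site_keep)
    if result.n_individuals == 0 or result.n_sites == 0:
        raise ValueError(
            "QC removed everything: "
            f"{int(ind_keep.sum())}/{matrix.n_individuals} individuals and "
            f"{int(site_keep.sum())}/{matrix.n_sites} sites survive thresholds "
            f"(individual cr >= {min_individual_cr}, SNP cr >= {min_snp_cr})"
        )
    report = QCReport(
        removed_individuals=[s for s, k in zip(matrix.individuals, ind_keep) if not k],
        removed_sites=list(trimmed.sites.loc[~site_keep, "id"]),
        n_individuals_before=matrix.n_individuals,
        n_sites_before=matrix.n_sites,
        n_individuals_after=result.n_individuals,
        n_sites_after=result.n_sites,
    )
    return result, report


# ---------------------------------------------------------------------------
# per-locus statistics


def genotype_counts(matrix: GenotypeMatrix) -> np.ndarray:
    """(n_sites, 3) counts of dosage 0/1/2 among called genotypes."""
    counts = np.zeros((matrix.n_sites, 3), dtype=int)
    for d in (0, 1, 2):
        counts[:, d] = (matrix.dosages == d).sum(axis=0)
    return counts


def locus_stats(matrix: GenotypeMatrix, hwe: bool = True) -> pd.DataFrame:
    """Per-site MAF, Ho, He, F_IS, call rate and (optionally) HWE p-value.

    Returns a DataFrame indexed like ``matrix.sites`` with columns
    ``id, maf, ho, he, fis, call_rate`` (+ ``hwe_p``).  F_IS is NaN where
    He = 0.
    """
    counts = genotype_counts(matrix)
    n = counts.sum(axis=1)
    if (n == 0).any():
        raise ValueError("sites with zero called genotypes; run QC first")
    p = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n)
    he = 2 * p * (1 - p)
    ho = counts[:, 1] / n
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(he > 0, (he - ho) / np.where(he > 0, he, 1), np.nan)
    out = pd.DataFrame({
        "id": matrix.sites["id"],
        "maf": np.minimum(p, 1 - p),
        "ho": ho,
        "he": he,
        "fis": fis,
        "call_rate": matrix.site_call_rates(),
    })
    if hwe:
        out["hwe_p"] = [hwe_exact(*row) for row in counts]
    return out


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test


def _het_log_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Possible heterozygote counts given allele counts, with log-probs of
    the conditional (hypergeometric-like) distribution."""
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logw = (hets * np.log(2.0) - gammaln(rare_hom + 1) - gammaln(hets + 1)
            - gammaln(common_hom + 1))
    return hets, logw


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and enumerates every
    heterozygote count they allow; the p-value is the summed probability
    of all configurations with probability less than or equal to the
    observed one.  Always in (0, 1]; monomorphic samples give 1.
    """
    for v in (n_aa, n_ab, n_bb):
        if v < 0:
            raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    hets, logw = _het_log_probs(n, n_rare)
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    observed = n_ab
    p_obs = probs[np.nonzero(hets == observed)[0][0]]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_bonferroni(
    stats: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], int]:
    """Bonferroni HWE screen over polymorphic sites.

    The per-test threshold is ``alpha / n_polymorphic``; returns the ids
    of sites failing HWE and the count of polymorphic sites in HWE.
    """
    if len(stats) == 0:
        raise ValueError("empty locus-stats table")
    poly = stats[stats["maf"] > 0]
    if len(poly) == 0:
        return [], 0
    threshold = alpha / len(poly)
    failing = poly[poly["hwe_p"] < threshold]
    return list(failing["id"]), len(poly) - len(failing)


# ---------------------------------------------------------------------------
# LD decay


@dataclass
class LDDecayCurve:
    bin_edges: np.ndarray        # len nbins+1, bp
    mean_r2: np.ndarray          # len nbins, NaN where no pairs
    pair_counts: np.ndarray      # len nbins
    half_max_distance: float | None
    below_01_distance: float | None
    max_mean_r2: float = field(default=float("nan"))

    def to_frame(self) -> pd.DataFrame:
        mids = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1],
            "bin_end": self.bin_edges[1:],
            "bin_mid": mids,
            "mean_r2": self.mean_r2,
            "n_pairs": self.pair_counts,
        })


def default_ld_bins(max_distance_bp: int = 500_000) -> np.ndarray:
    """Fine bins (100 bp) to 20 kb, coarse (1 kb) beyond, up to the cap."""
    fine_top = min(20_000, max_distance_bp)
    edges = list(range(0, fine_top + 1, 100))
    if max_distance_bp > 20_000:
        edges += list(range(21_000, max_distance_bp + 1, 1000))
    return np.asarray(edges, dtype=float)


def pairwise_r2(x: np.ndarray, y: np.ndarray, min_individuals: int) -> float | None:
    """Squared Pearson correlation of two dosage vectors over individuals
    called at both sites; None when too few individuals or no variance."""
    mask = (x != MISSING) & (y != MISSING)
    if int(mask.sum()) < min_individuals:
        return None
    xv = x[mask].astype(float)
    yv = y[mask].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return None
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_decay(
    matrix: GenotypeMatrix,
    max_distance_bp: int = 500_000,
    bin_width_bp: int | None = None,
    min_pairs_individuals: int = 10,
) -> LDDecayCurve:
    """Genotype-dosage LD decay curve.

    Every same-chromosome pair with ``0 < distance <= max_distance_bp``
    contributes its r² to a distance bin; ``bin_width_bp=None`` uses the
    composite default binning (100 bp to 20 kb, then 1 kb).  Reported
    summary distances are the first bin midpoint where the mean r² drops
    to half its maximum, and where it drops below 0.1.
    """
    edges = (np.arange(0, max_distance_bp + bin_width_bp, bin_width_bp, dtype=float)
             if bin_width_bp else default_ld_bins(max_distance_bp))
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)

    sites = matrix.sites
    for _, group in sites.groupby("chrom"):
        order = np.argsort(group["pos"].to_numpy(), kind="mergesort")
        idx = group.index.to_numpy()[order]
        pos = group["pos"].to_numpy()[order]
        for a in range(len(idx)):
            b = a + 1
            while b < len(idx) and pos[b] - pos[a] <= max_distance_bp:
                dist = pos[b] - pos[a]
                if dist > 0:
                    r2 = pairwise_r2(matrix.dosages[:, idx[a]],
                                     matrix.dosages[:, idx[b]],
                                     min_pairs_individuals)
                    if r2 is not None:
                        k = min(np.searchsorted(edges, dist, side="left") - 1,
                                nbins - 1)
                        sums[k] += r2
                        counts[k] += 1
                b += 1

    if counts.sum() == 0:
        raise ValueError("no eligible SNP pairs within the distance cap")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (edges[:-1] + edges[1:]) / 2
    peak = np.nanmax(means)

    def first_below(level: float) -> float | None:
        ok = ~np.isnan(means) & (means <= level)
        return float(mids[ok][0]) if ok.any() else None

    return LDDecayCurve(
        bin_edges=edges, mean_r2=means, pair_counts=counts,
        half_max_distance=first_below(peak / 2),
        below_01_distance=first_below(np.nextafter(0.1, 0)),
        max_mean_r2=float(peak),
    )


# ---------------------------------------------------------------------------
# conversion summary

SNP_TYPES = ("A/G", "C/T", "G/T", "A/C", "A/T", "C/G")
TRANSITIONS = ("A/G", "C/T")


def classify_snp_type(allele1: str, allele2: str) -> str:
    """Unordered allele pair → one of the six biallelic SNP types."""
    a, b = sorted((allele1.upper(), allele2.upper()))
    if a not in "ACGT" or b not in "ACGT" or len(a) != 1 or len(b) != 1 or a == b:
        raise ValueError(f"not a biallelic SNP allele pair: {allele1}/{allele2}")
    return f"{a}/{b}"


@dataclass
class ConversionSummary:
    """Per-SNP-type on-chip and converted counts with conversion rates."""

    table: pd.DataFrame   # snp_type, on_chip, on_chip_pct, converted,
                          # converted_pct, rate (2 dp)
    total_on_chip: int
    total_converted: int

    @property
    def overall_rate(self) -> float:
        return round(self.total_converted / self.total_on_chip, 2)

    @classmethod
    def from_counts(cls, on_chip: dict[str, int],
                    converted: dict[str, int]) -> "ConversionSummary":
        rows = []
        tot_on = sum(on_chip.values())
        tot_conv = sum(converted.values())
        for t in SNP_TYPES:
            n_on = on_chip.get(t, 0)
            n_conv = converted.get(t, 0)
            if n_conv > n_on:
                raise ValueError(f"type {t}: converted {n_conv} exceeds on-chip {n_on}")
            rows.append({
                "snp_type": t,
                "transition": t in TRANSITIONS,
                "on_chip": n_on,
                "on_chip_pct": round(100 * n_on / tot_on) if tot_on else 0,
                "converted": n_conv,
                "converted_pct": round(100 * n_conv / tot_conv) if tot_conv else 0,
                "rate": round(n_conv / n_on, 2) if n_on else float("nan"),
            })
        return cls(pd.DataFrame(rows), tot_on, tot_conv)


def conversion_summary(
    manifest: pd.DataFrame, converted_ids
) -> ConversionSummary:
    """Classify manifest probes into SNP types and tabulate conversion.

    ``manifest`` needs columns ``id, ref, alt``; ``converted_ids`` is the
    set of probe ids that yielded reliable polymorphic calls.  Every
    converted id must exist in the manifest.
    """
    converted_ids = set(converted_ids)
    unknown = converted_ids - set(manifest["id"])
    if unknown:
        raise ValueError(f"converted ids absent from manifest: {sorted(unknown)[:5]}")
    types = [classify_snp_type(r, a) for r, a in zip(manifest["ref"], manifest["alt"])]
    on_chip: dict[str, int] = {}
    converted: dict[str, int] = {}
    for t, ident in zip(types, manifest["id"]):
        on_chip[t] = on_chip.get(t, 0) + 1
        if ident in converted_ids:
            converted[t] = converted.get(t, 0) + 1
    return ConversionSummary.from_counts(on_chip, converted)


# ---------------------------------------------------------------------------
# chromosome density correlation & cohort summary


def chromosome_density_correlation(
    sites: pd.DataFrame, layout: GenomeLayout
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-chromosome SNP
    counts and chromosome lengths."""
    if layout.n_chromosomes < 3:
        raise ValueError("need at least 3 chromosomes")
    counts = sites["chrom"].value_counts()
    x = np.asarray([counts.get(name, 0) for name in layout.names], dtype=float)
    y = np.asarray(layout.lengths, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in counts or lengths")
    r, p = pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CohortSummary:
    """Headline panel-validation ratios for one cohort.

    Percentages follow the panel-report convention: polymorphic % is out
    of called SNPs, HWE % out of polymorphic SNPs, both to 2 decimals.
    """

    n_called_snps: int
    n_polymorphic: int
    n_in_hwe: int
    mean_ho: float = float("nan")
    mean_he: float = float("nan")
    mean_fis: float = float("nan")

    @property
    def pct_polymorphic(self) -> float:
        return round(100 * self.n_polymorphic / self.n_called_snps, 2)

    @property
    def pct_in_hwe(self) -> float:
        return round(100 * self.n_in_hwe / self.n_polymorphic, 2)


def cohort_summary(
    stats: pd.DataFrame,
    maf_threshold: float = 0.05,
    alpha: float = 0.05,
) -> CohortSummary:
    """Summarise a cohort's locus stats: polymorphism (MAF > threshold),
    Bonferroni-screened HWE among polymorphic sites, and mean Ho/He/F_IS
    over polymorphic sites."""
    poly = stats[stats["maf"] > maf_threshold]
    if len(poly) == 0:
        raise ValueError("no polymorphic sites at the MAF threshold")
    failing, n_in_hwe = hwe_bonferroni(poly, alpha)
    return CohortSummary(
        n_called_snps=len(stats),
        n_polymorphic=len(poly),
        n_in_hwe=n_in_hwe,
        mean_ho=float(poly["ho"].mean()),
        mean_he=float(poly["he"].mean()),
        mean_fis=float(poly["fis"].mean()),
    )
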