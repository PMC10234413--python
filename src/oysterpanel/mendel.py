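"""Trio-based Mendelian inheritance error (MIE) analysis.

Implements the standard eight-code taxonomy for biallelic trio errors
(A = ref homozygote, B = alt homozygote, ``*/*`` = any or missing parent):

====  ==========================  ===============
code  pattern                     null-consistent
====  ==========================  ===============
1     A/A x A/A -> A/B            no
2     B/B x B/B -> A/B            no
3     B/B x */* -> A/A (sire)     yes
4     */* x B/B -> A/A (dam)      yes
5     B/B x B/B -> A/A            no
6     A/A x */* -> B/B (sire)     yes
7     */* x A/A -> B/B (dam)      yes
8     A/A x A/A -> B/B            no
====  ==========================  ===============

Codes 3/4/6/7 — a homozygous child opposite to one homozygous parent —
are exactly the patterns a segregating null allele produces: a true
``B/n`` parent is rendered ``B/B`` while its ``A/n`` child is rendered
``A/A``.  Their aggregate share of all errors is the null-allele
diagnostic; individual- and SNP-level error rates plus an interquartile
outlier threshold complete the per-panel report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core import MISSING, GenotypeMatrix, Pedigree, UNKNOWN_PARENT

NULL_CONSISTENT_CODES = frozenset({3, 4, 6, 7})

CODE_DESCRIPTIONS = {
    1: "A/A x A/A -> A/B",
    2: "B/B x B/B -> A/B",
    3: "B/B x */* -> A/A",
    4: "*/* x B/B -> A/A",
    5: "B/B x B/B -> A/A",
    6: "A/A x */* -> B/B",
    7: "*/* x A/A -> B/B",
    8: "A/A x A/A -> B/B",
}


def classify_trios(
    sire: np.ndarray, dam: np.ndarray, child: np.ndarray
) -> np.ndarray:
    """Vectorised trio classification; 0 = consistent (or missing child).

    Precedence: both-homozygous-parent codes (5, 8) before single-parent
    codes (3, 4, 6, 7) before heterozygous-child codes (1, 2), so each
    error receives exactly one code.  A missing parent genotype only ever
    matches the ``*/*`` wildcard, never a homozygote pattern.
    """
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    child = np.asarray(child)
    for arr, who in ((sire, "sire"), (dam, "dam"), (child, "child")):
        if not np.isin(arr, (0, 1, 2, MISSING)).all():
            raise ValueError(f"invalid {who} dosage outside {{0,1,2,missing}}")
    code = np.zeros(np.broadcast(sire, dam, child).shape, dtype=np.int8)
    valid = child != MISSING
    s_aa, s_bb = sire == 0, sire == 2
    d_aa, d_bb = dam == 0, dam == 2
    c_aa, c_ab, c_bb = child == 0, child == 1, child == 2

    code[valid & s_bb & d_bb & c_aa] = 5
    code[valid & s_aa & d_aa & c_bb] = 8
    rem = valid & (code == 0)
    code[rem & s_bb & c_aa] = 3
    code[rem & d_bb & c_aa] = 4
    code[rem & s_aa & c_bb] = 6
    code[rem & d_aa & c_bb] = 7
    rem = valid & (code == 0)
    code[rem & s_aa & d_aa & c_ab] = 1
    code[rem & s_bb & d_bb & c_ab] = 2
    return code


def classify_trio(
    sire_dosage: int, dam_dosage: int, child_dosage: int
) -> int | None:
    """Scalar form of :func:`classify_trios`; None when consistent."""
    code = classify_trios(np.asarray([sire_dosage]), np.asarray([dam_dosage]),
                          np.asarray([child_dosage]))[0]
    return int(code) if code else None


@dataclass
class MIEReport:
    """Per-individual and per-SNP MIE rates with the code breakdown."""

    per_individual: pd.DataFrame   # id, n_errors, n_called, rate
    per_snp: pd.DataFrame          # id, n_errors, n_trios, rate
    code_counts: dict[int, int]
    total_errors: int
    n_offspring: int
    outlier_threshold: float | None = None
    flagged_snp_ids: list[str] | None = None

    @property
    def code_proportions(self) -> dict[int, float]:
        if self.total_errors == 0:
            return {c: float("nan") for c in range(1, 9)}
        return {c: self.code_counts.get(c, 0) / self.total_errors
                for c in range(1, 9)}


def mie_rates(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    per_site_denominator: bool = False,
) -> MIEReport:
    """Classify every (offspring, site) against the parental genotypes.

    Offspring with at least one known, genotyped parent are tested; an
    unknown or ungenotyped parent contributes missing dosages, so such
    duos can still yield the single-parent codes.  The individual-level
    rate divides by the offspring's called-SNP count.  The SNP-level rate
    divides by the (constant) number of tested offspring; set
    ``per_site_denominator=True`` to divide by the per-site count of
    offspring actually called instead.
    """
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    offspring = pedigree.offspring_with_parents()
    offspring = offspring[offspring["id"].isin(matrix.individuals)]
    if len(offspring) == 0:
        raise ValueError("no pedigree offspring present in the genotype matrix")

    missing_row = np.full(matrix.n_sites, MISSING, dtype=np.int8)

    def parent_dosages(parent_id: str) -> np.ndarray:
        if parent_id == UNKNOWN_PARENT or parent_id not in matrix.individuals:
            return missing_row
        return matrix.dosages[matrix.row_index(parent_id)]

    child_rows = np.stack([matrix.dosages[matrix.row_index(i)]
                           for i in offspring["id"]])
    sire_rows = np.stack([parent_dosages(s) for s in offspring["sire"]])
    dam_rows = np.stack([parent_dosages(d) for d in offspring["dam"]])

    codes = classify_trios(sire_rows, dam_rows, child_rows)
    is_error = codes > 0

    n_called = (child_rows != MISSING).sum(axis=1)
    ind_errors = is_error.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ind_rates = np.where(n_called > 0, ind_errors / np.maximum(n_called, 1),
                             np.nan)
    per_individual = pd.DataFrame({
        "id": offspring["id"].to_numpy(),
        "n_errors": ind_errors,
        "n_called": n_called,
        "rate": ind_rates,
    })

    snp_errors = is_error.sum(axis=0)
    if per_site_denominator:
        denom = (child_rows != MISSING).sum(axis=0)
    else:
        denom = np.full(matrix.n_sites, len(offspring))
    with np.errstate(divide="ignore", invalid="ignore"):
        snp_rates = np.where(denom > 0, snp_errors / np.maximum(denom, 1), np.nan)
    per_snp = pd.DataFrame({
        "id": matrix.sites["id"],
        "n_errors": snp_errors,
        "n_trios": denom,
        "rate": snp_rates,
    })

    tallies = np.bincount(codes[is_error].ravel(), minlength=9)
    report = MIEReport(
        per_individual=per_individual,
        per_snp=per_snp,
        code_counts={c: int(tallies[c]) for c in range(1, 9) if tallies[c]},
        total_errors=int(is_error.sum()),
        n_offspring=len(offspring),
    )
    if len(per_snp) >= 4:
        threshold, flagged = iqr_threshold(per_snp["rate"].to_numpy())
        report.outlier_threshold = threshold
        report.flagged_snp_ids = list(per_snp.loc[flagged, "id"])
    return report


def iqr_threshold(per_snp_rates: np.ndarray) -> tuple[float, np.ndarray]:
    """Upper outlier fence Q3 + 1.5*IQR over per-SNP error rates.

    Quantiles use linear interpolation between order statistics.  Returns
    the threshold and a boolean mask of rates strictly above it.
    """
    rates = np.asarray(per_snp_rates, dtype=float)
    if rates.size < 4:
        raise ValueError("need at least 4 rates for quartiles")
    q1, q3 = np.quantile(rates, [0.25, 0.75], method="linear")
    threshold = float(q3 + 1.5 * (q3 - q1))
    return threshold, rates > threshold


def retention_table(
    per_snp_rates: np.ndarray, cutoffs=(0.0, 0.01, 0.02, 0.03, 0.05)
) -> pd.DataFrame:
    """SNPs retained (rate <= cutoff) at each cutoff, with percentages."""
    rates = np.asarray(per_snp_rates, dtype=float)
    rows = [{
        "cutoff": c,
        "n_retained": int((rates <= c).sum()),
        "pct_retained": retention_percent(int((rates <= c).sum()), rates.size),
    } for c in cutoffs]
    return pd.DataFrame(rows)


def retention_percent(n_retained: int, n_total: int) -> int:
    """Percent of SNPs retained, to the whole percent of panel reports."""
    return round(100 * n_retained / n_total)


def individual_mie_rate_percent(n_errors: int, n_called: int) -> float:
    """An individual's MIE rate as a percentage, to one decimal."""
    return round(100 * n_errors / n_called, 1)


@dataclass
class FisMieCorrelation:
    r_overall: float
    p_overall: float
    r_below: float      # NaN when undefined (zero variance / too few sites)
    r_above: float
    split_at: float
    n_below: int
    n_above: int


def fis_mie_correlation(
    locus_stats: pd.DataFrame,
    per_snp: pd.DataFrame,
    split_at: float = 0.01,
) -> FisMieCorrelation:
    """Pearson correlation between per-locus F_IS and MIE rate.

    Also reports the correlation within the low-error (rate < split_at)
    and high-error (rate >= split_at) strata — under the null-allele
    mechanism the signal concentrates in the high-error stratum.
    """
    merged = locus_stats[["id", "fis"]].merge(per_snp[["id", "rate"]], on="id")
    merged = merged.dropna(subset=["fis", "rate"])

    def corr(frame: pd.DataFrame) -> tuple[float, float]:
        if len(frame) < 3:
            return float("nan"), float("nan")
        if frame["fis"].std() == 0 or frame["rate"].std() == 0:
            return float("nan"), float("nan")
        r, p = pearsonr(frame["fis"], frame["rate"])
        return float(r), float(p)

    r_all, p_all = corr(merged)
    if np.isnan(r_all):
        raise ValueError("overall F_IS/MIE correlation undefined (zero variance)")
    below = merged[merged["rate"] < split_at]
    above = merged[merged["rate"] >= split_at]
    return FisMieCorrelation(
        r_overall=r_all, p_overall=p_all,
        r_below=corr(below)[0], r_above=corr(above)[0],
        split_at=split_at, n_below=len(below), n_above=len(above),
    )


def null_allele_diagnosis(report: MIEReport) -> tuple[float, pd.DataFrame]:
    """Share of errors in the null-consistent codes, with the code table.

    Returns the proportion of all errors carried by codes {3, 4, 6, 7}
    and a per-code table (code, description, null_consistent, count,
    proportion).  Proportions near 1 indicate null alleles rather than
    random genotyping error as the dominant failure mode.
    """
    if report.total_errors == 0:
        raise ValueError("no Mendelian errors to diagnose")
    props = report.code_proportions
    table = pd.DataFrame([{
        "code": c,
        "description": CODE_DESCRIPTIONS[c],
        "null_consistent": c in NULL_CONSISTENT_CODES,
        "count": report.code_counts.get(c, 0),
        "proportion": props[c],
    } for c in range(1, 9)])
    proportion = sum(props[c] for c in NULL_CONSISTENT_CODES)
    return float(proportion), table
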