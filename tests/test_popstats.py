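"""Validation-statistics tests: QC, locus stats, exact HWE, LD decay,
conversion summary and density correlation."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from conftest import matrix_from_counts, matrix_from_dosages
from oysterpanel.core import MISSING, GenomeLayout
from oysterpanel.popstats import (
    CohortSummary,
    ConversionSummary,
    chromosome_density_correlation,
    classify_snp_type,
    cohort_summary,
    conversion_summary,
    hwe_bonferroni,
    hwe_exact,
    ld_decay,
    locus_stats,
    qc_call_rates,
)

# ---------------------------------------------------------------------------
# call-rate QC


class TestQC:
    def test_individual_above_threshold_retained(self):
        dosages = np.ones((2, 20), dtype=np.int8)
        dosages[0, 0] = MISSING  # 95% called
        dosages[1, :3] = MISSING  # 85% called
        m = matrix_from_dosages(dosages)
        result, report = qc_call_rates(m, 0.9, 0.0)
        assert result.individuals == ["i0"]
        assert report.removed_individuals == ["i1"]

    def test_fully_called_matrix_unchanged(self):
        m = matrix_from_dosages(np.ones((5, 8), dtype=np.int8))
        result, report = qc_call_rates(m)
        assert result.individuals == m.individuals
        assert result.n_sites == m.n_sites
        assert report.removed_sites == []

    def test_matches_brute_force_on_random_missingness(self):
        rng = np.random.default_rng(8)
        dosages = rng.integers(0, 3, size=(40, 80)).astype(np.int8)
        dosages[rng.random(dosages.shape) < 0.05] = MISSING
        m = matrix_from_dosages(dosages)
        result, _ = qc_call_rates(m, 0.96, 0.97)
        # brute force: individuals first, then SNPs on the survivors
        ind_keep = [(dosages[i] != MISSING).mean() >= 0.96
                    for i in range(m.n_individuals)]
        kept_rows = dosages[np.asarray(ind_keep)]
        site_keep = [(kept_rows[:, j] != MISSING).mean() >= 0.97
                     for j in range(m.n_sites)]
        assert result.individuals == [s for s, k in zip(m.individuals, ind_keep) if k]
        assert list(result.sites["id"]) == [
            s for s, k in zip(m.sites["id"], site_keep) if k]

    def test_everything_filtered_errors(self):
        m = matrix_from_dosages(np.full((3, 3), MISSING, dtype=np.int8))
        with pytest.raises(ValueError, match="QC removed everything"):
            qc_call_rates(m)


# ---------------------------------------------------------------------------
# locus statistics


@pytest.mark.parametrize("counts,expect", [
    # (nAA, nAB, nBB) -> (maf, he, ho, fis)
    ((25, 50, 25), (0.5, 0.5, 0.5, 0.0)),
    ((50, 0, 50), (0.5, 0.5, 0.0, 1.0)),       # complete heterozygote deficit
    ((30, 60, 10), (0.4, 0.48, 0.6, -0.25)),   # hand arithmetic, p = 0.4
])
def test_locus_stats_hand_examples(counts, expect):
    stats = locus_stats(matrix_from_counts(*counts), hwe=False)
    maf, he, ho, fis = expect
    row = stats.iloc[0]
    assert row["maf"] == pytest.approx(maf)
    assert row["he"] == pytest.approx(he)
    assert row["ho"] == pytest.approx(ho)
    assert row["fis"] == pytest.approx(fis)


def test_fis_undefined_at_monomorphic_locus():
    stats = locus_stats(matrix_from_counts(10, 0, 0), hwe=False)
    assert np.isnan(stats["fis"].iloc[0])
    assert stats["he"].iloc[0] == 0


def test_fis_boundary_identities():
    # Fis = 0 when Ho == He exactly; Fis = 1 when Ho = 0 and He > 0
    exact = locus_stats(matrix_from_counts(1, 2, 1), hwe=False)
    assert exact["fis"].iloc[0] == pytest.approx(0.0)
    no_hets = locus_stats(matrix_from_counts(3, 0, 7), hwe=False)
    assert no_hets["fis"].iloc[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# exact HWE test


def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Integer-arithmetic enumeration of the conditional distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        weights[h] = (Fraction(factorial(n),
                               factorial(rare_hom) * factorial(h)
                               * factorial(common_hom)) * 2 ** h)
    total = sum(weights.values())
    w_obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestHweExact:
    def test_modal_configuration_gives_one(self):
        assert hwe_exact(1, 2, 1) == pytest.approx(1.0)
        assert hwe_exact_oracle(1, 2, 1) == 1

    def test_extreme_heterozygote_deficit(self):
        assert hwe_exact(50, 0, 50) < 1e-20
        assert float(hwe_exact_oracle(50, 0, 50)) < 1e-20

    def test_monomorphic_sample_gives_one(self):
        assert hwe_exact(17, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 1)

    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 13):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact(n_aa, n_ab, n_bb)
                    want = float(hwe_exact_oracle(n_aa, n_ab, n_bb))
                    assert got == pytest.approx(want, rel=1e-9), (n_aa, n_ab, n_bb)


class TestBonferroni:
    def _stats(self, pvals, mafs=None):
        n = len(pvals)
        return pd.DataFrame({
            "id": [f"s{i}" for i in range(n)],
            "maf": mafs if mafs is not None else [0.3] * n,
            "hwe_p": pvals,
        })

    def test_all_p_one_no_failures(self):
        failing, n_ok = hwe_bonferroni(self._stats([1.0] * 20))
        assert failing == [] and n_ok == 20

    def test_threshold_arithmetic(self):
        pvals = [1.0] * 99 + [1e-10]
        failing, n_ok = hwe_bonferroni(self._stats(pvals), alpha=0.05)
        assert failing == ["s99"] and n_ok == 99
        # 1e-10 < 0.05/100 = 5e-4; a p just above the threshold survives
        pvals[99] = 6e-4
        failing, _ = hwe_bonferroni(self._stats(pvals), alpha=0.05)
        assert failing == []

    def test_monomorphic_sites_not_tested(self):
        failing, n_ok = hwe_bonferroni(self._stats([1.0, 1e-12],
                                                   mafs=[0.3, 0.0]))
        assert failing == [] and n_ok == 1

    def test_simulated_hwe_population_mostly_retained(self):
        rng = np.random.default_rng(99)
        n_ind, n_sites = 100, 10_000
        p = rng.uniform(0.1, 0.9, size=n_sites)
        n_bb = rng.binomial(n_ind, p * p)
        rest = n_ind - n_bb
        n_ab = rng.binomial(rest, 2 * p * (1 - p) / (1 - p * p))
        pvals = [hwe_exact(n_ind - bb - ab, ab, bb)
                 for ab, bb in zip(n_ab, n_bb)]
        failing, n_ok = hwe_bonferroni(self._stats(pvals), alpha=0.05)
        assert n_ok / n_sites >= 0.99


# ---------------------------------------------------------------------------
# LD decay


class TestLDDecay:
    def test_duplicated_column_perfect_r2(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=50).astype(np.int8)
        m = matrix_from_dosages(np.column_stack([col, col]), spacing=100)
        curve = ld_decay(m, max_distance_bp=1000, bin_width_bp=100)
        assert curve.max_mean_r2 == pytest.approx(1.0)
        assert curve.pair_counts.sum() == 1

    def test_independent_sites_mean_r2_near_reciprocal_n(self):
        rng = np.random.default_rng(2)
        n = 1000
        dosages = rng.binomial(2, 0.5, size=(n, 40)).astype(np.int8)
        m = matrix_from_dosages(dosages, spacing=1000)
        curve = ld_decay(m, max_distance_bp=50_000, bin_width_bp=5000)
        mean_r2 = (np.nansum(curve.mean_r2 * curve.pair_counts)
                   / curve.pair_counts.sum())
        assert 0.5 / n < mean_r2 < 2.0 / n

    def test_binned_means_match_brute_force(self):
        rng = np.random.default_rng(3)
        dosages = rng.integers(0, 3, size=(60, 50)).astype(np.int8)
        dosages[rng.random(dosages.shape) < 0.1] = MISSING
        pos = np.sort(rng.choice(5000, size=50, replace=False)) + 1
        m = matrix_from_dosages(dosages)
        m.sites["pos"] = pos
        width, maxd = 500, 5000
        curve = ld_decay(m, max_distance_bp=maxd, bin_width_bp=width,
                         min_pairs_individuals=10)
        sums = np.zeros(len(curve.mean_r2))
        counts = np.zeros(len(curve.mean_r2), dtype=int)
        for a in range(50):
            for b in range(a + 1, 50):
                d = abs(int(pos[b]) - int(pos[a]))
                if d == 0 or d > maxd:
                    continue
                both = (dosages[:, a] != MISSING) & (dosages[:, b] != MISSING)
                if both.sum() < 10:
                    continue
                x, y = dosages[both, a], dosages[both, b]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x.astype(float), y.astype(float))[0, 1]
                k = (d - 1) // width
                sums[k] += r * r
                counts[k] += 1
        assert np.array_equal(curve.pair_counts, counts)
        with np.errstate(invalid="ignore"):
            expect = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        np.testing.assert_allclose(curve.mean_r2, expect, equal_nan=True)

    def test_mean_r2_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(4)
        dosages = rng.integers(0, 3, size=(80, 10)).astype(np.int8)
        m1 = matrix_from_dosages(dosages, spacing=50)
        swapped = dosages.copy()
        swapped[:, 3] = 2 - swapped[:, 3]
        m2 = matrix_from_dosages(swapped, spacing=50)
        c1 = ld_decay(m1, max_distance_bp=1000, bin_width_bp=100)
        c2 = ld_decay(m2, max_distance_bp=1000, bin_width_bp=100)
        np.testing.assert_allclose(c1.mean_r2, c2.mean_r2, equal_nan=True)

    def test_no_eligible_pairs_errors(self):
        m = matrix_from_dosages(np.ones((30, 2), dtype=np.int8), spacing=10_000)
        with pytest.raises(ValueError, match="no eligible"):
            ld_decay(m, max_distance_bp=100, bin_width_bp=10)

    def test_half_max_and_threshold_distances(self):
        # one perfectly linked pair at 50 bp, independent sites far away:
        # the curve drops from r2 = 1 to ~0 in the (800, 900] bin
        rng = np.random.default_rng(6)
        n = 200
        a = rng.integers(0, 3, size=n).astype(np.int8)
        others = rng.integers(0, 3, size=(n, 2)).astype(np.int8)
        m = matrix_from_dosages(np.column_stack([a, a, others]))
        m.sites["pos"] = [100, 150, 1000, 5000]
        curve = ld_decay(m, max_distance_bp=5000, bin_width_bp=100)
        assert curve.max_mean_r2 == pytest.approx(1.0)
        assert curve.half_max_distance == 850  # midpoint of (800, 900]
        assert curve.below_01_distance == 850


# ---------------------------------------------------------------------------
# conversion summary

TABLE_ON_CHIP = {"A/G": 61_504, "C/T": 61_594, "G/T": 23_892,
                 "A/C": 24_310, "A/T": 35_852, "C/G": 12_295}
TABLE_CONVERTED = {"A/G": 40_499, "C/T": 40_626, "G/T": 14_368,
                   "A/C": 14_754, "A/T": 20_211, "C/G": 8_478}


class TestConversion:
    def test_unordered_alphabetical_classification(self):
        assert classify_snp_type("G", "A") == "A/G"
        assert classify_snp_type("t", "c") == "C/T"

    def test_non_acgt_allele_rejected(self):
        with pytest.raises(ValueError):
            classify_snp_type("A", "N")
        with pytest.raises(ValueError):
            classify_snp_type("A", "A")

    def test_printed_manifest_counts_reproduce_rates(self):
        summary = ConversionSummary.from_counts(TABLE_ON_CHIP, TABLE_CONVERTED)
        rates = dict(zip(summary.table["snp_type"], summary.table["rate"]))
        assert rates["A/G"] == 0.66
        assert rates["A/T"] == 0.56
        assert summary.overall_rate == 0.63

    def test_manifest_classification_roundtrip(self):
        manifest = pd.DataFrame({
            "id": ["a", "b", "c", "d"],
            "ref": ["G", "C", "T", "A"],
            "alt": ["A", "T", "G", "T"],
        })
        summary = conversion_summary(manifest, ["a", "c"])
        table = summary.table.set_index("snp_type")
        assert table.loc["A/G", "on_chip"] == 1
        assert table.loc["A/G", "converted"] == 1
        assert table.loc["C/T", "converted"] == 0
        assert table.loc["G/T", "rate"] == 1.0
        assert summary.total_on_chip == 4 and summary.total_converted == 2

    def test_converted_id_missing_from_manifest_errors(self):
        manifest = pd.DataFrame({"id": ["a"], "ref": ["A"], "alt": ["G"]})
        with pytest.raises(ValueError, match="absent from manifest"):
            conversion_summary(manifest, ["ghost"])

    def test_transitions_flagged(self):
        summary = ConversionSummary.from_counts(TABLE_ON_CHIP, TABLE_CONVERTED)
        trans = summary.table[summary.table["transition"]]
        assert set(trans["snp_type"]) == {"A/G", "C/T"}


# ---------------------------------------------------------------------------
# density correlation & cohort summary


class TestDensityCorrelation:
    layout = GenomeLayout(tuple(f"c{i}" for i in range(5)),
                          (100, 200, 300, 400, 500))

    def _sites(self, counts):
        rows = []
        for name, k in zip(self.layout.names, counts):
            rows += [{"chrom": name}] * k
        return pd.DataFrame(rows)

    def test_proportional_counts_give_r_one(self):
        r, p = chromosome_density_correlation(self._sites([1, 2, 3, 4, 5]),
                                              self.layout)
        assert r == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        counts = [7, 3, 9, 2, 6]
        r, _ = chromosome_density_correlation(self._sites(counts), self.layout)
        x = np.array(counts, float)
        y = np.array(self.layout.lengths, float)
        manual = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(manual)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            chromosome_density_correlation(self._sites([2, 2, 2, 2, 2]),
                                           self.layout)

    def test_too_few_chromosomes_errors(self):
        layout = GenomeLayout(("a", "b"), (10, 20))
        with pytest.raises(ValueError, match="3 chromosomes"):
            chromosome_density_correlation(pd.DataFrame({"chrom": ["a"]}), layout)


def test_cohort_summary_percentages_from_counts():
    s = CohortSummary(n_called_snps=144_570, n_polymorphic=138_992,
                      n_in_hwe=130_148)
    assert s.pct_polymorphic == 96.14
    assert s.pct_in_hwe == 93.64


def test_cohort_summary_from_locus_stats(small_dataset):
    matrix = small_dataset[0]
    stats = locus_stats(matrix)
    summary = cohort_summary(stats)
    assert 0 < summary.n_polymorphic <= summary.n_called_snps
    assert 0 <= summary.pct_in_hwe <= 100
    assert abs(summary.mean_fis) < 0.3
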