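"""Genotype QC filters: allele frequency, HWE, missingness, heterozygosity,
LD pruning, relatedness, ancestry assignment, and the orchestrator."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from cogsys.qc import (
    QcConfig,
    assign_ancestry,
    het_outlier_filter,
    hwe_exact_test,
    ld_prune,
    maf_filter,
    missingness_filters,
    relatedness_filter,
    run_qc,
)
from conftest import make_genotypes


class TestMafFilter:
    def test_rare_allele_threshold_boundary(self):
        # dosages {0,0,0,1}: 1 alt allele of 8 -> MAF 0.125
        G = make_genotypes([[0, 2], [0, 1], [0, 1], [1, 1]])
        assert maf_filter(G, 0.01).n_snps == 2
        assert maf_filter(G, 0.2).snp_ids.tolist() == ["s1"]

    def test_monomorphic_always_removed(self):
        G = make_genotypes([[0, 1], [0, 1], [0, 1]])
        assert maf_filter(G, 0.01).snp_ids.tolist() == ["s1"]

    def test_all_het_always_kept(self):
        G = make_genotypes([[1, 0], [1, 2], [1, 1], [1, 1]])
        assert "s0" in maf_filter(G, 0.49).snp_ids

    def test_all_missing_snp_removed_with_warning(self):
        G = make_genotypes([[np.nan, 1], [np.nan, 0], [np.nan, 1]])
        with pytest.warns(UserWarning, match="all-missing"):
            out = maf_filter(G, 0.01)
        assert out.snp_ids.tolist() == ["s1"]

    def test_refiltering_is_identity(self):
        G = make_genotypes([[0, 2, 1], [0, 1, 1], [1, 1, 0], [2, 0, 1]])
        once = maf_filter(G, 0.2)
        twice = maf_filter(once, 0.2)
        np.testing.assert_array_equal(once.dosages, twice.dosages)


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration over all tables with the observed allele counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    probs = {}
    for h in range(min(n_a, 2 * n - n_a) + 1):
        if (n_a - h) % 2:
            continue
        aa = (n_a - h) // 2
        bb = n - h - aa
        if aa < 0 or bb < 0:
            continue
        probs[h] = Fraction(comb(n, aa) * comb(n - aa, h) * 2**h)
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHweExact:
    def test_monomorphic_table_is_certain(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_total_heterozygosity_fails_hard(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    @pytest.mark.parametrize("n", [2, 5, 9, 12])
    def test_matches_enumeration_for_small_tables(self, n):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                    hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-12
                )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestMissingness:
    def test_individual_over_threshold_removed(self):
        d = np.ones((4, 10))
        d[0, 0] = np.nan  # 10% missing for individual 0
        G = make_genotypes(d)
        out = missingness_filters(G, snp_max=0.5, ind_max=0.05)
        assert out.n_individuals == 3

    def test_clean_matrix_untouched(self):
        G = make_genotypes(np.ones((4, 6)))
        out = missingness_filters(G)
        assert out.n_individuals == 4 and out.n_snps == 6

    def test_crafted_matrix_matches_hand_count(self):
        d = np.ones((6, 6))
        d[0, :4] = np.nan          # individual 0: 4/6 missing -> dropped
        d[1:, 5] = np.nan          # SNP 5: 5/6 missing; 5/5 after ind drop
        d[2, 2] = np.nan           # isolated call: under both thresholds
        G = make_genotypes(d)
        out = missingness_filters(G, snp_max=0.5, ind_max=0.5)
        assert out.n_individuals == 5
        assert out.n_snps == 5
        assert "s5" not in out.snp_ids


class TestHetOutlier:
    def test_identical_rows_not_removed(self):
        G = make_genotypes(np.tile([1, 0, 2, 1], (5, 1)))
        assert het_outlier_filter(G).n_individuals == 5

    def test_all_het_individual_among_homozygotes_removed(self):
        d = np.zeros((50, 20))
        d[:, ::2] = 2
        d[7, :] = 1  # fully heterozygous outlier
        G = make_genotypes(d)
        out = het_outlier_filter(G, k_sd=3)
        assert out.n_individuals == 49
        assert "ind00007" not in out.individuals

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        G = make_genotypes(rng.integers(0, 3, (20, 30)))
        assert het_outlier_filter(G, k_sd=np.inf).n_individuals == 20


class TestLdPrune:
    def test_duplicated_column_keeps_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 100)
        d = np.column_stack([x, x, rng.integers(0, 3, 100)])
        kept = ld_prune(make_genotypes(d), window=3, step=1)
        assert len([s for s in kept if s in ("s0", "s1")]) == 1

    def test_uncorrelated_snps_all_retained(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, (400, 10))
        kept = ld_prune(make_genotypes(d))
        assert len(kept) == 10

    def test_two_duplicate_pairs_pruned_as_expected(self):
        rng = np.random.default_rng(3)
        cols = [rng.integers(0, 3, 200) for _ in range(16)]
        cols.insert(4, cols[3].copy())    # duplicate pair (s3, s4)
        cols.insert(12, cols[11].copy())  # duplicate pair (s11, s12)
        kept = ld_prune(make_genotypes(np.column_stack(cols)), window=6, step=3)
        assert len(kept) == 16  # 18 columns minus one of each duplicate pair
        # ties in MAF drop the later position of each duplicate pair
        assert "s3" in kept and "s4" not in kept
        assert "s11" in kept and "s12" not in kept

    def test_no_retained_pair_exceeds_r2_cap(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, (300, 8)).astype(float)
        noisy = np.column_stack([base, base + rng.integers(0, 2, (300, 8))])
        noisy = np.clip(noisy, 0, 2)
        G = make_genotypes(noisy)
        kept = set(ld_prune(G, window=16, step=16, r2_max=0.2))
        idx = [j for j, s in enumerate(G.snp_ids) if s in kept]
        R = np.corrcoef(G.dosages[:, idx].T) ** 2
        np.fill_diagonal(R, 0)
        assert R.max() <= 0.2 + 1e-12

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            ld_prune(make_genotypes(np.ones((4, 4))), window=1)


class TestRelatedness:
    def test_duplicated_individual_removed(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.3, (30, 400)).astype(float)
        d[3] = d[10]  # identical pair
        out = relatedness_filter(make_genotypes(d))
        assert out.n_individuals == 29
        assert "ind00010" not in out.individuals  # tie -> later index dropped

    def test_independent_cohort_rarely_trimmed(self):
        removed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.1, 0.5, 5000)
            d = rng.binomial(2, p, (40, 5000)).astype(float)
            out = relatedness_filter(make_genotypes(d))
            removed += 40 - out.n_individuals
        assert removed == 0  # none removed across all seeds

    def test_parent_offspring_pair_flagged(self):
        rng = np.random.default_rng(6)
        m = 4000
        p = rng.uniform(0.2, 0.5, m)
        pop = rng.binomial(2, p, (30, m)).astype(float)
        # child: one allele transmitted from the parent, one from the population
        parent = pop[0]
        from_parent = rng.binomial(1, parent / 2.0)
        child = from_parent + rng.binomial(1, p)
        pop = np.vstack([pop, child])
        out = relatedness_filter(make_genotypes(pop))
        assert out.n_individuals == 30  # one member of the pair removed


class TestAncestry:
    def _panel(self, p, n, seed, ids):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, p, (n, p.size)).astype(float)
        return make_genotypes(d, individuals=ids)

    def test_samples_assigned_to_generating_cluster(self):
        rng = np.random.default_rng(7)
        m = 300
        pa = rng.uniform(0.05, 0.3, m)
        pb = np.clip(pa + 0.4, 0.05, 0.95)
        ref_a = self._panel(pa, 40, 1, [f"a{k}" for k in range(40)])
        ref_b = self._panel(pb, 40, 2, [f"b{k}" for k in range(40)])
        hits = 0
        for seed in range(20):
            samples = self._panel(pa, 5, 100 + seed, [f"x{k}" for k in range(5)])
            labels = assign_ancestry(samples, [("A", ref_a), ("B", ref_b)])
            hits += (labels["ancestry"] == "A").sum()
        assert hits >= 0.95 * 20 * 5

    def test_zero_k_sd_assigns_nothing_off_centroid(self):
        rng = np.random.default_rng(8)
        m = 100
        pa = rng.uniform(0.1, 0.4, m)
        ref = self._panel(pa, 30, 3, [f"a{k}" for k in range(30)])
        samples = self._panel(pa, 5, 4, [f"x{k}" for k in range(5)])
        labels = assign_ancestry(samples, [("A", ref)], k_sd=0.0)
        assert (labels["ancestry"] == "unassigned").all()

    def test_too_few_shared_snps_rejected(self):
        a = make_genotypes(np.ones((3, 1)))
        with pytest.raises(ValueError, match="shared SNPs"):
            assign_ancestry(a, [("A", a)], n_pcs=2)


class TestRunQc:
    def test_clean_fixture_passes_untouched(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.2, 0.5, 600)
        d = rng.binomial(2, p, (60, 600)).astype(float)
        G = make_genotypes(d)
        out, report = run_qc(G, QcConfig(maf_min=0.05))
        assert out.n_individuals == 60
        assert report.to_frame()["removed_snps"].sum() == 0
        assert report.to_frame()["removed_individuals"].sum() == 0

    def test_planted_violations_each_counted_once(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.2, 0.5, 600)
        d = rng.binomial(2, p, (60, 600)).astype(float)
        d[0, :] = 1.0                      # heterozygosity outlier
        d[1, :200] = np.nan                # 33% individual missingness
        d[3:, 597] = np.nan                # SNP missingness (after ind removal)
        d[:, 598] = 0.0                    # monomorphic -> MAF filter
        d[:, 599] = 1.0                    # all-het -> HWE failure
        G = make_genotypes(d)
        out, report = run_qc(G, QcConfig(maf_min=0.05))
        counts = report.to_frame().set_index("step")
        assert counts.loc["het_outlier", "removed_individuals"] == 1
        assert counts.loc["missingness", "removed_individuals"] == 1
        assert counts.loc["missingness", "removed_snps"] == 1
        assert counts.loc["maf", "removed_snps"] == 1
        assert counts.loc["hwe", "removed_snps"] == 1
        report.check_conservation()

    def test_report_rows_follow_filter_order(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.4, (40, 100)).astype(float)
        _, report = run_qc(make_genotypes(d), QcConfig(maf_min=0.05))
        assert report.to_frame()["step"].tolist() == [
            "het_outlier", "missingness", "relatedness", "maf", "hwe",
        ]
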