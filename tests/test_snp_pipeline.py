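"""SNP filtering cascade, polarization, fixed differences, diversity and
the Evanno ΔK statistic, on engineered toy matrices."""

import numpy as np
import pytest

from selfsig.snp_pipeline import (
    SNPMatrix,
    count_fixed_differences,
    evanno_delta_k,
    filter_snps,
    nucleotide_diversity,
    observed_het_per_snp,
    polarize_and_histogram,
    snp_diversity,
)


def _matrix(g, locus_ids=None, pos=None, labels=None):
    g = np.asarray(g, dtype=np.int8)
    n, s = g.shape
    labels = np.array(labels or ["A"] * (n // 2) + ["B"] * (n - n // 2), dtype=object)
    return SNPMatrix(
        samples=[f"s{i}" for i in range(n)],
        species=labels,
        population=labels.copy(),
        snp_ids=[f"snp{j}" for j in range(s)],
        locus_ids=np.array(locus_ids or [f"loc{j}" for j in range(s)], dtype=object),
        pos_in_locus=np.array(pos or [1] * s),
        genotypes=g,
    )


class TestFilterSnps:
    def test_each_rule_removes_its_target(self, toy_snp_matrix):
        f, rep = filter_snps(
            toy_snp_matrix, max_ho=0.6, min_minor_samples=3, min_prop_r=0.7,
            one_per_locus=True,
        )
        assert rep.to_dict() == {
            "n_input": 5,
            "removed_high_het": 1,    # snp_het: H_O = 0.7
            "removed_minor_count": 1, # snp_rare: minor allele in 2 samples
            "removed_missingness": 1, # snp_miss: called in 0.5 < 0.7
            "removed_linked": 1,      # snp_second: 2nd SNP on loc2
            "n_surviving": 1,
        }
        assert f.snp_ids == ["snp_keep"]

    def test_boundary_ho_exactly_0p6_removed(self):
        g = np.array([[1], [1], [1], [0], [2]] * 2, dtype=np.int8)  # 6/10 het
        m = _matrix(g)
        assert observed_het_per_snp(m)[0] == pytest.approx(0.6)
        _, rep = filter_snps(m, max_ho=0.6, min_minor_samples=0)
        assert rep.removed_high_het == 1

    def test_boundary_minor_allele_in_exactly_three_samples_retained(self):
        g = np.array([[1], [1], [2], [0], [0], [0], [0], [0], [0], [0]], dtype=np.int8)
        m = _matrix(g)  # alt allele carried by 3 samples, H_O = 0.1
        f, rep = filter_snps(m, min_minor_samples=3)
        assert rep.removed_minor_count == 0 and f.n_snps == 1
        g2 = g.copy()
        g2[2, 0] = 0  # now only 2 carriers
        _, rep2 = filter_snps(_matrix(g2), min_minor_samples=3)
        assert rep2.removed_minor_count == 1

    def test_minor_allele_counts_sample_once_het_or_hom(self):
        # 3 carriers: two het + one hom-alt; counts as 3, not 4 copies.
        g = np.array([[1], [1], [2]] + [[0]] * 7, dtype=np.int8)
        _, rep = filter_snps(_matrix(g), min_minor_samples=3)
        assert rep.removed_minor_count == 0

    def test_one_per_locus_keeps_first_by_position(self):
        g = np.tile(np.array([[0], [0], [1], [2], [2]], dtype=np.int8), (2, 5))
        m = _matrix(g, locus_ids=["locA"] * 5, pos=[3, 1, 4, 2, 5])
        f, rep = filter_snps(m, min_minor_samples=0, one_per_locus=True)
        assert rep.removed_linked == 4
        assert f.snp_ids == ["snp1"]  # pos_in_locus == 1

    def test_idempotent(self, toy_snp_matrix):
        f, _ = filter_snps(toy_snp_matrix, min_prop_r=0.7, one_per_locus=True)
        f2, rep2 = filter_snps(f, min_prop_r=0.7, one_per_locus=True)
        assert rep2.total_removed == 0
        assert f2.snp_ids == f.snp_ids

    def test_counts_reconcile(self, toy_snp_matrix):
        _, rep = filter_snps(toy_snp_matrix, min_prop_r=0.7, one_per_locus=True)
        assert rep.total_removed + rep.n_surviving == rep.n_input

    def test_empty_matrix_rejected(self, toy_snp_matrix):
        empty = toy_snp_matrix.take_snps(np.array([], dtype=int))
        with pytest.raises(ValueError):
            filter_snps(empty)


class TestPolarize:
    def test_fixed_same_allele_gives_zero_derived(self):
        g = np.zeros((6, 2), dtype=np.int8)
        res = polarize_and_histogram(_matrix(g), "A", "B")
        assert np.all(res["derived_freq"]["A"] == 0)
        assert np.all(res["derived_freq"]["B"] == 0)

    def test_fixed_opposite_gives_derived_one_in_cleistogamous(self):
        g = np.array([[0], [0], [0], [2], [2], [2]], dtype=np.int8)
        res = polarize_and_histogram(_matrix(g), "A", "B")
        assert res["derived_freq"]["B"][0] == pytest.approx(1.0)
        assert res["derived_freq"]["A"][0] == pytest.approx(0.0)

    def test_majority_alt_ancestral_flips_polarity(self):
        g = np.array([[2], [2], [1], [0], [0], [0]], dtype=np.int8)
        # ancestral group A = first 3 samples: alt freq 5/6 -> alt is ancestral
        res = polarize_and_histogram(_matrix(g), "A", "B")
        assert res["derived_freq"]["A"][0] == pytest.approx(1 / 6)
        assert res["derived_freq"]["B"][0] == pytest.approx(1.0)

    def test_ten_snp_fixture_histogram_matches_hand_count(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(8, 10)).astype(np.int8)
        m = _matrix(g)
        res = polarize_and_histogram(m, "A", "B", bins=5)
        # hand recomputation
        anc = g[:4]
        f_anc = anc.sum(axis=0) / 8
        anc_is_alt = f_anc > 0.5
        f_b = g[4:].sum(axis=0) / 8
        derived_b = np.where(anc_is_alt, 1 - f_b, f_b)
        hist, _ = np.histogram(derived_b, bins=np.linspace(0, 1, 6))
        assert np.array_equal(res["histogram"]["B"], hist)

    def test_snp_missing_in_ancestral_group_excluded_and_counted(self):
        g = np.array([[-1, 0], [-1, 0], [-1, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8)
        res = polarize_and_histogram(_matrix(g), "A", "B")
        assert res["n_excluded_no_ancestral_calls"] == 1
        assert len(res["derived_freq"]["B"]) == 1


class TestFixedDifferences:
    def test_identical_groups_zero(self):
        g = np.tile(np.array([[0, 1, 2]], dtype=np.int8), (6, 1))
        assert count_fixed_differences(_matrix(g), "A", "B") == 0

    def test_all_fixed_opposite_counts_all(self):
        g = np.array([[0] * 4] * 3 + [[2] * 4] * 3, dtype=np.int8)
        assert count_fixed_differences(_matrix(g), "A", "B") == 4

    def test_mixed_fixture_counts_only_fixed(self):
        # 3 fixed-opposite SNPs, 2 shared-polymorphic SNPs
        g = np.array(
            [
                [0, 0, 0, 1, 0],
                [0, 0, 0, 0, 1],
                [0, 0, 0, 1, 2],
                [2, 2, 2, 1, 0],
                [2, 2, 2, 0, 1],
                [2, 2, 2, 1, 2],
            ],
            dtype=np.int8,
        )
        assert count_fixed_differences(_matrix(g), "A", "B") == 3

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        m = _matrix(g)
        assert count_fixed_differences(m, "A", "B") == count_fixed_differences(m, "B", "A")

    def test_missing_genotypes_do_not_break_fixation(self):
        g = np.array([[0], [0], [-1], [2], [2], [-1]], dtype=np.int8)
        assert count_fixed_differences(_matrix(g), "A", "B") == 1


class TestNucleotideDiversity:
    def test_monomorphic_zero(self):
        g = np.zeros((6, 1), dtype=np.int8)
        assert nucleotide_diversity(_matrix(g)).iloc[0] == pytest.approx(0.0)

    def test_p_half_four_copies(self):
        # genotypes 0/0 and 1/1: 4 copies, p = 0.5 -> (4/3)*0.5 = 2/3,
        # equal to the mean pairwise difference over the 6 copy pairs.
        g = np.array([[0], [2]], dtype=np.int8)
        m = _matrix(g, labels=["A", "A"])
        assert nucleotide_diversity(m, "A").iloc[0] == pytest.approx(2 / 3)

    def test_within_group_pi_zero_at_fixed_difference(self):
        g = np.array([[0], [0], [0], [2], [2], [2]], dtype=np.int8)
        m = _matrix(g)
        assert nucleotide_diversity(m, "A").iloc[0] == pytest.approx(0.0)
        assert nucleotide_diversity(m, "B").iloc[0] == pytest.approx(0.0)

    def test_diversity_frame_fis_consistency(self):
        g = np.array([[0], [1], [2], [1]], dtype=np.int8)
        m = _matrix(g, labels=["A"] * 4)
        df = snp_diversity(m, "A")
        he, ho = df["H_E"].iloc[0], df["H_O"].iloc[0]
        assert df["F_IS"].iloc[0] == pytest.approx((he - ho) / he)


class TestEvannoDeltaK:
    def test_linear_means_give_zero(self):
        runs = {k: [-10.0 * k + d for d in (-1, 0, 1)] for k in range(1, 6)}
        dk = evanno_delta_k(runs)
        assert np.allclose(dk.to_numpy(), 0.0)

    def test_hand_example_with_unit_sd(self):
        # means (-100, -50, -40, -38), sd exactly 1 at every K
        runs = {
            1: [-101.0, -100.0, -99.0],
            2: [-51.0, -50.0, -49.0],
            3: [-41.0, -40.0, -39.0],
            4: [-39.0, -38.0, -37.0],
        }
        dk = evanno_delta_k(runs)
        assert dk[2] == pytest.approx(40.0)
        assert dk[3] == pytest.approx(8.0)

    def test_invariance_under_affine_shift_and_scaling(self):
        runs = {
            1: [-101.0, -99.5, -100.2],
            2: [-51.0, -50.4, -49.1],
            3: [-41.0, -40.3, -39.2],
            4: [-39.0, -38.1, -37.4],
        }
        base = evanno_delta_k(runs)
        shifted = evanno_delta_k({k: [v + 7.5 for v in vs] for k, vs in runs.items()})
        scaled = evanno_delta_k({k: [v * 3.0 for v in vs] for k, vs in runs.items()})
        assert np.allclose(base.to_numpy(), shifted.to_numpy())
        assert np.allclose(base.to_numpy(), scaled.to_numpy())

    def test_zero_sd_reported_missing(self):
        runs = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        dk = evanno_delta_k(runs)
        assert np.isnan(dk[2])

    @pytest.mark.parametrize(
        "runs",
        [
            {1: [-1.0, -2.0], 2: [-1.0, -2.0]},          # too few K
            {1: [-1.0, -2.0], 3: [-1.0, -2.0], 4: [-1.0, -2.0]},  # gap in K
            {1: [-1.0], 2: [-1.0, -2.0], 3: [-1.0, -2.0]},        # single run
        ],
    )
    def test_invalid_run_tables_rejected(self, runs):
        with pytest.raises(ValueError):
            evanno_delta_k(runs)
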