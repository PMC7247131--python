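"""Pair classification, the covariation rule, and the permutation test."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from rleader.covariation import (
    UndefinedScoreError,
    classify_pair,
    pair_association_score,
    permutation_test,
    r2r_rule,
    summarize_motif,
)
from rleader.stockholm import StructuredAlignment, extract_pairs

from conftest import make_pair_alignment, random_iid_alignment

PAIR = (0, 2)


class TestClassifyPair:
    def test_two_variants_counted(self):
        stats = classify_pair(make_pair_alignment(["GC", "GC", "AU"]), PAIR)
        assert stats.canonical_counts == {"GC": 2, "AU": 1}
        assert stats.covarying_variant_count == 2
        assert stats.n_noncanonical == 0

    def test_single_position_change_is_not_covariation(self):
        stats = classify_pair(make_pair_alignment(["GC", "GU"]), PAIR)
        assert stats.covarying_variant_count == 0

    def test_noncanonical_and_gapped_partition(self):
        stats = classify_pair(make_pair_alignment(["GC", "AU", "GA", "-U"]), PAIR)
        assert stats.n_noncanonical == 1
        assert stats.n_gapped == 1
        assert stats.covarying_variant_count == 2
        total = sum(stats.canonical_counts.values())
        assert total + stats.n_noncanonical + stats.n_gapped == stats.n_sequences

    def test_case_and_thymine_normalised(self):
        stats = classify_pair(make_pair_alignment(["gc", "AT"]), PAIR)
        assert stats.canonical_counts == {"GC": 1, "AU": 1}

    def test_out_of_range_indices(self):
        with pytest.raises(IndexError):
            classify_pair(make_pair_alignment(["GC"]), (0, 9))


class TestR2RRule:
    def test_two_variants_no_noise_true(self):
        stats = classify_pair(make_pair_alignment(["GC"] * 5 + ["AU"] * 5), PAIR)
        assert r2r_rule(stats) is True

    def test_exactly_ten_percent_noncanonical_false(self):
        contents = ["GC"] * 9 + ["AU"] * 9 + ["AG", "CU"]  # 2/20 non-canonical
        stats = classify_pair(make_pair_alignment(contents), PAIR)
        assert stats.noncanonical_fraction == pytest.approx(0.10)
        assert r2r_rule(stats) is False

    def test_gc_gu_only_false(self):
        stats = classify_pair(make_pair_alignment(["GC"] * 10 + ["GU"] * 10), PAIR)
        assert r2r_rule(stats) is False

    def test_adding_canonical_variant_never_flips_true_to_false(self):
        contents = ["GC"] * 8 + ["AU"] * 8
        base = classify_pair(make_pair_alignment(contents), PAIR)
        assert r2r_rule(base)
        for extra in ("UA", "CG", "UG"):
            grown = classify_pair(make_pair_alignment(contents + [extra]), PAIR)
            assert r2r_rule(grown)


class TestAssociationScore:
    def test_closed_form_perfect_binary_association(self):
        n = 12
        aln = make_pair_alignment(["GC"] * (n // 2) + ["AU"] * (n // 2))
        assert pair_association_score(aln, PAIR) == pytest.approx(
            2 * n * math.log(2)
        )

    def test_constant_column_scores_zero(self):
        aln = make_pair_alignment(["GC", "GU", "GA", "GC"])  # 5' column constant
        assert pair_association_score(aln, PAIR) == 0.0

    def test_matches_scipy_log_likelihood_chi2(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            aln = random_iid_alignment(40, 3, rng)
            ours = pair_association_score(aln, PAIR)
            cols = np.array([[s[0], s[2]] for _, s in aln.records])
            cats_x = {c: i for i, c in enumerate(sorted(set(cols[:, 0])))}
            cats_y = {c: i for i, c in enumerate(sorted(set(cols[:, 1])))}
            table = np.zeros((len(cats_x), len(cats_y)))
            for a, b in cols:
                table[cats_x[a], cats_y[b]] += 1
            g, _, _, _ = chi2_contingency(
                table, correction=False, lambda_="log-likelihood"
            )
            assert ours == pytest.approx(g)

    def test_mean_approaches_chi2_dof_under_independence(self):
        # 4x4 contingency of two iid uniform columns: G ~ chi2(9) asymptotically
        rng = np.random.default_rng(7)
        m, n = 250, 120
        scores = []
        for _ in range(m):
            aln = random_iid_alignment(n, 3, rng)
            scores.append(pair_association_score(aln, PAIR))
        dof = 9
        se = math.sqrt(2 * dof / m)
        assert abs(np.mean(scores) - dof) < 4 * se + 0.5  # +0.5 finite-n bias slack

    def test_too_few_ungapped_sequences(self):
        aln = make_pair_alignment(["-C", "G-", "GC"])
        with pytest.raises(UndefinedScoreError):
            pair_association_score(aln, PAIR)


class TestPermutationTest:
    def test_perfect_covariation_is_significant(self):
        aln = make_pair_alignment(["GC"] * 4 + ["AU"] * 4 + ["CG"] * 4)
        p = permutation_test(aln, PAIR, n_permutations=999, seed=5)
        assert p <= 0.01

    def test_constant_columns_give_p_one(self):
        aln = make_pair_alignment(["GC"] * 6)
        assert permutation_test(aln, PAIR, n_permutations=99, seed=0) == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        aln = random_iid_alignment(20, 3, rng)
        p1 = permutation_test(aln, PAIR, n_permutations=200, seed=11)
        p2 = permutation_test(aln, PAIR, n_permutations=200, seed=11)
        assert p1 == p2

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(8)
        aln = random_iid_alignment(15, 3, rng)
        shuffled = StructuredAlignment(
            records=list(reversed(aln.records)),
            consensus_structure=aln.consensus_structure,
        )
        p1 = permutation_test(aln, PAIR, n_permutations=300, seed=2)
        p2 = permutation_test(shuffled, PAIR, n_permutations=300, seed=2)
        assert p1 == p2


class TestSummarizeMotif:
    def test_identical_sequences_rated_borderline(self):
        aln = StructuredAlignment(
            records=[(f"s{i}", "GGAACC") for i in range(10)],
            consensus_structure="<<..>>",
        )
        summary = summarize_motif(
            aln, extract_pairs("<<..>>"), n_permutations=99, seed=0
        )
        assert summary.n_significant == 0
        assert summary.rating == "?"

    def test_planted_covariation_rated_likely(self):
        from rleader.synthetic import EvolutionParams, simulate_alignment

        structure = "<<<<....>>>>"
        aln = simulate_alignment(
            structure,
            EvolutionParams(
                n_sequences=24,
                seed=13,
                compensatory_rate=1.0,
                noncanonical_noise=0.0,
                tree_depth=1.0,
            ),
        )
        summary = summarize_motif(
            aln, extract_pairs(structure), n_permutations=300, seed=1
        )
        assert summary.n_significant >= 1
        assert summary.n_r2r_covarying >= 2
        assert summary.rating == "Y"

    def test_empty_pair_table(self):
        aln = StructuredAlignment(
            records=[("s1", "ACGU")], consensus_structure="...."
        )
        summary = summarize_motif(aln, extract_pairs("...."))
        assert summary.n_pairs == 0
        assert summary.rating == "?"

    def test_counts_bounded_by_pairs(self):
        rng = np.random.default_rng(1)
        aln = random_iid_alignment(18, 12, rng)
        structure = "<<<<....>>>>"
        aln = StructuredAlignment(
            records=aln.records, consensus_structure=structure
        )
        summary = summarize_motif(
            aln, extract_pairs(structure), n_permutations=99, seed=4
        )
        assert summary.n_significant <= summary.n_pairs
        assert summary.n_r2r_covarying <= summary.n_pairs
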