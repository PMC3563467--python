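"""Likelihood core: frequencies, rate matrices, transition probabilities,
and pruning likelihoods checked against independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lineageselect as ls
from lineageselect._genetic_code import (
    CODON_INDEX,
    MISSING,
    N_CODONS,
    SENSE_CODONS,
)
from lineageselect.alignment import alignment_from_strings
from lineageselect.engine import (
    LikelihoodEngine,
    SpectralGenerator,
    compress_patterns,
)
from lineageselect.simulate import (
    SimulationRecipe,
    simulate_codon_alignment,
    spec_from_model,
)


class TestFrequencies:
    def test_f61_equal_usage_gives_uniform(self):
        seq = "".join(SENSE_CODONS)
        aln = alignment_from_strings([("A", seq), ("B", seq)])
        fv = ls.estimate_codon_frequencies(aln, "F61")
        np.testing.assert_allclose(fv.pi, 1.0 / 61, atol=1e-12)

    def test_f3x4_two_codon_toy_matches_hand_product(self):
        # equal counts of AAA and AAG: pos1 P(A)=1, pos2 P(A)=1,
        # pos3 P(A)=P(G)=1/2; product over sense codons, renormalized.
        aln = alignment_from_strings([("A", "AAAAAG"), ("B", "AAGAAA")])
        fv = ls.estimate_codon_frequencies(aln, "F3x4")
        # only AAA and AAG have nonzero positional product; each gets 1/2
        expected = np.zeros(61)
        expected[CODON_INDEX["AAA"]] = 0.5
        expected[CODON_INDEX["AAG"]] = 0.5
        np.testing.assert_allclose(fv.pi, expected, atol=1e-12)

    @pytest.mark.parametrize("scheme", ["F61", "F3x4", "F1x4", "uniform"])
    def test_normalization(self, scheme, aln3):
        fv = ls.estimate_codon_frequencies(aln3, scheme)
        assert fv.pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_missing_is_error(self):
        aln = ls.CodonAlignment(["A", "B"], np.full((2, 3), MISSING, dtype=np.int16))
        with pytest.raises(ValueError, match="all-missing"):
            ls.estimate_codon_frequencies(aln, "F61")


class TestRateMatrix:
    def test_rows_sum_to_zero(self, uniform_pi):
        q = ls.build_rate_matrix(2.0, 0.5, uniform_pi)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_multi_nucleotide_change_has_zero_rate(self, uniform_pi):
        q = ls.build_rate_matrix(2.0, 0.5, uniform_pi, normalize=False)
        assert q[CODON_INDEX["TTT"], CODON_INDEX["GGG"]] == 0.0

    def test_synonymous_transition_rate_is_kappa_pi(self, uniform_pi):
        # TTT -> TTC: T<->C at position 3, Phe -> Phe (synonymous transition)
        kappa = 3.7
        q = ls.build_rate_matrix(kappa, 0.2, uniform_pi, normalize=False)
        assert q[CODON_INDEX["TTT"], CODON_INDEX["TTC"]] == pytest.approx(
            kappa * uniform_pi[CODON_INDEX["TTC"]]
        )

    def test_nonsynonymous_transversion_rate_is_omega_pi(self, uniform_pi):
        # TTT (Phe) -> TTA (Leu): T<->A transversion, nonsynonymous
        omega = 0.42
        q = ls.build_rate_matrix(2.0, omega, uniform_pi, normalize=False)
        assert q[CODON_INDEX["TTT"], CODON_INDEX["TTA"]] == pytest.approx(
            omega * uniform_pi[CODON_INDEX["TTA"]]
        )

    @settings(max_examples=15, deadline=None)
    @given(kappa=st.floats(0.2, 10), omega=st.floats(0.01, 5),
           seed=st.integers(0, 10 ** 6))
    def test_detailed_balance(self, kappa, omega, seed):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(N_CODONS))
        q = ls.build_rate_matrix(kappa, omega, pi)
        np.testing.assert_allclose(pi[:, None] * q, (pi[:, None] * q).T,
                                   atol=1e-12)

    def test_negative_parameters_rejected(self, uniform_pi):
        with pytest.raises(ValueError):
            ls.build_rate_matrix(-1.0, 0.5, uniform_pi)
        with pytest.raises(ValueError):
            ls.build_rate_matrix(2.0, -0.1, uniform_pi)


class TestTransitionMatrix:
    def test_t_zero_is_identity(self, uniform_pi):
        q = ls.build_rate_matrix(2.0, 0.3, uniform_pi)
        np.testing.assert_allclose(ls.transition_matrix(q, 0.0), np.eye(61),
                                   atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_rows_are_stochastic(self, t, uniform_pi):
        q = ls.build_rate_matrix(2.0, 0.3, uniform_pi)
        p = ls.transition_matrix(q, t)
        assert p.min() >= 0
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_long_branch_converges_to_stationary(self):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(N_CODONS) * 5)
        q = ls.build_rate_matrix(2.0, 0.3, pi)
        p = ls.transition_matrix(q, 50.0)
        assert np.abs(p - pi[None, :]).max() < 5e-5
        p200 = ls.transition_matrix(q, 200.0)
        assert np.abs(p200 - pi[None, :]).max() < 1e-8

    def test_spectral_matches_expm(self, uniform_pi):
        q = ls.build_rate_matrix(2.3, 0.7, uniform_pi)
        gen = SpectralGenerator(q, uniform_pi)
        for t in (0.05, 0.5, 3.0):
            np.testing.assert_allclose(gen.probability(t),
                                       ls.transition_matrix(q, t), atol=1e-9)

    def test_nonfinite_t_rejected(self, uniform_pi):
        q = ls.build_rate_matrix(2.0, 0.3, uniform_pi)
        with pytest.raises(ValueError):
            ls.transition_matrix(q, np.nan)


# ---------------------------------------------------------------------------
# pruning vs exhaustive enumeration
# ---------------------------------------------------------------------------

from oracles import brute_force_loglik


class TestPruningLikelihood:
    def test_single_leaf_star_closed_form(self):
        # one leaf at distance 0 from the root: lnL = sum ln pi(observed)
        tree = ls.SpeciesTree.from_newick("(A:0.0,B:0.0);")
        aln = alignment_from_strings([("A", "ATGAAA"), ("B", "ATGAAA")])
        spec = spec_from_model("M0", {"kappa": 2.0, "omega": 0.3})
        lnl = ls.log_likelihood(tree, aln, spec)
        expected = 2 * np.log(1 / 61)
        assert lnl == pytest.approx(expected, abs=1e-8)

    @settings(max_examples=8, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_three_taxon_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        bl = rng.uniform(0.05, 0.8, size=4)
        tree = ls.SpeciesTree.from_newick(
            f"((A:{bl[0]:.3f},B:{bl[1]:.3f}):{bl[2]:.3f},C:{bl[3]:.3f});"
        )
        spec = spec_from_model("M0", {"kappa": float(rng.uniform(1, 5)),
                                      "omega": float(rng.uniform(0.05, 2))})
        aln, _ = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=2, seed=seed)
        )
        assert ls.log_likelihood(tree, aln, spec) == pytest.approx(
            brute_force_loglik(tree, aln, spec), abs=1e-8
        )

    def test_four_taxon_mixture_matches_enumeration(self):
        tree = ls.SpeciesTree.from_newick(
            "((A:0.2,B:0.35):0.15,(C:0.4,D:0.1):0.25);"
        )
        spec = spec_from_model("M1a", {"kappa": 2.5, "p0": 0.6, "omega0": 0.2})
        aln, _ = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=3, seed=5)
        )
        # 3 internal nodes would be 61^3 per site; root this tree's index has
        # root + 2 internals -> still feasible (61^2 per class per site after
        # conditioning on the root by summing pi): enumeration handles it.
        assert ls.log_likelihood(tree, aln, spec) == pytest.approx(
            brute_force_loglik(tree, aln, spec), abs=1e-8
        )

    def test_missing_codons_marginalized(self):
        tree = ls.SpeciesTree.from_newick("((A:0.2,B:0.3):0.1,C:0.4);")
        spec = spec_from_model("M0", {"kappa": 2.0, "omega": 0.4})
        aln = alignment_from_strings([("A", "ATG---"), ("B", "ATGAAA"),
                                      ("C", "ATGAAG")])
        assert ls.log_likelihood(tree, aln, spec) == pytest.approx(
            brute_force_loglik(tree, aln, spec), abs=1e-8
        )

    def test_mixture_recomposition(self, tree3, aln3):
        """Two-class mixture lnL equals the per-site log of the weighted sum
        of single-class likelihoods computed in separate runs."""
        fv = ls.estimate_codon_frequencies(aln3, "uniform")
        engine = LikelihoodEngine(aln3, tree3, fv)
        bl = engine.tree_branch_lengths()
        spec_mix = spec_from_model("M1a", {"kappa": 2.0, "p0": 0.7,
                                           "omega0": 0.1})
        mix_lnl = engine.loglik(spec_mix, bl)
        logL = engine.class_logliks(spec_mix, bl)
        counts = engine.pattern_table.counts
        by_hand = counts @ np.log(0.7 * np.exp(logL[0]) + 0.3 * np.exp(logL[1]))
        assert mix_lnl == pytest.approx(by_hand, abs=1e-8)

    def test_invariant_to_taxon_order_and_compression(self, tree3, aln3):
        spec = spec_from_model("M0", {"kappa": 2.0, "omega": 0.4})
        base = ls.log_likelihood(tree3, aln3, spec)
        perm = ["C", "A", "B"]
        shuffled = aln3.subset_taxa(perm)
        assert ls.log_likelihood(tree3, shuffled, spec) == pytest.approx(base, abs=1e-8)
        # duplicating columns doubles lnL (pattern multiplicities)
        doubled = ls.CodonAlignment(list(aln3.taxon_names),
                                    np.hstack([aln3.codes, aln3.codes]))
        assert ls.log_likelihood(tree3, doubled, spec) == pytest.approx(
            2 * base, abs=1e-6)

    def test_taxon_mismatch_rejected(self, tree3):
        aln = alignment_from_strings([("A", "ATG"), ("B", "ATG"), ("X", "ATG")])
        fv = ls.estimate_codon_frequencies(aln, "uniform")
        with pytest.raises(ValueError):
            LikelihoodEngine(aln, tree3, fv)


class TestPatterns:
    def test_compression_counts(self):
        aln = alignment_from_strings([("A", "ATGATGAAA"), ("B", "ATGATGAAG")])
        pt = compress_patterns(aln)
        assert pt.counts.sum() == aln.n_sites
        assert pt.n_patterns == 2
        # expansion maps back exactly
        np.testing.assert_array_equal(pt.patterns[:, pt.site_to_pattern],
                                      aln.codes)
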