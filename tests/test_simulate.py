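"""Synthetic-data generators: codon alignments, conversion tracts,
haplotype panels."""

from __future__ import annotations

import numpy as np
import pytest

import lineageselect as ls
from lineageselect._genetic_code import MISSING
from lineageselect.simulate import (
    SimulationRecipe,
    SweepRecipe,
    simulate_codon_alignment,
    simulate_haplotypes,
    spec_from_model,
)
from conftest import make_tree


class TestCodonSimulation:
    def test_zero_branch_lengths_give_identical_taxa(self):
        tree = make_tree(5, bl=0.0)
        spec = spec_from_model("M0", {"kappa": 2.0, "omega": 0.3})
        aln, _ = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=50, seed=1))
        assert (aln.codes == aln.codes[0]).all()

    def test_class_fraction_within_binomial_noise(self):
        """Recorded class labels for a branch-site mixture with a 10%
        selected fraction land within 3 binomial SDs over 10,000 sites."""
        tree = ls.mark_foreground(make_tree(6), "t0")
        spec = spec_from_model("ModelA", {"kappa": 2.0, "s": 0.9, "r": 0.5,
                                          "omega0": 0.1, "omega2": 4.0})
        n = 10_000
        _, labels = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=n, seed=2))
        frac = (labels >= 2).mean()
        sd = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) < 3 * sd

    def test_long_tree_codon_usage_converges_to_pi(self):
        """After many expected substitutions the leaf states are draws from
        the stationary distribution."""
        tree = make_tree(8, bl=8.0)
        spec = spec_from_model("M0", {"kappa": 2.0, "omega": 0.3})
        aln, _ = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=3000, seed=3))
        counts = np.bincount(aln.codes.ravel(), minlength=61)
        freq = counts / counts.sum()
        # chi-square-style sanity: all 61 frequencies near 1/61
        assert np.abs(freq - 1 / 61).max() < 4 * np.sqrt((1 / 61) / (8 * 3000))

    def test_simulated_alignment_is_valid(self):
        tree = make_tree(7)
        spec = spec_from_model("M1a", {"kappa": 2.0, "p0": 0.7, "omega0": 0.2})
        aln, _ = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=120, seed=4))
        assert aln.n_taxa == 7 and aln.n_sites == 120
        assert (aln.codes >= 0).all() and (aln.codes <= 60).all()

    def test_seed_determinism(self):
        tree = make_tree(5)
        spec = spec_from_model("M0", {"kappa": 2.0, "omega": 0.5})
        a1, l1 = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=60, seed=7))
        a2, l2 = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=60, seed=7))
        np.testing.assert_array_equal(a1.codes, a2.codes)
        np.testing.assert_array_equal(l1, l2)

    def test_branch_site_requires_marked_tree(self):
        tree = make_tree(5)
        spec = spec_from_model("ModelA", {"kappa": 2.0, "s": 0.9, "r": 0.5,
                                          "omega0": 0.1, "omega2": 4.0})
        with pytest.raises(ValueError, match="foreground"):
            simulate_codon_alignment(
                SimulationRecipe(tree=tree, spec=spec, n_sites=10, seed=1))


class TestConversionTract:
    def _aln(self):
        tree = make_tree(4, bl=0.5)
        spec = spec_from_model("M0", {"kappa": 2.0, "omega": 0.5})
        aln, _ = simulate_codon_alignment(
            SimulationRecipe(tree=tree, spec=spec, n_sites=50, seed=5))
        return aln

    def test_single_codon_copy_changes_at_most_one_cell(self):
        aln = self._aln()
        out = ls.plant_conversion_tract(aln, "t0", "t3", 10, 10)
        assert (out.codes != aln.codes).sum() <= 1
        assert out.codes[out.row("t3"), 9] == aln.codes[aln.row("t0"), 9]

    def test_identical_segment_is_noop(self):
        aln = self._aln()
        aln.codes[aln.row("t3"), 4:9] = aln.codes[aln.row("t0"), 4:9]
        out = ls.plant_conversion_tract(aln, "t0", "t3", 5, 9)
        np.testing.assert_array_equal(out.codes, aln.codes)

    def test_out_of_bounds_rejected(self):
        aln = self._aln()
        with pytest.raises(IndexError):
            ls.plant_conversion_tract(aln, "t0", "t3", 0, 10)
        with pytest.raises(IndexError):
            ls.plant_conversion_tract(aln, "t0", "t3", 40, 60)

    def test_same_taxon_rejected(self):
        with pytest.raises(ValueError):
            ls.plant_conversion_tract(self._aln(), "t0", "t0", 1, 5)


class TestHaplotypes:
    def test_determinism(self):
        r = SweepRecipe(n_haplotypes=30, n_snps=50, core_index=25, seed=11)
        h1 = simulate_haplotypes(r)
        h2 = simulate_haplotypes(r)
        np.testing.assert_array_equal(h1.haplotypes, h2.haplotypes)

    def test_core_frequency_matches_recipe(self):
        haps = simulate_haplotypes(SweepRecipe(n_haplotypes=100, n_snps=40,
                                               core_index=20,
                                               derived_freq=0.3, seed=12))
        assert haps.derived_frequency(20) == pytest.approx(0.3, abs=0.01)

    def test_null_symmetry_of_ehh_decay(self):
        """With sweep_strength 0 the derived and ancestral carrier classes
        are exchangeable: their EHH decay profiles agree on average."""
        from lineageselect.ihs import snp_ihh
        diffs = []
        for seed in range(6):
            haps = simulate_haplotypes(
                SweepRecipe(n_haplotypes=80, n_snps=80, core_index=40,
                            derived_freq=0.5, sweep_strength=0.0, seed=seed))
            ia = snp_ihh(haps, 40, "ancestral")
            idv = snp_ihh(haps, 40, "derived")
            diffs.append(np.log(ia / idv))
        # mean log ratio near zero (no systematic class asymmetry)
        assert abs(np.mean(diffs)) < 0.35

    def test_sweep_raises_derived_ehh(self):
        from lineageselect.ihs import ehh_curve
        haps = simulate_haplotypes(
            SweepRecipe(n_haplotypes=100, n_snps=120, core_index=60,
                        derived_freq=0.5, sweep_strength=0.95, seed=7))
        _, ed = ehh_curve(haps, 60, "derived", "right")
        _, ea = ehh_curve(haps, 60, "ancestral", "right")
        assert ed[50] > ea[50]

    def test_too_few_carriers_rejected(self):
        with pytest.raises(ValueError, match="carriers"):
            SweepRecipe(n_haplotypes=10, n_snps=20, core_index=10,
                        derived_freq=0.05)
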