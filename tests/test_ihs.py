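"""EHH curves, iHH integration, raw/standardized iHS, significance flags."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import lineageselect as ls
from lineageselect.ihs import HaplotypeMatrix, ehh_curve, snp_ihh
from lineageselect.simulate import SweepRecipe, simulate_haplotypes


def matrix(rows, positions=None):
    rows = np.asarray(rows, dtype=np.int8)
    if positions is None:
        positions = np.arange(rows.shape[1]) * 1000 + 1
    return HaplotypeMatrix(rows, positions)


class TestEHH:
    def test_core_value_is_one(self):
        haps = matrix([[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 1]])
        _, e = ehh_curve(haps, 0, "derived", "right")
        assert e[0] == 1.0

    def test_all_distinct_one_snp_away_gives_zero(self):
        haps = matrix([
            [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1],
            [0, 0, 0], [0, 1, 1],
        ])
        span, e = ehh_curve(haps, 0, "derived", "right")
        # 4 carriers split into 2+2 one SNP away, all 4 distinct at SNP 2
        assert e[1] == pytest.approx(2 / 6)
        assert e[2] == 0.0

    def test_matches_hand_pair_counting(self):
        rows = [
            [1, 0, 1, 0],
            [1, 0, 1, 1],
            [1, 1, 0, 0],
            [0, 0, 0, 0],
            [0, 1, 0, 0],
            [1, 0, 1, 0],
        ]
        haps = matrix(rows)
        span, e = ehh_curve(haps, 0, "derived", "right")
        carriers = [r for r in rows if r[0] == 1]
        for d in range(4):
            same = sum(
                1 for a, b in itertools.combinations(carriers, 2)
                if a[: d + 1] == b[: d + 1]
            )
            assert e[d] == pytest.approx(same / 6.0)

    def test_non_increasing_with_distance(self):
        haps = simulate_haplotypes(SweepRecipe(n_haplotypes=40, n_snps=60,
                                               core_index=30, seed=9))
        for allele in ("ancestral", "derived"):
            for direction in ("left", "right"):
                _, e = ehh_curve(haps, 30, allele, direction)
                assert (np.diff(e) <= 1e-12).all()

    def test_fewer_than_two_carriers_rejected(self):
        haps = matrix([[1, 0], [0, 0], [0, 1], [0, 1]])
        with pytest.raises(ValueError, match="carriers"):
            ehh_curve(haps, 0, "derived")


class TestIntegration:
    def test_rectangle(self):
        # constant EHH 1 over 1000 bp: area 1000
        e = np.ones(11)
        pos = np.arange(11) * 100.0
        assert ls.integrate_ihh(e, pos) == pytest.approx(1000.0)

    def test_linear_decay_triangle(self):
        pos = np.linspace(0, 1000, 101)
        e = np.linspace(1, 0, 101)
        area = ls.integrate_ihh(e, pos, cutoff=0.05)
        # triangle area 500 minus the truncated sub-cutoff tail
        assert area == pytest.approx(500.0, rel=0.01)

    def test_cutoff_one_truncates_immediately(self):
        e = np.array([1.0, 0.99, 0.5])
        pos = np.array([0.0, 100.0, 200.0])
        assert ls.integrate_ihh(e, pos, cutoff=1.0) == 0.0

    def test_curve_must_start_at_one(self):
        with pytest.raises(ValueError):
            ls.integrate_ihh(np.array([0.9, 0.5]), np.array([0.0, 1.0]))


class TestRawIhs:
    def test_equal_integrals_give_zero(self):
        assert ls.raw_ihs(123.4, 123.4) == 0.0

    def test_e_ratio_gives_one(self):
        assert ls.raw_ihs(np.e * 7.0, 7.0) == pytest.approx(1.0)

    def test_antisymmetry(self):
        assert ls.raw_ihs(20.0, 5.0) == pytest.approx(-ls.raw_ihs(5.0, 20.0))

    def test_zero_integral_reported_missing(self):
        assert np.isnan(ls.raw_ihs(0.0, 5.0))
        assert np.isnan(ls.raw_ihs(5.0, 0.0))


class TestStandardize:
    def test_bins_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=300)
        freq = rng.uniform(0.06, 0.94, size=300)
        std = ls.standardize_ihs(raw, freq)
        edges = np.linspace(0, 1, 21)
        bins = np.digitize(freq, edges) - 1
        for b in np.unique(bins):
            z = std[bins == b]
            z = z[np.isfinite(z)]
            if z.size >= 2:
                assert abs(z.mean()) < 1e-10
                assert z.std() == pytest.approx(1.0, abs=1e-10)

    def test_two_bin_toy_matches_hand_computation(self):
        raw = np.array([1.0, 3.0, 10.0, 14.0])
        freq = np.array([0.11, 0.12, 0.51, 0.52])
        std = ls.standardize_ihs(raw, freq)
        np.testing.assert_allclose(std, [-1, 1, -1, 1])

    def test_zero_variance_bin_missing(self):
        std = ls.standardize_ihs(np.array([2.0, 2.0]), np.array([0.3, 0.31]))
        assert np.isnan(std).all()

    def test_extreme_frequencies_excluded(self):
        std = ls.standardize_ihs(np.array([1.0, 2.0, 1.0, 2.0]),
                                 np.array([0.01, 0.02, 0.97, 0.99]))
        assert np.isnan(std).all()

    def test_reference_distribution_used_for_bin_stats(self):
        ref_raw = np.array([0.0, 2.0, 0.0, 2.0])
        ref_freq = np.array([0.31, 0.32, 0.33, 0.34])
        std = ls.standardize_ihs(np.array([3.0]), np.array([0.32]),
                                 reference=(ref_raw, ref_freq))
        assert std[0] == pytest.approx((3.0 - 1.0) / 1.0)


class TestFlags:
    def test_published_positive_score_flagged(self):
        assert ls.flag_significant(+2.0385) == "positive"

    def test_below_threshold_not_flagged(self):
        assert ls.flag_significant(1.99) == ""

    def test_negative_direction(self):
        assert ls.flag_significant(-2.5838) == "negative"

    def test_missing_not_evaluated(self):
        assert ls.flag_significant(float("nan")) == ""


class TestScan:
    def test_scan_produces_row_per_snp(self):
        haps = simulate_haplotypes(SweepRecipe(n_haplotypes=30, n_snps=40,
                                               core_index=20, seed=3))
        df = ls.ihs_scan(haps)
        assert len(df) == 40
        assert {"raw_ihs", "std_ihs", "significant"} <= set(df.columns)

    def test_tsv_round_trip(self, tmp_path):
        haps = simulate_haplotypes(SweepRecipe(n_haplotypes=10, n_snps=12,
                                               core_index=6, seed=4))
        p = tmp_path / "haps.tsv"
        haps.to_tsv(p)
        back = HaplotypeMatrix.from_tsv(p)
        np.testing.assert_array_equal(back.haplotypes, haps.haplotypes)
        np.testing.assert_array_equal(back.positions, haps.positions)
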