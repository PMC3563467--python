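"""Model catalog, beta discretization, Model A mixture arithmetic, LRTs,
and the percent-of-sites-selected summaries."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chi2

import lineageselect as ls
from lineageselect.catalog import MODEL_IDS, get_model

# Branch-site mixture quadruples (p0, p1, p2a, p2b) for every reported
# branch-site fit, used as a regression fixture for the Model A constraint
# p2a = (1-p0-p1) p0/(p0+p1), p2b analogous.
MODEL_A_QUADRUPLES = [
    (0.93299, 0.05633, 0.01007, 0.00061),
    (0.75454, 0.23453, 0.00834, 0.00259),
    (0.93574, 0.05920, 0.00476, 0.00030),
    (0.73748, 0.25109, 0.00853, 0.00290),
    (0.90352, 0.09434, 0.00194, 0.00020),
    (0.73571, 0.25251, 0.00877, 0.00301),
    (0.92233, 0.06298, 0.01375, 0.00094),
    (0.89862, 0.08796, 0.01222, 0.00120),
    (0.78382, 0.18418, 0.02591, 0.00609),
    (0.80673, 0.17971, 0.01109, 0.00247),
    (0.79963, 0.18828, 0.00978, 0.00230),
    (0.90414, 0.09295, 0.00263, 0.00027),
    (0.89841, 0.09019, 0.01035, 0.00104),
    (0.72045, 0.22453, 0.04195, 0.01307),
    (0.81640, 0.18148, 0.00173, 0.00038),
    (0.80995, 0.18416, 0.00481, 0.00109),
    (0.87666, 0.08131, 0.03846, 0.00357),
    (0.79911, 0.19671, 0.00335, 0.00082),
    (0.93360, 0.01536, 0.05021, 0.00083),
    (0.96609, 0.02476, 0.00892, 0.00023),
    (0.80206, 0.18611, 0.00961, 0.00223),
    (0.97375, 0.02506, 0.00116, 0.00003),
    (0.80595, 0.18541, 0.00703, 0.00162),
    (0.61027, 0.37605, 0.00846, 0.00522),
    (0.57771, 0.06636, 0.31926, 0.03667),
    (0.81572, 0.18045, 0.00313, 0.00069),
    (0.90728, 0.05930, 0.03137, 0.00205),
]


class TestCatalog:
    def test_catalog_lists_all_models(self):
        cat = ls.model_catalog()
        assert [m.id for m in cat] == list(MODEL_IDS)

    def test_m1a_structure(self):
        m1a = get_model("M1a")
        classes = m1a.build_classes({"kappa": 2.0, "p0": 0.7, "omega0": 0.2})
        assert len(classes) == 2
        assert classes[0].omega == 0.2           # omega0 < 1 free
        assert classes[1].omega == 1.0           # omega1 = 1 fixed
        assert "omega1 = 1" in m1a.constraints

    def test_m8a_differs_from_m8_by_one_df(self):
        assert get_model("M8").n_free - get_model("M8a").n_free == 1

    def test_unknown_model_errors(self):
        with pytest.raises(KeyError, match="M99"):
            get_model("M99")

    def test_modelAnull_fixes_omega2(self):
        classes = get_model("ModelAnull").build_classes(
            {"kappa": 2.0, "s": 0.9, "r": 0.8, "omega0": 0.1})
        assert all(c.fg == c.omega or c.fg == 1.0 for c in classes)
        assert classes[2].fg == 1.0

    @pytest.mark.parametrize("null,alt,df", [("M0", "M3k2", 2),
                                             ("M0", "M3k3", 4),
                                             ("M1a", "M2a", 2),
                                             ("M7", "M8", 2),
                                             ("M8a", "M8", 1),
                                             ("ModelAnull", "ModelA", 1)])
    def test_battery_degrees_of_freedom(self, null, alt, df):
        assert get_model(alt).n_free - get_model(null).n_free == df


class TestDiscretizeBeta:
    def test_equal_weights(self):
        cats = ls.discretize_beta(0.3, 1.2, K=10)
        assert all(w == pytest.approx(0.1) for _, w in cats)

    def test_uniform_beta_gives_midpoint_quantiles(self):
        cats = ls.discretize_beta(1.0, 1.0, K=10)
        np.testing.assert_allclose([om for om, _ in cats],
                                   np.arange(0.05, 1.0, 0.1), atol=1e-12)

    def test_category_mean_close_to_beta_mean(self):
        p, q = 2.0, 3.0
        cats = ls.discretize_beta(p, q, K=10)
        mean = sum(om * w for om, w in cats)
        assert mean == pytest.approx(p / (p + q), abs=0.01)

    def test_nonpositive_shapes_rejected(self):
        with pytest.raises(ValueError):
            ls.discretize_beta(0.0, 1.0)


class TestMixtureWeights:
    @pytest.mark.parametrize("p0,p1,p2a,p2b", MODEL_A_QUADRUPLES)
    def test_reported_quadruples_satisfy_constraint(self, p0, p1, p2a, p2b):
        """Class-2a/2b proportions recomputed from p0, p1 match the
        published 5-decimal values (1.5e-5 allows one ulp of input
        rounding)."""
        mw = ls.modelA_class_proportions(p0, p1)
        assert mw.p2a == pytest.approx(p2a, abs=1.5e-5)
        assert mw.p2b == pytest.approx(p2b, abs=1.5e-5)
        assert sum(mw.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    def test_saturated_weights_give_empty_selected_class(self):
        mw = ls.modelA_class_proportions(0.6, 0.4)
        assert mw.p2a == 0.0 and mw.p2b == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ls.modelA_class_proportions(0.0, 0.0)


class _FakeFit:
    """Stand-in fit result carrying only what lrt() reads."""

    def __init__(self, model_id, lnL, n_free):
        self.model_id = model_id
        self.lnL = lnL
        self.n_free_params = n_free


class TestLRT:
    def test_equal_lnL_gives_stat_zero_p_one(self):
        r = ls.lrt(_FakeFit("M1a", -100.0, 3), _FakeFit("M2a", -100.0, 5))
        assert r.stat == 0.0 and r.p_value == 1.0

    def test_chi2_quantile(self):
        r = ls.lrt(_FakeFit("M1a", -100.0, 3),
                   _FakeFit("M2a", -100.0 + 5.991 / 2, 5))
        assert r.df == 2
        assert r.p_value == pytest.approx(0.05, abs=5e-4)
        assert r.p_value == pytest.approx(chi2.sf(5.991, 2))

    def test_worse_alternative_flags_optimization_failure(self):
        r = ls.lrt(_FakeFit("M1a", -100.0, 3), _FakeFit("M2a", -101.0, 5))
        assert r.optimization_failure
        assert r.stat == 0.0
        assert not r.significant

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError, match="not a nested"):
            ls.lrt(_FakeFit("M2a", -100.0, 5), _FakeFit("M7", -99.0, 3))

    def test_boundary_mixture_reference_halves_p(self):
        a = _FakeFit("M8a", -100.0, 5)
        b = _FakeFit("M8", -98.0, 6)
        plain = ls.lrt(a, b, boundary="chi2")
        mixed = ls.lrt(a, b, boundary="mixture")
        assert mixed.p_value == pytest.approx(plain.p_value / 2)


class _FitWithClasses:
    """Stand-in for percent_selected: model id, params, mixture classes."""

    def __init__(self, model_id, params, classes):
        from lineageselect.engine import OmegaClass
        self.model_id = model_id
        self.params = params
        self.mle = type("S", (), {})()
        self.mle.classes = [OmegaClass(*c) for c in classes]

    def selected_class_omega(self):
        if self.model_id == "M2a":
            return self.params["omega2"]
        if self.model_id == "M8":
            return self.params["omega_s"]
        if self.model_id == "M0":
            return self.params["omega"]
        return self.params.get("omega2", 1.0)


class TestPercentSelected:
    def test_branch_site_percentage_from_published_weights(self):
        # the headline 35.59% case: p2a + p2b = 0.31926 + 0.03667
        mw = ls.modelA_class_proportions(0.57771, 0.06636)
        om0, om2 = 0.12047, 3.59059
        fit = _FitWithClasses(
            "ModelA", {"omega2": om2},
            [(mw.p0, om0, om0), (mw.p1, 1.0, 1.0),
             (mw.p2a, om0, om2), (mw.p2b, 1.0, om2)],
        )
        assert ls.percent_selected(fit) == pytest.approx(35.59, abs=0.005)

    def test_m8_percentage(self):
        # 0.71% of sites in the selected class
        p1 = 0.00709
        fit = _FitWithClasses("M8", {"omega_s": 4.53766},
                              [(1 - p1, 0.1, None), (p1, 4.53766, None)])
        assert ls.percent_selected(fit) == pytest.approx(0.71, abs=0.005)

    def test_m1a_is_zero(self):
        fit = _FitWithClasses("M1a", {}, [(0.7, 0.1, None), (0.3, 1.0, None)])
        assert ls.percent_selected(fit) == 0.0

    def test_selected_class_at_omega_one_is_zero(self):
        fit = _FitWithClasses("M2a", {"omega2": 1.0},
                              [(0.6, 0.1, None), (0.3, 1.0, None),
                               (0.1, 1.0, None)])
        assert ls.percent_selected(fit) == 0.0
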