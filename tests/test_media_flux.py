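"""Spent-media adjustment arithmetic and the two uptake-branch dialects."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitoflux import media_flux
from mitoflux.media_flux import (
    GrowthAdjustment,
    adjust_media_ratio,
    classify_flux,
    estimate_alpha,
    estimate_delta_g,
    evaporation_correct,
    geometric_mean_normalize,
)

LN2 = math.log(2.0)


class TestGeometricMeanNormalize:
    def test_hand_example(self):
        table = pd.DataFrame({"a": [1.0], "b": [4.0], "c": [16.0]}, index=["s1"])
        out = geometric_mean_normalize(table)
        np.testing.assert_allclose(out.loc["s1"].to_numpy(), [0.25, 1.0, 4.0])

    def test_identical_values_become_ones(self):
        table = pd.DataFrame(np.full((2, 5), 7.3), index=["s1", "s2"])
        np.testing.assert_allclose(geometric_mean_normalize(table).to_numpy(), 1.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None)
    def test_scale_invariance(self, scale):
        table = pd.DataFrame({"a": [2.0], "b": [8.0], "c": [0.5]}, index=["s"])
        base = geometric_mean_normalize(table)
        scaled = geometric_mean_normalize(table * scale)
        np.testing.assert_allclose(scaled.to_numpy(), base.to_numpy(), rtol=1e-9)

    def test_error_names_sample_and_metabolite(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 0.0]},
                             index=["s1", "s2"])
        with pytest.raises(ValueError, match=r"'s2'.*'b'"):
            geometric_mean_normalize(table)

    def test_normalized_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.lognormal(0, 1, size=(4, 9)))
        out = geometric_mean_normalize(table).to_numpy()
        np.testing.assert_allclose(np.exp(np.log(out).mean(axis=1)), 1.0)


class TestEvaporation:
    def test_full_window_reproduces_measured_fraction(self):
        assert evaporation_correct(1.0, 0.12, t=3.0, T=3.0) == pytest.approx(0.88)

    def test_zero_evaporation_is_identity(self):
        assert evaporation_correct(1.7, 0.0, t=2.0, T=3.0) == 1.7

    def test_time_zero_is_identity(self):
        assert evaporation_correct(1.7, 0.12, t=0.0, T=3.0) == 1.7

    def test_full_loss_rejected(self):
        with pytest.raises(ValueError):
            evaporation_correct(1.0, 1.0, t=1.0, T=3.0)


class TestDeltaG:
    @staticmethod
    def _table(totals):
        return pd.DataFrame({"m1": [t / 2 for t in totals],
                             "m2": [t / 2 for t in totals]})

    def test_halved_totals_after_two_days(self):
        treated = self._table([5.0, 5.0])
        untreated = self._table([10.0, 10.0])
        assert estimate_delta_g(treated, untreated, 2.0) == pytest.approx(-0.5)

    def test_identical_tables_give_zero(self):
        t = self._table([8.0, 9.0])
        assert estimate_delta_g(t, t, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_doubled_totals_after_one_day(self):
        assert estimate_delta_g(self._table([4.0]), self._table([2.0]), 1.0) == \
            pytest.approx(1.0)

    def test_disjoint_metabolites_rejected(self):
        a = pd.DataFrame({"x": [1.0]})
        b = pd.DataFrame({"y": [1.0]})
        with pytest.raises(ValueError, match="share no metabolites"):
            estimate_delta_g(a, b, 1.0)


class TestAlpha:
    def test_no_deficit_gives_one(self):
        adj = GrowthAdjustment(delta_g=0.0, g_ctrl=0.5, t_treat=2.0, window_days=3.0)
        assert estimate_alpha(adj) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_example(self):
        adj = GrowthAdjustment(delta_g=-1.0, g_ctrl=0.0, t_treat=3.0, window_days=3.0)
        expected = (1.0 - 2.0 ** -3) / (3.0 * LN2)
        assert estimate_alpha(adj) == pytest.approx(expected, rel=1e-12)

    def test_continuity_in_delta_g_at_zero(self):
        near = estimate_alpha(GrowthAdjustment(delta_g=1e-9, g_ctrl=0.5,
                                               t_treat=3.0, window_days=3.0))
        assert near == pytest.approx(1.0, abs=1e-6)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            GrowthAdjustment(delta_g=0.0, t_treat=1.0, window_days=0.0)


class TestAdjustmentFunction:
    @pytest.mark.parametrize("dialect", ["literal", "power"])
    @pytest.mark.parametrize("alpha", [0.3, 0.8, 1.0, 1.5])
    def test_zero_flux_boundary(self, dialect, alpha):
        assert adjust_media_ratio(1.0, alpha, dialect) == pytest.approx(1.0)

    @pytest.mark.parametrize("dialect", ["literal", "power"])
    def test_alpha_one_is_identity(self, dialect):
        r = np.array([0.01, 0.4, 0.999, 1.0, 1.001, 2.5, 10.0])
        np.testing.assert_allclose(adjust_media_ratio(r, 1.0, dialect), r)

    def test_released_branch_hand_value(self):
        assert adjust_media_ratio(2.0, 0.8) == pytest.approx(1.8)

    def test_literal_uptake_branch_hand_value(self):
        expected = 0.5 ** 0.8 + 0.1
        assert adjust_media_ratio(0.5, 0.8, "literal") == pytest.approx(expected)

    def test_power_uptake_branch(self):
        assert adjust_media_ratio(0.5, 0.8, "power") == pytest.approx(0.5 ** 0.8)

    @pytest.mark.parametrize("dialect", ["literal", "power"])
    @given(alpha=st.floats(min_value=0.05, max_value=1.0),
           r1=st.floats(min_value=0.01, max_value=5.0),
           r2=st.floats(min_value=0.01, max_value=5.0))
    @settings(deadline=None, max_examples=200)
    def test_monotone_within_branch(self, dialect, alpha, r1, r2):
        lo, hi = sorted((r1, r2))
        same_branch = (lo >= 1.0) or (hi <= 1.0)
        if same_branch:
            assert adjust_media_ratio(lo, alpha, dialect) <= \
                adjust_media_ratio(hi, alpha, dialect) + 1e-12

    def test_power_dialect_meets_all_three_criteria(self):
        alpha = 0.7
        eps = 1e-7
        # (1) value and slope match the released branch at R = 1
        left = (adjust_media_ratio(1.0, alpha, "power")
                - adjust_media_ratio(1.0 - eps, alpha, "power")) / eps
        right = (adjust_media_ratio(1.0 + eps, alpha, "power")
                 - adjust_media_ratio(1.0, alpha, "power")) / eps
        assert left == pytest.approx(alpha, abs=1e-5)
        assert right == pytest.approx(alpha, abs=1e-5)
        assert adjust_media_ratio(1.0 - eps, alpha, "power") == \
            pytest.approx(1.0, abs=1e-6)
        # (2) continuity across the uptake range, (3) limit 0 as R -> 0
        grid = np.logspace(-9, 0, 200)
        vals = adjust_media_ratio(grid, alpha, "power")
        assert np.all(np.diff(vals) > 0)
        assert vals[0] == pytest.approx(0.0, abs=1e-5)
        assert np.all(vals > 0)

    def test_literal_left_limit_regression_guard(self):
        """The printed uptake branch approaches 2 - alpha as R -> 1-."""
        alpha = 0.7
        val = adjust_media_ratio(1.0 - 1e-9, alpha, "literal")
        assert val == pytest.approx(2.0 - alpha, abs=1e-6)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            adjust_media_ratio(0.0, 0.8)
        with pytest.raises(ValueError):
            adjust_media_ratio(1.5, 0.0)


class TestClassify:
    @pytest.mark.parametrize("r, expected", [
        (1.5, "released"), (0.2, "uptaken"), (1.0, "neutral"),
        (1.04, "neutral"), (0.96, "neutral"),
    ])
    def test_calls(self, r, expected):
        assert classify_flux(r, tol=0.05) == expected


class TestPanelRoundTrip:
    def test_flux_sign_recovered_for_every_metabolite(self, noiseless_dataset):
        ds = noiseless_dataset
        for cond in ("day2", "day3"):
            result, adj, alpha = media_flux.analyze_panel(
                ds.panel, cond, f_evap=ds.config.evaporation_fraction,
                g_ctrl=ds.config.g_ctrl_true, dialect="power",
            )
            assert adj.delta_g == pytest.approx(ds.config.delta_g_true, abs=1e-9)
            assert alpha == pytest.approx(
                ds.media_truth["alpha_true"][cond], rel=1e-9
            )
            flux = ds.media_truth["flux_true"]
            signs = np.sign(result["R_adj"].to_numpy() - 1.0)
            expected = np.array([np.sign(flux[m]) for m in result["metabolite"]])
            np.testing.assert_array_equal(signs, expected)
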