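"""Two-zone model, border fitting and the exact Kolmogorov-Smirnov test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from axregen import (
    FucciProfile,
    TwoZoneModel,
    ZoneFit,
    day4_fucci_truth,
    fit_zone_border,
    generate_fucci_profiles,
    ks_2samp_exact,
    ks_zone_test,
    profiles_from_frame,
    profiles_to_frame,
    two_zone_model,
    zone_distance,
)
from axregen.zones import KsResult


def make_profile(pct_g0g1, pct_sg2, n_cells=20, bin_width=100.0):
    n = len(pct_g0g1)
    starts = -bin_width * np.arange(n, 0, -1)
    return FucciProfile(
        animal="t",
        day=4.0,
        bins=pd.DataFrame(
            {
                "ap_start_um": starts,
                "ap_end_um": starts + bin_width,
                "n_cells": n_cells,
                "pct_g0g1": pct_g0g1,
                "pct_sg2": pct_sg2,
            }
        ),
    )


class TestTwoZoneModel:
    def test_anterior_and_posterior_values(self):
        fit = ZoneFit(80.0, 40.0, 10.0, 50.0, ap_border=-700.0)
        g, s = two_zone_model([-900.0, -100.0], fit)
        assert (g[0], s[0]) == (80.0, 10.0)
        assert (g[1], s[1]) == (40.0, 50.0)

    def test_border_belongs_to_posterior_zone(self):
        fit = ZoneFit(80.0, 40.0, 10.0, 50.0, ap_border=-700.0)
        g, s = two_zone_model(-700.0, fit)
        assert (float(g), float(s)) == (40.0, 50.0)

    def test_degenerate_step_is_constant(self):
        fit = ZoneFit(60.0, 60.0, 20.0, 20.0, ap_border=-500.0)
        g, _ = two_zone_model(np.linspace(-1600, 0, 17), fit)
        assert np.all(g == 60.0)

    def test_percentages_validated(self):
        with pytest.raises(ValueError):
            ZoneFit(120.0, 40.0, 10.0, 50.0, ap_border=0.0)


class TestZoneDistance:
    def test_perfect_fit_is_zero(self):
        prof = make_profile([80.0, 40.0], [10.0, 50.0])
        fit = ZoneFit(80.0, 40.0, 10.0, 50.0, ap_border=-100.0)
        assert zone_distance(fit, prof) == 0.0

    def test_hand_evaluated_residuals(self):
        # two bins with residuals (10, 0) and (0, 5) -> 100 + 25
        prof = make_profile([90.0, 40.0], [10.0, 55.0])
        fit = ZoneFit(80.0, 40.0, 10.0, 50.0, ap_border=-100.0)
        assert zone_distance(fit, prof) == pytest.approx(125.0)

    def test_invariant_to_bin_ordering(self):
        prof = make_profile([90.0, 40.0, 30.0], [10.0, 55.0, 60.0])
        fit = ZoneFit(80.0, 40.0, 10.0, 50.0, ap_border=-200.0)
        shuffled = FucciProfile(
            animal="t", day=4.0, bins=prof.bins.iloc[[2, 0, 1]].reset_index(drop=True)
        )
        assert zone_distance(fit, prof) == pytest.approx(zone_distance(fit, shuffled))


class TestBorderFit:
    def test_sharp_step_recovered_within_one_bin(self):
        truth = day4_fucci_truth(n_animals=1)
        profile = generate_fucci_profiles(truth, 11)[0]
        fit = fit_zone_border(profile, seed=1)
        assert abs(fit.ap_border - (-700.0)) <= 100.0

    def test_best_particle_approaches_zone_means(self):
        """At the true border the optimal levels are the zone means."""
        truth = day4_fucci_truth(n_animals=1, cells_per_animal=3200)
        profile = generate_fucci_profiles(truth, 21)[0]
        fit = fit_zone_border(profile, seed=2)
        v = profile.valid
        post = profile.centers >= fit.ap_border
        for col, a_val, p_val in (
            ("pct_g0g1", fit.g0g1_a, fit.g0g1_p),
            ("pct_sg2", fit.sg2_a, fit.sg2_p),
        ):
            obs = v[col].to_numpy(float)
            assert a_val == pytest.approx(obs[~post].mean(), abs=3.0)
            assert p_val == pytest.approx(obs[post].mean(), abs=3.0)

    def test_flat_profile_border_posterior_is_broad(self):
        rng = np.random.default_rng(3)
        n = 16
        pct_g = np.clip(rng.normal(85.0, 2.0, n), 0, 100)
        pct_s = np.clip(rng.normal(11.0, 2.0, n), 0, 100)
        profile = make_profile(pct_g, pct_s)
        res = TwoZoneModel(profile).fit(population_size=400, iterations=8, seed=4)
        # no step: the border posterior stays spread over the measured range
        assert res.border_spread() > 200.0

    def test_single_bin_unidentifiable(self):
        prof = make_profile([80.0], [10.0])
        with pytest.raises(ValueError):
            TwoZoneModel(prof)

    def test_profile_roundtrip_through_frame(self):
        truth = day4_fucci_truth(n_animals=3)
        profiles = generate_fucci_profiles(truth, 5)
        frame = profiles_to_frame(profiles)
        back = profiles_from_frame(frame)
        assert len(back) == 3
        pd.testing.assert_frame_equal(
            back[0].bins.reset_index(drop=True),
            profiles[0].bins.reset_index(drop=True),
        )


class TestExactKS:
    def test_complete_separation_n4(self):
        d, p = ks_2samp_exact([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0])
        assert d == 1.0
        assert p == pytest.approx(2.0 / math.comb(8, 4))  # 0.0286

    def test_identical_samples(self):
        d, p = ks_2samp_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    @pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 5), (5, 6), (6, 6)])
    def test_agrees_with_scipy_exact_small_samples(self, n, m, rng):
        for _ in range(5):
            x = rng.normal(size=n)
            y = rng.normal(0.5, size=m)
            d, p = ks_2samp_exact(x, y)
            ref = stats.ks_2samp(x, y, method="exact")
            assert d == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_enumeration_p_matches_brute_force_orderings(self, rng):
        """Independent oracle: walk every C(n+m, n) label assignment."""
        x = rng.normal(size=4)
        y = rng.normal(1.0, size=3)
        d_obs, p = ks_2samp_exact(x, y)
        pooled = np.sort(np.concatenate([x, y]))
        count = total = 0
        for combo in itertools.combinations(range(7), 4):
            fx = fy = 0.0
            d = 0.0
            for i in range(7):
                if i in combo:
                    fx += 1 / 4
                else:
                    fy += 1 / 3
                if i == 6 or pooled[i] != pooled[i + 1]:
                    d = max(d, abs(fx - fy))
            total += 1
            if d >= d_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)

    def test_fallback_path_matches_scipy_for_moderate_samples(self, rng):
        # n = m = 30 exceeds the enumeration budget; the fallback must agree
        # with scipy's lattice-path exact computation
        x = rng.normal(size=30)
        y = rng.normal(0.4, size=30)
        d, p = ks_2samp_exact(x, y)
        ref = stats.ks_2samp(x, y, method="exact")
        assert d == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_pvalues_in_unit_interval(self, rng):
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=4)
            _, p = ks_2samp_exact(x, y)
            assert 0.0 < p <= 1.0


class TestKsZoneTest:
    def test_full_separation_reproduces_printed_p(self):
        fits = [
            ZoneFit(80.0 + i, 40.0 + i, 15.0 + i, 55.0 + i, ap_border=-700.0)
            for i in range(4)
        ]
        out = ks_zone_test(fits)
        assert set(out) == {"g0g1", "sg2", "pooled"}
        assert out["g0g1"].pvalue == pytest.approx(2.0 / 70.0)
        assert out["g0g1"].statistic == 1.0

    def test_requires_two_animals(self):
        with pytest.raises(ValueError):
            ks_zone_test([ZoneFit(80.0, 40.0, 10.0, 50.0, ap_border=0.0)])
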