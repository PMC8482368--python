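"""Kinetics: exponential fits, turnover, network, fluxes and rates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cometchem import H3_18_26
from cometchem.kinetics import (
    AcetylationKineticsModel,
    build_network,
    fit_decay_fixed_intercept,
    fit_growth,
    fit_growth_fixed_plateau,
    initial_flux,
    label_fraction,
    reaction_rate,
    state_strings,
    turnover,
)

T7 = np.array([0.0, 30.0, 60.0, 120.0, 360.0, 720.0, 1440.0])  # min


class TestLabelFraction:
    def test_equal_heavy_light_is_half(self):
        mask, f = label_fraction(np.ones(5), np.ones(5))
        assert np.allclose(f, 0.5)

    def test_prelabel_point_is_zero(self):
        mask, f = label_fraction(np.array([0.0, 1.0]), np.array([4.0, 3.0]))
        assert f[0] == 0.0

    def test_undefined_points_masked(self):
        mask, f = label_fraction(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert not mask[0] and mask[1]

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            label_fraction(np.zeros(3), np.zeros(3))


class TestGrowthFit:
    @pytest.mark.parametrize("p,k", [(0.4, 0.1086), (0.8, 0.02), (0.25, 0.5)])
    def test_noise_free_recovery(self, p, k):
        f = p * (1 - np.exp(-k * T7 / 60.0))
        fit = fit_growth(T7, f)
        assert fit.ok
        assert fit.p == pytest.approx(p, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)

    def test_half_life_definition(self):
        f = 0.4 * (1 - np.exp(-math.log(2) * T7 / 60.0))
        fit = fit_growth(T7, f)
        assert fit.t_half_min == pytest.approx(60.0, rel=1e-6)
        assert fit.k * fit.t_half_min / 60.0 == pytest.approx(math.log(2), rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_growth(np.array([0.0, 60.0, 120.0]), np.array([0.0, 0.1, 0.2]))

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fit_growth(T7, np.full(7, 1.5))

    def test_fixed_plateau_recovers_rate_from_unsaturated_curve(self):
        # slow site: curve reaches only ~50% of plateau in 24 h
        f = 0.4 * (1 - np.exp(-0.032 * T7 / 60.0))
        fit = fit_growth_fixed_plateau(T7, f, 0.4)
        assert fit.k == pytest.approx(0.032, rel=1e-9)


class TestDecayFit:
    def test_noise_free_recovery(self):
        r = 100.0 * np.exp(-0.189 * T7[:5] / 60.0)
        fit = fit_decay_fixed_intercept(T7[:5], r)
        assert fit.ok
        assert fit.k == pytest.approx(0.189, rel=1e-9)

    def test_constant_series_flagged_no_decay(self):
        fit = fit_decay_fixed_intercept(T7, np.full(7, 100.0))
        assert not fit.ok
        assert fit.t_half_min == math.inf

    def test_half_reached_at_half_life(self):
        fit = fit_decay_fixed_intercept(T7, 100.0 * np.exp(-0.1 * T7 / 60.0))
        r_at_thalf = 100.0 * math.exp(-fit.k * fit.t_half_min / 60.0)
        assert r_at_thalf == pytest.approx(50.0, rel=1e-9)


class TestTurnover:
    # published site half-lives and abundances reproduce the published
    # abundance-corrected turnovers within 1%
    @pytest.mark.parametrize(
        "t_half_min,abundance,expected",
        [(549.0, 5.0, 0.38), (383.0, 28.4, 3.07), (220.0, 14.2, 2.69)],
    )
    def test_published_turnover_values(self, t_half_min, abundance, expected):
        k = math.log(2) / (t_half_min / 60.0)
        tv = turnover(k, abundance)
        assert tv.turnover_pct_per_h == pytest.approx(expected, rel=0.01)

    def test_zero_abundance(self):
        assert turnover(0.1, 0.0).turnover_pct_per_h == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.001, 10.0), st.floats(0.0, 100.0))
    def test_bilinearity(self, k, a):
        assert turnover(2 * k, a).turnover_pct_per_h == pytest.approx(
            2 * turnover(k, a).turnover_pct_per_h
        )
        assert turnover(k, 2 * a).turnover_pct_per_h == pytest.approx(
            2 * turnover(k, a).turnover_pct_per_h
        )


class TestNetwork:
    @pytest.mark.parametrize("n,species", [(1, 3), (2, 9), (3, 27)])
    def test_species_count(self, n, species):
        assert len(build_network(n).species) == species

    def test_two_site_network_has_at_least_twelve_reactions(self):
        assert len(build_network(2).reactions) >= 12

    def test_every_edge_changes_exactly_one_site(self):
        for n in (1, 2, 3):
            for rxn in build_network(n).reactions:
                diffs = [i for i, (a, b) in enumerate(zip(rxn.substrate, rxn.product)) if a != b]
                assert diffs == [rxn.site]

    def test_heavy_substrates_not_estimable(self):
        net = build_network(1)
        for rxn in net.reactions:
            assert rxn.estimable == ("H" not in rxn.substrate)
        est = net.estimable()
        assert {(r.kind, r.substrate) for r in est} == {
            ("acetylation", "U"), ("deacetylation", "L"),
        }

    def test_estimable_count_matches_heavy_free_substrates(self):
        net = build_network(2)
        by_hand = sum(1 for r in net.reactions if "H" not in r.substrate)
        assert len(net.estimable()) == by_hand == 8

    def test_conventional_labels_for_two_sites(self):
        labels = {(r.kind, r.site, r.substrate): r.label for r in build_network(2).estimable()}
        assert labels[("acetylation", 0, "UU")] == "a1"
        assert labels[("acetylation", 1, "UU")] == "a2"
        assert labels[("acetylation", 1, "LU")] == "a3"
        assert labels[("acetylation", 0, "UL")] == "a4"
        assert labels[("deacetylation", 0, "LU")] == "d1"
        assert labels[("deacetylation", 1, "UL")] == "d2"
        assert labels[("deacetylation", 0, "LL")] == "d3"


class TestInitialFlux:
    def test_exact_linear_series(self):
        t = T7[:4]
        y = 2.0 + 0.5 * t / 60.0
        res = initial_flux(t, y)
        assert res.slope_pct_per_h == pytest.approx(0.5, abs=1e-12)
        assert res.stderr == pytest.approx(0.0, abs=1e-9)
        assert res.intercept_pct == pytest.approx(2.0, abs=1e-12)

    def test_window_restricts_points(self):
        y = np.concatenate([0.5 * T7[:4] / 60.0, [50.0, 80.0, 99.0]])
        res = initial_flux(T7, y, window_h=4.0, max_points=4)
        assert res.n_points == 4
        assert res.slope_pct_per_h == pytest.approx(0.5, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            initial_flux(np.array([0.0, 30.0]), np.array([0.0, 1.0]))

    def test_pinned_intercept_ignores_t0_value(self):
        t = T7[:4]
        y = 0.5 * t / 60.0
        y0_noisy = y.copy()
        y0_noisy[0] = 7.0  # garbage at t = 0 must not matter
        res = initial_flux(t, y0_noisy, intercept_at=0.0)
        assert res.slope_pct_per_h == pytest.approx(0.5, abs=1e-12)

    def test_window_choice_stable_on_simulated_curve(self):
        # near-linear early phase: halving the window moves the slope < 10%
        t = np.linspace(0.0, 240.0, 9)
        y = 20.0 * (1.0 - np.exp(-0.05 * t / 60.0))
        s_full = initial_flux(t, y, window_h=4.0, max_points=9).slope_pct_per_h
        s_half = initial_flux(t, y, window_h=2.0, max_points=9).slope_pct_per_h
        assert abs(s_half - s_full) / s_full < 0.10


class TestReactionRate:
    def test_simple_division(self):
        est = reaction_rate(1.0, 50.0)
        assert est.rate_per_h == pytest.approx(0.02)
        assert est.estimable

    def test_plateau_correction(self):
        est = reaction_rate(1.0, 50.0, label_plateau=0.4)
        assert est.rate_per_h == pytest.approx(0.05)

    def test_zero_substrate_not_estimable(self):
        est = reaction_rate(1.0, 0.0)
        assert not est.estimable
        assert math.isnan(est.rate_per_h)

    def test_invalid_plateau_rejected(self):
        with pytest.raises(ValueError, match="label_plateau"):
            reaction_rate(1.0, 50.0, label_plateau=0.0)


def _states_df(traj, replicate=1):
    rows = []
    for t, dist in traj.items():
        for s, a in dist.items():
            rows.append({"time_min": t, "replicate": replicate, "state_id": s,
                         "abundance_pct": a})
    return pd.DataFrame(rows)


class TestModel:
    def test_input_validation(self):
        df = pd.DataFrame({
            "time_min": [0.0], "replicate": [1], "state_id": ["L"], "abundance_pct": [100.0]
        })
        with pytest.raises(ValueError, match="cover all"):
            AcetylationKineticsModel(df)

    def test_abundance_sum_checked(self):
        rows = [{"time_min": 0.0, "replicate": 1, "state_id": s, "abundance_pct": 10.0}
                for s in state_strings(1)]
        with pytest.raises(ValueError, match="sum to 100"):
            AcetylationKineticsModel(pd.DataFrame(rows))

    def test_noise_free_single_site_recovery(self):
        # one site, a = 0.01/h, d = 0.05/h, lambda = 0.4: occupancy theta is
        # constant, heavy fraction grows as lambda(1 - exp(-d t))
        a, d, lam = 0.01, 0.05, 0.4
        theta = a / (a + d)
        traj = {}
        for t in [0.0, 30.0, 60.0, 120.0, 360.0, 720.0, 1440.0]:
            th = t / 60.0
            h = theta * lam * (1 - math.exp(-d * th))
            traj[t] = {"U": (1 - theta) * 100.0, "L": (theta - h) * 100.0, "H": h * 100.0}
        model = AcetylationKineticsModel(_states_df(traj))
        res = model.fit()
        g = res.growth_fits.iloc[0]
        assert g["p"] == pytest.approx(lam, rel=1e-6)
        assert g["k_per_h"] == pytest.approx(d, rel=1e-6)
        rates = res.rates.set_index("reaction")
        # initial-flux linearization bias stays below ~10% on this window
        assert rates.loc["a[s0|ctx-]", "rate_per_h"] == pytest.approx(a, rel=0.10)
        assert rates.loc["d[s0|ctx-]", "rate_per_h"] == pytest.approx(d, rel=0.10)

    def test_pooled_replicates(self, default_dataset):
        from cometchem import run_pipeline

        res = run_pipeline(H3_18_26, default_dataset.ms1, default_dataset.ms2)
        pooled = AcetylationKineticsModel(
            res.species_abundances, H3_18_26
        ).fit(per_replicate=False)
        assert set(pooled.rates["replicate"]) == {"pooled"}
        assert len(pooled.rates) == 7
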