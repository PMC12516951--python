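"""Generator invariants: determinism, planted structure, limit behavior."""

import numpy as np
import pandas as pd
import pytest

from sewerflow.growth_fate import MassBalanceParams
from sewerflow.io_formats import CountTable
from sewerflow.synthetic_data import (
    CommunityScenario,
    ScenarioError,
    dry_days_before,
    simulate_as,
    simulate_habitats,
    simulate_rainfall,
    simulate_wastewater_mixing,
    steady_state_as_profile,
)


class TestScenario:
    def test_profiles_are_simplex(self, default_scenario):
        for hab in ("biofilm_g", "sediment", "SWW_g", "IWW", "AS"):
            prof = default_scenario.habitat_profile(hab)
            assert prof.sum() == pytest.approx(1.0, abs=1e-9)
            assert (prof >= 0).all()

    def test_low_evenness_top_taxa_dominate(self, default_scenario):
        # a few abundant taxa carry >25% of a sewer habitat's abundance
        prof = default_scenario.habitat_profile("biofilm_g")
        assert prof.sort_values(ascending=False).iloc[:5].sum() > 0.25

    def test_infeasible_structure_rejected(self):
        with pytest.raises(ScenarioError):
            CommunityScenario(n_species=60, n_gut_species=50)
        with pytest.raises(ScenarioError):
            CommunityScenario(gut_fraction={"IWW": 1.4})

    def test_unified_priority_is_exercised(self, default_scenario):
        """At least one species is strict in one habitat and loose in another."""
        cores = default_scenario.planted_cores()
        strict_anywhere = set().union(*(c["strict"] for c in cores.values()))
        loose_anywhere = set().union(*(c["loose"] for c in cores.values()))
        assert strict_anywhere & loose_anywhere


class TestSimulateHabitats:
    def test_same_seed_identical_tables(self, default_scenario, simulated):
        table, meta, tax, _ = simulated
        t2, m2, x2 = simulate_habitats(CommunityScenario(seed=default_scenario.seed))
        assert t2.counts.equals(table.counts)
        assert m2.equals(meta)

    def test_different_seed_differs(self, simulated):
        table, *_ = simulated
        t2, _, _ = simulate_habitats(CommunityScenario(seed=8))
        assert not t2.counts.equals(table.counts)

    def test_depths_in_declared_ranges(self, default_scenario, simulated):
        table, meta, _, _ = simulated
        totals = table.totals()
        hab = meta.set_index("sample_id")["habitat"]
        sewer = hab.isin(["biofilm_g", "biofilm_ep", "sediment"])
        lo, hi = default_scenario.sewer_depth_range
        # unclassified background ASVs add a handful of reads on top
        assert totals[sewer[totals.index]].between(lo, hi + 50).all()
        lo_w, hi_w = default_scenario.water_depth_range
        assert totals[~sewer[totals.index]].between(lo_w, hi_w + 50).all()

    def test_multinomial_limit_recovers_profile(self):
        sc = CommunityScenario(overdispersion=np.inf, seed=3)
        table, meta, tax = simulate_habitats(sc)
        from sewerflow.io_formats import aggregate

        species = aggregate(table, tax, "species")
        iww = [s for s in species.sample_ids if s.startswith("IWW")]
        rel = species.relative_abundance().loc[iww]
        prof = sc.habitat_profile("IWW")
        top = prof.sort_values(ascending=False).index[:10]
        assert np.allclose(rel[top].mean(axis=0), prof[top], atol=0.01)


class TestSteadyStateProfile:
    PARAMS = MassBalanceParams(20.0, 0.05)

    def test_surviving_species_sit_at_the_balance_ratio(self):
        iww = pd.Series({"a": 0.5, "b": 0.5})
        fate = pd.Series({"a": "surviving", "b": "surviving"})
        prof, mu = steady_state_as_profile(iww, fate, self.PARAMS)
        # a_IWW / a_AS = 1/(m*SRT) = 1 here
        assert np.allclose(prof, iww)
        assert np.allclose(mu, 0.0, atol=1e-12)

    def test_disappearing_species_depleted_by_immigration_balance(self):
        masses = [0.024] * 10 + [0.031] * 10 + [0.045] * 10
        iww = pd.Series(masses, index=[f"s{i}" for i in range(30)])
        fate = pd.Series(
            ["growing"] * 10 + ["surviving"] * 10 + ["disappearing"] * 10,
            index=iww.index,
        )
        prof, mu = steady_state_as_profile(iww, fate, self.PARAMS)
        enrich = prof / iww  # a_AS per unit of influent abundance
        assert enrich["s20"] < enrich["s10"] < enrich["s0"]
        assert (mu[fate == "disappearing"] < -self.PARAMS.epsilon).all()

    def test_profile_sums_to_one_with_realized_rates_in_class(self):
        # class masses 0.24/0.31/0.45 make the simplex close exactly, so the
        # offset is zero and every species realizes its target rate
        masses = [0.024] * 10 + [0.031] * 10 + [0.045] * 10
        iww = pd.Series(masses, index=[f"s{i}" for i in range(30)])
        fate = pd.Series(
            ["growing"] * 10 + ["surviving"] * 10 + ["disappearing"] * 10,
            index=iww.index,
        )
        prof, mu = steady_state_as_profile(iww, fate, self.PARAMS)
        assert prof.sum() == pytest.approx(1.0)
        assert np.allclose(mu[fate == "growing"], 0.03, atol=1e-9)
        assert np.allclose(mu[fate == "surviving"], 0.0, atol=1e-9)
        assert np.allclose(mu[fate == "disappearing"], -0.20, atol=1e-9)

    def test_infeasible_fate_set_raises(self):
        # two species that must both disappear cannot fill the sludge simplex
        iww = pd.Series({"a": 0.5, "b": 0.5})
        fate = pd.Series({"a": "disappearing", "b": "disappearing"})
        with pytest.raises(ScenarioError):
            steady_state_as_profile(iww, fate, self.PARAMS)


@pytest.fixture(scope="module")
def sludge(default_scenario, simulated):
    from sewerflow.io_formats import aggregate

    table, meta, tax, _ = simulated
    species = aggregate(table, tax, "species")
    iww_ids = list(meta.loc[meta["habitat"] == "IWW", "sample_id"])
    cols = [c for c in species.feature_ids if c.startswith("s")]
    iww = CountTable(species.counts.loc[iww_ids, cols], level="species")
    as_table, mu = simulate_as(default_scenario, iww, n_samples=24, depth=30_000)
    return iww, as_table, mu


class TestSimulateAs:
    def test_surviving_species_hold_the_balance_ratio(self, default_scenario, sludge):
        """For zero-growth species, a_IWW / a_AS = 1/(m*SRT) within noise."""
        iww, as_table, mu = sludge
        surviving = mu.index[(np.abs(mu) <= 2e-3)]
        a_i = iww.relative_abundance().mean(axis=0)[surviving]
        a_s = as_table.relative_abundance().mean(axis=0)[surviving]
        big = a_i > 1e-3  # away from the counting floor
        ratio = (a_i[big] / a_s[big]).mean()
        expected = 1 / (default_scenario.m_daily_fraction * default_scenario.srt_days)
        assert ratio == pytest.approx(expected, rel=0.1)

    def test_immigration_only_species_depleted_by_rate_factor(self, sludge):
        """Disappearing species keep a_AS = m*a_IWW/(1/SRT - mu): the sludge
        holds them only because immigration replenishes the washout."""
        iww, as_table, mu = sludge
        dis = mu.index[mu < -0.1]
        a_i = iww.relative_abundance().mean(axis=0)[dis]
        a_s = as_table.relative_abundance().mean(axis=0)[dis]
        big = a_i > 1e-3
        expected = 0.05 * a_i[big] / (1 / 20 - mu[dis][big])
        assert np.allclose(a_s[big], expected, rtol=0.15)

    def test_counts_are_integers_at_depth(self, sludge):
        _, as_table, _ = sludge
        assert (as_table.totals() == 30_000).all()
        assert np.issubdtype(as_table.counts.to_numpy().dtype, np.integer)


class TestRainfall:
    def test_zero_event_rate_all_dry(self):
        daily = simulate_rainfall(50, event_rate=0.0, seed=1)
        assert (daily["mm"] == 0).all()

    def test_seed_determinism(self):
        a = simulate_rainfall(80, seed=4)
        b = simulate_rainfall(80, seed=4)
        assert a.equals(b)

    def test_event_day_rate_matches_monte_carlo_expectation(self):
        # P(day >= 2mm) = event_rate * P(Exp(mean 6) >= 2)
        n = 4000
        daily = simulate_rainfall(n, event_rate=0.25, event_mm_mean=6.0, seed=9)
        p = 0.25 * np.exp(-2 / 6)
        observed = (daily["mm"] >= 2).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 4 * se

    def test_hourly_disaggregation_sums_to_daily(self):
        daily, hourly = simulate_rainfall(60, seed=2, hourly=True)
        by_day = hourly.groupby(hourly["datetime"].dt.normalize())["mm"].sum()
        for d, total in zip(daily["date"], daily["mm"]):
            if total > 0:
                assert by_day[d] == pytest.approx(total, abs=1e-6)


class TestWastewaterMixing:
    def test_zero_detachment_ignores_rain(self):
        sc = CommunityScenario(detachment_coefficient=0.0, seed=5)
        daily = simulate_rainfall(60, seed=5)
        _, _, weights = simulate_wastewater_mixing(sc, daily)
        assert (weights == sc.base_sewer_weight).all()

    def test_rain_after_dry_spell_beats_rain_after_rain(self, default_scenario):
        mm = [0.0] * 10 + [8.0, 8.0] + [0.0] * 5
        daily = pd.DataFrame(
            {"date": pd.date_range("2023-05-01", periods=len(mm), freq="D"), "mm": mm}
        )
        dates = [daily["date"][10], daily["date"][11]]  # 10 dry days vs 0
        _, _, weights = simulate_wastewater_mixing(
            default_scenario, daily, sample_dates=dates
        )
        assert weights.iloc[0] > weights.iloc[1]

    def test_mixture_weights_bounded(self, default_scenario):
        daily = simulate_rainfall(90, seed=8)
        _, _, weights = simulate_wastewater_mixing(default_scenario, daily)
        assert ((weights >= 0) & (weights <= 0.95)).all()

    def test_uncovered_sample_date_rejected(self, default_scenario):
        daily = simulate_rainfall(10, seed=1)
        with pytest.raises(ValueError):
            simulate_wastewater_mixing(
                default_scenario, daily, sample_dates=[pd.Timestamp("2030-01-01")]
            )


class TestDryDays:
    def test_counts_until_last_event(self):
        daily = pd.DataFrame(
            {
                "date": pd.date_range("2023-01-01", periods=6, freq="D"),
                "mm": [5.0, 0, 0, 0, 0, 0],
            }
        )
        assert dry_days_before(daily, "2023-01-04") == 2
        assert dry_days_before(daily, "2023-01-01") == 0
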