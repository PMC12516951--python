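"""Rarefaction, core tiers, detected-in-sewer and the unified merge."""

import numpy as np
import pandas as pd
import pytest

from sewerflow.core_communities import (
    classify_core_genera,
    classify_core_species,
    detect_in_sewer,
    min_reads_for_abundance,
    rarefy,
    unify_core,
)
from sewerflow.io_formats import CountTable

from conftest import make_meta


def _table(matrix, samples, features, level="species"):
    return CountTable(
        pd.DataFrame(matrix, index=samples, columns=features), level=level
    )


class TestRarefy:
    def test_row_sums_equal_depth(self, rng):
        counts = rng.integers(0, 200, size=(6, 30))
        t = _table(counts, [f"s{i}" for i in range(6)], [f"f{j}" for j in range(30)])
        out = rarefy(t, 500, seed=1)
        kept = t.totals() >= 500
        assert len(out.sample_ids) == int(kept.sum())
        assert (out.totals() == 500).all()

    def test_sample_at_exact_depth_unchanged(self):
        t = _table([[30, 70]], ["s"], ["a", "b"])
        out = rarefy(t, 100, seed=0)
        assert out.counts.loc["s"].tolist() == [30, 70]

    def test_seeded_and_reproducible(self, rng):
        counts = rng.integers(0, 100, size=(4, 20))
        t = _table(counts, list("abcd"), [f"f{j}" for j in range(20)])
        assert rarefy(t, 300, seed=9).counts.equals(rarefy(t, 300, seed=9).counts)

    def test_hypergeometric_expectation(self):
        """Mean over repeated draws approaches depth * original proportion."""
        row = np.array([500, 300, 150, 50])
        t = _table([row], ["s"], list("abcd"))
        depth = 400
        draws = np.stack(
            [rarefy(t, depth, seed=k).counts.loc["s"].to_numpy() for k in range(1000)]
        )
        expected = depth * row / row.sum()
        # hypergeometric variance, standard error of the mean of 1000 draws
        n_tot = row.sum()
        var = depth * (row / n_tot) * (1 - row / n_tot) * (n_tot - depth) / (n_tot - 1)
        se = np.sqrt(var / 1000)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9)

    def test_invalid_depth(self, tiny_table):
        with pytest.raises(ValueError):
            rarefy(tiny_table, 0, seed=1)


class TestReadCutoff:
    def test_min_reads_at_printed_median_depth(self):
        # 2 reads at a depth of 17896 is the smallest count above 0.01%
        assert min_reads_for_abundance(17896, 1e-4) == 2

    def test_scales_with_depth(self):
        assert min_reads_for_abundance(7322, 1e-4) == 1
        assert min_reads_for_abundance(100_000, 1e-4) == 11


def _habitat_meta(n, habitat="biofilm_g"):
    return make_meta([(f"s{i}", habitat) for i in range(n)])


class TestCoreSpecies:
    @pytest.mark.parametrize(
        "n_present,expected",
        [(8, "strict"), (5, "general"), (2, "loose"), (1, "none")],
    )
    def test_tier_thresholds_on_ten_samples(self, n_present, expected):
        depth = 10_000
        col = [3 if i < n_present else 0 for i in range(10)]  # 3 reads = 0.03%
        filler = [depth - c for c in col]
        t = _table(
            np.array([col, filler]).T, [f"s{i}" for i in range(10)], ["sp", "bulk"]
        )
        out = classify_core_species(t, _habitat_meta(10), habitats=["biofilm_g"])
        assert out.set_index("species_id").loc["sp", "tier"] == expected

    def test_gut_species_forced_to_none(self):
        t = _table([[100, 100]] * 10, [f"s{i}" for i in range(10)], ["gut_sp", "other"])
        out = classify_core_species(
            t, _habitat_meta(10), habitats=["biofilm_g"], gut_species={"gut_sp"}
        ).set_index("species_id")
        assert out.loc["gut_sp", "tier"] == "none"
        assert out.loc["gut_sp", "prevalence"] == 1.0
        assert out.loc["other", "tier"] == "strict"

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(30):
            n_s, n_f = int(rng.integers(3, 12)), int(rng.integers(2, 15))
            counts = rng.integers(0, 50, size=(n_s, n_f))
            counts[:, 0] += 1  # keep row sums positive
            t = _table(counts, [f"s{i}" for i in range(n_s)], [f"f{j}" for j in range(n_f)])
            out = classify_core_species(
                t, _habitat_meta(n_s), habitats=["biofilm_g"], abundance_cutoff=0.05
            ).set_index("species_id")
            rel = counts / counts.sum(axis=1, keepdims=True)
            for j in range(n_f):
                prev = np.mean(rel[:, j] >= 0.05)
                tier = (
                    "strict"
                    if prev >= 0.8
                    else "general" if prev >= 0.5 else "loose" if prev >= 0.2 else "none"
                )
                row = out.loc[f"f{j}"]
                assert row["tier"] == tier and row["prevalence"] == pytest.approx(prev)


class TestCoreGenera:
    def test_genus_thresholds(self):
        depth = 100_000
        hit = int(depth * 6e-4)  # 0.06% > 0.05%
        miss = int(depth * 4e-4)  # 0.04% < 0.05%
        rows = []
        for i in range(10):
            g1 = hit if i < 9 else 0
            rows.append([g1, miss, depth - g1 - miss])
        t = _table(rows, [f"s{i}" for i in range(10)], ["gA", "gB", "bulk"], level="genus")
        out = classify_core_genera(t, _habitat_meta(10), habitats=["biofilm_g"]).set_index(
            "genus"
        )
        assert out.loc["gA", "abundant_core"]
        assert not out.loc["gB", "abundant_core"]


class TestDetectedInSewer:
    def _setup(self, presence_counts, core_tier="none"):
        """One species present (1 read) in the given number of sewer samples."""
        n = 10
        col = [1 if i < presence_counts else 0 for i in range(n)]
        t = _table(
            np.array([col, [1000] * n]).T, [f"s{i}" for i in range(n)], ["sp", "bulk"]
        )
        meta = _habitat_meta(n, "sediment")
        core = pd.DataFrame(
            {"species_id": ["sp", "bulk"], "habitat": "sediment", "tier": [core_tier, "strict"],
             "prevalence": [0.1, 1.0], "n_samples": n}
        )
        return t, meta, core

    def test_three_samples_is_detected(self):
        t, meta, core = self._setup(3)
        assert "sp" in detect_in_sewer(t, meta, core)

    def test_two_samples_is_not(self):
        t, meta, core = self._setup(2)
        assert "sp" not in detect_in_sewer(t, meta, core)

    def test_core_species_never_relabeled(self):
        t, meta, core = self._setup(5, core_tier="loose")
        assert "sp" not in detect_in_sewer(t, meta, core)

    def test_gut_excluded(self):
        t, meta, core = self._setup(5)
        assert "sp" not in detect_in_sewer(t, meta, core, gut_species={"sp"})


class TestUnifyCore:
    def _core(self, tiers_by_habitat):
        rows = [
            ("sp", hab, tier, 0.5, 10) for hab, tier in tiers_by_habitat.items()
        ]
        return pd.DataFrame(
            rows, columns=["species_id", "habitat", "tier", "prevalence", "n_samples"]
        )

    def test_strict_beats_loose(self):
        core = self._core({"biofilm_g": "strict", "sediment": "loose", "biofilm_ep": "none"})
        out = unify_core(core)
        assert out.loc[0, "unified_tier"] == "strict"

    def test_loose_everywhere_stays_loose(self):
        core = self._core({"biofilm_g": "loose", "sediment": "loose", "biofilm_ep": "loose"})
        assert unify_core(core).loc[0, "unified_tier"] == "loose"

    def test_detected_only_without_core_tier(self):
        core = self._core({"biofilm_g": "none", "sediment": "none", "biofilm_ep": "none"})
        assert unify_core(core, {"sp"}).loc[0, "unified_tier"] == "detected"
        assert unify_core(core).loc[0, "unified_tier"] == "none"


class TestPlantedCoreRecovery:
    def test_recovered_tiers_match_planted_away_from_boundaries(
        self, simulated, default_scenario
    ):
        """Core tiers on rarefied synthetic data equal planted structure except
        for species whose realized prevalence landed near a tier threshold."""
        from sewerflow.io_formats import aggregate

        table, meta, tax, truth = simulated
        rarefied = rarefy(table, 14_000, seed=5)
        species = aggregate(rarefied, tax, "species")
        out = classify_core_species(
            species, meta, gut_species=set(truth["gut_species"])
        ).set_index(["species_id", "habitat"])
        margin = 0.16
        thresholds = (0.80, 0.50, 0.20)
        checked = mismatches = 0
        for hab, cores in truth["cores"].items():
            planted = {}
            for tier, members in cores.items():
                for sp in members:
                    planted[sp] = tier
            for sp in default_scenario.species_ids:
                row = out.loc[(sp, hab)]
                if any(abs(row["prevalence"] - t) <= margin for t in thresholds):
                    continue
                checked += 1
                if row["tier"] != planted.get(sp, "none"):
                    mismatches += 1
        assert checked > 300
        assert mismatches == 0
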