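import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from osteomorph.stats_mapping import (fit_two_way, p_band,
                                      permutation_interaction_p,
                                      positional_analysis, posthoc,
                                      render_heatmap, significance_heatmap)
from osteomorph.synthetic_data import CohortSpec, simulate_cohort


def _balanced_table(seed=0, n=4, effects=None):
    spec = CohortSpec(n_per_group=n, seed=seed, **(effects or {}))
    return simulate_cohort(spec)


class TestFitTwoWay:
    def test_balanced_f_matches_classical_decomposition(self):
        """Balanced design: Type-II F equals the textbook two-way ANOVA
        computed directly from cell means (independent oracle)."""
        t = _balanced_table(seed=21, n=5)
        y = t["value"].to_numpy()
        g = (t["genotype"] == "KO").to_numpy()
        ages = sorted(t["age"].unique())
        n, a = 5, len(ages)
        grand = y.mean()
        ss_g = sum((y[g == lvl].mean() - grand) ** 2 * (y[g == lvl].size)
                   for lvl in (False, True))
        ss_a = sum((y[t["age"] == age].mean() - grand) ** 2
                   * (t["age"] == age).sum() for age in ages)
        cell_means = {(lvl, age): y[(g == lvl) & (t["age"] == age)].mean()
                      for lvl in (False, True) for age in ages}
        ss_cells = sum(n * (cell_means[k] - grand) ** 2 for k in cell_means)
        ss_i = ss_cells - ss_g - ss_a
        ss_e = 0.0
        for (lvl, age), mean in cell_means.items():
            ss_e += ((y[(g == lvl) & (t["age"] == age)] - mean) ** 2).sum()
        ms_e = ss_e / (2 * a * (n - 1))
        r = fit_two_way(t, "value")
        assert r.f_genotype == pytest.approx(ss_g / 1 / ms_e, rel=1e-8)
        assert r.f_age == pytest.approx(ss_a / (a - 1) / ms_e, rel=1e-8)
        assert r.f_interaction == pytest.approx(ss_i / (a - 1) / ms_e,
                                                rel=1e-8)

    def test_empty_cell_error_names_cell(self):
        t = _balanced_table()
        t = t[~((t.genotype == "KO") & (t.age == 16))]
        with pytest.raises(ValueError, match="KO.*16"):
            fit_two_way(t, "value")

    def test_shapiro_detects_exponential_residuals(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(20):
            t = _balanced_table(seed=int(rng.integers(2**31)), n=6)
            t["value"] = rng.exponential(size=len(t))
            hits += fit_two_way(t, "value").shapiro_p < 0.05
        assert hits > 10  # majority of replicates flag non-normality

    def test_agrees_with_permutation_oracle(self):
        t = _balanced_table(seed=11, n=3)  # n = 24 observations
        r = fit_two_way(t, "value")
        p_perm = permutation_interaction_p(t, "value", n_permutations=20_000,
                                           seed=2)
        assert r.p_interaction == pytest.approx(p_perm, abs=0.02)


class TestPosthoc:
    def test_bonferroni_multiplies_and_caps(self):
        t = _balanced_table(seed=3)
        res = posthoc(t, "value", adjust="bonferroni")
        assert len(res) == 4
        for r in res:
            assert r["p_adjusted"] == pytest.approx(
                min(1.0, r["p_raw"] * 4))
            assert r["p_adjusted"] >= r["p_raw"]

    def test_none_is_identity(self):
        t = _balanced_table(seed=3)
        for r in posthoc(t, "value", adjust="none"):
            assert r["p_adjusted"] == r["p_raw"]

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_bonferroni_monotone(self, p1, p2):
        lo, hi = sorted([p1, p2])
        assert min(1.0, lo * 4) <= min(1.0, hi * 4)


class TestBanding:
    @pytest.mark.parametrize("p,band", [
        (0.0005, "red"), (0.001, "red"),
        (0.0011, "yellow"), (0.01, "yellow"),
        (0.03, "green"), (0.05, "green"),
        (0.0501, "blue"), (0.9, "blue"),
    ])
    def test_cutpoints(self, p, band):
        assert p_band(p) == band

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_total_and_deterministic(self, p):
        assert p_band(p) in {"red", "yellow", "green", "blue"}
        assert p_band(p) == p_band(p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            p_band(1.5)


class TestPositionalAnalysis:
    def _profiles(self, stations, effect_stations=(), effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for s in stations:
            eff = effect if s in effect_stations else 0.0
            t = simulate_cohort(CohortSpec(
                genotype_effect=eff, n_per_group=6,
                seed=int(rng.integers(2**31))), response="CSA")
            t["position"] = s
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def test_single_station_reduces_to_fit_two_way(self):
        prof = self._profiles([37.0], seed=5)
        results, medians = positional_analysis(prof, ["CSA"])
        direct = fit_two_way(prof, "CSA")
        row = results["CSA"].iloc[0]
        assert row["p_genotype"] == direct.p_genotype
        assert row["p_interaction"] == direct.p_interaction
        assert medians["CSA"] == direct.shapiro_p

    def test_localised_genotype_effect_detected(self):
        stations = list(range(10, 91, 5))
        hot = [s for s in stations if s >= 60]
        prof = self._profiles(stations, effect_stations=hot, effect=3.0,
                              seed=6)
        results, _ = positional_analysis(prof, ["CSA"])
        tab = results["CSA"].set_index("position")
        hot_sig = (tab.loc[hot, "p_genotype"] < 0.05).mean()
        cold = [s for s in stations if s < 60]
        cold_sig = (tab.loc[cold, "p_genotype"] < 0.05).mean()
        assert hot_sig >= 0.9
        assert cold_sig <= 0.2

    def test_heatmap_bands_and_figure(self, tmp_path):
        prof = self._profiles([10.0, 50.0, 90.0], seed=7)
        results, _ = positional_analysis(prof, ["CSA"])
        bands = significance_heatmap(results)
        assert set(bands["effect"]) == {"G", "GxA"}
        assert len(bands) == 6
        for _, row in bands.iterrows():
            assert row["band"] == p_band(row["p"])
        out = tmp_path / "map.svg"
        render_heatmap(bands, str(out))
        assert out.exists() and out.stat().st_size > 0
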