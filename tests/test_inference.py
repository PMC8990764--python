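"""Split-plot strata, entry models, response-ratio models, Holm adjustment
and the Poisson lodging GLM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mixtrial import inference, simulate
from mixtrial.indices import build_index_table, plot_frame
from mixtrial.inference import (
    RobustnessVerdict,
    fit_entry_model,
    fit_lodging_glm,
    fit_rme_model,
    fit_splitplot,
    holm_adjust,
    splitplot_system_contrast,
)
from mixtrial.model import (
    MIXTURE, MONO_PEA, MONO_WHEAT, DesignError, DomainError,
)
from _factories import small_design, yield_config

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def _holm_reference(pvals):
    """Independent hand step-down: sort ascending, multiply by (m - j + 1),
    running max, cap at 1, restore order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [None] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[i]))
        out[i] = running
    return out


class TestHolm:
    def test_hand_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_three_element_inputs_on_grid(self):
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 3)
        for a in grid:
            for b in grid:
                for c in grid:
                    p = [a, b, c]
                    np.testing.assert_allclose(
                        holm_adjust(p), _holm_reference(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_dominance_cap_and_reference(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p))
        assert np.all(adj <= 1.0)
        np.testing.assert_allclose(adj, _holm_reference(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = [p[i] for i in perm]
        adj_direct = holm_adjust(p)
        adj_perm = holm_adjust(shuffled)
        np.testing.assert_allclose([adj_perm[perm.index(i)]
                                    for i in range(len(p))],
                                   adj_direct, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 15))
            np.testing.assert_allclose(
                holm_adjust(p), multipletests(p, method="holm")[1],
                atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            holm_adjust([0.5, 1.2])


class TestSplitPlot:
    def test_zero_noise_marginal_means_equal_cell_means(self, zero_records,
                                                        zero_config):
        effects, mm, comp = fit_splitplot(zero_records, "wheat_yield",
                                          season="2018/19")
        spec = zero_config.responses["wheat_yield"]
        for _, row in mm.cells.iterrows():
            truth = spec.cell_mean("2018/19", row.system, row.entry)
            assert row.estimate == pytest.approx(truth, abs=1e-8)
            assert row.se == pytest.approx(0.0, abs=1e-8)

    def test_zero_noise_no_interaction_f_is_zero(self):
        design = small_design(n_entries=5, n_blocks=4)
        cfg = yield_config(design, sd_block=0.0, sd_mainplot=0.0,
                           sd_residual=0.0)
        recs = simulate.generate_trial(cfg)
        effects, mm, comp = fit_splitplot(recs, "wheat_yield")
        f_int = effects.set_index("term").loc["system:entry", "F"]
        assert f_int == pytest.approx(0.0, abs=1e-8)
        assert comp["boundary"]

    def test_marginal_means_equal_cell_means_balanced(self, noisy_records):
        frame = plot_frame(noisy_records, "protein", season="2018/19")
        _, mm, _ = fit_splitplot(frame, "protein", season="2018/19")
        raw = frame.groupby(["system", "entry"])["value"].mean()
        for _, row in mm.cells.iterrows():
            assert row.estimate == pytest.approx(
                raw[(row.system, row.entry)], abs=1e-10)

    def test_configured_system_effect_recovered(self, noisy_records):
        """Protein mono-minus-mixture contrast recovers the configured
        -1.5 shift within 3 SE."""
        res = splitplot_system_contrast(noisy_records, "protein",
                                        season="2018/19")
        assert abs(res["estimate"] - (-1.5)) <= 3.0 * res["se"]

    def test_effect_table_degrees_of_freedom(self, noisy_records):
        effects, _, _ = fit_splitplot(noisy_records, "wheat_yield",
                                      season="2018/19")
        table = effects.set_index("term")
        assert table.loc["system", ["df_num", "df_den"]].tolist() == [1, 3]
        assert table.loc["entry", ["df_num", "df_den"]].tolist() == [14, 84]
        assert table.loc["system:entry", "df_den"] == 84

    def test_mixed_seasons_demand_per_season_call(self, noisy_records):
        with pytest.raises(DesignError, match="season"):
            fit_splitplot(noisy_records, "wheat_yield")

    def test_degenerate_mainplot_variance(self):
        """sd_mainplot = 0: the fit never fails, the component is truncated
        to exactly zero in a substantial share of replicates (boundary flag
        set), and stays small relative to the residual on average."""
        design = small_design(n_entries=8, n_blocks=4)
        ratios, boundaries = [], 0
        for rep in range(30):
            cfg = yield_config(design, sd_mainplot=0.0, seed=20_000 + rep)
            recs = simulate.generate_trial(cfg)
            _, _, comp = fit_splitplot(recs, "wheat_yield")
            ratios.append(comp["sigma2_mainplot"]
                          / max(comp["sigma2_residual"], 1e-12))
            boundaries += comp["boundary"]
            if comp["boundary"]:
                assert comp["sigma2_mainplot"] == 0.0
        assert boundaries >= 10  # truncation hits the zero boundary often
        assert np.mean(ratios) <= 0.15

    def test_cross_check_against_reml_mixed_model(self):
        """Independent oracle: statsmodels MixedLM (REML) agrees with the
        stratum-based analysis on balanced data with an interior main-plot
        variance component."""
        import statsmodels.formula.api as smf

        design = small_design(n_entries=8, n_blocks=4)
        cfg = yield_config(design, sd_mainplot=0.5, seed=31)
        recs = simulate.generate_trial(cfg)
        frame = plot_frame(recs, "wheat_yield")
        _, mm, comp = fit_splitplot(frame, "wheat_yield")
        assert not comp["boundary"]
        fit = smf.mixedlm("value ~ C(system) * C(entry) + C(block)",
                          data=frame, groups=frame["mainplot"]
                          ).fit(reml=True)
        assert comp["sigma2_residual"] == pytest.approx(fit.scale, rel=1e-2)
        assert comp["sigma2_mainplot"] == pytest.approx(
            float(np.asarray(fit.cov_re)[0, 0]), rel=0.05)
        # cell means: REML GLS on balanced data equals raw cell means
        cell_mix = float(
            fit.predict(pd.DataFrame({
                "system": [MIXTURE] * 4, "entry": ["E00"] * 4,
                "block": [1, 2, 3, 4]})).mean())
        ours = mm.cells.set_index(["system", "entry"]).loc[
            (MIXTURE, "E00"), "estimate"]
        assert ours == pytest.approx(cell_mix, abs=1e-8)

    def test_holm_applied_to_contrast_family(self, noisy_records):
        _, mm, _ = fit_splitplot(noisy_records, "protein", season="2018/19")
        assert len(mm.contrasts) == 15  # mono-vs-mix within each entry
        np.testing.assert_allclose(
            mm.contrasts.p_holm,
            holm_adjust(mm.contrasts.p_raw.to_numpy()))
        assert (mm.contrasts.p_holm >= mm.contrasts.p_raw - 1e-12).all()


class TestEntryModel:
    def test_identical_blocks_give_zero_width_ci(self):
        rows = []
        for entry, v in (("A", 0.5), ("B", 0.0), ("C", 1.5)):
            for block in range(1, 5):
                rows.append({"season": "s1", "block": block, "entry": entry,
                             "yg_abs": v})
        table = pd.DataFrame(rows)
        _, mm, verdicts = fit_entry_model(table, "yg_abs")
        by_entry = {v.entry: v for v in verdicts}
        assert mm.cells.se.max() == pytest.approx(0.0, abs=1e-12)
        assert by_entry["A"].robust and by_entry["C"].robust
        assert not by_entry["B"].robust  # estimate equals the null exactly

    def test_largest_configured_yg_entries_are_robust(self, noisy_index_table):
        _, _, verdicts = fit_entry_model(noisy_index_table, "yg_abs",
                                         season="2018/19")
        robust = {v.entry for v in verdicts if v.robust}
        assert {"Kolompos", "Nemere", "Elit CCP"} <= robust

    def test_entry_f_degrees_match_design(self, noisy_index_table):
        effects, _, _ = fit_entry_model(noisy_index_table, "yg_abs",
                                        season="2018/19")
        assert effects.loc[0, ["df_num", "df_den"]].tolist() == [14, 42]

    def test_ler_null_value_is_one(self, noisy_index_table):
        _, _, verdicts = fit_entry_model(noisy_index_table, "ler",
                                         season="2018/19")
        assert all(v.null_value == 1.0 for v in verdicts)

    def test_verdict_is_pure_function_of_ci(self):
        v = RobustnessVerdict.from_ci("YG", "A", 0.5, 0.1, 0.9, 0.0)
        assert v.robust
        v = RobustnessVerdict.from_ci("LER", "A", 1.05, 0.95, 1.15, 1.0)
        assert not v.robust
        v = RobustnessVerdict.from_ci("RME", None, -3.0, -5.0, -1.0, 0.0)
        assert v.robust

    def test_null_config_type_one_error_rate(self):
        """With no mixture effect the per-entry robustness rate sits near the
        CI complement (5%) over 300 simulated trials."""
        entries = 5
        design = small_design(n_entries=entries, n_blocks=4)
        season = design.seasons[0]
        hits = total = 0
        for rep in range(300):
            cfg = simulate.SimulationConfig(
                design=design,
                responses={
                    "wheat_yield": simulate.ResponseSpec(
                        means={(season, MONO_WHEAT): 4.0,
                               (season, MIXTURE): 2.8},  # exactly 0.7 * mono
                        sd_block=0.1, sd_mainplot=0.05, sd_residual=0.25),
                    "pea_yield": simulate.ResponseSpec(
                        means={(season, MONO_PEA): 2.0,
                               (season, MIXTURE): 1.0},  # exactly 0.5 * mono
                        sd_block=0.05, sd_mainplot=0.03, sd_residual=0.12),
                },
                rng_seed=40_000 + rep)
            recs = simulate.generate_trial(cfg)
            table = build_index_table(recs, design)
            _, _, verdicts = fit_entry_model(table, "yg_abs")
            hits += sum(v.robust for v in verdicts)
            total += len(verdicts)
        rate = hits / total
        assert 0.02 <= rate <= 0.08


class TestRmeModel:
    def _long(self, values_by_response, blocks=4):
        rows = []
        for resp, values in values_by_response.items():
            for i, v in enumerate(values):
                rows.append({"season": "s1", "block": i % blocks + 1,
                             "entry": f"E{i // blocks}", "response": resp,
                             "baseline": "wheat_mono", "rme": v})
        return pd.DataFrame(rows)

    def test_all_zero_rmes_mean_zero_no_effect(self):
        out = fit_rme_model(self._long({"protein": [0.0] * 8}))
        row = out.iloc[0]
        assert row.estimate == 0.0
        assert not row.effect_present

    def test_homoscedastic_matches_block_mean_t_analysis(self):
        rng = np.random.default_rng(5)
        values = rng.normal(10.0, 3.0, size=16)
        out = fit_rme_model(self._long({"protein": list(values)}))
        row = out.iloc[0]
        block_means = values.reshape(4, 4).T.mean(axis=1)  # block = i % 4
        se = block_means.std(ddof=1) / np.sqrt(4)
        lo, hi = stats.t.interval(0.95, 3, loc=block_means.mean(), scale=se)
        assert row.estimate == pytest.approx(values.mean(), abs=1e-10)
        assert row.lower == pytest.approx(lo, abs=1e-8)
        assert row.upper == pytest.approx(hi, abs=1e-8)

    def test_per_response_weights_match_closed_form(self):
        """Two responses with a 4x residual variance ratio keep their own
        SEs: each equals the closed-form weighted-mean SE of its stratum."""
        rng = np.random.default_rng(11)
        a = rng.normal(5.0, 1.0, size=40)
        b = rng.normal(5.0, 2.0, size=40)
        out = fit_rme_model(self._long({"ra": list(a), "rb": list(b)}))
        out = out.set_index("response")
        for name, values in (("ra", a), ("rb", b)):
            bm = np.array([values[np.arange(40) % 4 == k].mean()
                           for k in range(4)])
            closed = bm.std(ddof=1) / np.sqrt(4)
            assert out.loc[name, "se"] == pytest.approx(closed, rel=0.05)


class TestLodgingGlm:
    def test_reference_rate_ratio_recovered(self, noisy_records):
        out = fit_lodging_glm(noisy_records, season="2018/19")
        row = out.set_index("term").loc["system:monoculture_pea"]
        assert abs(row.log_estimate - np.log(25.0)) <= 3.0 * row.se

    def test_equal_intensities_ci_covers_one(self):
        rng = np.random.default_rng(9)
        covered = 0
        n_sims = 300
        for _ in range(n_sims):
            frame = pd.DataFrame({
                "season": "s1",
                "block": list(range(20)) * 2,
                "system": [MONO_PEA] * 20 + [MIXTURE] * 20,
                "entry": "E",
                "value": rng.poisson(5.0, size=40),
            })
            out = fit_lodging_glm(frame).set_index("term")
            lo = out.loc["system:monoculture_pea", "lower"]
            hi = out.loc["system:monoculture_pea", "upper"]
            covered += lo <= 1.0 <= hi
        assert covered / n_sims >= 0.90

    def test_all_zero_lodging_degenerate_warning(self):
        frame = pd.DataFrame({
            "season": "s1", "block": [1, 2, 3, 4] * 2,
            "system": [MONO_PEA] * 4 + [MIXTURE] * 4,
            "entry": "E", "value": 0.0,
        })
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = fit_lodging_glm(frame)
        assert out.iloc[0]["degenerate"]

    def test_negative_lodging_rejected(self):
        frame = pd.DataFrame({"season": "s1", "block": [1], "system": [MIXTURE],
                              "entry": ["E"], "value": [-1.0]})
        with pytest.raises(DomainError):
            fit_lodging_glm(frame)


class TestCoverage:
    def test_system_effect_ci_coverage(self):
        """Whole-plot CIs for the configured system effect cover the truth at
        the nominal 95% rate (within [92%, 98%]) over 300 replicates."""
        design = small_design(n_entries=5, n_blocks=4)
        covered = 0
        n_sims = 300
        for rep in range(n_sims):
            cfg = yield_config(design, seed=60_000 + rep)
            recs = simulate.generate_trial(cfg)
            res = splitplot_system_contrast(recs, "wheat_yield")
            covered += res["lower"] <= 1.0 <= res["upper"]
        assert 0.92 <= covered / n_sims <= 0.98

    def test_entry_contrast_ci_coverage(self):
        """Subplot-stratum CIs for an entry difference also hold their level."""
        design = small_design(n_entries=5, n_blocks=4)
        truth = 0.05 * 1 - 0.05 * 0  # configured E01 - E00 shift
        covered = 0
        n_sims = 300
        for rep in range(n_sims):
            cfg = yield_config(design, seed=80_000 + rep)
            recs = simulate.generate_trial(cfg)
            _, mm, _ = fit_splitplot(recs, "wheat_yield",
                                     contrast_family="entry_within_system")
            row = mm.contrasts[mm.contrasts.contrast ==
                               f"{MONO_WHEAT}:E00 - {MONO_WHEAT}:E01"]
            est, se, df = row.iloc[0][["estimate", "se", "df"]]
            q = stats.t.ppf(0.975, df)
            covered += est - q * se <= -truth <= est + q * se
        assert 0.92 <= covered / n_sims <= 0.98
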