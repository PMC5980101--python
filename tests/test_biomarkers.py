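import numpy as np
import pandas as pd
import pytest

from pheegmark.biomarkers import (
    PRESETS,
    CompositeBiomarker,
    WeightReportEntry,
    biomarker_significance,
    consolidate,
    evaluate_biomarker,
    select_candidate_bands,
    strain_objective,
    weight_report,
)
from pheegmark.spectral import LOW_BANDS


def make_table(rng, n_samples=12, days=("D1",), strains=("SHR", "WKY")):
    """Random positive feature table over the five low bands."""
    rows = []
    for strain in strains:
        for i in range(n_samples):
            for day in days:
                for band in LOW_BANDS:
                    rows.append(
                        {
                            "strain": strain,
                            "animal": f"A{i}",
                            "channel": "LF",
                            "day": day,
                            "band": band,
                            "slope": rng.standard_normal(),
                            "intercept": 1.0 + rng.random(),
                            "mPower": 0.5 + rng.random(),
                        }
                    )
    return pd.DataFrame(rows)


def unit_table(days=("D1",), strains=("SHR",)):
    t = make_table(np.random.default_rng(0), n_samples=3, days=days, strains=strains)
    t["mPower"] = 1.0
    t["slope"] = 0.0
    return t


class TestCompositeBiomarker:
    def test_all_presets_evaluate_to_one_on_unit_input(self):
        table = unit_table()
        for name, bm in PRESETS.items():
            vals = evaluate_biomarker(bm, table, "D1")
            assert np.allclose(vals["value"], 1.0), name

    def test_lambda_zero_recovers_pure_ratio(self, rng):
        table = make_table(rng)
        bm = PRESETS["SHR"]
        pure = CompositeBiomarker(
            name="SHR0", num_bands=bm.num_bands, den_bands=bm.den_bands,
            slope_terms=bm.slope_terms, lam=0.0,
        )
        v0 = evaluate_biomarker(pure, table, "D1")["value"].to_numpy()
        wide = table[table["day"] == "D1"].pivot_table(
            index=["strain", "animal", "channel"], columns="band", values="mPower"
        )
        oracle = wide["Alpha"] / (wide["Delta"] * wide["Beta"])
        assert np.allclose(v0, oracle.to_numpy(), rtol=1e-12)

    def test_full_expression_matches_arithmetic_oracle(self, rng):
        table = make_table(rng)
        bm = PRESETS["WIS"]  # theta*beta/(m*alpha) + 0.1*(delta+theta-m)
        vals = evaluate_biomarker(bm, table, "D1")["value"].to_numpy()
        wide = table[table["day"] == "D1"].pivot_table(
            index=["strain", "animal", "channel"], columns="band",
            values=["mPower", "slope"],
        )
        mp, sl = wide["mPower"], wide["slope"]
        oracle = (mp["Theta"] * mp["Beta"]) / (mp["lDelta"] * mp["Alpha"]) + 0.1 * (
            sl["Delta"] + sl["Theta"] - sl["lDelta"]
        )
        assert np.allclose(vals, oracle.to_numpy(), rtol=1e-12)

    def test_scale_covariance_of_ratio_term(self, rng):
        table = make_table(rng)
        bm = PRESETS["MPH_SHR"]  # 1 numerator band, 2 denominator bands
        pure = CompositeBiomarker("p", bm.num_bands, bm.den_bands, (), 0.0)
        v1 = evaluate_biomarker(pure, table, "D1")["value"].to_numpy()
        scaled = table.copy()
        scaled["mPower"] *= 4.0
        v2 = evaluate_biomarker(pure, scaled, "D1")["value"].to_numpy()
        assert np.allclose(v2, v1 * 4.0 ** (1 - 2), rtol=1e-12)

    def test_round_trip_serialization(self):
        for bm in PRESETS.values():
            assert CompositeBiomarker.from_dict(bm.to_dict()) == bm

    def test_expressions_render(self):
        assert PRESETS["SHR"].expression() == (
            "alpha^(p)/(delta^(p)*beta^(p)) + 0.01*(delta^(s)-m^(s)-theta^(s))"
        )

    def test_nonpositive_denominator_rejected(self, rng):
        table = make_table(rng)
        table.loc[table["band"] == "Delta", "mPower"] = 0.0
        with pytest.raises(ValueError, match="Delta"):
            evaluate_biomarker(PRESETS["SHR"], table, "D1")


class TestSelectCandidateBands:
    @staticmethod
    def frames(sig_bands, good_bands, all_bands=("Total",) + LOW_BANDS + ("Gamma",)):
        anova_rows = []
        for band in all_bands:
            for param in ("slope", "intercept", "mPower"):
                p = 0.001 if band in sig_bands else 0.5
                anova_rows.append({"band": band, "parameter": param, "p_strain": p})
        grid_rows = []
        for band in all_bands:
            for obj in ("SHR vs WKY", "SHR vs WIS", "WKY vs WIS"):
                rate = 92.0 if band in good_bands else 55.0
                grid_rows.append({"band": band, "day": "ALL", "objective": obj,
                                  "mean_rate": rate})
        return pd.DataFrame(anova_rows), pd.DataFrame(grid_rows)

    def test_planted_low_bands_selected_exactly(self):
        anova, grid = self.frames(set(LOW_BANDS) | {"Total"}, set(LOW_BANDS) | {"Total"})
        assert select_candidate_bands(anova, grid) == list(LOW_BANDS)

    def test_null_inputs_select_nothing(self):
        anova, grid = self.frames(set(), set())
        with pytest.warns(UserWarning):
            assert select_candidate_bands(anova, grid) == []

    def test_single_planted_band(self):
        anova, grid = self.frames({"Theta"}, {"Theta"})
        assert select_candidate_bands(anova, grid) == ["Theta"]

    def test_both_rules_must_pass(self):
        anova, grid = self.frames({"Theta", "Alpha"}, {"Theta", "Beta"})
        assert select_candidate_bands(anova, grid) == ["Theta"]


class TestWeightReport:
    def test_informative_feature_dominates(self, rng):
        table = make_table(rng, n_samples=15)
        # plant a strong mPower difference in Alpha only
        sel = (table["strain"] == "SHR") & (table["band"] == "Alpha")
        table.loc[sel, "mPower"] += 3.0
        obj = strain_objective("SHR", ("WKY",))
        rep = weight_report(table, obj, feature_set=("mPower",), n_repeats=40, seed=2)
        w = rep.weights_mean.xs("mPower", level="parameter").abs()
        assert w.idxmax() == "Alpha"
        assert rep.weight("Alpha", "mPower") > 0  # larger in the target class
        assert rep.cv_rate > 90.0

    def test_all_noise_weights_average_to_zero_across_datasets(self):
        # exchangeable null: over independent datasets no band is
        # systematically weighted (a single dataset's bootstrap mean is a
        # stable estimate of that dataset's noise direction, so the null
        # must be checked across datasets)
        obj = strain_objective("SHR", ("WKY",))
        means = []
        for seed in range(25):
            rng = np.random.default_rng(5000 + seed)
            table = make_table(rng, n_samples=12)
            rep = weight_report(table, obj, feature_set=("mPower",), n_repeats=5, seed=seed)
            means.append(rep.weights_mean.to_numpy())
        means = np.asarray(means)
        sem = means.std(axis=0, ddof=1) / np.sqrt(means.shape[0])
        assert np.all(np.abs(means.mean(axis=0)) < 3 * sem + 0.05)

    def test_duplicated_features_split_with_matching_signs(self, rng):
        table = make_table(rng, n_samples=15)
        sel = table["band"].isin(["Theta", "Alpha"]) & (table["strain"] == "SHR")
        table.loc[sel, "mPower"] += 2.0
        table.loc[table["band"] == "Alpha", "mPower"] = (
            table.loc[table["band"] == "Theta", "mPower"].to_numpy()
        )
        obj = strain_objective("SHR", ("WKY",))
        rep = weight_report(
            table, obj, feature_set=("mPower",), n_repeats=30, seed=4, ridge=1e-6
        )
        wt = rep.weight("Theta", "mPower")
        wa = rep.weight("Alpha", "mPower")
        assert np.sign(wt) == np.sign(wa)
        assert abs(wt - wa) < 0.25 * max(abs(wt), abs(wa), 1e-9) + 0.05


class TestConsolidate:
    @staticmethod
    def report(mpower: dict, slope: dict | None = None) -> WeightReportEntry:
        idx, vals = [], []
        for b in LOW_BANDS:
            idx.append((b, "mPower"))
            vals.append(mpower.get(b, 0.0))
            if slope is not None:
                idx.append((b, "slope"))
                vals.append(slope.get(b, 0.0))
        mi = pd.MultiIndex.from_tuples(idx, names=["band", "parameter"])
        s = pd.Series(vals, index=mi)
        return WeightReportEntry(
            objective="SHR vs rest (D1)", feature_set=("slope", "mPower"),
            bands=LOW_BANDS, weights_mean=s, weights_sem=s * 0 + 0.01,
        )

    def test_reproduces_published_shr_ratio_and_slope_forms(self):
        rep = self.report(
            mpower={"Alpha": 0.4, "Delta": -0.3, "Beta": -0.2, "lDelta": 0.05, "Theta": -0.01},
            slope={"Delta": 0.4, "lDelta": -0.3, "Theta": -0.2, "Alpha": 0.05, "Beta": 0.01},
        )
        proposals = consolidate(rep, top_k=3)
        bm = proposals[0]
        assert bm.num_bands == ("Alpha",)
        assert set(bm.den_bands) == {"Delta", "Beta"}
        assert dict(bm.slope_terms) == {"Delta": 1, "lDelta": -1, "Theta": -1}
        assert {p.lam for p in proposals} == {0.1, 0.01}

    def test_equal_magnitudes_break_ties_by_band_order(self):
        rep = self.report(mpower={b: 0.2 for b in LOW_BANDS})
        (bm, _) = consolidate(rep, top_k=3)
        assert bm.num_bands == ("lDelta", "Delta", "Theta")

    def test_top_k_clamped_with_warning(self):
        rep = self.report(mpower={"Alpha": 0.4, "Delta": -0.3})
        with pytest.warns(UserWarning, match="clamp"):
            consolidate(rep, top_k=99)

    def test_held_out_ranking_runs(self, rng):
        table = make_table(rng, n_samples=20, strains=("SHR", "WKY", "WIS"))
        sel = (table["strain"] == "SHR") & (table["band"] == "Alpha")
        table.loc[sel, "mPower"] += 2.0
        rep = self.report(mpower={"Alpha": 0.5, "Delta": -0.2, "Beta": -0.1},
                          slope={"Delta": 0.3, "lDelta": -0.2})
        obj = strain_objective("SHR", ("WKY", "WIS"))
        ranked = consolidate(rep, top_k=3, feature_table=table, objective=obj, seed=5)
        assert len(ranked) == 2


class TestBiomarkerSignificance:
    def test_identical_groups_half(self, rng):
        g = rng.standard_normal(20)
        out = biomarker_significance({"SHR": g, "WKY": g.copy()})
        assert out["p_one_tailed"].iloc[0] == pytest.approx(0.5)
        assert out["level"].iloc[0] is None

    def test_constant_groups_p_one(self):
        out = biomarker_significance({"SHR": np.ones(5), "WKY": np.ones(5)})
        assert out["p_one_tailed"].iloc[0] == 1.0

    def test_planted_elevation_reaches_0005(self):
        hits = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(900 + seed)
            shr = rng.standard_normal(50) + 2.0  # 2 sd planted elevation
            wky = rng.standard_normal(50)
            wis = rng.standard_normal(50)
            out = biomarker_significance({"SHR": shr, "WKY": wky, "WIS": wis})
            hits += int((out["p_one_tailed"] <= 0.005).all())
        assert hits / reps >= 0.9
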