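import numpy as np
import pandas as pd
import pytest

from deqsyn import (
    BlissMatrixDesign,
    DrugParams,
    SimulationConfig,
    bliss_viability,
    build_ladder,
    fit_4pl,
    loewe_viability,
    make_deq_design,
    normalize_viability,
    simulate_combination,
    simulate_single_agent,
)
from deqsyn.synthetic_data import expected_viability

from conftest import DRUG_A, DRUG_B, noiseless_config


class TestSingleAgent:
    def test_noiseless_data_lie_on_true_curve(self):
        drug = DrugParams("x", log_ec50=-8.0, hill=1.5)
        cfg = noiseless_config({"x": drug}, seed=0)
        t = normalize_viability(simulate_single_agent(cfg, build_ladder(-8.0, drug="x")))
        rows = t.df[t.df["ratio_label"] == "alone"]
        fit = fit_4pl(rows["log_dose_a"], rows["viability"])
        assert fit.log_ec50 == pytest.approx(-8.0, abs=1e-8)
        assert fit.hill == pytest.approx(1.5, rel=1e-8)

    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(drugs={"x": DrugParams("x", log_ec50=-8.0)}, seed=42)
        lad = build_ladder(-8.0, drug="x")
        t1 = simulate_single_agent(cfg, lad)
        t2 = simulate_single_agent(cfg, lad)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_different_seeds_differ(self):
        lad = build_ladder(-8.0, drug="x")
        t1 = simulate_single_agent(
            SimulationConfig(drugs={"x": DrugParams("x", log_ec50=-8.0)}, seed=1), lad
        )
        t2 = simulate_single_agent(
            SimulationConfig(drugs={"x": DrugParams("x", log_ec50=-8.0)}, seed=2), lad
        )
        assert not t1.df["luminescence"].equals(t2.df["luminescence"])

    def test_noise_cv_calibrated(self):
        # one fixed well across 500 seeds: empirical CV within 10% of nominal
        lad = build_ladder(-8.0, drug="x")
        drug = {"x": DrugParams("x", log_ec50=-8.0)}
        vals = []
        for s in range(500):
            cfg = SimulationConfig(
                drugs=drug, noise_cv=0.1, experiment_cv=0.0,
                n_experiments=1, n_technical=1, seed=s,
            )
            t = simulate_single_agent(cfg, lad)
            row = t.df[t.df["log_dose_a"] == -8.0]
            vals.append(float(row["luminescence"].iloc[0]))
        cv = np.std(vals) / np.mean(vals)
        assert cv == pytest.approx(0.1, rel=0.10)


class TestReferenceSurfaces:
    def test_loewe_identical_agents_closed_form(self):
        drugs = {"p": DrugParams("p", log_ec50=-7.0, hill=1.4),
                 "q": DrugParams("q", log_ec50=-7.0, hill=1.4)}
        for a, b in [(1e-8, 2e-8), (5e-8, 5e-8), (1e-7, 3e-7)]:
            v = loewe_viability({"p": a, "q": b}, drugs)
            v_sum = drugs["p"].viability(np.log10(a + b))
            assert v == pytest.approx(v_sum, abs=1e-9)

    def test_bliss_is_survival_product_for_full_range_drugs(self):
        drugs = {"p": DrugParams("p", log_ec50=-7.0), "q": DrugParams("q", log_ec50=-6.0)}
        v = bliss_viability({"p": 1e-7, "q": 1e-6}, drugs)
        assert v == pytest.approx(0.25, abs=1e-12)

    def test_surfaces_monotone_nonincreasing_in_each_dose(self, pair_drugs):
        doses = np.logspace(-10, -4, 8)
        for model in ("loewe", "bliss"):
            cfg = noiseless_config(pair_drugs, model=model)
            for db in (1e-7, 1e-5):
                vs = [expected_viability(cfg, {"drugA": da, "drugB": db}) for da in doses]
                assert np.all(np.diff(vs) <= 1e-9)

    def test_synergy_alpha_strictly_lowers_interior_viability(self, pair_drugs):
        base = noiseless_config(pair_drugs, alpha=0.0)
        boosted = noiseless_config(pair_drugs, alpha=0.8)
        for da, db in [(1e-9, 1e-6), (2e-9, 2e-6), (5e-9, 5e-7)]:
            v0 = expected_viability(base, {"drugA": da, "drugB": db})
            v1 = expected_viability(boosted, {"drugA": da, "drugB": db})
            assert v1 < v0

    def test_alpha_never_touches_single_agent_wells(self, pair_drugs):
        base = noiseless_config(pair_drugs, alpha=0.0)
        boosted = noiseless_config(pair_drugs, alpha=2.0)
        for d in (1e-9, 1e-8):
            assert expected_viability(boosted, {"drugA": d}) == pytest.approx(
                expected_viability(base, {"drugA": d}), abs=1e-12
            )

    def test_loewe_out_of_range_clamps_with_warning(self):
        # partner q can push the effect below p's floor (bottom 0.4), where
        # p's iso-effective dose is undefined: clamp to the boundary effect
        drugs = {"p": DrugParams("p", log_ec50=-7.0, bottom=0.4),
                 "q": DrugParams("q", log_ec50=-7.0, bottom=0.0)}
        with pytest.warns(UserWarning, match="clamping"):
            v = loewe_viability({"p": 1e-9, "q": 1e-3}, drugs)
        assert v == pytest.approx(0.4, abs=1e-6)


class TestCombinationTables:
    def test_deq_table_contains_all_arms(self, pair_drugs, pair_design):
        cfg = noiseless_config(pair_drugs)
        t = simulate_combination(cfg, pair_design)
        labels = set(t.df["ratio_label"])
        assert labels == {"untreated", "alone", "4:1", "2:1", "1:1", "1:2", "1:4"}
        mix = t.df[t.df["ratio_label"] == "1:1"]
        # nominal axes carry the full ladder doses
        assert set(mix["log_dose_a"]) == set(pair_design.ladder_a.doses)

    def test_unknown_drug_rejected(self, pair_design):
        cfg = noiseless_config({"drugA": DRUG_A})
        with pytest.raises(ValueError, match="drugB"):
            simulate_combination(cfg, pair_design)

    def test_every_plate_has_untreated_wells(self, pair_drugs, pair_design):
        cfg = SimulationConfig(drugs=pair_drugs, seed=9)
        t = simulate_combination(cfg, pair_design)
        by_plate = t.df.groupby("plate_id")["ratio_label"]
        assert all((g == "untreated").sum() >= 3 for _, g in by_plate)

    def test_curve_arms_never_split_across_plates(self, pair_drugs, pair_design):
        t = simulate_combination(SimulationConfig(drugs=pair_drugs, seed=9), pair_design)
        treated = t.df[t.df["ratio_label"] != "untreated"]
        arms = treated.groupby(["experiment", "ratio_label", "drug_a", "drug_b"],
                               dropna=False)["plate_id"].nunique()
        assert (arms == 1).all()

    def test_bliss_matrix_full_doses(self, pair_drugs, pair_design):
        cfg = noiseless_config(pair_drugs, model="bliss")
        des = BlissMatrixDesign.full_matrix(pair_design.ladder_a, pair_design.ladder_b)
        t = normalize_viability(simulate_combination(cfg, des))
        combo = t.df[t.df["ratio_label"] == "combo"]
        assert len(combo) == 100 * cfg.n_technical
        # one spot check against the closed-form Bliss product
        da = pair_design.ladder_a.doses[7]
        db = pair_design.ladder_b.doses[7]
        row = combo[(combo["log_dose_a"] == da) & (combo["log_dose_b"] == db)].iloc[0]
        expect = bliss_viability({"drugA": 10.0 ** da, "drugB": 10.0 ** db}, pair_drugs)
        assert row["viability"] == pytest.approx(expect, abs=1e-10)
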