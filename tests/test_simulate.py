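"""Generator: population structure, effect drawing, and the exponential model."""

import numpy as np
import pandas as pd
import pytest

from hetvar.pedigree import load_pedigree
from hetvar.simulate import (
    GeneticParameters,
    SimulationDesign,
    build_population,
    draw_effects,
    expected_heritability,
    expected_residual_variance,
    mean_expected_residual_variance,
    simulate_dataset,
    simulate_on_pedigree,
    simulate_phenotypes,
)


class TestDesign:
    def test_default_counts(self):
        d = SimulationDesign()
        d.validate()
        assert d.n_records == 25_000
        assert d.records_per_generation == 5_000

    def test_small_preset(self):
        d = SimulationDesign.small()
        d.validate()
        assert d.n_records == 2_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cg_per_generation": 7},                 # CG grid does not tile
            {"offspring_per_sire": 49},               # not a multiple of per-CG block
            {"n_base_sires": 0},
            {"replacement_rate": 1.5},
        ],
    )
    def test_infeasible_design_raises(self, kwargs):
        with pytest.raises(ValueError):
            SimulationDesign(**{**dict(n_base_sires=20, n_base_dams=1000,
                                       n_generations=2, cg_per_generation=20),
                                **kwargs}).validate()


class TestBuildPopulation:
    def test_counting_toy(self):
        # 1 generation, 2 sires, 10 dams, 5 offspring/sire -> 10 records
        d = SimulationDesign(
            n_base_sires=2, n_base_dams=10, offspring_per_sire=5,
            offspring_per_sire_per_cg=5, sires_per_cg=2, cg_per_generation=1,
            n_generations=1,
        )
        ped, cg = build_population(d, seed=0)
        assert len(cg) == 10
        assert ped.n == 22  # 2 sires + 10 dams + 10 offspring

    def test_structure_small(self, test_design):
        ped, cg = build_population(test_design, seed=3)
        assert len(cg) == test_design.n_records
        assert ped.n == test_design.n_records + 510  # offspring + base animals
        # every CG holds sires_per_cg sires x block-size records
        merged = cg.copy()
        ix = ped.indices(merged["animal"])
        merged["sire"] = ped.ids[ped.sire[ix]]
        by_cg = merged.groupby("cg")
        assert (by_cg.size() == 50).all()
        assert (by_cg["sire"].nunique() == test_design.sires_per_cg).all()
        # every dam has offspring_per_dam offspring per generation
        merged["gen"] = [a.split("_")[0] for a in merged["animal"]]
        dams = ped.ids[ped.dam[ix]]
        assert pd.Series(dams).groupby([merged["gen"].values, dams]).size().max() == 1

    def test_replacement_brings_in_new_parents(self, test_design):
        ped, cg = build_population(test_design, seed=3)
        ix = ped.indices(cg["animal"])
        parents = set(ped.sire[ix]) | set(ped.dam[ix])
        non_base = [p for p in parents if not ped.is_founder()[p]]
        assert len(non_base) > 0  # some generation-1 animals became parents


class TestDrawEffects:
    def test_zero_dispersion_variance_degenerate(self):
        ped = load_pedigree([(f"f{i}", "0", "0") for i in range(50)])
        eff = draw_effects(ped, ["c1"], GeneticParameters(sigma2_Av_exp=0.0), seed=4)
        assert np.all(eff.a_v == 0.0)
        assert np.std(eff.a_m) > 0

    def test_founder_moments_and_correlation(self):
        n = 5000
        ped = load_pedigree([(f"f{i}", "0", "0") for i in range(n)])
        params = GeneticParameters(sigma2_a=200.0, sigma2_Av_exp=0.25, r_mv=0.5)
        eff = draw_effects(ped, ["c1"], params, seed=5)
        assert np.var(eff.a_m) == pytest.approx(200.0, rel=0.05)
        assert np.var(eff.a_v) == pytest.approx(0.25, rel=0.05)
        r = np.corrcoef(eff.a_m, eff.a_v)[0, 1]
        assert r == pytest.approx(0.5, abs=0.03)

    def test_cg_effects_within_ranges(self):
        ped = load_pedigree([("f", "0", "0")])
        eff = draw_effects(ped, [f"c{i}" for i in range(200)], GeneticParameters(), seed=6)
        assert eff.b_m.min() >= 300 and eff.b_m.max() <= 400
        assert eff.b_v.min() >= 5.40 and eff.b_v.max() <= 5.80

    def test_midparent_regression_slope_near_one(self, test_design):
        ds = simulate_dataset(test_design, GeneticParameters(sigma2_Av_exp=0.09), seed=7)
        ped, eff = ds.pedigree, ds.truth
        both = (ped.sire >= 0) & (ped.dam >= 0)
        mid = 0.5 * (eff.a_m[ped.sire[both]] + eff.a_m[ped.dam[both]])
        slope = np.polyfit(mid, eff.a_m[both], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)
        mid_v = 0.5 * (eff.a_v[ped.sire[both]] + eff.a_v[ped.dam[both]])
        slope_v = np.polyfit(mid_v, eff.a_v[both], 1)[0]
        assert slope_v == pytest.approx(1.0, abs=0.1)

    def test_invalid_correlation_raises(self):
        with pytest.raises(ValueError):
            GeneticParameters(r_mv=1.2).validate()


class TestSimulatePhenotypes:
    def test_model_identity_bit_exact(self, small_dataset):
        """y is exactly b_m + a_m + exp((b_v + a_v)/2) * epsilon."""
        ds = small_dataset
        ix = ds.pedigree.indices(ds.records["animal"])
        cg_pos = {c: i for i, c in enumerate(ds.truth.cg_ids)}
        c_ix = np.array([cg_pos[c] for c in ds.records["cg"]])
        y = (
            ds.truth.b_m[c_ix]
            + ds.truth.a_m[ix]
            + np.exp(0.5 * (ds.truth.b_v[c_ix] + ds.truth.a_v[ix])) * ds.epsilon
        )
        np.testing.assert_array_equal(y, ds.records["y"].to_numpy())

    def test_direct_evaluation(self):
        # b_m = 350, a_m = 0, b_v = 5.6, a_v = 0, eps = 1 -> 350 + e^2.8
        assert 350 + np.exp(2.8) == pytest.approx(366.4447, abs=1e-4)
        ped = load_pedigree([("f", "0", "0")])
        eff = draw_effects(ped, ["c"], GeneticParameters(sigma2_Av_exp=0.0), seed=0)
        eff.b_m[0], eff.b_v[0] = 350.0, 5.6
        eff.a_m[0] = 0.0
        rec = simulate_phenotypes(ped, pd.DataFrame({"animal": ["f"], "cg": ["c"]}), eff, seed=0)
        eps = rec["epsilon"][0]
        assert rec["y"][0] == 350.0 + np.exp(2.8) * eps

    def test_seed_reproducibility(self, test_design):
        p = GeneticParameters()
        a = simulate_dataset(test_design, p, seed=42)
        b = simulate_dataset(test_design, p, seed=42)
        c = simulate_dataset(test_design, p, seed=43)
        np.testing.assert_array_equal(a.records["y"], b.records["y"])
        assert not np.array_equal(a.epsilon, c.epsilon)

    def test_zero_dispersion_gives_constant_family_variance(self, test_design):
        ds = simulate_dataset(test_design, GeneticParameters(sigma2_Av_exp=0.0), seed=8)
        ped = ds.pedigree
        ix = ped.indices(ds.records["animal"])
        resid = ds.records["y"].to_numpy() - ds.truth.a_m[ix]
        df = pd.DataFrame({"sire": ped.sire[ix], "cg": ds.records["cg"], "r": resid})
        df["r"] -= df.groupby("cg")["r"].transform("mean")
        fam_var = df.groupby("sire")["r"].var()
        # dispersion across families limited to sampling noise of ~100-record vars
        assert fam_var.std() / fam_var.mean() < 0.35


class TestExpectedResidualVariance:
    def test_unit_case(self):
        assert expected_residual_variance(0.0, 0.0) == 1.0

    def test_lognormal_value(self):
        # independent Monte-Carlo oracle gave 222.516 for (5.4, 0.01)
        assert expected_residual_variance(5.4, 0.01) == pytest.approx(222.516, abs=0.01)

    def test_design_level_summaries(self):
        params = GeneticParameters(sigma2_Av_exp=0.09)
        assert mean_expected_residual_variance(params) == pytest.approx(284.77, abs=0.05)
        assert expected_heritability(params) == pytest.approx(0.4126, abs=0.001)

    def test_within_cg_variance_matches_closed_form(self, test_design):
        ds = simulate_dataset(
            test_design, GeneticParameters(sigma2_Av_exp=0.25, r_mv=0.0), seed=9
        )
        ix = ds.pedigree.indices(ds.records["animal"])
        e = ds.records["y"].to_numpy() - ds.truth.a_m[ix]
        cg_pos = {c: i for i, c in enumerate(ds.truth.cg_ids)}
        c_ix = np.array([cg_pos[c] for c in ds.records["cg"]])
        e = e - ds.truth.b_m[c_ix]
        # pooled empirical residual variance vs E over realized b_v draws
        expect = np.mean(
            [expected_residual_variance(bv, 0.25) for bv in ds.truth.b_v]
        )
        assert np.var(e) == pytest.approx(expect, rel=0.1)


class TestSimulateOnPedigree:
    def test_consistency_with_internal_population(self, test_design):
        p = GeneticParameters()
        ds1 = simulate_dataset(test_design, p, seed=11)
        ped, cg = build_population(test_design, seed=11)
        ds2 = simulate_on_pedigree(ped, cg, p, seed=11)
        np.testing.assert_array_equal(ds1.records["y"], ds2.records["y"])

    def test_toy_pedigree_record_count(self):
        ped = load_pedigree([("a", "0", "0"), ("b", "0", "0"), ("c", "a", "b")])
        cg = pd.DataFrame({"animal": ["a", "b", "c"], "cg": ["g", "g", "g"]})
        ds = simulate_on_pedigree(ped, cg, GeneticParameters(), seed=12)
        assert ds.n_records == 3

    def test_missing_cg_assignment_raises(self):
        ped = load_pedigree([("a", "0", "0")])
        cg = pd.DataFrame({"animal": ["zz"], "cg": ["g"]})
        with pytest.raises(ValueError, match="not in pedigree"):
            simulate_on_pedigree(ped, cg, GeneticParameters(), seed=0)
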