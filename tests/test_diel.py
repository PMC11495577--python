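"""Multi-tissue merging, dielization, phase constraints and scans."""

import numpy as np
import pytest

from dielflux import diel as dl
from dielflux.diel import (PoolSpec, StorageSpec, audit_structure,
                           merge_tissues, nutrient_scan, simulate_diel)
from dielflux.netcore import get_kind
from dielflux.simulate import fba

from conftest import build_model


def two_tiny_tissues():
    """Leaf fixes 'carbon' into sucr and exports it; stem only consumes."""
    leaf = build_model([
        ("EX_co2", -10, 0, {"co2_e": -1}),
        ("T_co2", 0, 1000, {"co2_e": -1, "co2_c": 1}),
        ("FIX", 0, 1000, {"co2_c": -1, "sucr_c": 1}),
        ("biomass_leaf", 0, 1000, {"sucr_c": -2.0}),
    ], objective="biomass_leaf", model_id="leaf")
    stem = build_model([
        ("GROW", 0, 1000, {"sucr_c": -1, "cw_c": 1}),
        ("biomass_stem", 0, 1000, {"cw_c": -1}),
    ], objective="biomass_stem", model_id="stem")
    for model, bid in ((leaf, "biomass_leaf"), (stem, "biomass_stem")):
        from dielflux.netcore import set_kind, annotate_kinds
        annotate_kinds(model)
        set_kind(model.reactions.get_by_id(bid), "biomass")
    return {"leaf": leaf, "stem": stem}


class TestMergeTissues:
    def test_reaction_count_is_sum_plus_transfers(self):
        tissues = two_tiny_tissues()
        pools = [PoolSpec("pool1", ("leaf", "stem"), frozenset({"sucr"}))]
        merged = merge_tissues(tissues, pools=pools, mineral_bases=(),
                               remove_exchange_bases=())
        n_leaf, n_stem = 4, 2
        n_transfers = 2  # leaf<->pool1 and stem<->pool1 for sucr
        assert len(merged.reactions) == n_leaf + n_stem + n_transfers

    def test_sucrose_feeds_the_stem_through_the_pool(self):
        tissues = two_tiny_tissues()
        pools = [PoolSpec("pool1", ("leaf", "stem"), frozenset({"sucr"}))]
        merged = merge_tissues(tissues, pools=pools, mineral_bases=(),
                               remove_exchange_bases=())
        state = fba(merged)
        assert state.ok
        assert state.fluxes["stem__biomass_stem"] > 1e-6
        assert abs(state.fluxes["TR__stem__pool1__sucr"]) > 1e-6

    def test_berry_touches_only_pool2(self, diel_model):
        berry_transfers = [r.id for r in diel_model.reactions
                           if r.id.startswith("TR__green_berry__")]
        assert berry_transfers
        assert all("pool2" in rid for rid in berry_transfers)

    def test_minerals_only_in_stem(self, toy_models):
        merged = merge_tissues({t: toy_models.tissues[t]
                                for t in ("leaf", "stem", "green_berry")})
        for rxn in merged.reactions:
            if get_kind(rxn) != "exchange":
                continue
            base = rxn.id.split("EX_")[-1].rsplit("_", 1)[0]
            if base in ("no3", "so4", "pi"):
                assert rxn.id.startswith("stem__")

    def test_missing_pool_metabolite_skipped(self, caplog):
        tissues = two_tiny_tissues()
        pools = [PoolSpec("pool1", ("leaf", "stem"),
                          frozenset({"sucr", "unobtainium"}))]
        with caplog.at_level("INFO", logger="dielflux"):
            merged = merge_tissues(tissues, pools=pools, mineral_bases=(),
                                   remove_exchange_bases=())
        assert "unobtainium" in caplog.text
        assert not any("unobtainium" in r.id for r in merged.reactions)


class TestDielize:
    def test_counting_identity(self, diel_model):
        n_storage = sum(1 for r in diel_model.reactions
                        if get_kind(r) == "storage")
        assert len(diel_model.reactions) == \
            2 * diel_model._merged_reaction_count + n_storage

    def test_amino_acid_storage_is_light_to_dark_only(self, diel_model):
        pro = diel_model.reactions.get_by_id("STORAGE__leaf__pro")
        assert pro.lower_bound == 0 and pro.upper_bound > 0

    def test_organic_acid_storage_is_reversible(self, diel_model):
        cit = diel_model.reactions.get_by_id("STORAGE__green_berry__cit")
        assert cit.lower_bound < 0 < cit.upper_bound

    def test_no_cross_phase_or_cross_tissue_coupling(self, diel_model):
        assert audit_structure(diel_model) == []

    def test_overlapping_storage_sets_rejected(self):
        with pytest.raises(ValueError):
            StorageSpec(reversible_metabolites=("pro",),
                        light_to_dark_only=("pro",))


class TestDielConstraints:
    def test_photon_only_in_leaf_light(self, diel_model):
        for rxn in diel_model.reactions:
            if "EX_photon" not in rxn.id:
                continue
            if rxn.id.startswith("leaf__light__"):
                assert rxn.lower_bound < 0
            else:
                assert rxn.bounds == (0.0, 0.0)

    def test_nitrate_ratio_holds_in_solution(self, diel_model, diel_solution):
        fluxes = diel_solution.state.fluxes
        light = fluxes["stem__light__EX_no3_e"]
        dark = fluxes["stem__dark__EX_no3_e"]
        assert abs(light) > 1e-6
        assert abs(light - 1.5 * dark) <= 1e-8

    def test_zero_biomass_without_photon_and_sucrose(self, diel_model):
        with diel_model:
            for rxn in diel_model.reactions:
                if "EX_photon" in rxn.id or "EX_sucr" in rxn.id:
                    rxn.bounds = (0.0, 0.0)
                if rxn.id.startswith(("leaf__", "stem__", "green_berry__")) \
                        and rxn.id.endswith("NGAM"):
                    rxn.bounds = (0.0, rxn.upper_bound)
                if "NGAM" in rxn.id:
                    rxn.bounds = (0.0, rxn.upper_bound)
            state = fba(diel_model)
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)


class TestDielSimulation:
    def test_diel_model_grows_with_leaf_starch_storage(self, diel_solution):
        assert diel_solution.state.ok
        assert diel_solution.state.objective_value > 1e-3
        starch = diel_solution.storage_report.query(
            "tissue == 'leaf' and metabolite == 'starch'")
        assert starch.flux.iloc[0] > 1e-6  # stored in light, used in dark

    def test_closing_storage_never_increases_biomass(self, diel_model,
                                                     diel_solution):
        with diel_model:
            for rxn in diel_model.reactions:
                if get_kind(rxn) == "storage":
                    rxn.bounds = (0.0, 0.0)
            closed = simulate_diel(
                diel_model, 300.0,
                rubisco_pairs=dl.leaf_rubisco_pairs(diel_model))
        if closed.state.ok:
            assert closed.state.objective_value <= \
                diel_solution.state.objective_value + 1e-6

    def test_storage_sign_convention(self, diel_model, diel_solution):
        # a storage reaction consumes the light species 1:1 into the dark
        # species, so positive flux means "stored in light, used in dark"
        rxn = diel_model.reactions.get_by_id("STORAGE__leaf__starch")
        coeffs = {m.id: c for m, c in rxn.metabolites.items()}
        light = [m for m in coeffs if "__light__" in m]
        dark = [m for m in coeffs if "__dark__" in m]
        assert coeffs[light[0]] == -1 and coeffs[dark[0]] == 1

    def test_rubisco_ratio_enforced_per_phase(self, diel_solution):
        fluxes = diel_solution.state.fluxes
        for phase in ("light", "dark"):
            carb = fluxes[f"leaf__{phase}__RBC_CARB"]
            oxy = fluxes[f"leaf__{phase}__RBC_OXY"]
            assert abs(carb - 3 * oxy) <= 1e-8


class TestNutrientScan:
    def test_sulfur_limitation_reduces_biomass(self, diel_model):
        watch = [r.id for r in diel_model.reactions
                 if "EX_terp" in r.id or "biomass" in r.id
                 or "SO4_RED" in r.id]
        with diel_model:
            # the scanned light-phase uptake is the total sulfur supply
            diel_model.reactions.get_by_id(
                "stem__dark__EX_so4_e").bounds = (0.0, 0.0)
            result = nutrient_scan(diel_model, "stem__light__EX_so4_e",
                                   levels=[0.001], reactions=watch)
        res = result.levels[0.001]
        assert res["status"] == "optimal"
        assert res["biomass"] < result.baseline_biomass - 1e-3

    def test_secondary_branch_gains_capacity_when_growth_collapses(
            self, diel_model):
        watch = [r.id for r in diel_model.reactions if "EX_terp" in r.id]
        with diel_model:
            diel_model.reactions.get_by_id(
                "stem__dark__EX_so4_e").bounds = (0.0, 0.0)
            result = nutrient_scan(diel_model, "stem__light__EX_so4_e",
                                   levels=[0.001], reactions=watch)
        delta = result.levels[0.001]["delta"]
        assert delta["delta_max"].max() > 1e-3

    def test_infeasible_level_recorded_and_scan_continues(self, diel_model):
        # forcing a huge sulfate influx has no overflow sink in the toy
        watch = ["leaf__light__EX_heat_e"]
        result = nutrient_scan(diel_model, "stem__light__EX_so4_e",
                               levels=[50.0, 0.01], reactions=watch,
                               mode="fix")
        assert result.levels[50.0]["status"] != "optimal"
        assert result.levels[0.01]["status"] == "optimal"

    def test_cap_at_baseline_level_changes_nothing(self, diel_model):
        watch = ["leaf__light__EX_terp_e", "green_berry__light__EX_terp_e"]
        result = nutrient_scan(diel_model, "stem__light__EX_so4_e",
                               levels=[1000.0], reactions=watch)
        delta = result.levels[1000.0]["delta"]
        assert np.allclose(delta[["delta_min", "delta_max"]].to_numpy(), 0.0,
                           atol=1e-6)
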