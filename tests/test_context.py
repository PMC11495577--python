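"""Expression preprocessing, local T2 calling, FASTCC and FASTCORE."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

import cobra
import cobra.flux_analysis

from dielflux import context as ctx
from dielflux.context import (CoreSet, ExpressionMatrix, ExpressionError,
                              InconsistentCoreError, ThresholdingConfig,
                              consistent_reaction_ids, discretize_stage,
                              extract_context_model, fastcc, fastcore,
                              fastcore_reaction_ids, local_t2_activity,
                              preprocess_expression, reaction_core_set)
from dielflux.simulate import fba

from conftest import build_model


def make_expr(values: dict[str, list[float]], genes: list[str],
              meta: dict | None = None) -> ExpressionMatrix:
    df = pd.DataFrame(values, index=genes)
    if meta is None:
        meta = {s: dict(tissue="t", time_point=1, stage="green",
                        replicate_group=s) for s in df.columns}
    meta_df = pd.DataFrame(meta).T
    meta_df.index.name = "sample_id"
    return ExpressionMatrix(values=df, sample_meta=meta_df)


class TestPreprocessing:
    def test_replicates_averaged_in_tpm_space(self):
        expr = make_expr({"r1": [2.0], "r2": [4.0]}, ["g1"],
                         meta={"r1": dict(replicate_group="b", tissue="t"),
                               "r2": dict(replicate_group="b", tissue="t")})
        out = preprocess_expression(expr)
        # mean(2, 4) = 3 before the log transform
        assert out.values.loc["g1", "b"] == pytest.approx(np.log2(4.0))

    def test_zero_tpm_maps_to_zero(self):
        expr = make_expr({"s1": [0.0], "s2": [0.0]}, ["g1"])
        out = preprocess_expression(expr, average_replicates=False)
        assert (out.values.loc["g1"] == 0.0).all()

    def test_unmapped_genes_dropped_with_count(self, caplog):
        expr = make_expr({"s1": [1, 2, 3]}, ["g1", "g2", "g3"])
        with caplog.at_level("INFO", logger="dielflux"):
            out = preprocess_expression(
                expr, gene_map={"g1": "P1", "g2": "P2"},
                average_replicates=False)
        assert list(out.values.index) == ["P1", "P2"]
        assert "1 gene(s) dropped" in caplog.text

    def test_empty_model_overlap_is_error(self, toy_models):
        expr = make_expr({"s1": [1.0]}, ["not_a_gene"])
        with pytest.raises(ExpressionError):
            preprocess_expression(expr, model=toy_models.generic,
                                  average_replicates=False)

    def test_negative_values_rejected(self):
        with pytest.raises(ExpressionError):
            make_expr({"s1": [-1.0]}, ["g1"])

    def test_tsv_roundtrip(self, tmp_path, fixture):
        expr = fixture.expression
        expr.write_tsv(tmp_path / "v.tsv", tmp_path / "m.tsv")
        back = ExpressionMatrix.read_tsv(tmp_path / "v.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.values, expr.values,
                                      check_names=False)


class TestStageDiscretization:
    @pytest.mark.parametrize("tp,stage", [(1, "green"), (4, "green"),
                                          (5, "mature"), (8, "mature")])
    def test_time_point_boundary(self, tp, stage):
        assert discretize_stage(tp) == stage

    def test_missing_time_point(self):
        with pytest.raises(ValueError):
            discretize_stage(float("nan"))


class TestLocalT2:
    def brute_force_states(self, values: pd.DataFrame, group, config):
        """Independent re-derivation of the calling rule."""
        gl = np.percentile(values.to_numpy().ravel(), config.global_lower_pct)
        gu = np.percentile(values.to_numpy().ravel(), config.global_upper_pct)
        states = {}
        for gene in values.index:
            local = np.percentile(values.loc[gene].to_numpy(),
                                  config.local_pct)
            local = min(max(local, gl), gu)
            e = values.loc[gene, group].mean()
            if e >= gu:
                states[gene] = "active"
            elif e < gl:
                states[gene] = "inactive"
            else:
                states[gene] = "active" if e >= local else "inactive"
        return states

    def test_matches_brute_force_on_4x4(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.uniform(0, 10, (4, 4)),
                              index=list("abcd"),
                              columns=["s1", "s2", "s3", "s4"])
        expr = make_expr({c: values[c].tolist() for c in values.columns},
                         list(values.index))
        config = ThresholdingConfig()
        for group in (["s1"], ["s2", "s3"], None):
            call = local_t2_activity(expr, config, group=group)
            expected = self.brute_force_states(
                values, group if group else list(values.columns), config)
            assert call.table["state"].to_dict() == expected

    def test_global_thresholds_dominate(self):
        # one gene far above everything, one far below
        expr = make_expr({"s1": [100, 0.0, 5], "s2": [100, 0.0, 6]},
                         ["hi", "lo", "mid"])
        call = local_t2_activity(expr, ThresholdingConfig())
        assert call.table.loc["hi", "state"] == "active"
        assert call.table.loc["lo", "state"] == "inactive"

    def test_invariant_to_column_order(self, fixture):
        expr = preprocess_expression(fixture.expression)
        shuffled = ExpressionMatrix(
            values=expr.values[expr.values.columns[::-1]],
            sample_meta=expr.sample_meta)
        a = local_t2_activity(expr, ThresholdingConfig())
        b = local_t2_activity(shuffled, ThresholdingConfig())
        assert a.table["state"].to_dict() == b.table["state"].to_dict()

    def test_invalid_percentile_order(self):
        with pytest.raises(ValueError):
            ThresholdingConfig(global_lower_pct=80, global_upper_pct=20)


class TestCoreSet:
    def _activity(self, states):
        table = pd.DataFrame({"state": pd.Series(states),
                              "score": 0.0, "threshold": 0.0})
        return ctx.ActivityCall(table=table)

    def test_or_rule_keeps_reaction(self, toy_models):
        model = toy_models.tissues["leaf"]
        # pick a reaction with an isozyme OR rule
        rxn = next(r for r in model.reactions if " or " in r.gene_reaction_rule)
        genes = sorted(g.id for g in rxn.genes)
        states = {g.id: "inactive" for g in model.genes}
        states[genes[0]] = "active"
        core = reaction_core_set(model, self._activity(states))
        assert rxn.id in core.core

    def test_and_rule_requires_all_subunits(self, toy_models):
        model = toy_models.tissues["leaf"]
        rxn = next(r for r in model.reactions
                   if " and " in r.gene_reaction_rule)
        genes = sorted(g.id for g in rxn.genes)
        states = {g.id: "active" for g in model.genes}
        states[genes[0]] = "inactive"
        core = reaction_core_set(model, self._activity(states))
        assert rxn.id not in core.core

    def test_gprless_reactions_not_core_and_biomass_protected(self, toy_models):
        model = toy_models.tissues["leaf"]
        states = {g.id: "active" for g in model.genes}
        core = reaction_core_set(model, self._activity(states))
        assert "NGAM" not in core.core  # no GPR
        assert "biomass_leaf" in core.protected


class TestFastcc:
    def test_dead_end_reaction_removed(self, chain_model):
        dead = cobra.Reaction("DEAD", lower_bound=0, upper_bound=10)
        orphan = cobra.Metabolite("orphan_c", compartment="c")
        dead.add_metabolites(
            {chain_model.metabolites.get_by_id("A_c"): -1, orphan: 1})
        chain_model.add_reactions([dead])
        out = fastcc(chain_model)
        assert "DEAD" not in {r.id for r in out.reactions}
        assert {"EX_A", "AB", "EX_B"} <= {r.id for r in out.reactions}

    def test_consistent_model_unchanged(self, fixture):
        out = fastcc(fixture.generic)
        assert {r.id for r in out.reactions} == \
            {r.id for r in fixture.generic.reactions}

    def test_idempotent(self, toy_models):
        model = toy_models.tissues["leaf"]
        once = fastcc(model)
        twice = fastcc(once)
        assert {r.id for r in twice.reactions} == \
            {r.id for r in once.reactions}

    def test_agrees_with_reference_implementation(self, toy_models):
        """Cross-check against cobra's FASTCC on the leaf variant."""
        model = toy_models.tissues["leaf"]
        ours = {r.id for r in fastcc(model, epsilon=1e-4).reactions}
        theirs = {r.id for r in
                  cobra.flux_analysis.fastcc(model,
                                             flux_threshold=1e-4).reactions}
        assert ours == theirs


def brute_force_minimal_supersets(model, core, epsilon=1e-4):
    """All minimum-cardinality flux-consistent subnetworks containing core.

    Enumerates reaction subsets (smallest first); a subset qualifies
    when every one of its reactions can carry |flux| >= epsilon within
    the subnetwork.
    """
    from cobra.util.array import create_stoichiometric_matrix

    rids = [r.id for r in model.reactions]
    S = create_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], float)
    ub = np.array([r.upper_bound for r in model.reactions], float)
    core_idx = {rids.index(r) for r in core}
    free = [i for i in range(len(rids)) if i not in core_idx]

    def consistent(subset):
        idx = sorted(subset)
        Ssub = S[:, idx]
        for j, i in enumerate(idx):
            for sense in ([1] if lb[i] >= 0 else [1, -1]):
                c = np.zeros(len(idx))
                c[j] = -sense
                res = linprog(c, A_eq=Ssub, b_eq=np.zeros(S.shape[0]),
                              bounds=[(lb[i2], ub[i2]) for i2 in idx],
                              method="highs")
                if res.success and sense * res.x[j] >= epsilon * (1 - 1e-6):
                    break
            else:
                return False
        return True

    for size in range(len(core_idx), len(rids) + 1):
        hits = []
        for extra in itertools.combinations(free, size - len(core_idx)):
            subset = core_idx | set(extra)
            if consistent(subset):
                hits.append(frozenset(rids[i] for i in subset))
        if hits:
            return hits
    return []


class TestFastcore:
    def test_linear_chain_needs_every_reaction(self):
        model = build_model([
            ("EX_A", -10, 0, {"A_c": -1}),
            ("R1", 0, 1000, {"A_c": -1, "B_c": 1}),
            ("R2", 0, 1000, {"B_c": -1, "C_c": 1}),
            ("R3", 0, 1000, {"C_c": -1, "D_c": 1}),
            ("EX_B", 0, 1000, {"D_c": -1}),
        ], objective="EX_B")
        keep = fastcore_reaction_ids(model, {"R2"})
        assert keep == {"EX_A", "R1", "R2", "R3", "EX_B"}

    def test_matches_brute_force_minimum_on_shortcut_toy(self, shortcut_model):
        keep = fastcore_reaction_ids(shortcut_model, {"R5"})
        minima = brute_force_minimal_supersets(shortcut_model, {"R5"})
        assert keep in minima

    def test_core_always_contained(self, shortcut_model):
        for core in ({"R1"}, {"R4"}, {"R5", "R2"}):
            keep = fastcore_reaction_ids(shortcut_model, core)
            assert core <= keep

    def test_output_is_flux_consistent(self, shortcut_model):
        sub = fastcore(shortcut_model, {"R3"})
        assert consistent_reaction_ids(sub) == {r.id for r in sub.reactions}

    def test_reversible_core_is_covered(self):
        # core reaction only able to carry flux in reverse
        model = build_model([
            ("EX_A", -10, 0, {"A_c": -1}),
            ("RREV", -1000, 1000, {"B_c": -1, "A_c": 1}),
            ("EX_B", 0, 1000, {"B_c": -1}),
        ], objective="EX_B")
        keep = fastcore_reaction_ids(model, {"RREV"})
        assert keep == {"EX_A", "RREV", "EX_B"}

    def test_blocked_core_reaction_raises(self, chain_model):
        dead = cobra.Reaction("DEAD", lower_bound=0, upper_bound=10)
        orphan = cobra.Metabolite("orphan_c", compartment="c")
        dead.add_metabolites(
            {chain_model.metabolites.get_by_id("A_c"): -1, orphan: 1})
        chain_model.add_reactions([dead])
        with pytest.raises(InconsistentCoreError, match="DEAD"):
            fastcore_reaction_ids(fastcc(chain_model), {"DEAD"})


class TestExtractionPipeline:
    def test_minimal_biomass_subnetwork_without_core(self, toy_models):
        model = fastcc(toy_models.tissues["leaf"])
        sub = fastcore(model, CoreSet(core=set(), protected={"biomass_leaf"}))
        assert "biomass_leaf" in {r.id for r in sub.reactions}
        assert fba(sub).objective_value > 0
        assert len(sub.reactions) < len(model.reactions)

    def test_every_tissue_context_model_grows(self, fixture, expr):
        meta = expr.sample_meta
        for tissue in ("leaf", "stem"):
            group = list(meta.index[meta["tissue"] == tissue])
            model = extract_context_model(fixture.models.tissues[tissue],
                                          expr, group=group)
            assert fba(model).objective_value > 1e-6

    def test_fastcore_output_passes_fastcc_unchanged(self, fixture, expr):
        meta = expr.sample_meta
        group = list(meta.index[(meta["tissue"] == "berry")
                                & (meta["stage"] == "green")])
        model = extract_context_model(fixture.models.tissues["green_berry"],
                                      expr, group=group)
        again = fastcc(model)
        assert {r.id for r in again.reactions} == \
            {r.id for r in model.reactions}

    def test_activity_invariant_to_replicate_duplication(self, fixture):
        # duplicating every replicate leaves all group means unchanged
        raw = fixture.expression
        dup_values = raw.values.copy()
        meta = raw.sample_meta.copy()
        for col in raw.values.columns:
            dup_values[f"{col}_dup"] = raw.values[col]
            meta.loc[f"{col}_dup"] = meta.loc[col]
        dup = ExpressionMatrix(values=dup_values, sample_meta=meta)
        a = local_t2_activity(preprocess_expression(raw),
                              ThresholdingConfig())
        b = local_t2_activity(preprocess_expression(dup),
                              ThresholdingConfig())
        assert a.table["state"].to_dict() == b.table["state"].to_dict()
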