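"""Shared fixtures: small LP toys, the synthetic plant fixture, and
session-scoped expensive artifacts (context models, samples, ML report)."""

from __future__ import annotations

import cobra
import numpy as np
import pytest
from scipy.optimize import linprog

import dielflux as dfl
from dielflux import context as ctx
from dielflux import diel as dl
from dielflux import diffflux as dfx
from dielflux import fluxml as fml
from dielflux.simulate import apply_condition, make_condition

SEED = 7


def build_model(reactions, objective=None, model_id="toy"):
    """reactions: list of (id, lb, ub, {met_id: coeff}); met ids end _c."""
    model = cobra.Model(model_id)
    mets = {}

    def met(mid):
        if mid not in mets:
            mets[mid] = cobra.Metabolite(mid, compartment=mid.rsplit("_", 1)[-1])
        return mets[mid]

    objs = []
    for rid, lb, ub, stoich in reactions:
        rxn = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites({met(m): c for m, c in stoich.items()})
        model.add_reactions([rxn])
        objs.append(rxn)
    model.objective = model.reactions.get_by_id(objective) if objective \
        else objs[-1]
    return model


def lp_oracle_optimum(model, objective_id=None, sense="max"):
    """Independent brute-force LP: solve max/min v_obj s.t. S v = 0, bounds."""
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(model)
    rids = [r.id for r in model.reactions]
    if objective_id is None:
        coeffs = cobra.util.solver.linear_reaction_coefficients(model)
        c = np.zeros(len(rids))
        for rxn, w in coeffs.items():
            c[rids.index(rxn.id)] = w
    else:
        c = np.zeros(len(rids))
        c[rids.index(objective_id)] = 1.0
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=[r.bounds for r in model.reactions], method="highs")
    assert res.success, res.message
    return float(c @ res.x)


# ---------------------------------------------------------------------------
# small LP toys
# ---------------------------------------------------------------------------

@pytest.fixture()
def chain_model():
    """EX_A (uptake <= 10) -> A -> B -> EX_B."""
    return build_model([
        ("EX_A", -10, 0, {"A_c": -1}),
        ("AB", 0, 1000, {"A_c": -1, "B_c": 1}),
        ("EX_B", 0, 1000, {"B_c": -1}),
    ], objective="EX_B")


@pytest.fixture()
def parallel_model():
    """Two routes A->B: direct (1 step) and via X (2 steps)."""
    return build_model([
        ("EX_A", -10, 0, {"A_c": -1}),
        ("DIRECT", 0, 1000, {"A_c": -1, "B_c": 1}),
        ("AX", 0, 1000, {"A_c": -1, "X_c": 1}),
        ("XB", 0, 1000, {"X_c": -1, "B_c": 1}),
        ("EX_B", 0, 1000, {"B_c": -1}),
    ], objective="EX_B")


@pytest.fixture()
def branch_model():
    """Redundant parallel paths with a demand of 10 (for FVA spans)."""
    return build_model([
        ("EX_A", -10, -10, {"A_c": -1}),
        ("P1", 0, 1000, {"A_c": -1, "B_c": 1}),
        ("P2", 0, 1000, {"A_c": -1, "B_c": 1}),
        ("EX_B", 0, 1000, {"B_c": -1}),
    ], objective="EX_B")


@pytest.fixture()
def uniform1d_model():
    """One free flux, uniform on [0, 10] at steady state."""
    return build_model([
        ("EX_A", -10, 0, {"A_c": -1}),
        ("AB", 0, 1000, {"A_c": -1, "B_c": 1}),
        ("EX_B", 0, 1000, {"B_c": -1}),
    ], objective="EX_B")


@pytest.fixture()
def shortcut_model():
    """<=12-reaction toy with a 2-step path and a 1-step shortcut A->D."""
    return build_model([
        ("EX_A", -10, 0, {"A_c": -1}),
        ("R1", 0, 1000, {"A_c": -1, "B_c": 1}),
        ("R2", 0, 1000, {"A_c": -1, "C_c": 1}),
        ("R3", 0, 1000, {"B_c": -1, "D_c": 1}),
        ("R4", 0, 1000, {"C_c": -1, "D_c": 1}),
        ("R6", 0, 1000, {"A_c": -1, "D_c": 1}),
        ("R5", 0, 1000, {"D_c": -1, "E_c": 1}),
        ("EX_E", 0, 1000, {"E_c": -1}),
    ], objective="EX_E")


# ---------------------------------------------------------------------------
# synthetic plant fixture (session-scoped: expensive)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fixture():
    return dfl.end_to_end_fixture(seed=SEED)


@pytest.fixture(scope="session")
def toy_models(fixture):
    return fixture.models


@pytest.fixture(scope="session")
def expr(fixture):
    return ctx.preprocess_expression(fixture.expression, model=fixture.generic)


@pytest.fixture(scope="session")
def berry_context_models(fixture, expr):
    """Green/mature berry context models under the respiration condition."""
    meta = expr.sample_meta
    models = {}
    for stage in ("green", "mature"):
        group = list(meta.index[(meta["tissue"] == "berry")
                                & (meta["stage"] == stage)])
        model = ctx.extract_context_model(
            fixture.models.tissues["green_berry"], expr, group=group)
        cond = make_condition("respiration", photon_exchange="EX_photon_e",
                              sucrose_exchange="EX_sucr_e")
        model = apply_condition(model, cond)
        model.id = f"berry_{stage}"
        models[stage] = model
    return models


@pytest.fixture(scope="session")
def berry_samples(berry_context_models):
    return {
        "green": dfx.achr_sample(berry_context_models["green"], n=2000,
                                 thinning=20, seed=SEED),
        "mature": dfx.achr_sample(berry_context_models["mature"], n=2000,
                                  thinning=20, seed=SEED + 1),
    }


@pytest.fixture(scope="session")
def diel_model(toy_models):
    tissues = {"leaf": toy_models.tissues["leaf"],
               "stem": toy_models.tissues["stem"],
               "green_berry": toy_models.tissues["green_berry"]}
    merged = dl.merge_tissues(tissues)
    model = dl.dielize(merged)
    dl.apply_diel_constraints(model)
    model._merged_reaction_count = len(merged.reactions)
    return model


@pytest.fixture(scope="session")
def diel_solution(diel_model):
    return dl.simulate_diel(diel_model, photon_uptake=300.0,
                            rubisco_pairs=dl.leaf_rubisco_pairs(diel_model))


@pytest.fixture(scope="session")
def ml_dataset(fixture, expr):
    meta = expr.sample_meta
    berry = meta.index[meta["tissue"] == "berry"]
    base = fixture.models.tissues["green_berry"]
    capacities, labels = {}, {}
    for sample in berry:
        model = ctx.extract_context_model(base, expr, group=[sample])
        capacities[sample] = fml.flux_capacity(model)
        labels[sample] = meta.loc[sample, "stage"]
    return fml.build_dataset(capacities, labels)


@pytest.fixture(scope="session")
def ml_report(ml_dataset):
    return fml.evaluate_classifiers(ml_dataset, fml.MLConfig(seed=SEED))


@pytest.fixture(scope="session")
def ml_attribution(ml_report, ml_dataset):
    return fml.shapley_attribution(ml_report, ml_dataset, seed=SEED)
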