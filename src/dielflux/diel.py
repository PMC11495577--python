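"""Diel multi-tissue model assembly and simulation protocols.

Assembly proceeds in three steps:

1. :func:`merge_tissues` — namespace each tissue model
   (``tissue__reaction``), join them through common pools (pool1:
   leaf–stem, pool2: stem–berry) via reversible pool-transfer
   reactions, keep mineral uptake only in the stem (no root tissue is
   modeled) and water/O2/CO2 exchange in every tissue;
2. :func:`dielize` — duplicate every reaction and metabolite into a
   light and a dark phase (``tissue__phase__reaction``) and add storage
   reactions linking the phases: sugars, organic acids, nitrate and
   starch may move in either direction, amino acids only light→dark;
3. :func:`apply_diel_constraints` — photon uptake only through the
   leaf in the light phase, minerals through the stem in both phases,
   and the nitrate light:dark uptake ratio row (3:2).

:func:`simulate_diel` runs the photon-300 photorespiration protocol
(pFBA, Rubisco carboxylation:oxygenation 3:1 in the leaf) and reports
per-tissue storage fluxes (positive = stored in light, used in dark).
:func:`nutrient_scan` varies one nutrient uptake and compares FVA
ranges at >= 80% of each optimum against the baseline.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from cobra.core import Group

from .netcore import BOUND_CAP, FluxState, get_kind, set_kind
from .simulate import (RatioConstraint, add_ratio_constraints, fba, fva,
                       pfba, FVAResult, UnknownReactionError)

logger = logging.getLogger("dielflux")

PHASES = ("light", "dark")

#: the 20 proteinogenic amino acids (base metabolite ids)
AMINO_ACIDS_20 = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)

#: storage metabolites movable in either direction between phases
REVERSIBLE_STORAGE = ("starch", "glucose", "glc", "sucrose", "sucr",
                      "fructose", "fru", "malate", "mal", "citrate", "cit",
                      "nitrate", "no3")


@dataclasses.dataclass(frozen=True)
class PoolSpec:
    """A common pool connecting two tissues."""

    pool_id: str
    member_tissues: tuple[str, str]
    exchanged_metabolites: frozenset[str]

    def __post_init__(self):
        if not self.exchanged_metabolites:
            raise ValueError("exchanged metabolite set must be nonempty")


#: default pool metabolite set: sugar + amino acids + minerals + shuttles
DEFAULT_POOL_METABOLITES = frozenset(
    {"sucr", "glu", "ala", "asp", "gln", "pro", "thr", "cys",
     "no3", "so4", "pi", "pyr"})


def default_pools(berry_tissue: str = "berry") -> list[PoolSpec]:
    return [
        PoolSpec("pool1", ("leaf", "stem"), DEFAULT_POOL_METABOLITES),
        PoolSpec("pool2", ("stem", berry_tissue), DEFAULT_POOL_METABOLITES),
    ]


@dataclasses.dataclass(frozen=True)
class StorageSpec:
    """Which metabolites may cross the light/dark boundary, and how."""

    reversible_metabolites: tuple[str, ...] = REVERSIBLE_STORAGE
    light_to_dark_only: tuple[str, ...] = AMINO_ACIDS_20
    capacity: float = BOUND_CAP

    def __post_init__(self):
        overlap = set(self.reversible_metabolites) & set(self.light_to_dark_only)
        if overlap:
            raise ValueError(f"storage sets overlap: {sorted(overlap)}")


@dataclasses.dataclass
class BiomassCombiner:
    """How tissue and phase biomass fluxes combine into total biomass."""

    tissue_weights: dict[str, float] | None = None
    phase_ratio: float | None = None  # light/dark biomass constraint


# ---------------------------------------------------------------------------
# id helpers
# ---------------------------------------------------------------------------

def diel_id(tissue: str, phase: str, original: str) -> str:
    return f"{tissue}__{phase}__{original}"


def parse_namespace(entity_id: str) -> tuple[str | None, str | None, str]:
    """Split ``tissue__phase__rest`` (phase may be absent) off an id."""
    parts = entity_id.split("__")
    if len(parts) >= 3 and parts[1] in PHASES:
        return parts[0], parts[1], "__".join(parts[2:])
    if len(parts) >= 2:
        return parts[0], None, "__".join(parts[1:])
    return None, None, entity_id


def _find_tissue_metabolite(model: cobra.Model, tissue: str, base: str,
                            phase: str | None = None,
                            compartment_order: Sequence[str] = ("c", "h", "v", "m", "e"),
                            ) -> cobra.Metabolite | None:
    prefix = diel_id(tissue, phase, "") if phase else f"{tissue}__"
    for comp in compartment_order:
        mid = f"{prefix}{base}_{comp}"
        if mid in model.metabolites:
            return model.metabolites.get_by_id(mid)
    return None


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _namespaced_copy(model: cobra.Model, prefix: str) -> cobra.Model:
    out = model.copy()
    for met in out.metabolites:
        met.id = f"{prefix}__{met.id}"
        met.compartment = f"{prefix}_{met.compartment}"
    for rxn in out.reactions:
        rxn.id = f"{prefix}__{rxn.id}"
    out.repair()
    return out


def merge_tissues(
    tissues: Mapping[str, cobra.Model],
    pools: Sequence[PoolSpec] | None = None,
    mineral_bases: Sequence[str] = ("no3", "so4", "pi"),
    mineral_tissue: str = "stem",
    shared_exchange_bases: Sequence[str] = ("h2o", "o2", "co2", "heat", "terp"),
    remove_exchange_bases: Sequence[str] = ("sucr",),
    capacity: float = BOUND_CAP,
) -> cobra.Model:
    """Join namespaced tissue models through common pools.

    Mineral exchanges survive only in ``mineral_tissue`` (the stem
    stands in for the missing root); water/O2/CO2-class exchanges stay
    in every tissue; sucrose exchanges are removed everywhere (sugar
    must travel leaf -> pool -> stem -> pool -> berry); the photon
    exchange is kept in the leaf only. Pool-transfer reactions are
    reversible; a pool metabolite missing from a member tissue is
    skipped with a log entry.
    """
    if pools is None:
        berry = next((t for t in tissues if "berry" in t), "berry")
        pools = default_pools(berry)

    merged = cobra.Model("multi_tissue")
    pathway_members: dict[str, list[str]] = {}
    for tissue, model in tissues.items():
        ns = _namespaced_copy(model, tissue)
        for group in model.groups:
            pathway_members.setdefault(group.id, []).extend(
                f"{tissue}__{m.id}" for m in group.members)
        drop: list[cobra.Reaction] = []
        for rxn in ns.reactions:
            if get_kind(rxn) != "exchange":
                continue
            base = rxn.id.split("__", 1)[1]
            base = base.removeprefix("EX_").rsplit("_", 1)[0]
            if base in remove_exchange_bases:
                drop.append(rxn)
            elif base in mineral_bases and tissue != mineral_tissue:
                drop.append(rxn)
            elif base == "photon" and tissue != "leaf":
                drop.append(rxn)
        ns.remove_reactions(drop, remove_orphans=False)
        merged.add_reactions(list(ns.reactions))

    pool_transfers: list[cobra.Reaction] = []
    for pool in pools:
        for base in sorted(pool.exchanged_metabolites):
            members = []
            for tissue in pool.member_tissues:
                met = _find_tissue_metabolite(merged, tissue, base)
                if met is None:
                    logger.info("merge_tissues: %s missing in %s for %s; "
                                "skipped", base, tissue, pool.pool_id)
                else:
                    members.append((tissue, met))
            if not members:
                continue
            pool_met = cobra.Metabolite(
                f"{pool.pool_id}__{base}", name=f"{base} ({pool.pool_id})",
                formula=members[0][1].formula, charge=members[0][1].charge,
                compartment=pool.pool_id)
            for tissue, met in members:
                tr = cobra.Reaction(
                    f"TR__{tissue}__{pool.pool_id}__{base}",
                    lower_bound=-capacity, upper_bound=capacity)
                tr.add_metabolites({met: -1, pool_met: 1})
                set_kind(tr, "pool-transfer")
                pool_transfers.append(tr)
    merged.add_reactions(pool_transfers)

    groups = []
    for pathway, rxn_ids in pathway_members.items():
        present = [merged.reactions.get_by_id(r) for r in rxn_ids
                   if r in merged.reactions]
        if present:
            g = Group(pathway, name=pathway, members=present)
            g.kind = "partonomy"
            groups.append(g)
    merged.add_groups(groups)

    biomass = [r for r in merged.reactions if get_kind(r) == "biomass"]
    merged.objective = {r: 1.0 for r in biomass}
    merged.compartments = {c: c for c in
                           {m.compartment for m in merged.metabolites}}
    return merged


# ---------------------------------------------------------------------------
# dielization
# ---------------------------------------------------------------------------

def _phase_copy(merged: cobra.Model, phase: str,
                tissues: Iterable[str]) -> cobra.Model:
    tissues = set(tissues)
    out = merged.copy()
    for met in out.metabolites:
        tissue, _, rest = parse_namespace(met.id)
        if tissue in tissues:
            met.id = diel_id(tissue, phase, rest)
        else:
            met.id = f"{met.id}__{phase}"
        met.compartment = f"{met.compartment}__{phase}"
    for rxn in out.reactions:
        tissue, _, rest = parse_namespace(rxn.id)
        if rxn.id.startswith("TR__") or tissue not in tissues:
            rxn.id = f"{rxn.id}__{phase}"
        else:
            rxn.id = diel_id(tissue, phase, rest)
    out.repair()
    return out


def dielize(merged: cobra.Model, storage: StorageSpec | None = None) -> cobra.Model:
    """Duplicate a merged model into light/dark phases plus storage links.

    The output has exactly 2 x (input reactions) + (storage reactions)
    reactions. Storage reactions convert one unit of a metabolite's
    light-phase species into its dark-phase species within a tissue;
    amino-acid storage is irreversible (store in light, use in dark),
    sugar/organic-acid/nitrate/starch storage is reversible.
    """
    storage = storage or StorageSpec()
    tissues = sorted({parse_namespace(r.id)[0] for r in merged.reactions
                      if get_kind(r) == "biomass"})

    diel = cobra.Model("diel_" + merged.id)
    phase_groups: dict[str, list[str]] = {}
    for phase in PHASES:
        ns = _phase_copy(merged, phase, tissues)
        for group in ns.groups:
            phase_groups.setdefault(group.id.split("__")[0], []).extend(
                m.id for m in group.members)
        diel.add_reactions(list(ns.reactions))

    storage_rxns: list[cobra.Reaction] = []
    for tissue in tissues:
        specs = ([(b, True) for b in storage.reversible_metabolites]
                 + [(b, False) for b in storage.light_to_dark_only])
        seen: set[str] = set()
        for base, reversible in specs:
            light = _find_tissue_metabolite(diel, tissue, base, "light")
            dark = _find_tissue_metabolite(diel, tissue, base, "dark")
            if light is None or dark is None:
                logger.info("dielize: storage metabolite %s absent in %s; "
                            "skipped", base, tissue)
                continue
            key = light.id
            if key in seen:
                continue
            seen.add(key)
            rxn = cobra.Reaction(
                f"STORAGE__{tissue}__{base}",
                name=f"{tissue} {base} storage (light->dark)",
                lower_bound=-storage.capacity if reversible else 0.0,
                upper_bound=storage.capacity)
            rxn.add_metabolites({light: -1, dark: 1})
            set_kind(rxn, "storage")
            storage_rxns.append(rxn)
    diel.add_reactions(storage_rxns)

    groups = []
    for pathway, rxn_ids in phase_groups.items():
        members = [diel.reactions.get_by_id(r) for r in rxn_ids
                   if r in diel.reactions]
        if members:
            g = Group(pathway, name=pathway, members=members)
            g.kind = "partonomy"
            groups.append(g)
    diel.add_groups(groups)

    biomass = [r for r in diel.reactions if get_kind(r) == "biomass"]
    diel.objective = {r: 1.0 for r in biomass}
    diel.compartments = {c: c for c in
                         {m.compartment for m in diel.metabolites}}
    return diel


# ---------------------------------------------------------------------------
# diel constraints
# ---------------------------------------------------------------------------

def _exchange_index(model: cobra.Model) -> pd.DataFrame:
    rows = []
    for rxn in model.reactions:
        if get_kind(rxn) != "exchange":
            continue
        tissue, phase, rest = parse_namespace(rxn.id)
        base = rest.removeprefix("EX_").rsplit("_", 1)[0]
        if phase is None and rest.endswith(("__light", "__dark")):
            # non-tissue entities carry the phase as a suffix
            phase = rest.rsplit("__", 1)[1]
            base = rest.removeprefix("EX_").rsplit("__", 1)[0].rsplit("_", 1)[0]
        rows.append(dict(reaction_id=rxn.id, tissue=tissue, phase=phase,
                         base=base))
    return pd.DataFrame(rows)


def apply_diel_constraints(
    model: cobra.Model,
    photon_base: str = "photon",
    mineral_bases: Sequence[str] = ("no3", "so4", "pi"),
    open_bases: Sequence[str] = ("h2o", "o2", "co2"),
    mineral_tissue: str = "stem",
    nitrate_base: str = "no3",
    nitrate_light_dark_ratio: float = 1.5,
    capacity: float = BOUND_CAP,
) -> cobra.Model:
    """Apply the diel exchange policy and the nitrate 3:2 ratio (in place).

    Photon uptake only through the leaf in the light phase; minerals
    through the stem in both phases; water/O2/CO2 open everywhere. The
    nitrate constraint is an equality row v_light = ratio * v_dark on
    the stem nitrate exchange.
    """
    index = _exchange_index(model)
    if index.empty:
        raise UnknownReactionError("model has no exchange reactions")
    for _, row in index.iterrows():
        rxn = model.reactions.get_by_id(row.reaction_id)
        if row.base == photon_base:
            if row.tissue == "leaf" and row.phase == "light":
                rxn.bounds = (-capacity, 0.0)
            else:
                rxn.bounds = (0.0, 0.0)
        elif row.base in mineral_bases:
            if row.tissue == mineral_tissue:
                rxn.bounds = (-capacity, 0.0)
            else:
                rxn.bounds = (0.0, 0.0)
        elif row.base in open_bases:
            rxn.bounds = (-capacity, capacity)

    nitrate = index[(index.base == nitrate_base)
                    & (index.tissue == mineral_tissue)]
    light = nitrate[nitrate.phase == "light"]
    dark = nitrate[nitrate.phase == "dark"]
    if light.empty or dark.empty:
        raise UnknownReactionError(
            f"stem {nitrate_base} exchange absent in a phase")
    add_ratio_constraints(model, [RatioConstraint(
        light.reaction_id.iloc[0], dark.reaction_id.iloc[0],
        nitrate_light_dark_ratio)])
    return model


# ---------------------------------------------------------------------------
# structural audits
# ---------------------------------------------------------------------------

def _entity_scope(met_id: str) -> tuple[str | None, str | None]:
    """(tissue, phase) of a diel metabolite id; pools have tissue None."""
    tissue, phase, _ = parse_namespace(met_id)
    if phase is None and "__" in met_id and met_id.endswith(tuple(PHASES)):
        phase = met_id.rsplit("__", 1)[1]
    if tissue is not None and tissue.startswith("pool"):
        tissue = None
    return tissue, phase


def audit_structure(model: cobra.Model) -> list[str]:
    """Return descriptions of phase/tissue coupling violations."""
    violations = []
    for rxn in model.reactions:
        kind = get_kind(rxn)
        scopes = [_entity_scope(m.id) for m in rxn.metabolites]
        phases = {p for _, p in scopes if p is not None}
        tissues = {t for t, _ in scopes if t is not None}
        if len(phases) > 1 and kind != "storage":
            violations.append(f"{rxn.id} ({kind}) couples phases {phases}")
        if len(tissues) > 1 and kind != "pool-transfer":
            violations.append(f"{rxn.id} ({kind}) couples tissues {tissues}")
    return violations


# ---------------------------------------------------------------------------
# diel simulation protocol
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DielSolution:
    state: FluxState
    storage_report: pd.DataFrame  # tissue, metabolite, reaction, flux
    biomass_report: pd.DataFrame  # tissue, phase, flux

    def storage_to_tsv(self, path) -> None:
        self.storage_report.to_csv(path, sep="\t", index=False)


def storage_report(model: cobra.Model, fluxes: pd.Series) -> pd.DataFrame:
    rows = []
    for rxn in model.reactions:
        if get_kind(rxn) != "storage":
            continue
        _, tissue, base = rxn.id.split("__")
        rows.append(dict(tissue=tissue, metabolite=base, reaction=rxn.id,
                         flux=float(fluxes.get(rxn.id, 0.0))))
    return pd.DataFrame(rows, columns=["tissue", "metabolite", "reaction",
                                       "flux"])


def biomass_report(model: cobra.Model, fluxes: pd.Series) -> pd.DataFrame:
    rows = []
    for rxn in model.reactions:
        if get_kind(rxn) != "biomass":
            continue
        tissue, phase, _ = parse_namespace(rxn.id)
        rows.append(dict(tissue=tissue, phase=phase,
                         flux=float(fluxes.get(rxn.id, 0.0))))
    return pd.DataFrame(rows, columns=["tissue", "phase", "flux"])


def apply_combiner(model: cobra.Model, combiner: BiomassCombiner) -> None:
    biomass = [r for r in model.reactions if get_kind(r) == "biomass"]
    weights = combiner.tissue_weights or {}
    model.objective = {
        r: float(weights.get(parse_namespace(r.id)[0], 1.0)) for r in biomass}
    if combiner.phase_ratio is not None:
        light = sum(r.flux_expression for r in biomass
                    if parse_namespace(r.id)[1] == "light")
        dark = sum(r.flux_expression for r in biomass
                   if parse_namespace(r.id)[1] == "dark")
        row = model.problem.Constraint(
            light - combiner.phase_ratio * dark, lb=0.0, ub=0.0,
            name="phase_biomass_ratio")
        model.add_cons_vars([row])


def simulate_diel(
    model: cobra.Model,
    photon_uptake: float = 300.0,
    photon_exchange: str | None = None,
    rubisco_pairs: Sequence[tuple[str, str]] = (),
    rubisco_ratio: float = 3.0,
    combiner: BiomassCombiner | None = None,
) -> DielSolution:
    """Photon-fixed diel pFBA with the photorespiration ratio in the leaf.

    ``rubisco_pairs`` lists (carboxylation_id, oxygenation_id) per
    phase; pairs whose reactions are absent are skipped. Total biomass
    (per the combiner, default unweighted sum over tissue x phase) is
    maximized, then total flux is minimized.
    """
    if photon_exchange is None:
        idx = _exchange_index(model)
        match = idx[(idx.base == "photon") & (idx.tissue == "leaf")
                    & (idx.phase == "light")]
        if match.empty:
            raise UnknownReactionError("leaf light photon exchange not found")
        photon_exchange = match.reaction_id.iloc[0]
    with model:
        model.reactions.get_by_id(photon_exchange).bounds = (
            -photon_uptake, -photon_uptake)
        pairs = [RatioConstraint(a, b, rubisco_ratio)
                 for a, b in rubisco_pairs
                 if a in model.reactions and b in model.reactions]
        if pairs:
            add_ratio_constraints(model, pairs)
        if combiner is not None:
            apply_combiner(model, combiner)
        state = pfba(model)
    if not state.ok:
        return DielSolution(state, pd.DataFrame(), pd.DataFrame())
    return DielSolution(state,
                        storage_report(model, state.fluxes),
                        biomass_report(model, state.fluxes))


def leaf_rubisco_pairs(model: cobra.Model,
                       carboxylation: str = "RBC_CARB",
                       oxygenation: str = "RBC_OXY") -> list[tuple[str, str]]:
    """Leaf (carboxylation, oxygenation) ids per phase, where present."""
    pairs = []
    for phase in PHASES:
        a = diel_id("leaf", phase, carboxylation)
        b = diel_id("leaf", phase, oxygenation)
        if a in model.reactions and b in model.reactions:
            pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# nutrient scans
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NutrientScanResult:
    exchange: str
    baseline_biomass: float
    baseline_fva: FVAResult
    levels: dict[float, dict]  # level -> {biomass, fva, delta, status}
    pathway_summary: pd.DataFrame

    def to_tsv(self, path) -> None:
        frames = []
        for level, res in self.levels.items():
            if res["status"] != "optimal":
                continue
            df = res["delta"].copy()
            df.insert(0, "level", level)
            frames.append(df.rename_axis("reaction_id").reset_index())
        pd.concat(frames).to_csv(path, sep="\t", index=False)


def nutrient_scan(
    model: cobra.Model,
    exchange: str,
    levels: Sequence[float],
    fva_fraction: float = 0.8,
    reactions: Sequence[str] | None = None,
    mode: str = "cap",
) -> NutrientScanResult:
    """Constrain a nutrient uptake at each level and compare FVA ranges.

    ``mode="cap"`` (default) limits the uptake magnitude to the level;
    ``mode="fix"`` pins the uptake flux at exactly the level, which in a
    minimal network without an overflow sink for the nutrient can be
    infeasible at high levels. Per level: the new total-biomass optimum,
    FVA at >= ``fva_fraction`` of that optimum, per-reaction delta of
    flux_min/flux_max against the unconstrained baseline, and a
    pathway-level aggregation of the span changes. Infeasible levels are
    recorded and the scan continues.
    """
    if mode not in ("cap", "fix"):
        raise ValueError(f"unknown scan mode {mode!r}")
    ex = model.reactions.get_by_id(exchange) if exchange in model.reactions \
        else None
    if ex is None:
        raise UnknownReactionError(f"exchange {exchange!r} not in model")

    base_state = fba(model)
    if not base_state.ok:
        raise RuntimeError("baseline model infeasible")
    base_fva = fva(model, fraction_of_optimum=fva_fraction,
                   reactions=reactions)

    levels_out: dict[float, dict] = {}
    rows = []
    for level in levels:
        with model:
            if mode == "fix":
                ex.bounds = (-level, -level)
            else:
                ex.bounds = (-level, max(ex.upper_bound, 0.0))
            state = fba(model)
            if not state.ok:
                levels_out[level] = dict(status=state.status, biomass=None,
                                         fva=None, delta=None)
                continue
            level_fva = fva(model, fraction_of_optimum=fva_fraction,
                            reactions=reactions)
        delta = pd.DataFrame({
            "baseline_min": base_fva.ranges["flux_min"],
            "baseline_max": base_fva.ranges["flux_max"],
            "level_min": level_fva.ranges["flux_min"],
            "level_max": level_fva.ranges["flux_max"],
        })
        delta["delta_min"] = delta["level_min"] - delta["baseline_min"]
        delta["delta_max"] = delta["level_max"] - delta["baseline_max"]
        delta["delta_span"] = ((delta["level_max"] - delta["level_min"])
                               - (delta["baseline_max"] - delta["baseline_min"]))
        levels_out[level] = dict(status="optimal",
                                 biomass=state.objective_value,
                                 fva=level_fva, delta=delta)
        for group in model.groups:
            members = [m.id for m in group.members if m.id in delta.index]
            if members:
                rows.append(dict(pathway=group.id.split("__")[0], level=level,
                                 mean_delta_span=float(
                                     delta.loc[members, "delta_span"].mean())))
    summary = (pd.DataFrame(rows, columns=["pathway", "level",
                                           "mean_delta_span"])
               .groupby(["pathway", "level"], as_index=False).mean())
    return NutrientScanResult(exchange=exchange,
                              baseline_biomass=base_state.objective_value,
                              baseline_fva=base_fva, levels=levels_out,
                              pathway_summary=summary)
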