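"""Synthetic toy plant network and expression data with planted truth.

The toy network is a compartmentalized (cytosol, chloroplast,
mitochondrion, vacuole, extracellular) plant metabolism of ~65
reactions spanning light reactions, the Calvin cycle, starch and
sucrose turnover, glycolysis, a lumped TCA/oxidative phosphorylation,
nitrate and sulfate assimilation, amino-acid biosynthesis, an
MEP-terpenoid branch and an anthocyanin-like branch. Its chemistry is
artificial but strictly elementally consistent over the reduced
alphabet C,H,O,N,S,P; photons carry a bookkeeping pseudo-element Z that
leaves the system as a dissipated "heat" metabolite, so every enzymatic
reaction passes elemental balancing.

Tissue variants (leaf, stem, green_berry, mature_berry) share the
network and differ in their biomass pseudo-reaction: stem is enriched
in cell-wall precursor, the green berry in organic acids, the mature
berry in sugars plus an anthocyanin-like vacuolar component. Each
biomass reaction carries the growth-associated maintenance ATP cost
(53.26 mmol gDW^-1) and the model has a mandatory non-growth
maintenance ATP hydrolysis flux of 2 mmol gDW^-1 h^-1.

The expression generator draws per-gene baseline log2-TPM levels,
plants group-wise pathway-level shifts, adds replicate noise, and
exports TPM with sample metadata. Everything the planted-recovery
tests need to know is recorded in :class:`PlantedTruth`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping

import cobra
import numpy as np
import pandas as pd
from cobra.core import Group

from .context import ExpressionMatrix, discretize_stage
from .netcore import BOUND_CAP, set_kind

logger = logging.getLogger("dielflux")

GAM_ATP_DEFAULT = 53.26  # mmol gDW^-1 per unit biomass
NGAM_FLUX_DEFAULT = 2.0  # mmol gDW^-1 h^-1 mandatory ATP hydrolysis

PATHWAY_MODULES = (
    "light_reactions", "calvin", "starch", "sucrose", "glycolysis", "tca",
    "amino_acids", "nitrate_assimilation", "sulfate_assimilation",
    "mep_terpenoid", "anthocyanin_like",
)

TISSUES = ("leaf", "stem", "green_berry", "mature_berry")

#: artificial but internally consistent formulas (Z = photon bookkeeping)
FORMULAS = {
    "photon": "Z", "heat": "Z",
    "co2": "CO2", "o2": "O2", "h2o": "H2O",
    "pi": "HO3P", "atp": "C5H7O9P3", "adp": "C5H8O7P2",
    "nadp": "C10H10N2O5", "nadph": "C10H12N2O5",
    "t": "C3H6O3", "glc": "C6H12O6", "fru": "C6H12O6",
    "sucr": "C12H22O11", "starch": "C6H10O5", "cw": "C12H22O11",
    "pyr": "C3H4O3", "mal": "C4H6O5", "cit": "C7H10O8",
    "no3": "HNO3", "nh3": "H3N", "so4": "H2O4S", "h2s": "H2S",
    "glu": "C4H9NO4", "gln": "C4H10N2O3", "asp": "C4H7NO4",
    "ala": "C3H7NO2", "pro": "C4H9NO3", "thr": "C4H7NO3",
    "cys": "C4H9NO3S",
    "acd": "C2H4O", "etoh": "C2H6O",
    "dxp": "C6H10O6", "mep": "C6H12O6", "ipp": "C6H10O5",
    "terp": "C12H20O10",
    "ant1": "C9H16O9", "ant2": "C9H18O9", "anth": "C9H16O8",
}

#: per-tissue biomass substrate coefficients (sum to 1 per tissue)
BIOMASS_TABLES: dict[str, dict[str, float]] = {
    "leaf": {"glc_c": 0.23, "gln_c": 0.02, "cw_c": 0.20, "mal_c": 0.10, "cit_c": 0.05,
             "glu_c": 0.10, "ala_c": 0.08, "pro_c": 0.05, "thr_c": 0.05,
             "cys_c": 0.04, "asp_c": 0.05, "pi_c": 0.03},
    "stem": {"glc_c": 0.16, "gln_c": 0.02, "cw_c": 0.40, "mal_c": 0.06, "cit_c": 0.04,
             "glu_c": 0.08, "ala_c": 0.06, "pro_c": 0.03, "thr_c": 0.04,
             "cys_c": 0.03, "asp_c": 0.04, "pi_c": 0.04},
    "green_berry": {"glc_c": 0.18, "gln_c": 0.02, "cw_c": 0.15, "mal_c": 0.18, "cit_c": 0.12,
                    "glu_c": 0.08, "ala_c": 0.06, "pro_c": 0.05, "thr_c": 0.05,
                    "cys_c": 0.04, "asp_c": 0.04, "pi_c": 0.03},
    "mature_berry": {"glc_c": 0.28, "gln_c": 0.02, "fru_c": 0.10, "cw_c": 0.10, "mal_c": 0.06,
                     "cit_c": 0.04, "glu_c": 0.07, "ala_c": 0.05, "pro_c": 0.04,
                     "thr_c": 0.04, "cys_c": 0.03, "asp_c": 0.04,
                     "anth_v": 0.10, "pi_c": 0.03},
}

#: (id, pathway, lb, ub, stoichiometry {met_id: coeff}) — coeff < 0 consumed
_REACTIONS: list[tuple[str, str, float, float, dict[str, float]]] = [
    # light reactions (chloroplast)
    ("LIGHT_NADPH", "light_reactions", 0, BOUND_CAP,
     {"h2o_h": -2, "nadp_h": -2, "photon_h": -8,
      "o2_h": 1, "nadph_h": 2, "heat_h": 8}),
    ("LIGHT_ATP", "light_reactions", 0, BOUND_CAP,
     {"adp_h": -1, "pi_h": -1, "photon_h": -2,
      "atp_h": 1, "h2o_h": 1, "heat_h": 2}),
    # Calvin cycle: Rubisco carboxylation / oxygenation (lumped)
    ("RBC_CARB", "calvin", 0, BOUND_CAP,
     {"co2_h": -3, "atp_h": -9, "nadph_h": -6, "h2o_h": -6,
      "t_h": 1, "adp_h": 9, "pi_h": 9, "nadp_h": 6}),
    ("RBC_OXY", "calvin", 0, BOUND_CAP,
     {"t_h": -1, "o2_h": -3, "atp_h": -1,
      "co2_h": 3, "adp_h": 1, "pi_h": 1, "h2o_h": 2}),
    # starch turnover (chloroplast)
    ("STARCH_SYN", "starch", 0, BOUND_CAP,
     {"t_h": -2, "atp_h": -1, "starch_h": 1, "adp_h": 1, "pi_h": 1}),
    ("STARCH_DEG", "starch", 0, BOUND_CAP,
     {"starch_h": -1, "h2o_h": -1, "glc_h": 1}),
    # sucrose / carbohydrate metabolism (cytosol)
    ("SUC_SYN", "sucrose", 0, BOUND_CAP,
     {"t_c": -4, "atp_c": -1, "sucr_c": 1, "adp_c": 1, "pi_c": 1}),
    ("INV", "sucrose", 0, BOUND_CAP,
     {"sucr_c": -1, "h2o_c": -1, "glc_c": 1, "fru_c": 1}),
    ("FRU_ISO", "sucrose", -BOUND_CAP, BOUND_CAP, {"fru_c": -1, "glc_c": 1}),
    ("CW_SYN", "sucrose", 0, BOUND_CAP,
     {"glc_c": -2, "atp_c": -1, "cw_c": 1, "adp_c": 1, "pi_c": 1}),
    # glycolysis & pentose phosphate (cytosol)
    ("GLC_CLV", "glycolysis", 0, BOUND_CAP, {"glc_c": -1, "t_c": 2}),
    ("PYK", "glycolysis", 0, BOUND_CAP,
     {"t_c": -1, "nadp_c": -1, "pyr_c": 1, "nadph_c": 1}),
    ("PPP", "glycolysis", 0, BOUND_CAP,
     {"glc_c": -1, "nadp_c": -12, "h2o_c": -6, "co2_c": 6, "nadph_c": 12}),
    # fermentative overflow (pyruvate -> acetaldehyde -> ethanol, exported)
    ("PDC", "glycolysis", 0, BOUND_CAP,
     {"pyr_c": -1, "acd_c": 1, "co2_c": 1}),
    ("ADH", "glycolysis", 0, BOUND_CAP,
     {"acd_c": -1, "nadph_c": -1, "etoh_c": 1, "nadp_c": 1}),
    # TCA-like organic-acid metabolism + respiration (cytosol/mitochondrion)
    ("MAL_SYN", "tca", 0, BOUND_CAP,
     {"pyr_c": -1, "co2_c": -1, "nadph_c": -1, "mal_c": 1, "nadp_c": 1}),
    ("CIT_SYN", "tca", -BOUND_CAP, BOUND_CAP,
     {"mal_c": -1, "pyr_c": -1, "cit_c": 1}),
    ("RESP", "tca", 0, BOUND_CAP,
     {"t_m": -1, "o2_m": -3, "adp_m": -13, "pi_m": -13,
      "co2_m": 3, "atp_m": 13, "h2o_m": 16}),
    # nitrogen and sulfur assimilation (cytosol)
    ("NO3_RED", "nitrate_assimilation", 0, BOUND_CAP,
     {"no3_c": -1, "nadph_c": -4, "nh3_c": 1, "nadp_c": 4, "h2o_c": 3}),
    ("SO4_RED", "sulfate_assimilation", 0, BOUND_CAP,
     {"so4_c": -1, "nadph_c": -4, "h2s_c": 1, "nadp_c": 4, "h2o_c": 4}),
    # amino-acid biosynthesis (cytosol)
    ("GLU_SYN", "amino_acids", 0, BOUND_CAP,
     {"mal_c": -1, "nh3_c": -1, "nadph_c": -1,
      "glu_c": 1, "nadp_c": 1, "h2o_c": 1}),
    ("GLN_SYN", "amino_acids", 0, BOUND_CAP,
     {"glu_c": -1, "nh3_c": -1, "atp_c": -1,
      "gln_c": 1, "adp_c": 1, "pi_c": 1}),
    ("ASP_SYN", "amino_acids", 0, BOUND_CAP,
     {"mal_c": -1, "nh3_c": -1, "asp_c": 1, "h2o_c": 1}),
    ("ALA_SYN", "amino_acids", 0, BOUND_CAP,
     {"pyr_c": -1, "nh3_c": -1, "nadph_c": -1,
      "ala_c": 1, "nadp_c": 1, "h2o_c": 1}),
    ("PRO_SYN", "amino_acids", 0, BOUND_CAP,
     {"glu_c": -1, "nadph_c": -1, "pro_c": 1, "nadp_c": 1, "h2o_c": 1}),
    ("THR_SYN", "amino_acids", 0, BOUND_CAP,
     {"glu_c": -1, "atp_c": -1, "thr_c": 1, "adp_c": 1, "pi_c": 1}),
    ("CYS_SYN", "amino_acids", 0, BOUND_CAP,
     {"glu_c": -1, "h2s_c": -1, "cys_c": 1, "h2o_c": 1}),
    # MEP-like terpenoid branch (cytosol, exported product)
    ("MEP1", "mep_terpenoid", 0, BOUND_CAP,
     {"t_c": -1, "pyr_c": -1, "dxp_c": 1}),
    ("MEP2", "mep_terpenoid", 0, BOUND_CAP,
     {"dxp_c": -1, "nadph_c": -1, "mep_c": 1, "nadp_c": 1}),
    ("MEP3", "mep_terpenoid", 0, BOUND_CAP,
     {"mep_c": -1, "atp_c": -1, "ipp_c": 1, "adp_c": 1, "pi_c": 1}),
    ("MEP4", "mep_terpenoid", 0, BOUND_CAP, {"ipp_c": -2, "terp_c": 1}),
    # anthocyanin-like branch (cytosol -> vacuole)
    ("ANT1", "anthocyanin_like", 0, BOUND_CAP,
     {"t_c": -2, "pyr_c": -1, "ant1_c": 1}),
    ("ANT2", "anthocyanin_like", 0, BOUND_CAP,
     {"ant1_c": -1, "nadph_c": -1, "ant2_c": 1, "nadp_c": 1}),
    ("ANT3", "anthocyanin_like", 0, BOUND_CAP,
     {"ant2_c": -1, "anth_c": 1, "h2o_c": 1}),
]

#: transports: (id, pathway, lb, ub, {met: coeff})
_TRANSPORTS: list[tuple[str, str, float, float, dict[str, float]]] = [
    ("TR_photon_eh", "light_reactions", 0, BOUND_CAP,
     {"photon_e": -1, "photon_h": 1}),
    ("TR_heat_he", "light_reactions", 0, BOUND_CAP,
     {"heat_h": -1, "heat_e": 1}),
    ("TR_co2_ec", "calvin", -BOUND_CAP, BOUND_CAP, {"co2_e": -1, "co2_c": 1}),
    ("TR_o2_ec", "calvin", -BOUND_CAP, BOUND_CAP, {"o2_e": -1, "o2_c": 1}),
    ("TR_h2o_ec", "calvin", -BOUND_CAP, BOUND_CAP, {"h2o_e": -1, "h2o_c": 1}),
    ("TR_co2_ch", "calvin", -BOUND_CAP, BOUND_CAP, {"co2_c": -1, "co2_h": 1}),
    ("TR_o2_ch", "calvin", -BOUND_CAP, BOUND_CAP, {"o2_c": -1, "o2_h": 1}),
    ("TR_h2o_ch", "calvin", -BOUND_CAP, BOUND_CAP, {"h2o_c": -1, "h2o_h": 1}),
    ("TR_co2_cm", "tca", -BOUND_CAP, BOUND_CAP, {"co2_c": -1, "co2_m": 1}),
    ("TR_o2_cm", "tca", -BOUND_CAP, BOUND_CAP, {"o2_c": -1, "o2_m": 1}),
    ("TR_h2o_cm", "tca", -BOUND_CAP, BOUND_CAP, {"h2o_c": -1, "h2o_m": 1}),
    ("TR_t_hc", "calvin", -BOUND_CAP, BOUND_CAP, {"t_h": -1, "t_c": 1}),
    ("TR_glc_hc", "starch", 0, BOUND_CAP, {"glc_h": -1, "glc_c": 1}),
    ("TR_t_cm", "tca", 0, BOUND_CAP, {"t_c": -1, "t_m": 1}),
    ("TR_pi_ec", "glycolysis", -BOUND_CAP, BOUND_CAP, {"pi_e": -1, "pi_c": 1}),
    ("TR_pi_cm", "tca", -BOUND_CAP, BOUND_CAP, {"pi_c": -1, "pi_m": 1}),
    ("ANT_ATP", "tca", -BOUND_CAP, BOUND_CAP,
     {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1}),
    ("TR_no3_ec", "nitrate_assimilation", 0, BOUND_CAP,
     {"no3_e": -1, "no3_c": 1}),
    ("TR_so4_ec", "sulfate_assimilation", 0, BOUND_CAP,
     {"so4_e": -1, "so4_c": 1}),
    ("TR_sucr_ce", "sucrose", -BOUND_CAP, BOUND_CAP,
     {"sucr_c": -1, "sucr_e": 1}),
    ("TR_etoh_ce", "glycolysis", 0, BOUND_CAP, {"etoh_c": -1, "etoh_e": 1}),
    ("TR_terp_ce", "mep_terpenoid", 0, BOUND_CAP, {"terp_c": -1, "terp_e": 1}),
    ("TR_anth_cv", "anthocyanin_like", 0, BOUND_CAP,
     {"anth_c": -1, "anth_v": 1}),
]

#: exchanges: (base, lb, ub, pathway or None); uptake = negative flux
_EXCHANGES: list[tuple[str, float, float, str | None]] = [
    ("photon", -BOUND_CAP, 0, "light_reactions"),
    ("co2", -BOUND_CAP, BOUND_CAP, None),
    ("o2", -BOUND_CAP, BOUND_CAP, None),
    ("h2o", -BOUND_CAP, BOUND_CAP, None),
    ("sucr", -BOUND_CAP, BOUND_CAP, None),
    ("no3", -BOUND_CAP, 0, "nitrate_assimilation"),
    ("so4", -BOUND_CAP, 0, "sulfate_assimilation"),
    ("pi", -BOUND_CAP, 0, None),
    ("heat", 0, BOUND_CAP, "light_reactions"),
    ("etoh", 0, BOUND_CAP, "glycolysis"),
    ("terp", 0, 10.0, "mep_terpenoid"),  # secondary metabolism is low-flux
]

COMPARTMENTS = {"c": "cytosol", "h": "chloroplast", "m": "mitochondrion",
                "v": "vacuole", "e": "extracellular"}

#: mineral nutrient exchange bases (taken up by the stem in diel models)
MINERAL_BASES = ("no3", "so4", "pi")


@dataclasses.dataclass
class ToyModelConfig:
    """Configuration of the toy plant network generator."""

    included_pathway_modules: tuple[str, ...] = PATHWAY_MODULES
    tissues: tuple[str, ...] = TISSUES
    biomass_tables: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: BIOMASS_TABLES)
    gam_atp: float = GAM_ATP_DEFAULT
    ngam_flux: float = NGAM_FLUX_DEFAULT
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.included_pathway_modules) - set(PATHWAY_MODULES)
        if unknown:
            raise ValueError(f"unknown pathway modules: {sorted(unknown)}")
        # carbon can enter via Calvin-cycle CO2 fixation or sucrose uptake
        if ("calvin" not in self.included_pathway_modules
                and "sucrose" not in self.included_pathway_modules):
            raise ValueError("config excludes both carbon-entry modules "
                             "(calvin and sucrose)")
        for tissue, table in self.biomass_tables.items():
            coeffs = np.array(list(table.values()), float)
            if (coeffs <= 0).any():
                raise ValueError(f"{tissue}: biomass coefficients must be > 0")
            if abs(coeffs.sum() - 1.0) > 1e-6:
                raise ValueError(f"{tissue}: biomass coefficients must sum "
                                 f"to 1 (got {coeffs.sum():.4f})")


@dataclasses.dataclass
class ToyModels:
    """The generic network plus tissue-specific biomass variants."""

    generic: cobra.Model
    tissues: dict[str, cobra.Model]
    config: ToyModelConfig


def _metabolite(met_id: str) -> cobra.Metabolite:
    base, comp = met_id.rsplit("_", 1)
    return cobra.Metabolite(met_id, formula=FORMULAS[base], charge=0,
                            name=base, compartment=comp)


def _gpr_for(rxn_id: str, index: int) -> str:
    mode = index % 3
    if mode == 0:
        return f"g_{rxn_id}_1"
    if mode == 1:  # isozymes
        return f"g_{rxn_id}_1 or g_{rxn_id}_2"
    return f"g_{rxn_id}_1 and g_{rxn_id}_2"  # complex


def make_toy_plant_model(config: ToyModelConfig | None = None) -> ToyModels:
    """Build the generic toy network and its tissue biomass variants.

    The generic model carries all four tissue biomass pseudo-reactions
    (objective: leaf); each tissue variant keeps only its own.
    """
    config = config or ToyModelConfig()
    modules = set(config.included_pathway_modules)

    model = cobra.Model("toyplant_generic")
    model.compartments = dict(COMPARTMENTS)
    mets: dict[str, cobra.Metabolite] = {}

    def get_met(met_id: str) -> cobra.Metabolite:
        if met_id not in mets:
            mets[met_id] = _metabolite(met_id)
        return mets[met_id]

    reactions: list[cobra.Reaction] = []
    pathway_members: dict[str, list[cobra.Reaction]] = {
        m: [] for m in PATHWAY_MODULES}
    gene_index = 0
    for rid, pathway, lb, ub, stoich in _REACTIONS + _TRANSPORTS:
        if pathway not in modules:
            continue
        rxn = cobra.Reaction(rid, name=rid, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites({get_met(m): c for m, c in stoich.items()})
        rxn.gene_reaction_rule = _gpr_for(rid, gene_index)
        gene_index += 1
        kind = "transport" if rid.startswith(("TR_", "ANT_ATP")) else "metabolic"
        set_kind(rxn, kind)
        reactions.append(rxn)
        pathway_members[pathway].append(rxn)

    needed_mets = {m for r in reactions for m in r.metabolites}
    for base, lb, ub, pathway in _EXCHANGES:
        met = mets.get(f"{base}_e")
        if met is None or met not in needed_mets:
            continue
        ex = cobra.Reaction(f"EX_{base}_e", name=f"{base} exchange",
                            lower_bound=lb, upper_bound=ub)
        ex.add_metabolites({met: -1})
        set_kind(ex, "exchange")
        reactions.append(ex)
        if pathway in modules:
            pathway_members[pathway].append(ex)

    ngam = cobra.Reaction("NGAM", name="non-growth maintenance ATP hydrolysis",
                          lower_bound=config.ngam_flux,
                          upper_bound=config.ngam_flux)
    ngam.add_metabolites({get_met("atp_c"): -1, get_met("h2o_c"): -1,
                          get_met("adp_c"): 1, get_met("pi_c"): 1})
    set_kind(ngam, "maintenance")
    reactions.append(ngam)

    biomass_rxns: dict[str, cobra.Reaction] = {}
    for tissue in config.tissues:
        table = config.biomass_tables[tissue]
        rxn = cobra.Reaction(f"biomass_{tissue}", name=f"{tissue} biomass",
                             lower_bound=0, upper_bound=BOUND_CAP)
        stoich: dict[cobra.Metabolite, float] = {
            get_met(met_id): -coeff for met_id, coeff in table.items()}
        # growth-associated maintenance ATP
        stoich[get_met("atp_c")] = stoich.get(get_met("atp_c"), 0) - config.gam_atp
        stoich[get_met("h2o_c")] = stoich.get(get_met("h2o_c"), 0) - config.gam_atp
        stoich[get_met("adp_c")] = stoich.get(get_met("adp_c"), 0) + config.gam_atp
        stoich[get_met("pi_c")] = stoich.get(get_met("pi_c"), 0) + config.gam_atp
        rxn.add_metabolites(stoich)
        set_kind(rxn, "biomass")
        biomass_rxns[tissue] = rxn
        reactions.append(rxn)

    model.add_reactions(reactions)
    groups = []
    for pathway, members in pathway_members.items():
        if members:
            g = Group(pathway, name=pathway, members=members)
            g.kind = "partonomy"
            groups.append(g)
    model.add_groups(groups)
    model.objective = biomass_rxns[config.tissues[0]]

    tissue_models: dict[str, cobra.Model] = {}
    for tissue in config.tissues:
        variant = model.copy()
        variant.id = f"toyplant_{tissue}"
        drop = [variant.reactions.get_by_id(f"biomass_{t}")
                for t in config.tissues if t != tissue]
        variant.remove_reactions(drop, remove_orphans=True)
        variant.objective = variant.reactions.get_by_id(f"biomass_{tissue}")
        tissue_models[tissue] = variant
    return ToyModels(generic=model, tissues=tissue_models, config=config)


def pathway_map(model: cobra.Model) -> dict[str, set[str]]:
    """Pathway -> reaction-id sets from the model's SBML groups."""
    return {g.id: {m.id for m in g.members} for g in model.groups}


def module_genes(model: cobra.Model, module: str) -> set[str]:
    genes: set[str] = set()
    for group in model.groups:
        if group.id == module:
            for rxn in group.members:
                genes |= {g.id for g in rxn.genes}
    return genes


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroupSpec:
    """One biological condition in the simulated expression design."""

    tissue: str
    time_point: int | None = None
    n_samples: int = 3
    n_replicates: int = 2

    @property
    def stage(self) -> str:
        if self.time_point is None:
            return "na"
        return discretize_stage(self.time_point)


def default_groups() -> list[GroupSpec]:
    """Leaf and stem conditions plus an 8-time-point berry course."""
    groups = [GroupSpec("leaf", None, 3, 2), GroupSpec("stem", None, 3, 2)]
    groups += [GroupSpec("berry", tp, 4, 2) for tp in range(1, 9)]
    return groups


#: planted pathway-level log2 shifts per (tissue, stage)
DEFAULT_PLANTED_EFFECTS: dict[tuple[str, str], dict[str, float]] = {
    ("leaf", "na"): {"light_reactions": 3.0, "calvin": 3.0, "starch": 3.0},
    ("berry", "green"): {"mep_terpenoid": -6.0, "anthocyanin_like": -6.0},
    ("berry", "mature"): {"mep_terpenoid": 3.0, "anthocyanin_like": 3.0},
}


@dataclasses.dataclass
class ExpressionSimConfig:
    """Design and noise model of the synthetic expression data."""

    groups: list[GroupSpec] = dataclasses.field(default_factory=default_groups)
    planted_effects: dict[tuple[str, str], dict[str, float]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_PLANTED_EFFECTS.items()})
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0


@dataclasses.dataclass
class PlantedTruth:
    """Generator-side record of what was planted, for recovery checks."""

    effects: dict[tuple[str, str], dict[str, float]]
    module_genes: dict[str, set[str]]
    module_reactions: dict[str, set[str]]

    def planted_modules(self, key: tuple[str, str]) -> dict[str, float]:
        return self.effects.get(key, {})

    def differential_modules(self, key_a: tuple[str, str],
                             key_b: tuple[str, str]) -> set[str]:
        """Modules whose planted effect differs between two groups."""
        a, b = self.effects.get(key_a, {}), self.effects.get(key_b, {})
        return {m for m in set(a) | set(b)
                if a.get(m, 0.0) != b.get(m, 0.0)}

    def to_json(self, path) -> None:
        payload = {
            "effects": {f"{t}|{s}": eff for (t, s), eff in self.effects.items()},
            "module_genes": {m: sorted(g) for m, g in self.module_genes.items()},
            "module_reactions": {m: sorted(r)
                                 for m, r in self.module_reactions.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def make_expression_data(
    model: cobra.Model,
    config: ExpressionSimConfig | None = None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate a TPM matrix with planted pathway shifts.

    Baseline log2-TPM per gene ~ Normal(baseline_mean, baseline_sd);
    planted module effects are added per (tissue, stage) group; replicate
    noise ~ Normal(0, noise_sd); values clip at 0 and export as
    TPM = 2^log2 - 1 so the preprocessing log2(x+1) round-trips.
    """
    config = config or ExpressionSimConfig()
    genes = sorted(g.id for g in model.genes)
    if not genes:
        raise ValueError("model has no genes")
    mod_genes = {m: module_genes(model, m) for m in PATHWAY_MODULES}
    mod_rxns = pathway_map(model)
    for key, effects in config.planted_effects.items():
        for module in effects:
            if not mod_genes.get(module):
                raise ValueError(
                    f"planted effect on module {module!r} absent from model")

    rng = np.random.default_rng(config.seed)
    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, len(genes)),
        index=genes)

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for spec in config.groups:
        effects = config.planted_effects.get((spec.tissue, spec.stage), {})
        shift = pd.Series(0.0, index=baseline.index)
        for module, delta in effects.items():
            shift[list(mod_genes[module] & set(genes))] += delta
        for s in range(1, spec.n_samples + 1):
            tp = "" if spec.time_point is None else f"_t{spec.time_point}"
            bio_id = f"{spec.tissue}{tp}_s{s}"
            for r in range(1, spec.n_replicates + 1):
                col = f"{bio_id}_r{r}"
                log2 = (baseline + shift
                        + rng.normal(0.0, config.noise_sd, len(genes)))
                columns[col] = np.clip(log2.to_numpy(), 0.0, None)
                meta_rows.append(dict(
                    sample_id=col, tissue=spec.tissue,
                    time_point=spec.time_point, stage=spec.stage,
                    replicate_group=bio_id, cultivar="toy"))

    log2_values = pd.DataFrame(columns, index=baseline.index)
    tpm = np.power(2.0, log2_values) - 1.0
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    expr = ExpressionMatrix(values=tpm, sample_meta=meta)
    truth = PlantedTruth(effects={k: dict(v) for k, v in
                                  config.planted_effects.items()},
                         module_genes=mod_genes,
                         module_reactions={m: set(r)
                                           for m, r in mod_rxns.items()})
    return expr, truth


# ---------------------------------------------------------------------------
# one-call fixture
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EndToEndFixture:
    """Everything the pipeline stages need, from a single seed."""

    models: ToyModels
    expression: ExpressionMatrix  # raw TPM
    truth: PlantedTruth
    seed: int

    @property
    def generic(self) -> cobra.Model:
        return self.models.generic


def end_to_end_fixture(seed: int = 0) -> EndToEndFixture:
    models = make_toy_plant_model(ToyModelConfig(seed=seed))
    expr, truth = make_expression_data(
        models.generic, ExpressionSimConfig(seed=seed))
    return EndToEndFixture(models=models, expression=expr, truth=truth,
                           seed=seed)
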