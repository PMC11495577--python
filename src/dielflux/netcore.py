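"""Core constraint-based model layer.

Models are held as :class:`cobra.Model` objects (the field's canonical
container), with a thin layer on top providing

* SBML (Level 3 + fbc) read/write with validation of flux bounds,
* a reaction *kind* taxonomy (metabolic, transport, exchange, biomass,
  storage, pool-transfer, maintenance) used throughout the pipeline,
* elemental mass / charge balance auditing,
* reversibility splitting (v = v+ - v-),
* evaluation of gene-protein-reaction (GPR) boolean rules against
  numeric per-gene values.

Sign convention: uptake is a *negative* exchange flux; presentation
layers negate where uptake tables are reported as positive numbers.
"""

from __future__ import annotations

import ast
import dataclasses
import logging
from pathlib import Path
from typing import Callable, Iterable, Mapping

import cobra
import cobra.io
import numpy as np
import pandas as pd
from cobra.core.gene import GPR
from cobra.util.array import create_stoichiometric_matrix

logger = logging.getLogger("dielflux")

#: absolute tolerance for comparing fluxes (mmol gDW^-1 h^-1)
FLUX_TOL = 1e-6
#: LP feasibility tolerance
FEAS_TOL = 1e-9
#: default bound magnitude for effectively unbounded reactions
BOUND_CAP = 1000.0

#: valid reaction kinds
KINDS = (
    "metabolic",
    "transport",
    "exchange",
    "biomass",
    "storage",
    "pool-transfer",
    "maintenance",
)

#: pseudo-reaction kinds exempt from elemental balancing
BALANCE_EXEMPT_KINDS = frozenset(
    {"exchange", "biomass", "storage", "pool-transfer", "maintenance"}
)

_KIND_KEY = "dielflux_kind"


class ModelValidationError(ValueError):
    """A model violates a structural invariant (for example lb > ub)."""


class GPRMissingValueError(KeyError):
    """A GPR leaf has no value and no default was declared."""

    def __init__(self, missing: Iterable[str]):
        self.missing = sorted(missing)
        super().__init__(f"no value for gene(s): {', '.join(self.missing)}")


# ---------------------------------------------------------------------------
# reaction kinds
# ---------------------------------------------------------------------------

def set_kind(reaction: cobra.Reaction, kind: str) -> None:
    if kind not in KINDS:
        raise ValueError(f"unknown reaction kind {kind!r}")
    reaction.annotation[_KIND_KEY] = kind


def get_kind(reaction: cobra.Reaction) -> str:
    """Return the reaction's kind, inferring one when not annotated.

    Inference: a boundary reaction touching exactly one metabolite is an
    exchange; a reaction spanning more than one compartment is a
    transport; anything else is metabolic.
    """
    kind = reaction.annotation.get(_KIND_KEY)
    if kind in KINDS:
        return kind
    if len(reaction.metabolites) == 1:
        return "exchange"
    if len(reaction.compartments) > 1:
        return "transport"
    return "metabolic"


def annotate_kinds(model: cobra.Model) -> None:
    """Persist inferred kinds on every reaction lacking an annotation."""
    for rxn in model.reactions:
        set_kind(rxn, get_kind(rxn))


# ---------------------------------------------------------------------------
# flux state
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FluxState:
    """A solved flux distribution.

    fluxes are in mmol gDW^-1 h^-1 (biomass pseudo-flux in h^-1);
    ``status`` is one of optimal / infeasible / unbounded.
    """

    fluxes: pd.Series
    objective_value: float | None
    status: str

    @classmethod
    def from_solution(cls, solution: "cobra.Solution") -> "FluxState":
        status = solution.status
        if status not in ("optimal", "infeasible", "unbounded"):
            status = "infeasible"
        if status != "optimal":
            return cls(fluxes=pd.Series(dtype=float), objective_value=None,
                       status=status)
        return cls(fluxes=solution.fluxes.copy(),
                   objective_value=float(solution.objective_value),
                   status="optimal")

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path: str | Path) -> None:
        df = self.fluxes.rename("flux").rename_axis("reaction_id").reset_index()
        df.to_csv(path, sep="\t", index=False)


def steady_state_residual(model: cobra.Model, fluxes: pd.Series) -> float:
    """Infinity norm of S.v for a candidate flux vector."""
    S = create_stoichiometric_matrix(model)
    v = fluxes.reindex([r.id for r in model.reactions]).fillna(0.0).to_numpy()
    return float(np.abs(S @ v).max()) if S.size else 0.0


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

def validate_model(model: cobra.Model) -> None:
    """Check structural invariants; raise ModelValidationError on failure."""
    seen: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in seen:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        seen.add(rxn.id)
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
    met_ids = {m.id for m in model.metabolites}
    if len(met_ids) != len(model.metabolites):
        raise ModelValidationError("duplicate metabolite ids")
    compartments = set(model.compartments) | {m.compartment for m in model.metabolites}
    for met in model.metabolites:
        if met.compartment and met.compartment not in compartments:
            raise ModelValidationError(
                f"metabolite {met.id!r}: unknown compartment {met.compartment!r}"
            )


def read_model(path: str | Path) -> cobra.Model:
    """Read an SBML Level 3 (fbc) model, validate it, annotate kinds."""
    path = Path(path)
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises many concrete types
        raise ModelValidationError(f"cannot parse SBML file {path}: {exc}") from exc
    validate_model(model)
    annotate_kinds(model)
    return model


def write_model(model: cobra.Model, path: str | Path) -> None:
    annotate_kinds(model)
    path = Path(path)
    cobra.io.write_sbml_model(model, str(path))
    _canonicalize_group_members(path)


def _canonicalize_group_members(path: Path) -> None:
    """Sort SBML group member lists (stored unordered in memory) so that
    identical models serialize to byte-identical files."""
    import re

    text = path.read_text()

    def sort_block(match: "re.Match[str]") -> str:
        head, body, tail = match.group(1), match.group(2), match.group(3)
        members = re.findall(r"\s*<groups:member[^>]*/>", body)
        return head + "".join(sorted(members)) + tail

    new = re.sub(
        r"(<groups:listOfMembers>)(.*?)(\s*</groups:listOfMembers>)",
        sort_block, text, flags=re.S)
    if new != text:
        path.write_text(new)


def write_model_json(model: cobra.Model, path: str | Path) -> None:
    """Debug dump in cobra's JSON schema."""
    cobra.io.save_json_model(model, str(Path(path)))


# ---------------------------------------------------------------------------
# mass / charge balance
# ---------------------------------------------------------------------------

def check_mass_charge_balance(model: cobra.Model) -> pd.DataFrame:
    """Audit elemental and charge balance of every chemical reaction.

    Pseudo-reactions (exchange, biomass, storage, pool-transfer,
    maintenance) are reported as exempt; reactions whose participants
    lack formulas are reported as unverifiable. Returns a long-format
    frame with columns reaction_id, status, element, net, charge_net,
    flag — one row per imbalanced element, plus a single summary row for
    balanced / exempt / unverifiable reactions.
    """
    rows: list[dict] = []
    for rxn in model.reactions:
        kind = get_kind(rxn)
        if kind in BALANCE_EXEMPT_KINDS:
            rows.append(dict(reaction_id=rxn.id, status="exempt", element="",
                             net=0.0, charge_net=0.0, flag=False))
            continue
        missing = [m.id for m in rxn.metabolites if not m.formula]
        if missing:
            rows.append(dict(reaction_id=rxn.id, status="unverifiable",
                             element="", net=0.0, charge_net=0.0, flag=False))
            continue
        imbalance = rxn.check_mass_balance()
        charge_net = float(imbalance.pop("charge", 0.0))
        elements = {e: float(n) for e, n in imbalance.items() if abs(n) > 1e-9}
        if abs(charge_net) <= 1e-9:
            charge_net = 0.0
        if not elements and charge_net == 0.0:
            rows.append(dict(reaction_id=rxn.id, status="balanced", element="",
                             net=0.0, charge_net=0.0, flag=False))
        else:
            for element, net in sorted(elements.items()):
                rows.append(dict(reaction_id=rxn.id, status="imbalanced",
                                 element=element, net=net,
                                 charge_net=charge_net, flag=True))
            if not elements:
                rows.append(dict(reaction_id=rxn.id, status="imbalanced",
                                 element="", net=0.0, charge_net=charge_net,
                                 flag=True))
    return pd.DataFrame(rows, columns=["reaction_id", "status", "element",
                                       "net", "charge_net", "flag"])


def balance_report_to_tsv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reversibility splitting
# ---------------------------------------------------------------------------

def split_reversible(model: cobra.Model) -> tuple[cobra.Model, dict[str, dict[str, str]]]:
    """Split every reversible reaction into irreversible forward/reverse copies.

    Returns the split model and a map ``{original_id: {"forward": fid,
    "reverse": rid}}`` (reverse key present only when a reverse copy was
    created). Feasible flux sets are in bijection via v = v+ - v-.
    """
    split = model.copy()
    id_map: dict[str, dict[str, str]] = {}
    new_reactions = []
    for rxn in split.reactions:
        entry = {"forward": rxn.id}
        if rxn.lower_bound < 0:
            rev = cobra.Reaction(
                id=rxn.id + "_rev",
                name=(rxn.name or rxn.id) + " (reverse)",
                lower_bound=max(0.0, -rxn.upper_bound),
                upper_bound=-rxn.lower_bound,
            )
            rev.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
            if rxn.gene_reaction_rule:
                rev.gene_reaction_rule = rxn.gene_reaction_rule
            rev.annotation = dict(rxn.annotation)
            new_reactions.append(rev)
            entry["reverse"] = rev.id
            rxn.bounds = (0.0, max(0.0, rxn.upper_bound))
        id_map[rxn.id] = entry
    if new_reactions:
        split.add_reactions(new_reactions)
    return split, id_map


# ---------------------------------------------------------------------------
# GPR evaluation
# ---------------------------------------------------------------------------

def parse_gpr(rule: str | GPR) -> GPR:
    """Parse a GPR rule string (and/or, any case, parentheses)."""
    if isinstance(rule, GPR):
        return rule
    gpr = GPR.from_string(str(rule))
    if not gpr.genes:
        raise ValueError(f"GPR rule {rule!r} has no gene leaves")
    return gpr


def evaluate_gpr(
    gpr: str | GPR,
    values: Mapping[str, float],
    and_rule: Callable[[Iterable[float]], float] = min,
    or_rule: Callable[[Iterable[float]], float] = max,
    default: float | None = None,
) -> float:
    """Evaluate a GPR boolean tree against numeric per-gene values.

    AND nodes aggregate with ``and_rule`` (default min: a complex is
    limited by its scarcest subunit), OR nodes with ``or_rule`` (default
    max: isozymes are interchangeable). A leaf without a value falls
    back to ``default``; with ``default=None`` missing leaves raise
    :class:`GPRMissingValueError` listing every absent gene.
    """
    gpr = parse_gpr(gpr)
    missing = [g for g in gpr.genes if g not in values]
    if missing and default is None:
        raise GPRMissingValueError(missing)

    def walk(node: ast.AST) -> float:
        if isinstance(node, ast.Name):
            return float(values.get(node.id, default))
        if isinstance(node, ast.BoolOp):
            agg = and_rule if isinstance(node.op, ast.And) else or_rule
            return float(agg([walk(v) for v in node.values]))
        raise ValueError(f"unsupported GPR node {type(node).__name__}")

    body = gpr.body if hasattr(gpr, "body") else None
    if not body:
        raise ValueError("empty GPR")
    return walk(body)
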