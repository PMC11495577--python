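"""Linear-programming phenotype prediction.

FBA, parsimonious FBA and FVA (delegated to cobra's LP layer), plus the
condition protocols used throughout the pipeline:

* *photosynthesis* — photoautotrophic: photon and CO2 uptake open,
  sucrose uptake closed;
* *photorespiration* — photosynthesis plus a fixed Rubisco
  carboxylation:oxygenation flux ratio (3:1 by default);
* *respiration* — heterotrophic: photon closed, sucrose uptake open.

Flux-ratio constraints (3:1 Rubisco, 3:2 diel nitrate) are added as
auxiliary equality rows v_a - ratio * v_b = 0 in the LP, so they hold
exactly in every returned solution.

Two named prediction strategies:

* :func:`strategy_min_uptake` — fix the growth rate (0.11 h^-1 by
  default) and minimize photon/sucrose uptake, then minimize total flux;
* :func:`strategy_max_biomass` — fix the driver uptake (photon 100 or
  300, sucrose 1) and maximize growth, then apply pFBA.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import cobra
import cobra.flux_analysis
import pandas as pd

from .netcore import BOUND_CAP, FluxState

#: residual tolerance on ratio-constraint rows
RATIO_TOL = 1e-9


class UnknownReactionError(KeyError):
    """A condition or constraint references a reaction id not in the model."""


@dataclasses.dataclass(frozen=True)
class RatioConstraint:
    """Equality v_a = ratio * v_b between two reaction fluxes."""

    reaction_a: str
    reaction_b: str
    ratio: float

    def __post_init__(self):
        if not self.ratio > 0:
            raise ValueError("ratio must be positive")


@dataclasses.dataclass
class ConditionSpec:
    """A named simulation condition: bound overrides, fixed fluxes, ratios."""

    name: str
    fixed_fluxes: dict[str, float] = dataclasses.field(default_factory=dict)
    bound_overrides: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict)
    ratio_constraints: list[RatioConstraint] = dataclasses.field(
        default_factory=list)


@dataclasses.dataclass
class FVAResult:
    """Per-reaction flux min/max at a given fraction of the optimum."""

    ranges: pd.DataFrame  # index reaction_id, columns flux_min, flux_max
    fraction_of_optimum: float

    def to_tsv(self, path) -> None:
        self.ranges.rename_axis("reaction_id").reset_index().to_csv(
            path, sep="\t", index=False)

    def span(self) -> pd.Series:
        return self.ranges["flux_max"] - self.ranges["flux_min"]


def _require(model: cobra.Model, reaction_id: str) -> cobra.Reaction:
    try:
        return model.reactions.get_by_id(reaction_id)
    except KeyError as exc:
        raise UnknownReactionError(
            f"reaction {reaction_id!r} not in model {model.id!r}") from exc


def add_ratio_constraints(model: cobra.Model,
                          constraints: Sequence[RatioConstraint]) -> None:
    """Attach v_a - ratio*v_b = 0 rows to the model's LP (in place)."""
    rows = []
    for rc in constraints:
        ra = _require(model, rc.reaction_a)
        rb = _require(model, rc.reaction_b)
        row = model.problem.Constraint(
            ra.flux_expression - rc.ratio * rb.flux_expression,
            lb=0.0, ub=0.0, name=f"ratio__{rc.reaction_a}__{rc.reaction_b}")
        rows.append(row)
    model.add_cons_vars(rows)


def _set_objective(model: cobra.Model, objective: str | None,
                   sense: str = "max") -> None:
    if objective is not None:
        model.objective = _require(model, objective)
    model.objective_direction = sense


def objective_flux(model: cobra.Model, fluxes: pd.Series) -> float:
    """Value of the model's linear objective under a flux vector."""
    coeffs = {r.id: c for r, c in
              cobra.util.solver.linear_reaction_coefficients(model).items()}
    return float(sum(c * fluxes.get(rid, 0.0) for rid, c in coeffs.items()))


def fba(model: cobra.Model, objective: str | None = None,
        sense: str = "max") -> FluxState:
    """Flux balance analysis; never raises on infeasibility."""
    with model:
        _set_objective(model, objective, sense)
        solution = model.optimize(raise_error=False)
        return FluxState.from_solution(solution)


def pfba(model: cobra.Model, objective: str | None = None,
         fraction_of_optimum: float = 1.0,
         fixed_value: float | None = None) -> FluxState:
    """Parsimonious FBA: attain the objective target, then minimize sum |v|.

    ``objective_value`` of the result is the achieved value of the
    *original* objective, not the minimized total flux.
    """
    with model:
        _set_objective(model, objective, "max")
        if fixed_value is not None:
            for rxn in cobra.util.solver.linear_reaction_coefficients(model):
                rxn.bounds = (fixed_value, fixed_value)
            fraction_of_optimum = 1.0
        try:
            solution = cobra.flux_analysis.pfba(
                model, fraction_of_optimum=fraction_of_optimum)
        except Exception:
            return FluxState(pd.Series(dtype=float), None, "infeasible")
        obj = objective_flux(model, solution.fluxes)
        return FluxState(solution.fluxes.copy(), obj, "optimal")


def fva(model: cobra.Model, objective: str | None = None,
        fraction_of_optimum: float = 1.0,
        reactions: Sequence[str] | None = None) -> FVAResult:
    """Flux variability analysis at >= fraction of the objective optimum."""
    with model:
        if objective is not None:
            _set_objective(model, objective, "max")
        rxns = None if reactions is None else [
            _require(model, r) for r in reactions]
        try:
            df = cobra.flux_analysis.flux_variability_analysis(
                model, reaction_list=rxns,
                fraction_of_optimum=fraction_of_optimum, loopless=None)
        except Exception as exc:
            raise RuntimeError(f"FVA failed (infeasible model?): {exc}") from exc
    df = df.rename(columns={"minimum": "flux_min", "maximum": "flux_max"})
    # clip solver jitter so flux_min <= flux_max holds exactly
    bad = df["flux_min"] > df["flux_max"]
    if bad.any():
        mid = df.loc[bad].mean(axis=1)
        df.loc[bad, "flux_min"] = mid
        df.loc[bad, "flux_max"] = mid
    return FVAResult(ranges=df[["flux_min", "flux_max"]],
                     fraction_of_optimum=fraction_of_optimum)


# ---------------------------------------------------------------------------
# condition protocols
# ---------------------------------------------------------------------------

def make_condition(name: str, *, photon_exchange: str, sucrose_exchange: str,
                   co2_exchange: str | None = None,
                   carboxylation: str | None = None,
                   oxygenation: str | None = None,
                   rubisco_ratio: float = 3.0,
                   uptake_cap: float = BOUND_CAP) -> ConditionSpec:
    """Build one of the named condition protocols from exchange ids."""
    spec = ConditionSpec(name=name)
    if name in ("photosynthesis", "photorespiration"):
        spec.bound_overrides[sucrose_exchange] = (0.0, uptake_cap)
        spec.bound_overrides[photon_exchange] = (-uptake_cap, 0.0)
        if co2_exchange is not None:
            spec.bound_overrides[co2_exchange] = (-uptake_cap, uptake_cap)
        if name == "photorespiration":
            if carboxylation is None or oxygenation is None:
                raise ValueError(
                    "photorespiration requires carboxylation and oxygenation ids")
            spec.ratio_constraints.append(
                RatioConstraint(carboxylation, oxygenation, rubisco_ratio))
    elif name == "respiration":
        spec.bound_overrides[photon_exchange] = (0.0, 0.0)
        spec.bound_overrides[sucrose_exchange] = (-uptake_cap, uptake_cap)
    else:
        raise ValueError(f"unknown condition {name!r}")
    return spec


def apply_condition(model: cobra.Model, spec: ConditionSpec) -> cobra.Model:
    """Return a copy of the model constrained to the condition."""
    out = model.copy()
    for rid, bounds in spec.bound_overrides.items():
        _require(out, rid).bounds = bounds
    for rid, value in spec.fixed_fluxes.items():
        _require(out, rid).bounds = (value, value)
    if spec.ratio_constraints:
        add_ratio_constraints(out, spec.ratio_constraints)
    return out


# ---------------------------------------------------------------------------
# prediction strategies
# ---------------------------------------------------------------------------

def strategy_min_uptake(model: cobra.Model, uptake_reaction: str,
                        biomass_reaction: str | None = None,
                        biomass_value: float = 0.11) -> FluxState:
    """Fix growth and minimize the magnitude of a nutrient uptake.

    The growth rate is pinned at ``biomass_value`` (0.11 h^-1 by
    default), the uptake exchange flux is maximized (uptake is negative,
    so this minimizes its magnitude), then total flux is minimized at
    the optimal uptake as a parsimony tie-break. ``objective_value`` is
    the uptake magnitude (positive).
    """
    with model:
        if biomass_reaction is not None:
            model.objective = _require(model, biomass_reaction)
        for rxn in cobra.util.solver.linear_reaction_coefficients(model):
            rxn.bounds = (biomass_value, biomass_value)
        uptake = _require(model, uptake_reaction)
        model.objective = uptake
        model.objective_direction = "max"
        first = model.optimize(raise_error=False)
        if first.status != "optimal":
            return FluxState(pd.Series(dtype=float), None, first.status
                             if first.status in ("infeasible", "unbounded")
                             else "infeasible")
        best = float(first.objective_value)
        uptake.bounds = (best, best)
        try:
            solution = cobra.flux_analysis.pfba(model)
        except Exception:
            return FluxState(pd.Series(dtype=float), None, "infeasible")
        return FluxState(solution.fluxes.copy(), abs(best), "optimal")


def strategy_max_biomass(model: cobra.Model, driver_reaction: str,
                         uptake: float,
                         biomass_reaction: str | None = None) -> FluxState:
    """Fix a driver uptake (photon or sucrose) and maximize growth (pFBA)."""
    with model:
        _require(model, driver_reaction).bounds = (-uptake, -uptake)
        return pfba(model, objective=biomass_reaction)
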