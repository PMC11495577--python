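"""Context-specific model extraction from expression data.

The route from a TPM matrix to a tissue model:

1. :func:`preprocess_expression` — average replicates, log2(x+1), map
   gene ids onto the model's protein ids;
2. :func:`local_t2_activity` — call genes active/inactive with the
   local T2 scheme: global lower/upper percentile thresholds over the
   pooled value distribution plus a per-gene (local) threshold clamped
   between them;
3. :func:`reaction_core_set` — push gene activity through GPR rules
   (AND = min, OR = max) to mark core reactions;
4. :func:`fastcc` / :func:`fastcore` — reduce the generic network to a
   flux-consistent subnetwork containing every core and protected
   reaction (the biomass pseudo-reaction is always protected).

FASTCC and FASTCORE are implemented on an explicit stoichiometric-matrix
representation solved with scipy's HiGHS LP backend; the surrounding
model bookkeeping stays in cobra.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from cobra.util.array import create_stoichiometric_matrix
from scipy.optimize import linprog

from .netcore import evaluate_gpr, get_kind

logger = logging.getLogger("dielflux")

#: minimum flux magnitude counted as "carrying flux" in FASTCC/FASTCORE
DEFAULT_EPSILON = 1e-4
#: scaling factor applied inside the FASTCORE support-minimisation LP
LP10_SCALING = 1e5


class ExpressionError(ValueError):
    pass


class InconsistentCoreError(ValueError):
    """Core reactions that cannot carry flux in the consistent input."""

    def __init__(self, reactions: Iterable[str]):
        self.reactions = sorted(reactions)
        super().__init__(
            "core reactions cannot carry flux: " + ", ".join(self.reactions))


# ---------------------------------------------------------------------------
# expression containers and preprocessing
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples expression table plus per-sample metadata.

    ``values`` may hold TPM (raw) or log2(TPM+1) (after preprocessing);
    ``sample_meta`` is indexed by sample id with columns such as tissue,
    cultivar, time_point, stage, replicate_group.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ExpressionError("expression values must be nonnegative")
        if self.values.columns.duplicated().any():
            raise ExpressionError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ExpressionError(f"samples without metadata: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def write_tsv(self, values_path, meta_path) -> None:
        self.values.rename_axis("gene_id").to_csv(values_path, sep="\t")
        self.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")

    @classmethod
    def read_tsv(cls, values_path, meta_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, sample_meta=meta)


def discretize_stage(time_point) -> str:
    """Developmental stage from a berry time point: <=4 green, >4 mature."""
    if time_point is None or (isinstance(time_point, float) and np.isnan(time_point)):
        raise ValueError("missing time point")
    return "green" if int(time_point) <= 4 else "mature"


def preprocess_expression(
    raw: ExpressionMatrix,
    gene_map: Mapping[str, str] | None = None,
    model: cobra.Model | None = None,
    average_replicates: bool = True,
) -> ExpressionMatrix:
    """Average replicate groups, apply log2(x+1), map gene ids.

    Replicates are averaged in TPM space before the log transform; each
    replicate group collapses to one column named after the group. Gene
    ids are translated through ``gene_map`` (unmapped genes dropped with
    a logged count); when a model is given, an empty intersection with
    its gene set is an error.
    """
    values = raw.values
    meta = raw.sample_meta.loc[list(values.columns)].copy()

    if gene_map is not None:
        mapped = values.index.to_series().map(dict(gene_map))
        dropped = int(mapped.isna().sum())
        if dropped:
            logger.info("preprocess_expression: %d gene(s) dropped (unmapped)",
                        dropped)
        values = values.loc[mapped.notna()]
        values.index = mapped.dropna().values
        values = values.groupby(level=0).mean()

    if average_replicates and "replicate_group" in meta.columns:
        groups = meta["replicate_group"].astype(str)
        values = values.T.groupby(groups).mean().T
        meta = meta.groupby(groups).first()
        meta.index.name = raw.sample_meta.index.name or "sample_id"

    if model is not None:
        model_genes = {g.id for g in model.genes}
        if not model_genes & set(values.index):
            raise ExpressionError(
                "no overlap between expression gene ids and model proteins")

    values = np.log2(values + 1.0)
    return ExpressionMatrix(values=values, sample_meta=meta)


# ---------------------------------------------------------------------------
# local T2 thresholding
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ThresholdingConfig:
    """Percentile choices for the local T2 activity-calling scheme."""

    global_lower_pct: float = 25.0
    global_upper_pct: float = 75.0
    local_pct: float = 50.0

    def __post_init__(self):
        if not 0 <= self.global_lower_pct < self.global_upper_pct <= 100:
            raise ValueError("require 0 <= lower < upper <= 100")


@dataclasses.dataclass
class ActivityCall:
    """Per-gene activity states and signed distances to the threshold."""

    table: pd.DataFrame  # index gene, columns state, score, threshold

    @property
    def active_genes(self) -> set[str]:
        return set(self.table.index[self.table["state"] == "active"])

    def as_values(self) -> dict[str, float]:
        return {g: 1.0 if s == "active" else 0.0
                for g, s in self.table["state"].items()}


def local_t2_activity(expr: ExpressionMatrix, config: ThresholdingConfig,
                      group: Sequence[str] | None = None) -> ActivityCall:
    """Call genes active/inactive with local T2 thresholding.

    GL and GU are global percentiles of the pooled (all genes x all
    samples) value distribution; the local threshold L(g) is the
    per-gene ``local_pct`` percentile across all samples, clamped into
    [GL, GU]. A gene's group-level expression e (mean over ``group``,
    all samples when None) is called active when e >= GU, inactive when
    e < GL, and otherwise active iff e >= L(g). Ties at a threshold
    resolve to active. Percentiles use linear interpolation.
    """
    values = expr.values
    if values.shape[1] < 2:
        logger.warning("local T2 thresholding on fewer than 2 samples")
    pooled = values.to_numpy().ravel()
    gl = float(np.percentile(pooled, config.global_lower_pct))
    gu = float(np.percentile(pooled, config.global_upper_pct))
    local = values.quantile(config.local_pct / 100.0, axis=1).clip(gl, gu)
    cols = list(group) if group is not None else list(values.columns)
    e = values[cols].mean(axis=1)

    threshold = local.copy()
    threshold[e >= gu] = gu
    threshold[e < gl] = gl
    state = np.where(e >= gu, "active",
                     np.where(e < gl, "inactive",
                              np.where(e >= local, "active", "inactive")))
    table = pd.DataFrame({"state": state, "score": e - threshold,
                          "threshold": threshold}, index=values.index)
    return ActivityCall(table=table)


# ---------------------------------------------------------------------------
# core set from GPRs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CoreSet:
    """Reactions that must be kept (core) or are protected (biomass etc.)."""

    core: set[str]
    protected: set[str]

    @property
    def all(self) -> set[str]:
        return self.core | self.protected


def reaction_core_set(model: cobra.Model, activity: ActivityCall,
                      missing_value: float = 0.0,
                      extra_protected: Iterable[str] = ()) -> CoreSet:
    """Mark reactions core when their GPR evaluates active (AND=min, OR=max).

    Genes without an activity call default to ``missing_value`` (0 =
    inactive). Reactions without a GPR are never core. The objective
    (biomass) reaction is always protected.
    """
    values = activity.as_values()
    core: set[str] = set()
    for rxn in model.reactions:
        rule = rxn.gene_reaction_rule
        if not rule:
            continue
        score = evaluate_gpr(rule, values, default=missing_value)
        if score >= 0.5:
            core.add(rxn.id)
    protected = {
        r.id for r in cobra.util.solver.linear_reaction_coefficients(model)}
    protected |= {r.id for r in model.reactions if get_kind(r) == "biomass"}
    protected |= set(extra_protected)
    core -= protected
    return CoreSet(core=core, protected=protected)


# ---------------------------------------------------------------------------
# LP machinery shared by FASTCC / FASTCORE
# ---------------------------------------------------------------------------

class _Network:
    """Dense stoichiometric view of a cobra model for the extraction LPs."""

    def __init__(self, model: cobra.Model):
        self.reaction_ids = [r.id for r in model.reactions]
        self.index = {rid: i for i, rid in enumerate(self.reaction_ids)}
        self.S = create_stoichiometric_matrix(model)
        self.lb = np.array([r.lower_bound for r in model.reactions], float)
        self.ub = np.array([r.upper_bound for r in model.reactions], float)

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    def max_flux(self, i: int, sense: int) -> float:
        """LP max of sense * v_i over the steady-state polytope."""
        c = np.zeros(self.n)
        c[i] = -sense
        res = linprog(c, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=list(zip(self.lb, self.ub)), method="highs")
        if not res.success:
            return 0.0
        return float(sense * res.x[i])


def _lp7(S: np.ndarray, j_idx: np.ndarray, lb: np.ndarray, ub: np.ndarray,
         epsilon: float) -> np.ndarray | None:
    """Maximize the number of reactions in J carrying flux >= epsilon.

    LP over x = [v, z]: maximize sum z, with z_j <= v_j, 0 <= z_j <=
    epsilon, S v = 0, lb <= v <= ub. Returns v or None if the LP fails.
    """
    m, n = S.shape
    k = len(j_idx)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = np.hstack([S, np.zeros((m, k))])
    A_ub = np.zeros((k, n + k))
    A_ub[np.arange(k), n + np.arange(k)] = 1.0
    A_ub[np.arange(k), j_idx] = -1.0
    bounds = list(zip(lb, ub)) + [(0.0, epsilon)] * k
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(k), A_eq=A_eq,
                  b_eq=np.zeros(m), bounds=bounds, method="highs")
    if not res.success:
        return None
    return res.x[:n]


def _lp10(S: np.ndarray, k_idx: np.ndarray, p_idx: np.ndarray,
          lb: np.ndarray, ub: np.ndarray, epsilon: float) -> np.ndarray | None:
    """Minimize L1 flux through the penalty set P while forcing v_K >= eps.

    Solved in units scaled by LP10_SCALING so that supporting reactions
    with tiny fluxes still register above the support threshold.
    """
    sf = LP10_SCALING
    m, n = S.shape
    npen = len(p_idx)
    lo, hi = lb * sf, ub * sf
    lo = lo.copy()
    lo[k_idx] = np.maximum(lo[k_idx], 0.99 * epsilon * sf)
    c = np.concatenate([np.zeros(n), np.ones(npen)])
    A_eq = np.hstack([S, np.zeros((m, npen))])
    # v_p - w_p <= 0 and -v_p - w_p <= 0
    A_ub = np.zeros((2 * npen, n + npen))
    A_ub[np.arange(npen), p_idx] = 1.0
    A_ub[np.arange(npen), n + np.arange(npen)] = -1.0
    A_ub[npen + np.arange(npen), p_idx] = -1.0
    A_ub[npen + np.arange(npen), n + np.arange(npen)] = -1.0
    bounds = list(zip(lo, hi)) + [(0.0, None)] * npen
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(2 * npen), A_eq=A_eq,
                  b_eq=np.zeros(m), bounds=bounds, method="highs")
    if not res.success:
        return None
    return res.x[:n] / sf


# ---------------------------------------------------------------------------
# FASTCC
# ---------------------------------------------------------------------------

def consistent_reaction_ids(model: cobra.Model,
                            epsilon: float = DEFAULT_EPSILON) -> set[str]:
    """Ids of reactions able to carry |flux| >= epsilon at steady state."""
    net = _Network(model)
    keep: set[str] = set()
    for i, rid in enumerate(net.reaction_ids):
        if net.max_flux(i, +1) >= epsilon * (1 - 1e-6):
            keep.add(rid)
        elif net.lb[i] < 0 and -net.max_flux(i, -1) <= -epsilon * (1 - 1e-6):
            keep.add(rid)
    return keep


def fastcc(model: cobra.Model, epsilon: float = DEFAULT_EPSILON) -> cobra.Model:
    """Return the flux-consistent submodel (blocked reactions removed)."""
    keep = consistent_reaction_ids(model, epsilon)
    out = model.copy()
    blocked = [r for r in out.reactions if r.id not in keep]
    if blocked:
        logger.info("fastcc: removing %d blocked reaction(s)", len(blocked))
        out.remove_reactions(blocked, remove_orphans=True)
    return out


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------

def _find_sparse_mode(S, j_idx, p_idx, lb, ub, epsilon) -> set[int]:
    if len(j_idx) == 0:
        return set()
    v = _lp7(S, j_idx, lb, ub, epsilon)
    if v is None:
        return set()
    k_idx = j_idx[v[j_idx] >= 0.99 * epsilon]
    if len(k_idx) == 0:
        return set()
    v = _lp10(S, k_idx, p_idx, lb, ub, epsilon)
    if v is None:
        return set()
    return set(np.flatnonzero(np.abs(v) >= 0.99 * epsilon / LP10_SCALING))


def fastcore_reaction_ids(model: cobra.Model, core: Iterable[str],
                          epsilon: float = DEFAULT_EPSILON) -> set[str]:
    """FASTCORE: ids of an approximately minimal flux-consistent
    subnetwork of ``model`` containing every reaction in ``core``.

    ``model`` must itself be flux-consistent. Alternates a core-coverage
    LP (maximize the number of core reactions above epsilon) with an
    L1 support-minimisation LP over non-core reactions, flipping
    reversible core reactions that resist coverage, until every core
    reaction carries flux.
    """
    net = _Network(model)
    missing = set(core) - set(net.reaction_ids)
    if missing:
        raise InconsistentCoreError(missing)
    core_idx = np.array(sorted(net.index[r] for r in core), dtype=int)
    all_idx = np.arange(net.n)
    noncore_mask = np.ones(net.n, bool)
    noncore_mask[core_idx] = False

    # working copies: flipping a reversible reaction negates its column
    # and mirrors its bounds
    S = net.S.copy()
    lb, ub = net.lb.copy(), net.ub.copy()
    irreversible = net.lb >= 0

    def flip(indices):
        for i in indices:
            S[:, i] *= -1.0
            lb[i], ub[i] = -ub[i], -lb[i]

    J = set(core_idx[irreversible[core_idx]].tolist())
    A = _find_sparse_mode(S, np.array(sorted(J), int),
                          all_idx[noncore_mask], lb, ub, epsilon)
    if not J <= A:
        raise InconsistentCoreError(
            net.reaction_ids[i] for i in sorted(J - A))
    J = set(core_idx.tolist()) - A

    flipped = False
    singleton = False
    while J:
        p_idx = np.array([i for i in all_idx if noncore_mask[i] and i not in A],
                         int)
        j_now = {min(J)} if singleton else J
        A |= _find_sparse_mode(S, np.array(sorted(j_now), int),
                               p_idx, lb, ub, epsilon)
        if J & A:
            J -= A
            flipped = False
            singleton = False
            continue
        j_rev = {i for i in j_now if not irreversible[i]}
        if flipped or not j_rev:
            if singleton:
                raise InconsistentCoreError(
                    net.reaction_ids[i] for i in sorted(J))
            flipped = False
            singleton = True
        else:
            flip(j_rev)
            flipped = True
    return {net.reaction_ids[i] for i in sorted(A)}


def fastcore(model: cobra.Model, core: CoreSet | Iterable[str],
             epsilon: float = DEFAULT_EPSILON) -> cobra.Model:
    """Extract the context-specific submodel for a core reaction set."""
    core_ids = core.all if isinstance(core, CoreSet) else set(core)
    keep = fastcore_reaction_ids(model, core_ids, epsilon)
    out = model.copy()
    drop = [r for r in out.reactions if r.id not in keep]
    out.remove_reactions(drop, remove_orphans=True)
    return out


def extract_context_model(
    model: cobra.Model,
    expr: ExpressionMatrix,
    group: Sequence[str] | None = None,
    config: ThresholdingConfig | None = None,
    epsilon: float = DEFAULT_EPSILON,
    missing_value: float = 0.0,
    extra_protected: Iterable[str] = (),
) -> cobra.Model:
    """Full extraction route: activity -> core set -> FASTCC -> FASTCORE.

    Core reactions blocked in the consistent input (they can never carry
    flux) are dropped from the core with a logged count, mirroring the
    treatment of blocked reactions kept in the generic reconstruction.
    """
    config = config or ThresholdingConfig()
    activity = local_t2_activity(expr, config, group=group)
    core = reaction_core_set(model, activity, missing_value=missing_value,
                             extra_protected=extra_protected)
    consistent = fastcc(model, epsilon)
    present = {r.id for r in consistent.reactions}
    lost_protected = core.protected - present
    if lost_protected:
        raise InconsistentCoreError(lost_protected)
    blocked_core = core.core - present
    if blocked_core:
        logger.info("extract_context_model: %d core reaction(s) blocked in "
                    "the consistent model; dropped", len(blocked_core))
    keep = (core.core & present) | core.protected
    return fastcore(consistent, keep, epsilon)
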