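"""Sampling-based differential flux analysis.

Flux distributions are drawn with the artificial-centering hit-and-run
(ACHR) sampler (sample size 10000, thinning 100 by default). Two
models are compared reaction by reaction:

* reactions present in both — a two-sample Kolmogorov-Smirnov test on
  the sampled flux distributions, Benjamini-Hochberg adjusted across
  reactions, combined with the flux-change statistic

      FC = (m1 - m2) / |m1 + m2|

  on the sample means; |FC| >= 0.82 corresponds to a 10-fold change
  and smaller values are treated as insignificant;
* reactions absent in one model — their flux there is taken as zero
  and the present model's mean gets a percentile-bootstrap 95%
  confidence interval; the reaction is differential when zero falls
  outside the interval.

Pathway-level over-representation of altered reactions is assessed
with an upper-tail hypergeometric test, Benjamini-Hochberg adjusted
across pathways.

Caveat carried over from the procedure this mirrors: consecutive chain
samples are autocorrelated, which inflates KS significance; the flux-
change cutoff is what keeps self-comparisons quiet.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from cobra.sampling import ACHRSampler
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netcore import FLUX_TOL

logger = logging.getLogger("dielflux")

DEFAULT_N_SAMPLES = 10_000
DEFAULT_THINNING = 100
FC_THRESHOLD = 0.82
FC_SENTINEL = 1e6
ALPHA = 0.05


@dataclasses.dataclass
class FluxSamples:
    """Sampled flux distributions for one model."""

    model_id: str
    samples: pd.DataFrame  # n_samples x reactions
    settings: dict

    @property
    def reactions(self) -> set[str]:
        return set(self.samples.columns)

    def means(self) -> pd.Series:
        return self.samples.mean(axis=0)

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


def _invalid_rows(model: cobra.Model, samples: pd.DataFrame,
                  tol: float = FLUX_TOL) -> np.ndarray:
    from cobra.util.array import create_stoichiometric_matrix

    order = [r.id for r in model.reactions]
    V = samples[order].to_numpy()
    S = create_stoichiometric_matrix(model)
    resid = np.abs(S @ V.T).max(axis=0)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    in_bounds = ((V >= lb - tol) & (V <= ub + tol)).all(axis=1)
    return np.flatnonzero((resid > tol) | ~in_bounds)


def achr_sample(model: cobra.Model, n: int = DEFAULT_N_SAMPLES,
                thinning: int = DEFAULT_THINNING, seed: int | None = None,
                nproj: int = 500) -> FluxSamples:
    """Draw ACHR samples; invalid draws are resampled with a log entry.

    The sampler warms up from per-reaction FVA optima and proposes
    directions through the running center of previous points; every
    ``thinning``-th state is kept and the chain is reprojected onto the
    steady-state subspace every ``nproj`` iterations to curb numerical
    drift. Samples are validated against the package flux tolerance
    (|S v| and bound violations <= 1e-6). Identical seeds give
    identical sample matrices.

    Reactions with nonzero fixed bounds (maintenance fluxes, pinned
    uptakes) would turn the steady-state system inhomogeneous and
    disable the sampler's drift correction; their bounds are widened by
    +-1e-6 in a sampling copy, which perturbs each such flux by at most
    the package flux tolerance.
    """
    pinned = [r.id for r in model.reactions
              if r.lower_bound == r.upper_bound and r.lower_bound != 0.0]
    sampling_model = model
    if pinned:
        sampling_model = model.copy()
        for rid in pinned:
            rxn = sampling_model.reactions.get_by_id(rid)
            rxn.bounds = (rxn.lower_bound - FLUX_TOL,
                          rxn.upper_bound + FLUX_TOL)
    sampler = ACHRSampler(sampling_model, thinning=thinning, seed=seed,
                          nproj=nproj)
    samples = sampler.sample(n)
    bad = _invalid_rows(model, samples)
    rounds = 0
    while bad.size and rounds < 2:
        logger.info("achr_sample: resampling %d invalid draw(s)", bad.size)
        redraw = sampler.sample(len(bad))
        samples.iloc[bad] = redraw.to_numpy()
        bad = _invalid_rows(model, samples)
        rounds += 1
    if bad.size:
        # residual numerical drift: alternate projection onto S v = 0
        # with clipping into the bounds until within tolerance
        logger.info("achr_sample: repairing %d drifted draw(s)", bad.size)
        from cobra.util.array import create_stoichiometric_matrix
        from scipy.linalg import null_space

        order = [r.id for r in model.reactions]
        S = create_stoichiometric_matrix(model)
        N = null_space(S)
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        V = samples[order].to_numpy()
        for _ in range(10):
            V[bad] = np.clip(V[bad] @ N @ N.T, lb, ub)
            samples.loc[:, order] = V
            bad = _invalid_rows(model, samples)
            if not bad.size:
                break
    if bad.size:
        raise RuntimeError(f"{bad.size} sample(s) remain infeasible")
    return FluxSamples(model_id=model.id, samples=samples,
                       settings=dict(n=n, thinning=thinning, seed=seed))


def flux_change(mean1: float, mean2: float) -> float:
    """FC = (m1 - m2)/|m1 + m2|; 0 for (0,0), signed sentinel when the
    denominator vanishes but the means differ."""
    num = mean1 - mean2
    den = abs(mean1 + mean2)
    if den < 1e-12:
        if abs(num) < 1e-12:
            return 0.0
        return float(np.sign(num) * FC_SENTINEL)
    return float(num / den)


def bootstrap_ci(samples: Sequence[float], n_boot: int = 1000,
                 level: float = 0.95,
                 seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two sample values")
    if np.ptp(arr) == 0:
        return float(arr[0]), float(arr[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    means = arr[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100,
                                   (1 + level) / 2 * 100])
    return float(lo), float(hi)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_flux(
    samples_a: FluxSamples,
    samples_b: FluxSamples,
    alpha: float = ALPHA,
    fc_threshold: float = FC_THRESHOLD,
    require_fc: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-reaction differential-flux table between two sampled models.

    Shared reactions: KS p-value (asymptotic), BH-adjusted, significant
    iff p_adj < alpha and (when ``require_fc``) |FC| >= fc_threshold.
    Reactions absent in one model: mean 0 there, significant when the
    bootstrap CI of the present model's mean excludes zero.
    """
    shared = sorted(samples_a.reactions & samples_b.reactions)
    only_a = sorted(samples_a.reactions - samples_b.reactions)
    only_b = sorted(samples_b.reactions - samples_a.reactions)
    if not shared and not only_a and not only_b:
        logger.warning("differential_flux: no comparable reactions")
        return pd.DataFrame()

    means_a, means_b = samples_a.means(), samples_b.means()
    rows = []
    p_values = []
    for rid in shared:
        a = samples_a.samples[rid].to_numpy()
        b = samples_b.samples[rid].to_numpy()
        ks = stats.ks_2samp(a, b, method="asymp")
        m1, m2 = float(means_a[rid]), float(means_b[rid])
        p_values.append(float(ks.pvalue))
        rows.append(dict(reaction_id=rid, mean_model1=m1, mean_model2=m2,
                         ks_statistic=float(ks.statistic),
                         p_value=float(ks.pvalue), FC=flux_change(m1, m2),
                         absent_in="none", ci_low=np.nan, ci_high=np.nan))
    p_adj = bh_adjust(p_values) if p_values else np.array([])
    for row, adj in zip(rows, p_adj):
        row["p_adjusted"] = float(adj)
        sig = adj < alpha
        if require_fc:
            sig = sig and abs(row["FC"]) >= fc_threshold
        row["significant"] = bool(sig)

    rng = np.random.default_rng(seed)
    for rid_list, absent_in, present in ((only_a, "model2", samples_a),
                                         (only_b, "model1", samples_b)):
        for rid in rid_list:
            arr = present.samples[rid].to_numpy()
            lo, hi = bootstrap_ci(arr, n_boot=n_boot,
                                  seed=int(rng.integers(2**31)))
            m = float(arr.mean())
            m1, m2 = (m, 0.0) if absent_in == "model2" else (0.0, m)
            rows.append(dict(reaction_id=rid, mean_model1=m1, mean_model2=m2,
                             ks_statistic=np.nan, p_value=np.nan,
                             p_adjusted=np.nan, FC=flux_change(m1, m2),
                             absent_in=absent_in, ci_low=lo, ci_high=hi,
                             significant=bool(lo > 0 or hi < 0)))
    df = pd.DataFrame(rows).set_index("reaction_id")
    return df[["mean_model1", "mean_model2", "ks_statistic", "p_value",
               "p_adjusted", "FC", "absent_in", "ci_low", "ci_high",
               "significant"]]


def hypergeom_enrichment(
    altered: set[str],
    pathways: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of altered reactions.

    Population N = |universe|, successes n = |altered|, draws
    K = |pathway ∩ universe|, observed k = |altered ∩ pathway|;
    p = P(X >= k). BH adjustment across pathways.
    """
    if not altered <= universe:
        raise ValueError("altered reactions must be a subset of the universe")
    N, n = len(universe), len(altered)
    rows = []
    for pathway, members in sorted(pathways.items()):
        members = set(members) & universe
        if not members:
            continue
        K = len(members)
        k = len(altered & members)
        p = float(stats.hypergeom.sf(k - 1, N, n, K))
        rows.append(dict(pathway=pathway, k=k, K=K, n=n, N=N,
                         p_value=min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "pathway"]).reset_index(drop=True)
    return df


def check_samples_feasible(model: cobra.Model, samples: FluxSamples,
                           tol: float = FLUX_TOL) -> bool:
    """Every sample satisfies S.v = 0 and the bounds within tolerance."""
    from cobra.util.array import create_stoichiometric_matrix

    order = [r.id for r in model.reactions]
    V = samples.samples[order].to_numpy()
    S = create_stoichiometric_matrix(model)
    if np.abs(S @ V.T).max() > tol:
        return False
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return bool(((V >= lb - tol) & (V <= ub + tol)).all())
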