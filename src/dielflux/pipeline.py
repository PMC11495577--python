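"""End-to-end orchestration of the diel multi-tissue analysis.

Stages run in dependency order — context extraction, diel assembly and
simulation, sampling-based differential flux, flux-capacity machine
learning — each toggleable from the configuration. Inputs default to
the synthetic toy fixture when no SBML/TSV paths are configured. A run
manifest records the config digest, seeds, per-file checksums and
timestamps; deterministic stages reproduce identical checksums under
an identical manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import context as ctx
from . import diel as dl
from . import diffflux as dfx
from . import fluxml as fml
from . import netcore
from . import synthetic as syn
from .config import PipelineConfig
from .simulate import apply_condition, make_condition

logger = logging.getLogger("dielflux")


@dataclasses.dataclass
class RunManifest:
    config_digest: str
    package_version: str
    seed: int
    started: str
    finished: str | None = None
    stages: dict = dataclasses.field(default_factory=dict)
    checksums: dict = dataclasses.field(default_factory=dict)
    failure: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _load_inputs(config: PipelineConfig):
    if config.paths.model is None:
        fixture = syn.end_to_end_fixture(seed=config.seed)
        return fixture.models, fixture.expression
    model = netcore.read_model(config.paths.model)
    if config.paths.expression is None or config.paths.metadata is None:
        raise FileNotFoundError("expression and metadata paths are required "
                                "when a model path is given")
    expr = ctx.ExpressionMatrix.read_tsv(config.paths.expression,
                                         config.paths.metadata)
    models = syn.ToyModels(generic=model, tissues={},
                           config=syn.ToyModelConfig(seed=config.seed))
    return models, expr


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages; outputs land in ``paths.out_dir``."""
    out = Path(config.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_digest=config.digest(),
                           package_version=_version(), seed=config.seed,
                           started=_now())
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        manifest.failure = f"{type(exc).__name__}: {exc}"
        manifest.finished = _now()
        manifest.to_json(out / "manifest.json")
        raise
    manifest.finished = _now()
    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.checksums[path.name] = _checksum(path)
    manifest.to_json(out / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, out: Path,
                manifest: RunManifest) -> None:
    models, raw_expr = _load_inputs(config)
    generic = models.generic
    expr = ctx.preprocess_expression(raw_expr, model=generic)
    tcfg = ctx.ThresholdingConfig(config.thresholding.global_lower_pct,
                                  config.thresholding.global_upper_pct,
                                  config.thresholding.local_pct)

    tissue_models: dict[str, "object"] = {}
    if config.stages.context:
        meta = expr.sample_meta
        for tissue in sorted(meta["tissue"].unique()):
            base = models.tissues.get(_variant_for(tissue, "green"), generic)
            group = list(meta.index[meta["tissue"] == tissue])
            extracted = ctx.extract_context_model(
                base, expr, group=group, config=tcfg,
                epsilon=config.extraction.epsilon,
                missing_value=config.extraction.missing_gene_value)
            extracted.id = f"context_{tissue}"
            tissue_models[tissue] = extracted
            netcore.write_model(extracted, out / f"context_{tissue}.xml")
        manifest.stages["context"] = {"tissues": sorted(tissue_models)}

    if config.stages.diel and tissue_models:
        merged = dl.merge_tissues(tissue_models)
        diel_model = dl.dielize(merged)
        dl.apply_diel_constraints(
            diel_model,
            nitrate_light_dark_ratio=config.diel.nitrate_light_dark_ratio)
        netcore.write_model(diel_model, out / "diel_model.xml")
        solution = dl.simulate_diel(
            diel_model, photon_uptake=config.diel.photon_uptake,
            rubisco_pairs=dl.leaf_rubisco_pairs(diel_model),
            rubisco_ratio=config.diel.rubisco_ratio)
        solution.state.to_tsv(out / "diel_fluxes.tsv")
        solution.storage_report.to_csv(out / "diel_storage.tsv", sep="\t",
                                       index=False)
        manifest.stages["diel"] = {
            "status": solution.state.status,
            "total_biomass": solution.state.objective_value}

    if config.stages.diffflux:
        pair = _diffflux_pair(config, models, expr, tcfg)
        if pair is not None:
            (name_a, model_a), (name_b, model_b) = pair
            samples = {}
            for name, model in ((name_a, model_a), (name_b, model_b)):
                samples[name] = dfx.achr_sample(
                    model, n=config.sampling.n,
                    thinning=config.sampling.thinning,
                    seed=config.sampling.seed)
            table = dfx.differential_flux(
                samples[name_a], samples[name_b],
                alpha=config.diffflux.alpha,
                fc_threshold=config.diffflux.fc_threshold,
                require_fc=config.diffflux.require_fc,
                n_boot=config.diffflux.n_boot, seed=config.seed)
            table.to_csv(out / "differential_flux.tsv", sep="\t")
            altered = set(table.index[table["significant"]])
            universe = set(table.index)
            enrichment = dfx.hypergeom_enrichment(
                altered, syn.pathway_map(generic), universe)
            enrichment.to_csv(out / "pathway_enrichment.tsv", sep="\t",
                              index=False)
            manifest.stages["diffflux"] = {
                "pair": [name_a, name_b], "n_significant": len(altered)}

    if config.stages.fluxml:
        data = _per_sample_dataset(config, models, expr, tcfg)
        if data is not None:
            mlc = fml.MLConfig(n_folds=config.ml.n_folds,
                               n_repeats=config.ml.n_repeats,
                               k_best=config.ml.k_best, seed=config.ml.seed,
                               positive_label=config.ml.positive_label)
            report = fml.evaluate_classifiers(data, mlc)
            report.to_tsv(out / "ml_evaluation.tsv")
            data.to_tsv(out / "flux_capacity.tsv")
            attribution = fml.shapley_attribution(
                report, data, family=config.ml.attribution_family,
                n_permutations=config.ml.n_permutations, seed=config.seed)
            attribution.to_tsv(out / "ml_attribution.tsv")
            manifest.stages["fluxml"] = {
                "balanced_accuracy": report.summary["balanced_accuracy"]
                .to_dict()}


def _variant_for(tissue: str, stage: str) -> str:
    if tissue == "berry":
        return "green_berry" if stage == "green" else "mature_berry"
    return tissue


def _berry_context(config, models, expr, tcfg, stage: str):
    meta = expr.sample_meta
    group = list(meta.index[(meta["tissue"] == "berry")
                            & (meta["stage"] == stage)])
    if not group:
        return None
    base = models.tissues.get("green_berry", models.generic)
    model = ctx.extract_context_model(
        base, expr, group=group, config=tcfg,
        epsilon=config.extraction.epsilon,
        missing_value=config.extraction.missing_gene_value)
    model.id = f"berry_{stage}"
    cond = make_condition("respiration", photon_exchange="EX_photon_e",
                          sucrose_exchange="EX_sucr_e") \
        if "EX_photon_e" in model.reactions else None
    return apply_condition(model, cond) if cond else model


def _diffflux_pair(config, models, expr, tcfg):
    a = _berry_context(config, models, expr, tcfg, "green")
    b = _berry_context(config, models, expr, tcfg, "mature")
    if a is None or b is None:
        return None
    return ("berry_green", a), ("berry_mature", b)


def _per_sample_dataset(config, models, expr, tcfg):
    meta = expr.sample_meta
    berry = meta.index[meta["tissue"] == "berry"]
    if berry.empty:
        return None
    base = models.tissues.get("green_berry", models.generic)
    capacities: dict[str, pd.Series] = {}
    labels: dict[str, str] = {}
    for sample in berry:
        model = ctx.extract_context_model(
            base, expr, group=[sample], config=tcfg,
            epsilon=config.extraction.epsilon,
            missing_value=config.extraction.missing_gene_value)
        capacities[sample] = fml.flux_capacity(
            model, biomass_fraction=config.fva.fraction_of_optimum)
        labels[sample] = meta.loc[sample, "stage"]
    return fml.build_dataset(capacities, labels,
                             biomass_fraction=config.fva.fraction_of_optimum)


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("dielflux")
    except Exception:
        return "unknown"
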