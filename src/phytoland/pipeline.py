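"""End-to-end orchestration of the two analysis paths.

Path 1 (reduce, then estimate): z-transform -> correlation-network module
detection -> module eigenvectors + leaf traits -> lasso feature selection
per response with leave-one-plant-out CV -> Bayesian GLMs on the selected
predictors -> LOO predictive validation and the random-module null.

Path 2 (estimate everything): ridge regression on all compounds at once
with a plant-level bootstrap -> natural-scale deltas, class summaries and
top-effect lists -> CV-vs-effect association -> pairwise-interaction
lasso with class enrichment.

``run_pipeline`` executes the stages in order, writing every artifact as
CSV/JSON/GraphML into a run directory together with a manifest that
records the seed, per-stage timings and a content hash of every output.
One global seed fans out to per-stage seeds through ``SeedSequence.spawn``
with a fixed stage order, so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import effects as eff
from .bayes import McmcSettings, fit_bayes_glm, summarize_posterior
from .data_model import RESPONSES, build_design, load_tables, write_tables, z_transform
from .network import NetworkParams, export_network, find_modules
from .penalized import (
    bootstrap_ridge,
    build_interaction_design,
    cv_select_lambda,
    interaction_lasso,
)
from .synthetic import SynthConfig, generate
from .validation import ModelSpec, cv_effect_association, loo_validate, random_module_null

logger = logging.getLogger(__name__)

STAGES = [
    "data",
    "modules",
    "select",
    "bayes",
    "validate",
    "ridge",
    "interactions",
]

TRAIT_COLS = ["protein", "sla", "toughness"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    outdir: str = "phytoland_run"
    seed: int = 0
    inputs: Optional[Dict[str, str]] = None  # compounds/traits/caterpillars/classes paths
    simulate: Optional[Dict] = None  # SynthConfig fields
    network: Dict = field(default_factory=dict)  # NetworkParams fields
    mcmc: Dict = field(default_factory=dict)  # McmcSettings fields
    penalized: Dict = field(default_factory=dict)  # n_lambda, bootstrap_B, bootstrap_unit
    validation: Dict = field(default_factory=dict)  # n_resamples, method
    interactions: Dict = field(default_factory=dict)  # enabled, responses, max_compounds
    responses: List[str] = field(default_factory=lambda: list(RESPONSES))

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config must supply exactly one of 'inputs' or 'simulate'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed).spawn(len(STAGES))[STAGES.index(stage)]


def run_pipeline(config: RunConfig, upto: Optional[str] = None) -> Dict:
    """Run the pipeline through stage ``upto`` (default: everything).

    Returns a dict of in-memory artifacts; files land in ``config.outdir``.
    A failure inside a stage raises with the stage named; artifacts written
    before the failure remain on disk.
    """
    upto = upto or STAGES[-1]
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; expected one of {STAGES}")
    last = STAGES.index(upto)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    logger.info("run seed = %d, outdir = %s", config.seed, outdir)

    art: Dict = {}
    timings: Dict[str, float] = {}
    written: List[Path] = []

    def stage(name):
        return STAGES.index(name) <= last

    def save_df(df: pd.DataFrame, name: str, index: bool = True):
        path = outdir / name
        df.to_csv(path, index=index)
        written.append(path)
        return path

    def save_json(obj, name: str):
        path = outdir / name
        path.write_text(json.dumps(obj, indent=2, default=float))
        written.append(path)
        return path

    try:
        t0 = time.perf_counter()
        if config.simulate is not None:
            syn = SynthConfig(**config.simulate)
            seed = int(_stage_seed(config.seed, "data").generate_state(1)[0] % (2**31))
            cm, traits, cats, truth = generate(syn, seed=seed)
            art["truth"] = truth
            paths = write_tables(outdir / "tables", cm, traits, cats)
            written.extend(paths.values())
            save_json(
                {
                    "membership": truth.membership.to_dict(),
                    "config": {
                        k: v for k, v in asdict(truth.config).items() if k != "class_freqs"
                    },
                },
                "truth.json",
            )
        else:
            cm, traits, cats = load_tables(
                config.inputs["compounds"],
                config.inputs["traits"],
                config.inputs["caterpillars"],
                config.inputs.get("classes"),
            )
        art.update(cm=cm, traits=traits, caterpillars=cats)
        timings["data"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"stage 'data' failed: {e}") from e
    if not stage("modules"):
        return _finish(art, config, outdir, timings, written, save_json)

    try:
        t0 = time.perf_counter()
        params = NetworkParams(**config.network)
        solution = find_modules(cm, params)
        art["modules"] = solution
        save_df(solution.assignment.rename("module").to_frame().assign(
            round_of_assignment=solution.round_of_assignment,
            compound_class=cm.class_of,
        ), "module_membership.csv")
        save_df(solution.eigenvectors.rename_axis("plant_id"), "module_eigenvectors.csv")
        cor = np.corrcoef(cm.zscores().to_numpy(), rowvar=False)
        sizes = solution.module_sizes
        weak = set(sizes.index[sizes <= max(params.min_module_size, 6)])
        edges, G = export_network(cor, solution, cm.class_of, weak_modules=weak)
        save_df(edges, "network_edges.csv", index=False)
        import networkx as nx

        gml = outdir / "network.graphml"
        nx.write_graphml(G, gml)
        written.append(gml)
        timings["modules"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"stage 'modules' failed: {e}") from e
    if not stage("select"):
        return _finish(art, config, outdir, timings, written, save_json)

    # plant-level predictor table: eigenvectors + z-scored traits
    predictors = solution.eigenvectors.join(z_transform(traits.table[TRAIT_COLS]))
    art["plant_predictors"] = predictors

    try:
        t0 = time.perf_counter()
        n_lambda = int(config.penalized.get("n_lambda", 100))
        selected: Dict[str, List[str]] = {}
        rows = []
        for resp in config.responses:
            design = build_design(resp, predictors, cats)
            fit = cv_select_lambda(design, "lasso", n_lambda=n_lambda)
            keep = [
                c
                for c in fit.nonzero()
                if c in predictors.columns  # covariates are not selectable traits
            ]
            selected[resp] = keep
            for c in keep:
                rows.append((resp, c, float(fit.coef_at_chosen()[c]), fit.chosen_lambda))
        art["selected"] = selected
        save_df(
            pd.DataFrame(rows, columns=["response", "term", "lasso_coefficient", "lambda"]),
            "lasso_selected.csv",
            index=False,
        )
        timings["select"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"stage 'select' failed: {e}") from e
    if not stage("bayes"):
        return _finish(art, config, outdir, timings, written, save_json)

    try:
        t0 = time.perf_counter()
        seed = int(_stage_seed(config.seed, "bayes").generate_state(1)[0] % (2**31))
        summaries = {}
        tables = []
        for i, resp in enumerate(config.responses):
            settings = McmcSettings(**{"seed": seed + i, **config.mcmc})
            design = build_design(resp, predictors, cats, selected[resp])
            chains = fit_bayes_glm(design, settings)
            summ = summarize_posterior(chains)
            summaries[resp] = summ
            tables.append(summ.assign(response=resp))
        art["posterior"] = summaries
        save_df(pd.concat(tables), "posterior_summaries.csv")
        timings["bayes"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"stage 'bayes' failed: {e}") from e
    if not stage("validate"):
        return _finish(art, config, outdir, timings, written, save_json)

    try:
        t0 = time.perf_counter()
        seed = int(_stage_seed(config.seed, "validate").generate_state(1)[0] % (2**31))
        n_resamples = int(config.validation.get("n_resamples", 1000))
        method = config.validation.get("method", "ml")
        val_rows = []
        null_summ = {}
        for resp in config.responses:
            spec = ModelSpec(response=resp, predictors=selected[resp])
            if not spec.predictors:
                logger.info("no predictors selected for %s; validation skipped", resp)
                continue
            res = loo_validate(spec, predictors, cats, method=method)
            save_df(res.per_plant, f"loo_{resp}.csv", index=False)
            val_rows.append((resp, res.r, res.r2_percent))
            module_cols = [c for c in spec.predictors if c in solution.eigenvectors.columns]
            if module_cols:
                sizes = [int(solution.module_sizes[int(c[1:])]) for c in module_cols]
                null = random_module_null(
                    cm,
                    sizes,
                    spec,
                    cats,
                    trait_predictors=predictors,
                    real_module_cols=module_cols,
                    n_resamples=n_resamples,
                    seed=seed,
                )
                null_summ[resp] = {
                    "empirical": null.empirical,
                    "exceedance_fraction": null.exceedance_fraction,
                    "n_resamples": null.n_resamples,
                    "statistic": null.statistic,
                }
                save_df(
                    pd.DataFrame({"resampled": null.resampled}),
                    f"random_module_null_{resp}.csv",
                    index=False,
                )
        save_df(
            pd.DataFrame(val_rows, columns=["response", "r", "r2_percent"]),
            "validation.csv",
            index=False,
        )
        save_json({"seed": seed, "nulls": null_summ}, "random_module_null.json")
        art["validation"] = val_rows
        art["nulls"] = null_summ
        timings["validate"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"stage 'validate' failed: {e}") from e
    if not stage("ridge"):
        return _finish(art, config, outdir, timings, written, save_json)

    try:
        t0 = time.perf_counter()
        seed = int(_stage_seed(config.seed, "ridge").generate_state(1)[0] % (2**31))
        B = int(config.penalized.get("bootstrap_B", 1000))
        unit = config.penalized.get("bootstrap_unit", "plant")
        compound_preds = cm.zscores()
        deltas = {}
        ridge_effects = {}
        all_rows = []
        for i, resp in enumerate(config.responses):
            design = build_design(resp, compound_preds, cats)
            fit = cv_select_lambda(design, "ridge", n_lambda=int(config.penalized.get("n_lambda", 100)))
            boot = bootstrap_ridge(design, B=B, lam=fit.chosen_lambda, unit=unit, seed=seed + i)
            boot = boot[boot["term"].isin(cm.compound_ids)].set_index("term")
            intercept = fit.intercept_at_chosen()
            tbl = eff.effects_table(
                boot["estimate"], resp, intercept, flags=boot["excludes_zero"]
            )
            tbl["ci_low"] = boot["ci_low"]
            tbl["ci_high"] = boot["ci_high"]
            tbl["compound_class"] = cm.class_of
            tbl["module"] = art["modules"].assignment
            save_df(tbl, f"ridge_effects_{resp}.csv")
            top = eff.top_effects(tbl)
            save_df(top, f"top_effects_{resp}.csv")
            deltas[resp] = tbl["delta"]
            ridge_effects[resp] = tbl["coefficient"]
            all_rows.append(tbl)
        delta_df = pd.DataFrame(deltas)
        class_summary = eff.summarize_by_class(delta_df, cm.class_of)
        save_df(class_summary, "class_summary.csv", index=False)
        cv_summary, cv_table = cv_effect_association(cm, pd.DataFrame(ridge_effects))
        save_df(cv_summary, "cv_effect_association.csv", index=False)
        save_df(cv_table.rename_axis("compound_id"), "cv_effect_table.csv")
        art["ridge_effects"] = pd.DataFrame(ridge_effects)
        art["deltas"] = delta_df
        art["class_summary"] = class_summary
        timings["ridge"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"stage 'ridge' failed: {e}") from e
    if not stage("interactions"):
        return _finish(art, config, outdir, timings, written, save_json)

    try:
        t0 = time.perf_counter()
        seed = int(_stage_seed(config.seed, "interactions").generate_state(1)[0] % (2**31))
        icfg = config.interactions
        if icfg.get("enabled", True):
            responses = icfg.get("responses", ["survival"])
            max_c = icfg.get("max_compounds")
            sub = cm.abundance
            if max_c is not None and cm.n_compounds > max_c:
                # keep the most variable compounds (by CV) for the scan
                cv = sub.std(ddof=1) / sub.mean()
                sub = sub[cv.sort_values(ascending=False).index[:max_c]]
            idesign_plants = build_interaction_design(sub)
            itables = []
            for resp in responses:
                design = build_design(resp, idesign_plants, cats)
                hits = interaction_lasso(
                    design, cm.class_of, n_lambda=int(icfg.get("n_lambda", 30))
                )
                hits["response"] = resp
                itables.append(hits)
                if len(hits):
                    enr = eff.interaction_class_enrichment(
                        hits,
                        cm.class_of,
                        n_permutations=int(icfg.get("n_permutations", 10_000)),
                        seed=seed,
                    )
                    save_df(enr, f"interaction_enrichment_{resp}.csv", index=False)
            inter = pd.concat(itables) if itables else pd.DataFrame()
            save_df(inter, "interactions.csv", index=False)
            art["interactions"] = inter
        timings["interactions"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"stage 'interactions' failed: {e}") from e

    return _finish(art, config, outdir, timings, written, save_json)


def _finish(art, config, outdir, timings, written, save_json):
    import platform

    manifest = {
        "seed": config.seed,
        "stages_completed": list(timings),
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "python": platform.python_version(),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(Path(p)) for p in written if Path(p).exists()
        },
    }
    save_json(manifest, "manifest.json")
    art["manifest"] = manifest
    return art
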