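"""End-to-end analysis pipeline over a synthetic or user-supplied dataset.

``run_pipeline`` chains the stages in dependency order — curation statistics,
functional enrichment, mechanistic classification, gene properties,
co-mutation, prediction, screen calling — and emits one JSON report bundle.
Every source of randomness derives from the config seed, and the report
embeds the seed and a hash of the configuration so reruns are reproducible
and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import (
    BackgroundPairSet,
    SimConfig,
    StandardKind,
    apply_curation_filters,
    build_standard,
    class_distribution,
    compare_class_distributions,
    compare_property,
    comutation_enrichment,
    effect_fractions,
    evaluate_ranks,
    fold_enrichment,
    gen_annotation_universe,
    gen_mutation_matrix,
    gen_property_table,
    gen_screen_counts,
    gen_suppression_network,
    network_summary,
    prioritize,
    train_classifier,
    unique_interactions,
)
from .mechanisms import MechanismClass
from .network import StudyType
from .screen import call_suppressors, filter_guides, normalize_counts

logger = logging.getLogger("suppnet.pipeline")

ALL_STAGES = (
    "curate",
    "properties",
    "enrich",
    "classify",
    "comutate",
    "predict",
    "screen",
)


@dataclass
class RunConfig:
    """Pipeline configuration: seed, stage toggles, and thresholds."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    alpha: float = 0.05
    lfc_threshold: float = 2.0
    frac_threshold: float = 0.5
    flag_quantile: float = 0.95
    negative_rate: float = 10.0
    sim: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else str(f)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the requested stages on a seeded synthetic dataset; return the report."""
    t0 = time.time()
    sim_kwargs = dict(cfg.sim)
    sim_kwargs.setdefault("seed", cfg.seed)
    sim = SimConfig(**sim_kwargs)
    report: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "stages": {}}

    logger.info("generating annotation universe and suppression network")
    universe = gen_annotation_universe(sim)
    raw_net, truth = gen_suppression_network(sim, universe)
    net = apply_curation_filters(raw_net)
    pairs = unique_interactions(net)
    truth_pairs = set(zip(truth["query"], truth["suppressor"]))
    standards = {
        "co_complex": build_standard(universe.complexes, StandardKind.CO_COMPLEX),
        "co_pathway": build_standard(universe.pathways, StandardKind.CO_PATHWAY),
        "co_expression": build_standard(universe.clusters, StandardKind.CO_EXPRESSION),
        "co_localization": build_standard(universe.compartments, StandardKind.CO_LOCALIZATION),
    }
    background = BackgroundPairSet(net.queries, universe.gene_set, excluded=pairs)

    def stage_enabled(name: str) -> bool:
        return name in cfg.stages

    if stage_enabled("curate"):
        t = time.time()
        report["stages"]["curate"] = network_summary(net)
        logger.info("curate stage done in %.2fs", time.time() - t)

    if stage_enabled("properties"):
        t = time.time()
        table = gen_property_table(sim, universe, net)
        res = compare_property(net.queries, net.suppressors, universe.gene_set, table, "pli")
        report["stages"]["properties"] = {
            "property": "pli",
            "medians": {g: v["median"] for g, v in res["groups"].items()},
            "p_queries_vs_other": res["p_queries_vs_other"],
            "p_suppressors_vs_other": res["p_suppressors_vs_other"],
            "effect_fractions": effect_fractions(net),
        }
        logger.info("properties stage done in %.2fs", time.time() - t)

    if stage_enabled("enrich"):
        t = time.time()
        enrich = {}
        for name, std in standards.items():
            enrich[name] = fold_enrichment(pairs, std, background).as_dict()
        report["stages"]["enrich"] = enrich
        logger.info("enrich stage done in %.2fs", time.time() - t)

    if stage_enabled("classify"):
        t = time.time()
        dist = class_distribution(pairs, universe.process, universe.complexes, universe.pathways)
        cell = unique_interactions(net.by_study_type(StudyType.CELL))
        patient = unique_interactions(net.by_study_type(StudyType.PATIENT))
        cls_report = {
            "fractions": dist["fractions"],
            "family_fractions": dist["family_fractions"],
            "assigned_fraction": dist["assigned_fraction"],
        }
        if cell and patient:
            d_cell = class_distribution(
                cell, universe.process, universe.complexes, universe.pathways
            )
            d_pat = class_distribution(
                patient, universe.process, universe.complexes, universe.pathways
            )
            cls_report["cell_vs_patient_p"] = compare_class_distributions(d_cell, d_pat)
        planted = dict(zip(zip(truth["query"], truth["suppressor"]), truth["planted_class"]))
        labels = dist["labels"]
        overlap = [p for p in labels if p in planted]
        cls_report["planted_recovery"] = (
            sum(1 for p in overlap if labels[p].value == planted[p]) / len(overlap)
            if overlap
            else None
        )
        report["stages"]["classify"] = {
            k: v for k, v in cls_report.items()
        }
        logger.info("classify stage done in %.2fs", time.time() - t)

    if stage_enabled("comutate"):
        t = time.time()
        mm = gen_mutation_matrix(sim, truth_pairs, universe.genes)
        res = comutation_enrichment(pairs, background, mm, test="mannwhitney")
        report["stages"]["comutate"] = {
            "p_value": res["p_value"],
            "test": res["test"],
            "frac_comutated_suppression": res["curve_suppression"][0],
            "frac_comutated_background": res["curve_background"][0],
        }
        logger.info("comutate stage done in %.2fs", time.time() - t)

    if stage_enabled("predict"):
        t = time.time()
        rankings = {
            q: prioritize(q, universe.gene_set, standards) for q in sorted(net.queries)
        }
        eval_res = evaluate_ranks(rankings, pairs, thresholds=(10, 100))
        mm = gen_mutation_matrix(sim, truth_pairs, universe.genes)
        forest = train_classifier(
            sorted(pairs),
            list(background),
            standards,
            seed=cfg.seed,
            negative_rate=cfg.negative_rate,
            n_estimators=200,
            mm=mm,
        )
        report["stages"]["predict"] = {
            "n_queries": eval_res["n_queries"],
            "top_10": eval_res["top_10"],
            "top_100": eval_res["top_100"],
            "expected_top_100": eval_res["expected_top_100"],
            "forest_oob_auc": forest.oob_auc,
        }
        logger.info("predict stage done in %.2fs", time.time() - t)

    if stage_enabled("screen"):
        t = time.time()
        m, planted_genes = gen_screen_counts(sim)
        calls = call_suppressors(
            filter_guides(normalize_counts(m)),
            alpha=cfg.alpha,
            lfc_threshold=cfg.lfc_threshold,
            frac_threshold=cfg.frac_threshold,
        )
        called = sorted(c.gene for c in calls if c.called)
        report["stages"]["screen"] = {
            "n_genes_tested": len(calls),
            "called": called,
            "planted": planted_genes,
            "recovered_all_planted": set(called) == set(planted_genes),
        }
        logger.info("screen stage done in %.2fs", time.time() - t)

    report["runtime_s"] = round(time.time() - t0, 2)
    report = _jsonable(report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
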