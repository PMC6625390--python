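"""End-to-end orchestration: fixtures -> features -> train -> predict ->
evaluate -> crosstalk, with seeded reproducibility and a summary report.

Every stage writes its artifacts under the run directory; the summary
(``summary.json``) collects the numbers a reader needs: per-feature
coverage, cross-validation metrics, the ratio-sweep table, planted-pair
recovery, network topology and the pathway-crosstalk statistics.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .evaluation import ConfusionCounts, confusion_metrics, kfold_cv, pr_curve
from .features import feature_coverage
from .fixtures import FixtureBundle, FixtureConfig, generate_fixture
from .model import (
    ForestConfig,
    InteractionForest,
    LabeledFeatureTable,
    sweep_ratios,
)
from .network import (
    interaction_enrichment_matrix,
    overlap_matrix,
    topology_summary,
)
from .pairs import Pair

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "ppinet_run"
    seed: int = 17
    fixture: FixtureConfig | None = None  # defaults to FixtureConfig(seed=seed)
    forest: ForestConfig = field(default_factory=ForestConfig)
    cv_folds: int = 10
    sweep_ratios_plain: tuple[int, ...] = (1, 5, 10, 40)
    sweep_ratios_smote: tuple[int, ...] = (10, 20, 40)
    enrichment_replicates: int = 1000
    predict_all_pairs: bool = True
    stages: tuple[str, ...] = ("fixtures", "features", "train", "sweep", "predict", "crosstalk")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "fixture" in raw and raw["fixture"] is not None:
            raw["fixture"] = FixtureConfig(**raw["fixture"])
        if "forest" in raw:
            raw["forest"] = ForestConfig(**raw["forest"])
        for key in ("sweep_ratios_plain", "sweep_ratios_smote", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return (and write) the summary report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable({**asdict(config)})}
    t0 = time.time()
    stage_state: dict = {}

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    try:
        # --- fixtures
        fixture_config = config.fixture or FixtureConfig(seed=config.seed)
        if stage_enabled("fixtures"):
            bundle = generate_fixture(fixture_config, outdir / "fixtures")
            stage_state["bundle"] = bundle
            summary["fixtures"] = {
                "n_genes": fixture_config.n_genes,
                "n_planted_pairs": len(bundle.gold),
                "negative_pool": len(bundle.negative_pool),
            }
        else:
            bundle = generate_fixture(fixture_config)  # in-memory only
            stage_state["bundle"] = bundle

        # --- features
        if stage_enabled("features"):
            labeled_pairs = bundle.planted_pairs + bundle.negative_pool
            features = bundle.feature_table(labeled_pairs)
            pio.write_feature_table(features, outdir / "features.tsv")
            coverage = feature_coverage(features)
            summary["feature_coverage"] = _jsonable(coverage)
            stage_state["features"] = features
        else:
            raise RuntimeError("stage 'features' is required by all downstream stages")

        positives = features.loc[[tuple(p) for p in bundle.planted_pairs]]
        pool = features.drop(index=positives.index)

        # --- train (balanced reference model + cross-validation)
        if stage_enabled("train"):
            n_pos = len(positives)
            balanced_neg = pool.iloc[
                np.sort(
                    np.random.default_rng(config.seed).choice(len(pool), size=n_pos, replace=False)
                )
            ]
            table = LabeledFeatureTable.from_tables(positives, balanced_neg)
            results = InteractionForest(table, config.forest).fit()
            stage_state["results"] = results
            cv = kfold_cv(table, config.forest, k=config.cv_folds, seed=config.seed)
            cv.pop("per_fold")
            summary["cross_validation"] = _jsonable(cv)
            (outdir / "model_summary.txt").write_text(results.summary() + "\n")

        # --- ratio sweep
        if stage_enabled("sweep"):
            sweep = sweep_ratios(
                positives,
                pool,
                ratios=list(config.sweep_ratios_plain),
                smote_ratios=list(config.sweep_ratios_smote),
                config=config.forest,
                seed=config.seed,
            )
            sweep.to_csv(outdir / "ratio_sweep.tsv", sep="\t", index=False)
            summary["ratio_sweep"] = _jsonable(sweep.to_dict(orient="records"))

        # --- predict
        if stage_enabled("predict"):
            if "results" not in stage_state:
                raise RuntimeError("stage 'predict' needs stage 'train'")
            if config.predict_all_pairs:
                candidates: list[Pair] = [
                    (a, b) if a <= b else (b, a)
                    for a, b in itertools.combinations(bundle.genes, 2)
                ]
                candidate_features = bundle.feature_table(candidates)
            else:
                candidate_features = features
            scores, net = stage_state["results"].predict_interactome(candidate_features)
            stage_state["network"] = net
            pio.write_network_edgelist(net, outdir / "predicted_network.sif", fmt="sif")
            planted_scores = scores.loc[[tuple(p) for p in bundle.planted_pairs]]
            recovery = float((planted_scores >= config.forest.threshold).mean())
            labeled_scores = scores.loc[features.index]
            labels = np.r_[np.ones(len(positives), bool), np.zeros(len(pool), bool)]
            curve = pr_curve(labeled_scores.to_numpy(), labels)
            counts = ConfusionCounts.from_scores(
                labeled_scores.to_numpy(), labels, config.forest.threshold
            )
            topo = topology_summary(net)
            summary["prediction"] = _jsonable(
                {
                    "n_candidates": len(candidate_features),
                    "n_called": net.n_interactions,
                    "n_proteins": net.n_proteins,
                    "planted_recovery": recovery,
                    "pr_auc_labeled_pool": curve.auc,
                    "labeled_pool_metrics": confusion_metrics(counts),
                    "powerlaw_slope": topo.powerlaw_slope,
                    "average_clustering": topo.average_clustering,
                }
            )

        # --- crosstalk
        if stage_enabled("crosstalk"):
            if "network" not in stage_state:
                raise RuntimeError("stage 'crosstalk' needs stage 'predict'")
            net = stage_state["network"]
            overlaps = overlap_matrix(net, bundle.pathways)
            overlaps.to_csv(outdir / "pathway_overlap_matrix.tsv", sep="\t")
            fold, pval = interaction_enrichment_matrix(
                net, bundle.pathways, r=config.enrichment_replicates, seed=config.seed
            )
            fold.to_csv(outdir / "core_link_enrichment_fold.tsv", sep="\t")
            pval.to_csv(outdir / "core_link_enrichment_p.tsv", sep="\t")
            summary["crosstalk"] = _jsonable(
                {
                    "overlap_matrix": overlaps,
                    "enrichment_fold": fold,
                    "enrichment_p": pval,
                    "replicates": config.enrichment_replicates,
                }
            )
    except Exception as exc:  # persist partial state before propagating
        summary["failed_stage"] = getattr(exc, "stage", type(exc).__name__)
        summary["error"] = str(exc)
        (outdir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
        raise

    summary["wall_time_s"] = round(time.time() - t0, 2)
    (outdir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2) + "\n")
    return summary
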