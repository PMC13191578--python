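"""End-to-end pipeline: simulate/load -> screen -> compare -> tune -> explain.

``run_pipeline`` wires the stages together, writes every intermediate
artifact (CSV/JSON) into a run directory and aggregates a deterministic
``report.json``; two runs with the same config and seed are bit-identical.

The driver defaults deliberately scale the GA (population 12, 10
generations) and the Shapley estimator (50 permutations) so a full
619-sample run finishes in minutes on one CPU; the underlying modules keep
their own stated defaults for standalone use.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attrib
from .data_io import (
    DEFAULT_LABEL_COLUMN,
    FeatureTable,
    read_feature_table,
    stratified_split,
    write_feature_table,
)
from .derive import derive
from .ga import GAConfig, build_rf, default_rf_space, tune_rf
from .modeling import (
    ModelSpec,
    apply_preprocess,
    compare_models,
    evaluate,
    fit_preprocess,
    model_zoo,
)
from .screening import ScreeningConfig, run_three_tier
from .simulate import GeneratorConfig, generate

logger = logging.getLogger("aromatype")


@dataclass
class PipelineConfig:
    """Seeds and stage parameters for one reproducible run."""

    seed: int = 42
    input_csv: str | None = None  # when None, simulate
    generator: GeneratorConfig | None = None
    screening: ScreeningConfig | None = None
    test_fraction: float = 0.2
    cap_quantiles: tuple[float, float] = (0.01, 0.99)
    cv_folds: int = 5
    ga_population: int = 12
    ga_generations: int = 10
    ga_stall: int = 5
    shap_permutations: int = 50
    shap_background: int = 100
    pca_components: int = 3

    def resolved_generator(self) -> GeneratorConfig:
        return self.generator or GeneratorConfig(seed=self.seed)

    def resolved_screening(self) -> ScreeningConfig:
        return self.screening or ScreeningConfig(seed=self.seed)

    def resolved_ga(self) -> GAConfig:
        return GAConfig(
            population_size=self.ga_population,
            max_generations=self.ga_generations,
            stall_generations=self.ga_stall,
            seed=self.seed,
        )


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and return the aggregated report (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"config": _config_dict(config)}

    # --- data
    if config.input_csv is not None:
        raw = read_feature_table(config.input_csv, DEFAULT_LABEL_COLUMN)
        logger.info("loaded %d x %d table from %s", raw.n_samples, raw.n_features,
                    config.input_csv)
    else:
        raw = generate(config.resolved_generator())
        logger.info("simulated %d x %d table", raw.n_samples, raw.n_features)
    write_feature_table(raw, out / "data.csv")
    report["data"] = {
        "n_samples": raw.n_samples,
        "n_features": raw.n_features,
        "class_counts": [int(np.sum(raw.labels == c)) for c in (0, 1, 2)],
    }

    # --- three-tier screening
    screening_report = run_three_tier(raw, config.resolved_screening())
    _dump_json(screening_report.to_dict(), out / "screening_report.json")
    keys = screening_report.final
    logger.info("screening kept %d key features: %s", len(keys), keys)
    report["screening"] = {
        "n_key_features": len(keys),
        "key_features": keys,
        "per_dataset_kept": {
            k: v.kept for k, v in screening_report.datasets.items()
        },
    }

    # --- key-feature dataset and split
    expanded, _ = derive(raw)
    key_table = expanded.select_features(keys)
    write_feature_table(key_table, out / "keys.csv")
    train, test = stratified_split(key_table, config.test_fraction, config.seed)
    write_feature_table(train, out / "train.csv")
    write_feature_table(test, out / "test.csv")
    report["split"] = {
        "train_size": train.n_samples,
        "test_size": test.n_samples,
        "test_class_counts": [int(np.sum(test.labels == c)) for c in (0, 1, 2)],
    }

    # --- model comparison on the training split
    ranking = compare_models(train, model_zoo(config.seed), config.cv_folds, config.seed)
    report["model_comparison"] = {name: m.to_dict() for name, m in ranking}
    report["model_ranking"] = [name for name, _ in ranking]
    _dump_json(report["model_comparison"], out / "model_comparison.json")

    # --- GA tuning of the random forest
    best_params, forest, best_fitness, history = tune_rf(
        train, default_rf_space(), config.resolved_ga(), config.cv_folds,
        rf_seed=config.seed,
    )
    _dump_json(
        {"best_params": best_params, "cv_macro_f1": best_fitness, "history": history},
        out / "tuned.json",
    )
    report["ga"] = {
        "best_params": best_params,
        "cv_macro_f1": best_fitness,
        "generations_run": len(history),
    }

    # --- held-out evaluation (preprocessing fitted on train only)
    params = fit_preprocess(train, config.cap_quantiles)
    train_p, test_p = apply_preprocess(params, train), apply_preprocess(params, test)
    tuned = build_rf(best_params, config.seed)
    tuned.fit(train_p.values, train_p.labels)
    test_metrics = evaluate(tuned, test_p)
    report["test_metrics"] = test_metrics.to_dict()
    _dump_json(report["test_metrics"], out / "test_metrics.json")

    # --- Shapley interpretation on the test split
    background = attrib.sample_background(train_p, config.shap_background, config.seed)
    attr = attrib.shapley_attributions(
        tuned.predict_proba, background, test_p,
        n_permutations=config.shap_permutations, seed=config.seed,
    )
    imp = attrib.global_importance(attr)
    imp_df = pd.DataFrame(
        np.vstack([imp["per_class"], imp["pooled"]]).T,
        index=attr.feature_names,
        columns=["class_0", "class_1", "class_2", "pooled"],
    )
    imp_df.to_csv(out / "global_importance.csv", index_label="feature")
    for cls in (0, 1, 2):
        rows = []
        for name, pairs in attrib.beeswarm_export(attr, cls).items():
            for raw_v, shap_v in pairs:
                rows.append((name, raw_v, shap_v))
        pd.DataFrame(rows, columns=["feature", "value", "shap"]).to_csv(
            out / f"beeswarm_{cls}.csv", index=False
        )
    thresholds = {}
    for name in attr.feature_names:
        for cls in (0, 1, 2):
            thr = attrib.dependence_threshold(attr, name, cls)
            if thr is not None:
                thresholds[f"{name}|class{cls}"] = thr
    _dump_json(thresholds, out / "dependence_thresholds.json")
    report["attribution"] = {
        "top_feature_pooled": attr.feature_names[int(np.argmax(imp["pooled"]))],
        "mean_efficiency_residual": float(attr.efficiency_residuals().mean()),
        "dependence_thresholds": thresholds,
    }

    # --- PCA of the key-feature dataset
    scores, loadings, evr = attrib.pca_scores_loadings(
        key_table, min(config.pca_components, len(keys), key_table.n_samples - 1)
    )
    pd.DataFrame(
        scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    ).assign(aroma_type=key_table.labels).to_csv(out / "pca_scores.csv", index=False)
    pd.DataFrame(
        loadings,
        index=keys,
        columns=[f"PC{i+1}" for i in range(loadings.shape[1])],
    ).to_csv(out / "pca_loadings.csv", index_label="feature")
    report["pca"] = {"explained_variance_ratio": evr.tolist()}

    report["runtime_seconds"] = round(time.time() - t0, 3)
    # runtime varies between runs; keep report.json bit-reproducible without it
    stable = {k: v for k, v in report.items() if k != "runtime_seconds"}
    _dump_json(stable, out / "report.json")
    logger.info("pipeline finished in %.1f s", report["runtime_seconds"])
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    gen = config.resolved_generator()
    d["generator"] = {
        "class_sizes": list(gen.class_sizes),
        "n_indices": len(gen.catalog),
        "correlation": gen.correlation,
        "seed": gen.seed,
        "effects": {f"{c}|{n}": v for (c, n), v in sorted(gen.effects.items())},
    }
    d["screening"] = asdict(config.resolved_screening())
    return d
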