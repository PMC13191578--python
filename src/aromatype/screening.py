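"""Three-tier key-feature screening cascade.

Tier 1 retains features whose separation index exceeds 0.8 for at least one
aroma-type pair; tier 2 ranks the survivors of each operation-type dataset
(primitive / additive / subtractive / divisive) by random-forest mean decrease
in impurity averaged over 5 stratified CV folds and keeps the top 10
(primitives keep all tier-1 survivors); tier 3 greedily eliminates one member
of every candidate pair with |Pearson r| > 0.8, preferring to keep the more
important — and on an importance tie the higher-content — feature.  The final
key set is the union across datasets, followed by one cross-dataset pruning
pass at the same threshold so the set is jointly non-redundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data_io import FeatureTable, stratified_kfold
from .derive import (
    KINDS,
    PRIMITIVE,
    FeatureDescriptor,
    derive,
    descriptors_by_name,
    split_by_kind,
)
from .separability import SeparabilityScores, filter_separable, score_all

#: Content level (mg g^-1) above which the tie-break prefers a feature.
CONTENT_NOTE_THRESHOLD = 1.0


def rf_importance(
    table: FeatureTable,
    n_folds: int = 5,
    seed: int = 42,
    n_estimators: int = 100,
) -> dict[str, float]:
    """Fold-averaged random-forest impurity importance per feature.

    A 100-tree forest (min_samples_split=2, min_samples_leaf=1, seeded) is fit
    on each of ``n_folds`` stratified training folds; the mean decrease in
    impurity is averaged across the fold models.
    """
    if table.labels is None:
        raise ValueError("rf_importance requires labels")
    folds = stratified_kfold(table.labels, n_folds, seed)
    total = np.zeros(table.n_features)
    for train_idx, _ in folds:
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            min_samples_split=2,
            min_samples_leaf=1,
            random_state=seed,
            n_jobs=1,
        )
        forest.fit(table.values[train_idx], table.labels[train_idx])
        total += forest.feature_importances_
    mean = total / len(folds)
    return dict(zip(table.feature_names, mean.tolist()))


def top_k(importances: Mapping[str, float], k: int = 10) -> list[str]:
    """The ``k`` highest-importance names, descending; ties keep catalog order."""
    names = list(importances)
    order = sorted(range(len(names)), key=lambda i: (-importances[names[i]], i))
    return [names[i] for i in order[: max(k, 0)]]


def _content_of(
    name: str,
    content_levels: Mapping[str, float],
    descriptors: Mapping[str, FeatureDescriptor] | None,
) -> float:
    """Content level of a feature: for composites, the mean of its primitives'."""
    if descriptors is not None and name in descriptors:
        prims = descriptors[name].primitives
    else:
        prims = (name,)
    return float(np.mean([content_levels.get(p, 0.0) for p in prims]))


@dataclass
class PrunedPair:
    name_a: str
    name_b: str
    r: float
    dropped: str


def prune_correlated(
    table: FeatureTable,
    importances: Mapping[str, float],
    content_levels: Mapping[str, float],
    threshold: float = 0.8,
    descriptors: Mapping[str, FeatureDescriptor] | None = None,
) -> tuple[list[str], list[PrunedPair]]:
    """Greedy redundancy pruning of |Pearson r| > threshold candidate pairs.

    Pairs are processed in descending |r|; from each still-unresolved pair the
    member with lower importance is dropped; importance ties fall back to the
    lower substance-content member (content of a composite = mean content of
    its constituent primitives), then to later column order.  Zero-variance
    features have undefined correlations and are dropped with a warning.
    """
    if table.n_samples < 2:
        raise ValueError("pruning requires >= 2 samples")
    names = list(table.feature_names)
    X = table.values
    variances = X.std(axis=0)
    alive = dict.fromkeys(names, True)
    for j, name in enumerate(names):
        if variances[j] == 0:
            warnings.warn(
                f"feature {name!r} has zero variance; dropped from candidates",
                RuntimeWarning,
                stacklevel=2,
            )
            alive[name] = False

    live_idx = [j for j, n in enumerate(names) if alive[n]]
    pruned: list[PrunedPair] = []
    if len(live_idx) >= 2:
        corr = np.corrcoef(X[:, live_idx], rowvar=False)
        pairs = []
        for a in range(len(live_idx)):
            for b in range(a + 1, len(live_idx)):
                r = corr[a, b]
                if abs(r) > threshold:
                    pairs.append((abs(r), a, b, r))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        for _, a, b, r in pairs:
            na, nb = names[live_idx[a]], names[live_idx[b]]
            if not (alive[na] and alive[nb]):
                continue
            drop = _choose_drop(na, nb, importances, content_levels, descriptors)
            alive[drop] = False
            pruned.append(PrunedPair(na, nb, float(r), drop))
    kept = [n for n in names if alive[n]]
    return kept, pruned


def _choose_drop(na, nb, importances, content_levels, descriptors) -> str:
    ia, ib = importances.get(na, 0.0), importances.get(nb, 0.0)
    if ia != ib:
        return na if ia < ib else nb
    ca = _content_of(na, content_levels, descriptors)
    cb = _content_of(nb, content_levels, descriptors)
    if ca != cb:
        return na if ca < cb else nb
    return nb  # total tie: keep the earlier column


@dataclass
class ScreeningConfig:
    seed: int = 42
    separability_method: str = "gaussian"
    separability_threshold: float = 0.8
    separability_rule: str = "any"
    top_k: int = 10
    corr_threshold: float = 0.8
    n_folds: int = 5
    n_estimators: int = 100


@dataclass
class DatasetReport:
    """Per-operation-type record of the cascade."""

    retained: list[str] = field(default_factory=list)
    importances: dict[str, float] = field(default_factory=dict)
    top: list[str] = field(default_factory=list)
    pruned: list[PrunedPair] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)


@dataclass
class ScreeningReport:
    datasets: dict[str, DatasetReport]
    final_pruned: list[PrunedPair]
    final: list[str]
    cross_dataset_pass: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def run_three_tier(
    raw: FeatureTable, config: ScreeningConfig | None = None
) -> ScreeningReport:
    """Run derive -> separability -> RF importance / top-k -> pruning -> union.

    Fully deterministic given (data, config).  Within each dataset the final
    kept set is a subset of its top-k, itself a subset of the tier-1
    survivors.
    """
    if raw.labels is None:
        raise ValueError("screening requires labels")
    cfg = config or ScreeningConfig()
    expanded, descriptors = derive(raw)
    by_name = descriptors_by_name(descriptors)
    datasets = split_by_kind(expanded, descriptors)
    content_levels = {
        name: float(np.mean(raw.column(name))) for name in raw.feature_names
    }

    reports: dict[str, DatasetReport] = {}
    union: list[str] = []
    union_importances: dict[str, float] = {}
    for kind in KINDS:
        ds = datasets[kind]
        rep = DatasetReport()
        scores: SeparabilityScores = score_all(ds, method=cfg.separability_method)
        rep.retained = filter_separable(
            scores, cfg.separability_threshold, cfg.separability_rule
        )
        if len(rep.retained) >= 2:
            survivors = ds.select_features(rep.retained)
            rep.importances = rf_importance(
                survivors, cfg.n_folds, cfg.seed, cfg.n_estimators
            )
            # primitives keep every tier-1 survivor; composites keep the top k
            k = len(rep.retained) if kind == PRIMITIVE else cfg.top_k
            rep.top = top_k(rep.importances, k)
            candidates = ds.select_features(rep.top)
            rep.kept, rep.pruned = prune_correlated(
                candidates,
                rep.importances,
                content_levels,
                cfg.corr_threshold,
                by_name,
            )
        elif len(rep.retained) == 1:
            rep.importances = {rep.retained[0]: 1.0}
            rep.top = list(rep.retained)
            rep.kept = list(rep.retained)
        reports[kind] = rep
        union.extend(rep.kept)
        union_importances.update({n: rep.importances.get(n, 0.0) for n in rep.kept})

    final_pruned: list[PrunedPair] = []
    final = list(union)
    if len(union) >= 2:
        union_table = expanded.select_features(union)
        final, final_pruned = prune_correlated(
            union_table,
            union_importances,
            content_levels,
            cfg.corr_threshold,
            by_name,
        )
    return ScreeningReport(
        datasets=reports,
        final_pruned=final_pruned,
        final=final,
        cross_dataset_pass=True,
    )
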