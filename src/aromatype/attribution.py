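"""Shapley-value model interpretation and PCA export.

Attributions are estimated with a Monte-Carlo permutation Shapley scheme: for
each random feature ordering, features are switched one by one from a
background row's values to the explained sample's values, and the marginal
change in each class probability is credited to the switched feature.
Averaged over orderings and background rows this converges to the Shapley
value of the class-probability game, so for every sample the per-class
attributions plus the class base value (mean predicted probability over the
background) sum to the predicted probability, up to Monte-Carlo error.

Also provided: global importance (mean |Shapley|), beeswarm export
(raw value, attribution) pairs, sign-change dependence thresholds (the
content at which a feature's contribution to a class flips sign), and
standardized-PCA scores/loadings for visualizing the key-feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.decomposition import PCA

from .data_io import FeatureTable


@dataclass
class AttributionResult:
    """Per-class, per-sample, per-feature Shapley values in probability units."""

    feature_names: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_classes, n_samples, n_features)
    base_values: np.ndarray  # (n_classes,)
    raw: np.ndarray  # (n_samples, n_features) explained feature values
    predictions: np.ndarray  # (n_samples, n_classes) model probabilities

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    def efficiency_residuals(self) -> np.ndarray:
        """|base + sum(phi) - p| per sample and class; small under convergence."""
        total = self.base_values[:, None] + self.values.sum(axis=2)
        return np.abs(total - self.predictions.T)


def shapley_attributions(
    predict_proba: Callable[[np.ndarray], np.ndarray],
    background: FeatureTable | np.ndarray,
    X: FeatureTable | np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> AttributionResult:
    """Monte-Carlo permutation Shapley values for every explained sample.

    Each permutation draws one feature ordering (shared across samples) and an
    independent background row per sample; the class-probability deltas along
    the switch path are credited to the switched features.  Deterministic
    under ``seed``.
    """
    if isinstance(background, FeatureTable):
        bg = background.values
    else:
        bg = np.asarray(background, dtype=float)
    if isinstance(X, FeatureTable):
        names = list(X.feature_names)
        ids = list(X.sample_ids)
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
        ids = [str(i) for i in range(Xv.shape[0])]
    if bg.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if bg.shape[1] != Xv.shape[1]:
        raise ValueError("background and X feature counts differ")

    rng = np.random.default_rng(seed)
    n, d = Xv.shape
    bg_proba = np.asarray(predict_proba(bg))
    n_classes = bg_proba.shape[1]
    base = bg_proba.mean(axis=0)
    phi = np.zeros((n_classes, n, d))

    # balanced background cycling: each explained sample walks through the
    # (shuffled) background rows evenly across permutations, so the
    # background-mean term of the efficiency identity carries no sampling
    # error once permutations cover the rows a whole number of times
    bg = bg[rng.permutation(bg.shape[0])]
    n_bg = bg.shape[0]
    for t in range(n_permutations):
        order = rng.permutation(d)
        rows = (np.arange(n) + t) % n_bg
        z = bg[rows].copy()
        p_prev = np.asarray(predict_proba(z))
        for j in order:
            z[:, j] = Xv[:, j]
            p_new = np.asarray(predict_proba(z))
            phi[:, :, j] += (p_new - p_prev).T
            p_prev = p_new
    phi /= n_permutations

    predictions = np.asarray(predict_proba(Xv))
    return AttributionResult(names, ids, phi, base, Xv.copy(), predictions)


def exact_shapley(
    predict_proba: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    X: np.ndarray,
    max_features: int = 5,
) -> np.ndarray:
    """Exact Shapley values by full enumeration of feature orderings.

    Independent oracle for small models (d! orderings, so d <= ``max_features``).
    Returns an array of shape (n_classes, n_samples, n_features).
    """
    from itertools import permutations

    bg = np.asarray(background, dtype=float)
    Xv = np.asarray(X, dtype=float)
    n, d = Xv.shape
    if d > max_features:
        raise ValueError(f"exact enumeration limited to {max_features} features")
    n_classes = np.asarray(predict_proba(bg[:1])).shape[1]
    phi = np.zeros((n_classes, n, d))
    orders = list(permutations(range(d)))
    for order in orders:
        for b in range(bg.shape[0]):
            z = np.tile(bg[b], (n, 1))
            p_prev = np.asarray(predict_proba(z))
            for j in order:
                z[:, j] = Xv[:, j]
                p_new = np.asarray(predict_proba(z))
                phi[:, :, j] += (p_new - p_prev).T
                p_prev = p_new
    return phi / (len(orders) * bg.shape[0])


def sample_background(
    train: FeatureTable, max_rows: int = 100, seed: int = 0
) -> FeatureTable:
    """Up to ``max_rows`` training rows, sampled without replacement."""
    if train.n_samples <= max_rows:
        return train.take(np.arange(train.n_samples))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(train.n_samples, size=max_rows, replace=False))
    return train.take(idx)


def global_importance(attr: AttributionResult) -> dict[str, np.ndarray]:
    """Mean |Shapley| per feature: one row per class plus the class-pooled mean."""
    per_class = np.abs(attr.values).mean(axis=1)  # (n_classes, d)
    return {"per_class": per_class, "pooled": per_class.mean(axis=0)}


def beeswarm_export(attr: AttributionResult, cls: int) -> dict[str, np.ndarray]:
    """Per feature, the (raw value, Shapley value) pairs behind a beeswarm plot."""
    out = {}
    for j, name in enumerate(attr.feature_names):
        out[name] = np.column_stack([attr.raw[:, j], attr.values[cls, :, j]])
    return out


def dependence_threshold(
    attr: AttributionResult, feature: str, cls: int
) -> float | None:
    """Feature content at which its smoothed attribution to ``cls`` changes sign.

    Samples are sorted by raw feature value; attributions are smoothed with a
    centered moving average (window = max(5, n/20)); the raw value at the
    first sign change of the smoothed curve is returned (linear interpolation
    between the bracketing samples), or None when the curve never crosses
    zero.
    """
    j = attr.feature_names.index(feature)
    x = attr.raw[:, j]
    s = attr.values[cls, :, j]
    n = len(x)
    if n < 10:
        raise ValueError("dependence threshold requires >= 10 samples")
    order = np.argsort(x, kind="stable")
    x, s = x[order], s[order]
    window = max(5, n // 20)
    kernel = np.ones(window) / window
    # centered moving average with edge shrinkage
    smooth = np.convolve(s, kernel, mode="same")
    norm = np.convolve(np.ones(n), kernel, mode="same")
    smooth = smooth / norm
    for i in range(n - 1):
        a, b = smooth[i], smooth[i + 1]
        if a == 0.0:
            return float(x[i])
        if a * b < 0:
            t = a / (a - b)
            return float(x[i] + t * (x[i + 1] - x[i]))
    if smooth[-1] == 0.0:
        return float(x[-1])
    return None


def pca_scores_loadings(
    table: FeatureTable | np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized PCA: scores, loadings (features x components), variance fractions.

    Features are Z-scored first, so loadings are comparable across indices of
    different magnitude.
    """
    X = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds min(samples-1, features)")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature; PCA on standardized data undefined")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T
    return scores, loadings, pca.explained_variance_ratio_
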