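"""Peak-resolution separation index between class-conditional distributions.

Screening tier 1.  For a feature measured in two aroma types, the separation
index is

    f = 1.18 * |dX| / (W1 + W2)

where dX is the distance between the centers of the two frequency-distribution
peaks and W1, W2 are their half-peak widths (FWHM).  This is the
chromatographic-resolution statistic transplanted to class-conditional
distributions; f > 0.8 marks a feature with some power to separate the pair.

Two peak estimators are provided: ``gaussian`` (default) takes the sample
mean and the normal-density FWHM ``2*sqrt(2*ln 2)*sd``, which is deterministic
and closed-form testable; ``kde`` reads center and half-height width off a
Gaussian-kernel density estimate, the literal frequency-distribution-peak
variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .data_io import FeatureTable, VALID_LABELS

RESOLUTION_CONSTANT = 1.18
#: FWHM of a unit-variance normal density.
GAUSSIAN_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Class pairs scored, in reporting order: f01, f12, f02.
CLASS_PAIRS = ((0, 1), (1, 2), (0, 2))
PAIR_NAMES = ("f01", "f12", "f02")

_KDE_GRID = 512


def peak_stats(values, method: str = "gaussian") -> tuple[float, float]:
    """Center and half-peak width (FWHM) of one sample's distribution peak.

    ``gaussian``: sample mean and 2.3548 * sample SD.  ``kde``: mode of a
    Silverman-bandwidth Gaussian KDE on a 512-point grid and the distance
    between the two half-height crossings around it (linear interpolation);
    the grid is widened once (x2) if a crossing falls outside it.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("peak_stats requires at least 2 values")
    if method == "gaussian":
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValueError("zero spread: gaussian peak width undefined")
        return float(np.mean(x)), GAUSSIAN_FWHM * sd
    if method == "kde":
        return _kde_peak(x)
    raise ValueError(f"unknown method {method!r}")


def _kde_peak(x: np.ndarray) -> tuple[float, float]:
    if float(np.std(x)) == 0.0:
        raise ValueError("zero spread: kde peak width undefined")
    kde = gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor * np.std(x, ddof=1))
    pad = 3.0 * bw
    for attempt in range(2):
        lo, hi = x.min() - pad, x.max() + pad
        grid = np.linspace(lo, hi, _KDE_GRID)
        dens = kde(grid)
        k = int(np.argmax(dens))
        half = dens[k] / 2.0
        left = _cross(grid, dens, k, half, direction=-1)
        right = _cross(grid, dens, k, half, direction=+1)
        if left is not None and right is not None:
            return float(grid[k]), float(right - left)
        pad *= 4.0
    raise ValueError("no half-height crossing within widened KDE grid")


def _cross(grid, dens, k, half, direction) -> float | None:
    """Half-height crossing nearest the mode, by linear interpolation."""
    i = k
    while 0 <= i + direction < len(grid):
        j = i + direction
        if dens[j] <= half:
            t = (dens[i] - half) / (dens[i] - dens[j])
            return float(grid[i] + t * (grid[j] - grid[i]))
        i = j
    return None


def separation_index(values_a, values_b, method: str = "gaussian") -> float:
    """Separation index f = 1.18 * |centerA - centerB| / (widthA + widthB)."""
    ca, wa = peak_stats(values_a, method)
    cb, wb = peak_stats(values_b, method)
    return RESOLUTION_CONSTANT * abs(ca - cb) / (wa + wb)


@dataclass
class SeparabilityScores:
    """Per-feature pairwise separation indices (columns f01, f12, f02)."""

    feature_names: list[str]
    values: np.ndarray  # shape (n_features, 3), order f01, f12, f02

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_names), 3):
            raise ValueError("scores must be (n_features, 3)")

    def of(self, name: str) -> dict[str, float]:
        row = self.values[self.feature_names.index(name)]
        return dict(zip(PAIR_NAMES, row.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names, columns=PAIR_NAMES)


def score_all(table: FeatureTable, method: str = "gaussian") -> SeparabilityScores:
    """Separation indices for every feature and class pair.

    Requires all three aroma types present with >= 2 samples.  Features whose
    peak statistics fail for a pair (zero spread, no KDE crossing) score 0 for
    that pair, with a warning.
    """
    if table.labels is None:
        raise ValueError("score_all requires labels")
    groups = {}
    for c in VALID_LABELS:
        idx = np.flatnonzero(table.labels == c)
        if idx.size < 2:
            raise ValueError(f"class {c} needs >= 2 samples (has {idx.size})")
        groups[c] = table.values[idx]

    p = table.n_features
    out = np.zeros((p, 3))
    if method == "gaussian":
        means = {c: g.mean(axis=0) for c, g in groups.items()}
        widths = {c: GAUSSIAN_FWHM * g.std(axis=0, ddof=1) for c, g in groups.items()}
        for k, (a, b) in enumerate(CLASS_PAIRS):
            denom = widths[a] + widths[b]
            ok = denom > 0
            out[ok, k] = RESOLUTION_CONSTANT * np.abs(means[a] - means[b])[ok] / denom[ok]
            if not ok.all():
                warnings.warn(
                    f"{int((~ok).sum())} feature(s) with zero spread scored 0 "
                    f"for pair {PAIR_NAMES[k]}",
                    RuntimeWarning,
                    stacklevel=2,
                )
    else:
        for j in range(p):
            for k, (a, b) in enumerate(CLASS_PAIRS):
                try:
                    out[j, k] = separation_index(
                        groups[a][:, j], groups[b][:, j], method
                    )
                except ValueError as exc:
                    warnings.warn(
                        f"feature {table.feature_names[j]!r} pair "
                        f"{PAIR_NAMES[k]}: {exc}; scored 0",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    out[j, k] = 0.0
    return SeparabilityScores(list(table.feature_names), out)


def filter_separable(
    scores: SeparabilityScores, threshold: float = 0.8, rule: str = "any"
) -> list[str]:
    """Feature names passing the f > threshold filter (strict inequality).

    ``any`` (default) retains a feature when its best class pair exceeds the
    threshold; ``all`` requires every pair to.  Order is preserved.
    """
    if rule == "any":
        agg = scores.values.max(axis=1)
    elif rule == "all":
        agg = scores.values.min(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return [n for n, v in zip(scores.feature_names, agg) if v > threshold]
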