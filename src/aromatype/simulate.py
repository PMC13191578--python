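"""Synthetic chemical-profile generator.

Emulates the statistical structure of a flue-cured tobacco chemistry survey:
619 samples in three imbalanced aroma-type classes (411 fresh-sweet, 151
honey-sweet, 57 mellow-sweet) measured on 51 chemical indices spanning
conventional components, sugars, alkaloids, polyphenols, sugar alcohols,
organic acids and free amino acids.  Per class the indices are drawn from a
multivariate Gaussian with within-group block correlation; marker substances
carry class-dependent mean shifts (rutin elevated in fresh-sweet, chlorogenic
acid depressed in mellow-sweet, ...).  Values are kept strictly positive by
resampling non-positive coordinates from their truncated-positive marginal,
so downstream ratio features never divide by zero.

The baseline means and SDs are invented plausible values on the mg g^-1
scale; they are fixtures for exercising the pipeline, not claims about real
tobacco chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .data_io import FeatureTable

N_INDICES = 51

#: Default planted marker shift, in SD units.  At 4 SD the Gaussian-limit
#: separation index is 1.18 * 4 / 4.7096 ~ 1.002, comfortably above the 0.8
#: screening threshold (a 3 SD shift sits at ~0.75, below it).
MARKER_SHIFT = 4.0


@dataclass(frozen=True)
class IndexSpec:
    """One chemical index: name, substance group, baseline mean and SD (mg g^-1)."""

    name: str
    group: str
    mean: float
    sd: float


def _catalog_entries() -> list[tuple[str, str, float, float]]:
    # (name, group, baseline mean, baseline SD); SD ~= 18% of mean unless the
    # index is a planted marker with a hand-set spread.
    conventional = [
        ("total sugars", 250.0), ("reducing sugar", 200.0), ("starch", 40.0),
        ("protein", 80.0), ("total nitrogen", 20.0), ("potassium", 22.0),
        ("chlorine", 5.0),
    ]
    sugars = [
        ("glucose", 80.0), ("sucrose", 90.0), ("fructose", 70.0),
        ("rhamnose", 2.0), ("maltose", 5.0),
    ]
    alkaloids = [
        ("total alkaloids", 25.0), ("nicotine", 22.0), ("anatabine", 1.2),
        ("anabasine", 0.15), ("nornicotine", 0.6),
    ]
    polyphenols = [
        ("rutin", 9.0), ("chlorogenic acid", 14.0),
        ("cryptochlorogenic acid", 2.5), ("scopoletin", 0.3),
    ]
    sugar_alcohols = [
        ("xylitol", 0.8), ("mannitol", 1.5), ("glycerol", 2.5),
        ("sorbitol", 0.6), ("inositol", 3.0),
    ]
    organic_acids = [
        ("malonic acid", 4.0), ("oxalic acid", 10.0), ("succinic acid", 1.5),
        ("citric acid", 6.0), ("malic acid", 25.0), ("quinic acid", 7.0),
    ]
    amino_acids = [
        ("serine", 1.2), ("proline", 3.0), ("valine", 0.5), ("lysine", 0.4),
        ("histidine", 0.25), ("tryptophan", 0.3), ("phenylalanine", 0.6),
        ("asparagine", 1.8), ("glutamine", 1.0), ("alanine", 0.8),
        ("glutamic acid", 1.5), ("isoleucine", 0.35), ("leucine", 0.4),
        ("threonine", 0.45), ("glycine", 0.3), ("methionine", 0.15),
        ("tyrosine", 0.4), ("arginine", 0.5), ("aspartic acid", 1.2),
    ]
    override_sd = {"rutin": 2.5, "chlorogenic acid": 2.0, "anatabine": 0.25,
                   "serine": 0.3}
    groups = [
        ("conventional", conventional), ("sugar", sugars),
        ("alkaloid", alkaloids), ("polyphenol", polyphenols),
        ("sugar alcohol", sugar_alcohols), ("organic acid", organic_acids),
        ("amino acid", amino_acids),
    ]
    entries = []
    for group, members in groups:
        for name, mean in members:
            sd = override_sd.get(name, round(0.18 * mean, 4))
            entries.append((name, group, mean, sd))
    return entries


def default_index_catalog() -> list[IndexSpec]:
    """The 51-index catalog: names, groups and baseline moments."""
    catalog = [IndexSpec(*e) for e in _catalog_entries()]
    assert len(catalog) == N_INDICES
    return catalog


def default_effects() -> dict[tuple[int, str], float]:
    """Class-dependent additive mean shifts, in SD units.

    Four planted markers at +/-4 SD — rutin high in fresh-sweet (0),
    chlorogenic acid low in mellow-sweet (2), anatabine high in mellow-sweet,
    serine high in honey-sweet (1) — plus mild sub-threshold structure so the
    classifier has more than the markers to work with.
    """
    return {
        (0, "rutin"): MARKER_SHIFT,
        (2, "chlorogenic acid"): -MARKER_SHIFT,
        (2, "anatabine"): MARKER_SHIFT,
        (1, "serine"): MARKER_SHIFT,
        (0, "total sugars"): 1.0,
        (2, "total sugars"): -0.5,
        (1, "nicotine"): 0.8,
        (0, "proline"): 0.7,
    }


DEFAULT_MARKERS = ("rutin", "chlorogenic acid", "anatabine", "serine")


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic survey."""

    class_sizes: tuple[int, int, int] = (411, 151, 57)
    catalog: list[IndexSpec] = field(default_factory=default_index_catalog)
    effects: dict[tuple[int, str], float] = field(default_factory=default_effects)
    correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.catalog) != N_INDICES:
            raise ValueError(f"catalog must hold exactly {N_INDICES} indices")
        if any(s.mean <= 0 or s.sd <= 0 for s in self.catalog):
            raise ValueError("baseline means and SDs must be positive")
        if not 0 <= abs(self.correlation) < 1:
            raise ValueError("|correlation| must be < 1")
        if any(n <= 0 for n in self.class_sizes):
            raise ValueError("class sizes must be positive")
        names = [s.name for s in self.catalog]
        unknown = {n for (_, n) in self.effects} - set(names)
        if unknown:
            raise ValueError(f"effects reference unknown indices {sorted(unknown)}")

    def class_means(self) -> np.ndarray:
        """Configured per-class mean matrix, shape (3, 51)."""
        base = np.array([s.mean for s in self.catalog])
        sds = np.array([s.sd for s in self.catalog])
        means = np.tile(base, (3, 1))
        name_idx = {s.name: j for j, s in enumerate(self.catalog)}
        for (c, name), shift in self.effects.items():
            j = name_idx[name]
            means[c, j] += shift * sds[j]
        return means


def _correlation_matrix(catalog: list[IndexSpec], r: float) -> np.ndarray:
    groups = np.array([s.group for s in catalog])
    same = groups[:, None] == groups[None, :]
    R = np.where(same, r, 0.0)
    np.fill_diagonal(R, 1.0)
    return R


def generate(config: GeneratorConfig) -> FeatureTable:
    """Draw a labelled synthetic feature table, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    sds = np.array([s.sd for s in config.catalog])
    R = _correlation_matrix(config.catalog, config.correlation)
    cov = R * np.outer(sds, sds)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("constructed covariance is not positive definite") from exc

    means = config.class_means()
    blocks = []
    labels = []
    for c, n in enumerate(config.class_sizes):
        z = rng.standard_normal((n, len(config.catalog)))
        x = means[c] + z @ L.T
        # strict positivity: redraw non-positive coordinates from the
        # truncated-positive marginal (no point mass at zero)
        bad_rows, bad_cols = np.nonzero(x <= 0)
        for i, j in zip(bad_rows, bad_cols):
            a = (0.0 - means[c, j]) / sds[j]
            x[i, j] = truncnorm.rvs(
                a, np.inf, loc=means[c, j], scale=sds[j], random_state=rng
            )
        blocks.append(x)
        labels.extend([c] * n)

    values = np.vstack(blocks)
    n_total = values.shape[0]
    ids = [f"S{i:04d}" for i in range(n_total)]
    return FeatureTable(
        ids, [s.name for s in config.catalog], values, np.asarray(labels)
    )
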