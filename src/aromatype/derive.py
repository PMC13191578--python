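"""Pairwise-arithmetic feature derivation.

Expands ``p`` primitive chemical indices into composites by elementwise
addition, subtraction and division:

* additive: all unordered pairs *including* self-pairs (i <= j) -> p(p+1)/2
* subtractive: unordered pairs i < j, oriented earlier - later -> p(p-1)/2
* divisive: unordered pairs i < j, oriented earlier / later -> p(p-1)/2

Primitives are retained, so the expanded table has (3p^2 + p)/2 columns; for
p = 51 that is 1326 + 1275 + 1275 + 51 = 3927.  One orientation per unordered
pair suffices: a sign flip or reciprocal changes neither tree-model splits nor
absolute correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data_io import FeatureTable

PRIMITIVE = "primitive"
ADDITIVE = "additive"
SUBTRACTIVE = "subtractive"
DIVISIVE = "divisive"
KINDS = (PRIMITIVE, ADDITIVE, SUBTRACTIVE, DIVISIVE)

_DENOM_FLOOR = 1e-9

_OP_SYMBOL = {ADDITIVE: "+", SUBTRACTIVE: "-", DIVISIVE: "/"}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one (possibly derived) feature column.

    ``operands`` holds one primitive name for kind ``primitive`` and an
    ordered pair of primitive names otherwise.
    """

    name: str
    kind: str
    operands: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == PRIMITIVE:
            if len(self.operands) != 1 or self.operands[0] != self.name:
                raise ValueError("primitive descriptor must name itself")
        else:
            if len(self.operands) != 2:
                raise ValueError("composite descriptor needs two operands")
            if self.kind in (SUBTRACTIVE, DIVISIVE) and self.operands[0] == self.operands[1]:
                raise ValueError(f"{self.kind} self-pairs are excluded")

    @property
    def primitives(self) -> tuple[str, ...]:
        """Distinct primitive constituents."""
        return tuple(dict.fromkeys(self.operands))


def name_of(descriptor: FeatureDescriptor) -> str:
    """Canonical display name: ``A + B``, ``A - B``, ``A / B`` or the primitive."""
    if descriptor.kind == PRIMITIVE:
        return descriptor.operands[0]
    a, b = descriptor.operands
    return f"{a} {_OP_SYMBOL[descriptor.kind]} {b}"


def make_descriptor(kind: str, operands: tuple[str, ...]) -> FeatureDescriptor:
    if kind == PRIMITIVE:
        return FeatureDescriptor(operands[0], kind, operands)
    a, b = operands
    return FeatureDescriptor(f"{a} {_OP_SYMBOL[kind]} {b}", kind, (a, b))


def expected_counts(p: int) -> dict[str, int]:
    """Column counts per kind for ``p`` primitives."""
    return {
        PRIMITIVE: p,
        ADDITIVE: p * (p + 1) // 2,
        SUBTRACTIVE: p * (p - 1) // 2,
        DIVISIVE: p * (p - 1) // 2,
        "total": (3 * p * p + p) // 2,
    }


def derive(table: FeatureTable) -> tuple[FeatureTable, list[FeatureDescriptor]]:
    """Expand a primitive table into the full composite feature space.

    Returns the expanded table (primitives first, then additive, subtractive,
    divisive blocks, pairs in column order) and a descriptor list parallel to
    its columns.  Labels pass through unchanged.  Denominators with magnitude
    below 1e-9 are floored (sign-preserving) with a warning; chemical contents
    are strictly positive, so this fires only on pathological input.
    """
    p = table.n_features
    if p < 2:
        raise ValueError("derivation requires at least 2 primitive features")
    X = table.values
    names = table.feature_names

    descriptors: list[FeatureDescriptor] = [
        make_descriptor(PRIMITIVE, (n,)) for n in names
    ]
    columns: list[np.ndarray] = [X]

    add_cols = [X[:, i] + X[:, j] for i in range(p) for j in range(i, p)]
    descriptors += [
        make_descriptor(ADDITIVE, (names[i], names[j]))
        for i in range(p)
        for j in range(i, p)
    ]
    columns.append(np.column_stack(add_cols) if add_cols else np.empty((X.shape[0], 0)))

    sub_cols = [X[:, i] - X[:, j] for i in range(p) for j in range(i + 1, p)]
    descriptors += [
        make_descriptor(SUBTRACTIVE, (names[i], names[j]))
        for i in range(p)
        for j in range(i + 1, p)
    ]
    if sub_cols:
        columns.append(np.column_stack(sub_cols))

    denom_warned = False
    div_cols = []
    for i in range(p):
        for j in range(i + 1, p):
            den = X[:, j]
            small = np.abs(den) < _DENOM_FLOOR
            if small.any():
                if not denom_warned:
                    warnings.warn(
                        f"degenerate denominator in {names[j]!r}; floored at "
                        f"{_DENOM_FLOOR:g}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    denom_warned = True
                den = np.where(small, np.where(den < 0, -_DENOM_FLOOR, _DENOM_FLOOR), den)
            div_cols.append(X[:, i] / den)
    descriptors += [
        make_descriptor(DIVISIVE, (names[i], names[j]))
        for i in range(p)
        for j in range(i + 1, p)
    ]
    if div_cols:
        columns.append(np.column_stack(div_cols))

    values = np.hstack(columns)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite composite value after division guard")
    expanded = replace(
        table,
        feature_names=[d.name for d in descriptors],
        values=values,
        labels=None if table.labels is None else table.labels.copy(),
    )
    return expanded, descriptors


def descriptors_by_name(
    descriptors: list[FeatureDescriptor],
) -> dict[str, FeatureDescriptor]:
    return {d.name: d for d in descriptors}


def split_by_kind(
    expanded: FeatureTable, descriptors: list[FeatureDescriptor]
) -> dict[str, FeatureTable]:
    """Partition the expanded table into the four operation-type datasets."""
    out = {}
    for kind in KINDS:
        names = [d.name for d in descriptors if d.kind == kind]
        out[kind] = expanded.select_features(names)
    return out
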