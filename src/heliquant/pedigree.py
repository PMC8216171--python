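"""Pedigree validation and the additive (numerator) relationship matrix.

The animal model treats the vector of individual genetic effects as
multivariate normal with covariance proportional to the additive
relationship matrix A, built here from a two-column (dam, sire) pedigree
by the tabular method.  Founders are assumed non-inbred and mutually
unrelated, which matches a breeding design in which the parental
generation is drawn from a large outbred stock.

A companion exact-rational kinship recursion (:func:`kinship`) is kept
deliberately independent of the tabular construction so the two can be
cross-checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "RelationshipMatrix",
    "validate_pedigree",
    "additive_relationship_matrix",
    "kinship",
]

#: Sentinel used for unknown parents in in-memory tables and CSV files.
UNKNOWN = "NA"

FEMALE = "F"
MALE = "M"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids,
    missing parent rows, sex-inconsistent parent roles)."""


def _is_unknown(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip().upper() in ("", "NA", "NAN")
    )


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("id", "dam", "sire"):
        if col not in out.columns:
            raise PedigreeError(f"pedigree table lacks required column {col!r}")
        out[col] = out[col].map(lambda v: None if _is_unknown(v) else str(v))
    if out["id"].isna().any() if hasattr(out["id"], "isna") else False:
        raise PedigreeError("pedigree contains a row with no id")
    if "sex" not in out.columns:
        out["sex"] = None
    else:
        out["sex"] = out["sex"].map(
            lambda v: None if _is_unknown(v) else str(v).strip().upper()[0]
        )
    return out


def validate_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Validate a pedigree table and return it in parents-before-offspring order.

    Parameters
    ----------
    pedigree : DataFrame
        Columns ``id``, ``dam``, ``sire`` (unknown parents as ``"NA"``,
        ``None`` or NaN) and optionally ``sex`` (``F``/``M``) plus any
        extra columns, which are carried through unchanged.

    Returns
    -------
    DataFrame
        The same rows, topologically ordered so every parent precedes its
        offspring, with unknown parents normalized to ``None``.

    Raises
    ------
    PedigreeError
        On duplicate ids, a parent that has no row of its own, an
        ancestry cycle, or an individual used both as a dam while male or
        as a sire while female.
    """
    df = _normalize(pedigree)
    ids = list(df["id"])
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise PedigreeError(f"duplicate ids in pedigree: {dupes}")
    known = set(ids)
    sex = dict(zip(df["id"], df["sex"]))

    for _, row in df.iterrows():
        for role, col, required in (("dam", "dam", FEMALE), ("sire", "sire", MALE)):
            parent = row[col]
            if parent is None:
                continue
            if parent not in known:
                raise PedigreeError(
                    f"{role} {parent!r} of {row['id']!r} has no pedigree row"
                )
            psex = sex.get(parent)
            if psex is not None and psex != required:
                raise PedigreeError(
                    f"individual {parent!r} has sex {psex!r} but is used as {role}"
                )

    # Kahn topological sort on the parent -> offspring DAG.
    dam = dict(zip(df["id"], df["dam"]))
    sire = dict(zip(df["id"], df["sire"]))
    n_parents = {
        i: sum(p is not None for p in (dam[i], sire[i])) for i in ids
    }
    children: dict[str, list[str]] = {i: [] for i in ids}
    for i in ids:
        for p in (dam[i], sire[i]):
            if p is not None:
                children[p].append(i)
    queue = [i for i in ids if n_parents[i] == 0]
    order: list[str] = []
    while queue:
        cur = queue.pop(0)
        order.append(cur)
        for child in children[cur]:
            n_parents[child] -= 1
            if n_parents[child] == 0:
                queue.append(child)
    if len(order) != len(ids):
        cyclic = sorted(set(ids) - set(order))
        raise PedigreeError(f"pedigree contains an ancestry cycle involving {cyclic}")

    out = df.set_index("id", drop=False).loc[order].reset_index(drop=True)
    return out


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix A over a fixed id ordering.

    ``values[i, j]`` is twice the kinship coefficient between individuals
    ``ids[i]`` and ``ids[j]``; the diagonal is ``1 + F`` with ``F`` the
    inbreeding coefficient.
    """

    ids: list[str]
    values: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {ind: k for k, ind in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def submatrix(self, ids) -> np.ndarray:
        idx = [self._index[i] for i in ids]
        return self.values[np.ix_(idx, idx)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def additive_relationship_matrix(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Build A by the tabular method.

    Rows are processed in topological order; for individual i with
    parents (d, s)::

        A[i, i] = 1 + 0.5 * A[d, s]
        A[i, j] = 0.5 * (A[j, d] + A[j, s])   for earlier j

    with unknown-parent terms contributing 0.  All entries are dyadic
    rationals, so double-precision arithmetic is exact here.
    """
    df = validate_pedigree(pedigree)
    ids = list(df["id"])
    idx = {ind: k for k, ind in enumerate(ids)}
    dam = [None if d is None else idx[d] for d in df["dam"]]
    sire = [None if s is None else idx[s] for s in df["sire"]]

    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam[i], sire[i]
        A[i, i] = 1.0 + (0.5 * A[d, s] if d is not None and s is not None else 0.0)
        for j in range(i):
            a = 0.0
            if d is not None:
                a += 0.5 * A[j, d]
            if s is not None:
                a += 0.5 * A[j, s]
            A[i, j] = A[j, i] = a
    return RelationshipMatrix(ids=ids, values=A)


def kinship(pedigree: pd.DataFrame, i: str, j: str) -> Fraction:
    """Exact kinship coefficient between ``i`` and ``j`` by recursion.

    Computed in rational arithmetic, independently of the tabular method:
    f(i, i) = (1 + f(dam_i, sire_i)) / 2 and, recursing on whichever of
    the pair comes later in the topological order,
    f(i, j) = (f(i, dam_j) + f(i, sire_j)) / 2.  Twice this value equals
    the additive relationship.
    """
    df = validate_pedigree(pedigree)
    order = {ind: k for k, ind in enumerate(df["id"])}
    if i not in order or j not in order:
        missing = [x for x in (i, j) if x not in order]
        raise PedigreeError(f"unknown id(s): {missing}")
    dam = dict(zip(df["id"], df["dam"]))
    sire = dict(zip(df["id"], df["sire"]))
    cache: dict[tuple, Fraction] = {}

    def f(a, b) -> Fraction:
        if a is None or b is None:
            return Fraction(0)
        key = (a, b) if order[a] <= order[b] else (b, a)
        if key in cache:
            return cache[key]
        x, y = key
        if x == y:
            val = Fraction(1, 2) * (1 + f(dam[x], sire[x]))
        else:
            # y is not an ancestor of x (topological order), so condition on y's parents
            val = Fraction(1, 2) * (f(x, dam[y]) + f(x, sire[y]))
        cache[key] = val
        return val

    return f(i, j)
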