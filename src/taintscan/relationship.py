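"""Pedigree additive (numerator) relationship matrix.

The polygenic effect in the mixed model has covariance proportional to the
additive relationship matrix A, built from the pedigree with the standard
tabular recursion: individuals are processed parents-first, with

    A_ii = 1 + 0.5 * A_{sire,dam}
    A_ij = 0.5 * (A_{j,sire(i)} + A_{j,dam(i)})   for earlier j,

where unknown parents are treated as unique unrelated founders
(contribution 0). Equivalently A_ij is twice the kinship coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = "0"


def _toposort(ped: pd.DataFrame) -> list[str]:
    """Order pedigree ids so every parent precedes its offspring.

    Raises on cycles (an individual that is its own ancestor).
    """
    parents = {
        str(r.id): [p for p in (str(r.sire), str(r.dam)) if p != UNKNOWN]
        for r in ped.itertuples()
    }
    order: list[str] = []
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    for root in parents:
        if root in state:
            continue
        stack = [(root, iter(parents.get(root, [])))]
        state[root] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if p not in parents:
                    continue  # parent without a record: founder
                if state.get(p) == 0:
                    raise ValueError(f"pedigree cycle involving '{p}'")
                if p not in state:
                    state[p] = 0
                    stack.append((p, iter(parents[p])))
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                order.append(node)
                stack.pop()
    return order


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix with its id ordering."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self._index = {i: k for k, i in enumerate(self.ids)}

    def loc(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def submatrix(self, ids) -> "RelationshipMatrix":
        """Restrict and reorder to ``ids`` (e.g. the phenotyped sample)."""
        ids = [str(i) for i in ids]
        try:
            idx = np.array([self._index[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"id {e} not in relationship matrix") from e
        return RelationshipMatrix(ids, self.values[np.ix_(idx, idx)])


def additive_relationship(ped: pd.DataFrame) -> RelationshipMatrix:
    """Tabular-method A over all pedigree members.

    ``ped`` has columns id, sire, dam with '0' marking an unknown parent.
    Named parents without their own record are appended as founders.
    """
    ped = ped.astype(str)
    if ped["id"].duplicated().any():
        dup = ped.loc[ped["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate pedigree id: {dup}")
    known = set(ped["id"])
    extra = sorted(
        {p for col in ("sire", "dam") for p in ped[col] if p != UNKNOWN} - known
    )
    if extra:
        ped = pd.concat(
            [pd.DataFrame({"id": extra, "sire": UNKNOWN, "dam": UNKNOWN}), ped],
            ignore_index=True,
        )
    order = _toposort(ped)
    pos = {i: k for k, i in enumerate(order)}
    rows = ped.set_index("id")
    n = len(order)
    sire_idx = np.full(n, -1)
    dam_idx = np.full(n, -1)
    for i, ind in enumerate(order):
        s, d = rows.at[ind, "sire"], rows.at[ind, "dam"]
        sire_idx[i] = pos.get(s, -1) if s != UNKNOWN else -1
        dam_idx[i] = pos.get(d, -1) if d != UNKNOWN else -1

    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(order, A)


def submatrix(A: RelationshipMatrix, ids) -> RelationshipMatrix:
    """Functional alias for :meth:`RelationshipMatrix.submatrix`."""
    return A.submatrix(ids)
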