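"""Pedigree container and the numerator relationship matrix A.

The additive-genetic covariance of the animal model is ``A * sigma2_a``
where A is the pedigree-based numerator relationship matrix. Only its
sparse inverse (Henderson's rules) is ever needed by the sampler; the
dense tabular construction is retained as the small-pedigree oracle.
Unknown parents are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeOrderError",
    "inbreeding_coefficients",
    "tabular_a_matrix",
    "henderson_a_inverse",
    "sire_covariance",
]

UNKNOWN = -1


class PedigreeOrderError(ValueError):
    """Pedigree is not sorted parents-before-offspring (or ids repeat)."""


@dataclass
class Pedigree:
    """Topologically ordered (animal, sire, dam) triples.

    ``sire`` and ``dam`` hold positional indices into ``ids`` with
    ``-1`` for an unknown parent. Construction validates the ordering
    invariant: every known parent precedes its offspring.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeOrderError("pedigree ids are not unique")
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise ValueError("sire/dam arrays must match the id list length")
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p == i:
                    raise PedigreeOrderError(f"animal {self.ids[i]} is its own parent")
                if p != UNKNOWN and not (0 <= p < i):
                    raise PedigreeOrderError(
                        f"parent of {self.ids[i]} does not precede it in pedigree order"
                    )
        self.index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a table with columns animal_id, sire_id, dam_id;
        empty string / NA parent means unknown founder."""
        ids = frame["animal_id"].astype(str).tolist()
        index = {a: i for i, a in enumerate(ids)}

        def resolve(col: pd.Series) -> np.ndarray:
            out = np.full(len(ids), UNKNOWN, dtype=np.int64)
            for i, v in enumerate(col):
                if pd.isna(v) or v == "":
                    continue
                v = str(v)
                if v not in index:
                    raise PedigreeOrderError(f"parent {v!r} not present as an animal")
                out[i] = index[v]
            return out

        return cls(ids, resolve(frame["sire_id"]), resolve(frame["dam_id"]))

    def to_frame(self) -> pd.DataFrame:
        def name(p: np.ndarray) -> list[str]:
            return ["" if j == UNKNOWN else self.ids[j] for j in p]

        return pd.DataFrame(
            {"animal_id": self.ids, "sire_id": name(self.sire), "dam_id": name(self.dam)}
        )


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficient F (memoized kinship recursion).

    F_i is the kinship between the parents of i; founders and animals
    with any unknown parent have F = 0 under the unrelated-founder
    assumption.
    """
    sire, dam = pedigree.sire, pedigree.dam
    cache: dict[tuple[int, int], float] = {}

    def kinship(i: int, j: int) -> float:
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        hit = cache.get(key)
        if hit is not None:
            return hit
        if i == j:
            val = 0.5 * (1.0 + kinship(sire[i], dam[i]))
        else:
            # j is the younger of the pair; recurse through its parents
            val = 0.5 * (kinship(sire[j], i) + kinship(dam[j], i))
        cache[key] = val
        return val

    return np.array([kinship(sire[i], dam[i]) for i in range(len(pedigree))])


def tabular_a_matrix(pedigree: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the recursive tabular method.

    Intended as the oracle for small pedigrees (O(n^2) memory); the
    sampler itself only consumes :func:`henderson_a_inverse`.
    """
    n = len(pedigree)
    sire, dam = pedigree.sire, pedigree.dam
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.5 * ((A[j, s] if s != UNKNOWN else 0.0) + (A[j, d] if d != UNKNOWN else 0.0))
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return A


def henderson_a_inverse(pedigree: Pedigree, with_inbreeding: bool = True) -> sparse.csr_matrix:
    """Sparse inverse of A accumulated by Henderson's rules.

    Each animal contributes a precision block over {animal, sire, dam}
    weighted by the reciprocal of its Mendelian-sampling variance
    ``m_i = 0.5 - 0.25 (F_s + F_d)`` (both parents known; 0.75 with one,
    1 with none). ``with_inbreeding=False`` sets all F to zero.
    """
    n = len(pedigree)
    F = inbreeding_coefficients(pedigree) if with_inbreeding else np.zeros(n)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        parents = [p for p in (pedigree.sire[i], pedigree.dam[i]) if p != UNKNOWN]
        m = 1.0 - sum(0.25 * (1.0 + F[p]) for p in parents)
        alpha = 1.0 / m
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * alpha)
    out = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    out.sum_duplicates()
    return out


def sire_covariance(
    pedigree: Pedigree, sire_ids: list[str], mode: str = "independent"
) -> np.ndarray:
    """Relationship matrix among the sires of a sire model.

    ``independent`` returns the identity (the default: unrelated sires);
    ``pedigree`` extracts the A-submatrix over the sires via the kinship
    recursion, honouring any sire-of-sire links present.
    """
    missing = [s for s in sire_ids if s not in pedigree.index]
    if missing:
        raise KeyError(f"sire ids not in pedigree: {missing[:5]}")
    q = len(sire_ids)
    if mode == "independent":
        return np.eye(q)
    if mode != "pedigree":
        raise ValueError(f"unknown sire covariance mode {mode!r}")
    idx = [pedigree.index[s] for s in sire_ids]
    A = tabular_a_matrix(pedigree)
    return A[np.ix_(idx, idx)]
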