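"""Pedigree handling and the numerator relationship matrix (NRM).

The additive-genetic covariance among animals is sigma_a^2 * A where A is
the pedigree NRM: A_ii = 1 + F_i (F = inbreeding coefficient), off-diagonals
are twice the kinship. The mixed-model equations need A^{-1}, which is
sparse and assembled directly from Henderson's rules with inbreeding from
the Meuwissen-Luo recursion; the dense tabular A is kept for desk-scale
checking and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "sort_pedigree",
    "read_pedigree",
    "inbreeding",
    "build_nrm",
    "build_nrm_inverse",
    "nrm_logdet",
]

UNKNOWN = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    ``sire`` / ``dam`` hold positional indices into ``animals``
    (:data:`UNKNOWN` = -1 for an unknown parent).
    """

    animals: list[str]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {a: i for i, a in enumerate(self.animals)}
        n = len(self.animals)
        for vec, name in ((self.sire, "sire"), (self.dam, "dam")):
            if len(vec) != n:
                raise PedigreeError(f"{name} vector length mismatch")
            if np.any(vec >= np.arange(n)):
                raise PedigreeError("pedigree is not topologically ordered")

    def __len__(self) -> int:
        return len(self.animals)


def sort_pedigree(triples) -> Pedigree:
    """Topologically sort (animal, sire, dam) triples into a Pedigree.

    Parents that are referenced but never listed as animals are inserted
    as founders. Unknown parents are '', '0', None or NaN. A cycle
    (an animal its own ancestor) raises naming one member.
    """
    def norm(x) -> str | None:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return None
        s = str(x).strip()
        return None if s in ("", "0", "nan", "NA") else s

    parents: dict[str, tuple[str | None, str | None]] = {}
    order_seen: list[str] = []
    for animal, sire, dam in triples:
        a = norm(animal)
        if a is None:
            raise PedigreeError("empty animal id")
        if a in parents:
            raise PedigreeError(f"animal {a!r} listed twice")
        parents[a] = (norm(sire), norm(dam))
        order_seen.append(a)
    # insert referenced-but-unlisted parents as founders, stable order
    for a in list(order_seen):
        for p in parents[a]:
            if p is not None and p not in parents:
                parents[p] = (None, None)
                order_seen.append(p)

    # Kahn's algorithm, preserving input order among ready animals
    ordered: list[str] = []
    state: dict[str, int] = {}  # 0 unvisited, 1 in stack, 2 done

    def visit(a: str) -> None:
        if state.get(a) == 2:
            return
        if state.get(a) == 1:
            raise PedigreeError(f"pedigree cycle involving animal {a!r}")
        state[a] = 1
        for p in parents[a]:
            if p is not None:
                visit(p)
        state[a] = 2
        ordered.append(a)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(parents) + 100))
    try:
        for a in order_seen:
            visit(a)
    finally:
        sys.setrecursionlimit(old)

    idx = {a: i for i, a in enumerate(ordered)}
    sire = np.array([idx[parents[a][0]] if parents[a][0] else UNKNOWN for a in ordered])
    dam = np.array([idx[parents[a][1]] if parents[a][1] else UNKNOWN for a in ordered])
    return Pedigree(ordered, sire, dam)


def read_pedigree(path) -> Pedigree:
    """Read a 3-column (animal, sire, dam) delimited text file.

    '0' or empty denotes an unknown parent; separator chosen by
    extension (.tsv -> tab, otherwise comma).
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise PedigreeError(f"pedigree file {path} needs 3 columns, got {df.shape[1]}")
    return sort_pedigree(df.iloc[:, :3].itertuples(index=False, name=None))


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo recursion.

    For each animal with both parents known, F_i = 0.5 * A(sire,dam) is
    obtained by accumulating the L-vector over its ancestors:
    A_ii = 1 + F_i = sum_j L_j^2 d_j with d_j the Mendelian-sampling
    variance scale of ancestor j.
    """
    n = len(ped)
    F = np.zeros(n)
    d = np.zeros(n)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, dm = sire[i], dam[i]
        d[i] = 1.0
        if s != UNKNOWN:
            d[i] -= 0.25 * (1 + F[s])
        if dm != UNKNOWN:
            d[i] -= 0.25 * (1 + F[dm])
        if s == UNKNOWN or dm == UNKNOWN:
            F[i] = 0.0
            continue
        L = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * d[j]
            if sire[j] != UNKNOWN:
                L[sire[j]] = L.get(sire[j], 0.0) + 0.5 * lj
            if dam[j] != UNKNOWN:
                L[dam[j]] = L.get(dam[j], 0.0) + 0.5 * lj
        F[i] = aii - 1.0
    return F


def mendelian_variance(ped: Pedigree, with_inbreeding: bool = True) -> np.ndarray:
    """Mendelian-sampling variance scale d_i for each animal.

    d_i = 1 - 0.25(1+F_s) - 0.25(1+F_d), each term present only when the
    parent is known. These are the diagonal of D in A = T D T'.
    """
    F = inbreeding(ped) if with_inbreeding else np.zeros(len(ped))
    d = np.ones(len(ped))
    known_s = ped.sire != UNKNOWN
    known_d = ped.dam != UNKNOWN
    d[known_s] -= 0.25 * (1 + F[ped.sire[known_s]])
    d[known_d] -= 0.25 * (1 + F[ped.dam[known_d]])
    return d


def build_nrm(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        if i > 0:
            row = np.zeros(i)
            if s != UNKNOWN:
                row += 0.5 * A[:i, s]
            if dm != UNKNOWN:
                row += 0.5 * A[:i, dm]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, dm] if s != UNKNOWN and dm != UNKNOWN else 0.0)
    return A


def build_nrm_inverse(ped: Pedigree, with_inbreeding: bool = True) -> sparse.csr_matrix:
    """Sparse A^{-1} by Henderson's rules.

    Each animal contributes 1/d_i to (i,i), -0.5/d_i to (i,parent), and
    0.25/d_i to each (parent,parent) pair, for its known parents.
    ``with_inbreeding=False`` uses d from F=0 (classic rules without
    inbreeding adjustment).
    """
    n = len(ped)
    d = mendelian_variance(ped, with_inbreeding)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        di = 1.0 / d[i]
        ps = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        add(i, i, di)
        for p in ps:
            add(i, p, -0.5 * di)
            add(p, i, -0.5 * di)
            for q in ps:
                add(p, q, 0.25 * di)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def nrm_logdet(ped: Pedigree, with_inbreeding: bool = True) -> float:
    """log|A| = sum_i log d_i (from the A = T D T' decomposition, |T| = 1)."""
    return float(np.sum(np.log(mendelian_variance(ped, with_inbreeding))))
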