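"""Pedigree machinery: sorting, inbreeding, and the inverse relationship matrix.

The additive genetic covariance between animals is proportional to the
numerator relationship matrix A.  Mixed-model equations need A⁻¹, which for a
pedigree is sparse and can be written down directly from Henderson's rules
once every animal's inbreeding coefficient F is known.  Inbreeding is
computed with the Meuwissen & Luo algorithm, which traces each animal's
ancestor contributions through the Cholesky decomposition A = T D T'.

The dense tabular A (``build_a_dense``) is a deliberately independent
recursive construction kept as a brute-force oracle for small pedigrees.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SortedPedigree",
    "topological_sort",
    "compute_inbreeding",
    "build_a_inverse",
    "build_a_dense",
]

UNKNOWN = -1  # sentinel index for an unknown parent


@dataclass
class SortedPedigree:
    """Pedigree re-coded to integer indices, parents before offspring.

    ``sire`` / ``dam`` hold the row index of each animal's parents or
    ``UNKNOWN`` (-1).  ``inbreeding`` is filled by :func:`compute_inbreeding`.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    inbreeding: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index_of(self) -> dict:
        return {a: i for i, a in enumerate(self.ids)}

    def mendelian_variances(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variance share d_i for each animal.

        d_i = 0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_p
        with one known parent, and 1 for founders.  These are the diagonal of
        D in A = T D T', so log|A| = sum(log d_i).
        """
        if self.inbreeding is None:
            compute_inbreeding(self)
        F = self.inbreeding
        d = np.empty(len(self))
        for i in range(len(self)):
            s, m = self.sire[i], self.dam[i]
            if s == UNKNOWN and m == UNKNOWN:
                d[i] = 1.0
            elif s == UNKNOWN:
                d[i] = 0.75 - 0.25 * F[m]
            elif m == UNKNOWN:
                d[i] = 0.75 - 0.25 * F[s]
            else:
                d[i] = 0.5 - 0.25 * (F[s] + F[m])
        return d


def topological_sort(pedigree: pd.DataFrame) -> SortedPedigree:
    """Order a pedigree so that every parent precedes all its offspring.

    Parameters
    ----------
    pedigree
        DataFrame with columns ``animal_id``, ``sire_id``, ``dam_id`` where
        missing parents are the sentinel "0" (see :mod:`rrtdm.data`).
        Animals referenced only as parents are inserted as founders.

    Raises
    ------
    ValueError
        If the pedigree contains a cycle (an animal its own ancestor); the
        message names one animal on the cycle.
    """
    animal = pedigree["animal_id"].tolist()
    sire = pedigree["sire_id"].tolist()
    dam = pedigree["dam_id"].tolist()
    parents = {a: (s, d) for a, s, d in zip(animal, sire, dam)}

    missing = "0"
    listed = set(animal)
    extra = []
    for p in [*sire, *dam]:
        if p != missing and p not in listed:
            listed.add(p)
            extra.append(p)
    for p in extra:
        parents[p] = (missing, missing)

    # Kahn's algorithm, stable in input order with inserted founders first.
    order_in = {a: i for i, a in enumerate([*extra, *animal])}
    children: dict = {a: [] for a in parents}
    indeg = {a: 0 for a in parents}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p != missing:
                children[p].append(a)
                indeg[a] += 1
    ready = sorted([a for a, k in indeg.items() if k == 0], key=order_in.get)
    out: list = []
    while ready:
        ready.sort(key=order_in.get)
        a = ready.pop(0)
        out.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(out) < len(parents):
        on_cycle = next(a for a, k in indeg.items() if k > 0)
        raise ValueError(f"pedigree contains a cycle through animal {on_cycle!r}")

    idx = {a: i for i, a in enumerate(out)}
    sire_ix = np.array(
        [idx[parents[a][0]] if parents[a][0] != missing else UNKNOWN for a in out],
        dtype=np.int64,
    )
    dam_ix = np.array(
        [idx[parents[a][1]] if parents[a][1] != missing else UNKNOWN for a in out],
        dtype=np.int64,
    )
    return SortedPedigree(ids=out, sire=sire_ix, dam=dam_ix)


def compute_inbreeding(ped: SortedPedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo ancestor-tracing method.

    F_i = 0.5 a(sire_i, dam_i); founders have F = 0.  Fills and returns
    ``ped.inbreeding``.
    """
    n = len(ped)
    F = np.zeros(n)
    d = np.empty(n)  # Mendelian variances, filled as we go
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, m = sire[i], dam[i]
        if s == UNKNOWN and m == UNKNOWN:
            d[i] = 1.0
            continue
        if s == UNKNOWN or m == UNKNOWN:
            p = s if s != UNKNOWN else m
            d[i] = 0.75 - 0.25 * F[p]
            continue
        d[i] = 0.5 - 0.25 * (F[s] + F[m])
        # trace ancestor contributions from both parents down to founders,
        # youngest ancestor first so each is expanded exactly once
        contrib: dict[int, float] = {}
        for p in (int(s), int(m)):
            contrib[p] = contrib.get(p, 0.0) + 0.5
        heap = [-p for p in contrib]
        heapq.heapify(heap)
        a_sm = 0.0
        while heap:
            j = -heapq.heappop(heap)
            if j not in contrib:
                continue
            lj = contrib.pop(j)
            a_sm += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    p = int(p)
                    if p in contrib:
                        contrib[p] += 0.5 * lj
                    else:
                        contrib[p] = 0.5 * lj
                        heapq.heappush(heap, -p)
        # contrib holds L_{i,j} over ancestors j, so a_sm = a_ii - d_i
        # = 1 + F_i - d_i with d_i = 0.5 - 0.25 (F_s + F_m)
        F[i] = a_sm - 0.5 - 0.25 * (F[s] + F[m])
        d[i] = 0.5 - 0.25 * (F[s] + F[m])
    ped.inbreeding = F
    return F


def build_a_inverse(ped: SortedPedigree) -> sp.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    Each animal i contributes 1/d_i times the pattern
    (i,i): 1, (i,parent): -1/2, (parent,parent'): 1/4 over its known parents,
    where d_i is the Mendelian sampling variance share.
    """
    d = ped.mendelian_variances()
    n = len(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / d[i]
        members = [(i, 1.0)]
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                members.append((int(p), -0.5))
        for a, wa in members:
            for b, wb in members:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * wa * wb)
    A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A_inv.sum_duplicates()
    return A_inv


def build_a_dense(ped: SortedPedigree, max_animals: int = 2000) -> np.ndarray:
    """Dense numerator relationship matrix by the recursive tabular method.

    a_ii = 1 + F_i and a_ij = 0.5 (a_{j,sire(i)} + a_{j,dam(i)}).  Quadratic
    in pedigree size; guarded to small pedigrees, intended as a test oracle.
    """
    n = len(ped)
    if n > max_animals:
        raise ValueError(f"tabular A limited to {max_animals} animals, got {n}")
    A = np.zeros((n, n))
    for i in range(n):
        s, m = ped.sire[i], ped.dam[i]
        for j in range(i):
            a_js = A[j, s] if s != UNKNOWN else 0.0
            a_jm = A[j, m] if m != UNKNOWN else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jm)
        A[i, i] = 1.0 + (0.5 * A[s, m] if s != UNKNOWN and m != UNKNOWN else 0.0)
    return A
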