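"""Design matrices and Henderson's mixed-model equations for the test-day model.

The observation model for a test-day yield of cow *i* at DIM *t* is

    y = HYS_l + AGE_m + DIM_t + sum_k z_tk a_ik + sum_k z_tk pe_ik + e

with fixed contemporary-group (herd x calving-year x season), calving-age and
DIM-class effects, random regression coefficients ``a_i ~ N(0, A (x) G)`` on
the pedigree, cow permanent-environment coefficients ``pe_i ~ N(0, I (x) P)``
and residual ``e ~ N(0, v / w)`` with per-record weight w (1 when residual
variance is homogeneous).

Henderson's equations are

    [ W' R^-1 W + blockdiag(0, A^-1 (x) G^-1, I (x) P^-1) ] theta = W' R^-1 y

with ``W = [X  Z_a  Z_pe]``.  With full indicator sets for HYS, AGE and DIM
the fixed part is rank deficient; identifiability is restored by
zero-constraining the last observed AGE level and the last observed DIM
level (dropping those columns), which leaves estimable contrasts untouched.

``MMEWorkspace`` supports the repeated factorizations REML needs: the
sparsity pattern and a fill-reducing symmetric ordering are computed once,
after which each factorization is numeric-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .basis import LegendreBasis
from .data import N_RESIDUAL_CLASSES
from .pedigree import SortedPedigree

__all__ = [
    "ModelSpec",
    "Design",
    "MMESystem",
    "Solutions",
    "build_design",
    "assemble_mme",
    "solve_mme",
    "compute_rank_x",
    "MMEWorkspace",
]


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration: polynomial orders and residual-variance mode."""

    order_genetic: int
    order_pe: int
    residual_mode: str = "homogeneous"
    dim_min: int = 5
    dim_max: int = 305

    def __post_init__(self):
        if self.residual_mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown residual mode {self.residual_mode!r}")
        if self.order_genetic < 0 or self.order_pe < 0:
            raise ValueError("polynomial orders must be >= 0")

    @property
    def basis_genetic(self) -> LegendreBasis:
        return LegendreBasis(self.order_genetic, self.dim_min, self.dim_max)

    @property
    def basis_pe(self) -> LegendreBasis:
        return LegendreBasis(self.order_pe, self.dim_min, self.dim_max)

    @property
    def k_genetic(self) -> int:
        return self.order_genetic + 1

    @property
    def k_pe(self) -> int:
        return self.order_pe + 1


@dataclass
class Design:
    """Assembled model matrices for one dataset and one :class:`ModelSpec`."""

    spec: ModelSpec
    y: np.ndarray
    X: sp.csr_matrix              # constrained fixed-effect indicators
    x_labels: list                # (effect, level) per retained column
    dropped: list                 # (effect, level) zero-constrained
    Z_a: sp.csr_matrix
    Z_pe: sp.csr_matrix
    ped: SortedPedigree
    cow_ids: list                 # recorded cows, solution order
    animal_index: np.ndarray      # per record, row in pedigree
    cow_index: np.ndarray         # per record, position in cow_ids
    residual_class: np.ndarray    # per record, 0-based class 0..9
    hys_levels: np.ndarray
    age_levels: np.ndarray
    dim_levels: np.ndarray

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_animals(self) -> int:
        return len(self.ped)

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    def record_weights(self, class_weights=None) -> np.ndarray:
        """Per-record residual weights from per-class weights (default all 1)."""
        if class_weights is None:
            return np.ones(self.n_records)
        class_weights = np.asarray(class_weights, dtype=float)
        return class_weights[self.residual_class]


def build_design(records: pd.DataFrame, ped: SortedPedigree, spec: ModelSpec) -> Design:
    """Build y, X, Z_a, Z_pe from classified records.

    ``records`` must carry the columns added by
    :func:`rrtdm.data.classify_records`.  Every recorded cow must appear in
    the pedigree.
    """
    n = len(records)
    y = records["milk_kg"].to_numpy(dtype=float)
    dims = records["dim"].to_numpy(dtype=int)

    # --- fixed-effect indicators --------------------------------------
    hys = records["hys_class"].to_numpy()
    age = records["age_class"].to_numpy()
    hys_levels, hys_code = np.unique(hys, return_inverse=True)
    age_levels, age_code = np.unique(age, return_inverse=True)
    dim_levels, dim_code = np.unique(dims, return_inverse=True)
    n_h, n_a, n_d = len(hys_levels), len(age_levels), len(dim_levels)

    cols = np.concatenate([hys_code, n_h + age_code, n_h + n_a + dim_code])
    rows = np.tile(np.arange(n), 3)
    X_full = sp.csr_matrix(
        (np.ones(3 * n), (rows, cols)), shape=(n, n_h + n_a + n_d)
    )
    labels = (
        [("hys", l) for l in hys_levels]
        + [("age", l) for l in age_levels]
        + [("dim", l) for l in dim_levels]
    )
    # zero-constrain the last observed AGE and DIM levels: the AGE and DIM
    # indicator blocks each sum to the all-ones vector already spanned by the
    # HYS block, so the system is rank-deficient by exactly two
    drop = []
    if n_a >= 1:
        drop.append(n_h + n_a - 1)
    if n_d >= 1:
        drop.append(n_h + n_a + n_d - 1)
    keep = np.setdiff1d(np.arange(X_full.shape[1]), drop)
    X = X_full[:, keep].tocsr()
    x_labels = [labels[j] for j in keep]
    dropped = [labels[j] for j in drop]

    # --- random-effect covariates -------------------------------------
    idx = ped.index_of
    try:
        animal_index = np.array([idx[c] for c in records["cow_id"]], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"recorded cow {e.args[0]!r} absent from pedigree") from None
    cow_ids = list(pd.unique(records["cow_id"]))
    cow_pos = {c: i for i, c in enumerate(cow_ids)}
    cow_index = np.array([cow_pos[c] for c in records["cow_id"]], dtype=np.int64)

    Ba = spec.basis_genetic.matrix()
    Bp = spec.basis_pe.matrix()
    za = Ba[dims - spec.dim_min]          # (n, ka)
    zp = Bp[dims - spec.dim_min]          # (n, kp)
    ka, kp = spec.k_genetic, spec.k_pe

    rows_a = np.repeat(np.arange(n), ka)
    cols_a = (animal_index[:, None] * ka + np.arange(ka)[None, :]).ravel()
    Z_a = sp.csr_matrix((za.ravel(), (rows_a, cols_a)), shape=(n, len(ped) * ka))

    rows_p = np.repeat(np.arange(n), kp)
    cols_p = (cow_index[:, None] * kp + np.arange(kp)[None, :]).ravel()
    Z_pe = sp.csr_matrix((zp.ravel(), (rows_p, cols_p)), shape=(n, len(cow_ids) * kp))

    residual_class = np.searchsorted(np.arange(5, 305, 30), dims, side="right") - 1
    return Design(
        spec=spec, y=y, X=X, x_labels=x_labels, dropped=dropped,
        Z_a=Z_a, Z_pe=Z_pe, ped=ped, cow_ids=cow_ids,
        animal_index=animal_index, cow_index=cow_index,
        residual_class=residual_class,
        hys_levels=hys_levels, age_levels=age_levels, dim_levels=dim_levels,
    )


# ---------------------------------------------------------------------------


@dataclass
class MMESystem:
    C: sp.csc_matrix
    rhs: np.ndarray
    blocks: dict          # name -> slice into the solution vector
    design: Design


@dataclass
class Solutions:
    """Fixed-effect estimates and random regression coefficient solutions."""

    fixed: pd.DataFrame            # columns: effect, level, estimate
    a: np.ndarray                  # (n_animals, k_genetic), pedigree order
    pe: np.ndarray                 # (n_cows, k_pe), cow_ids order
    animal_ids: list
    cow_ids: list
    vector: np.ndarray             # raw stacked solution

    def a_by_id(self) -> dict:
        return {i: self.a[j] for j, i in enumerate(self.animal_ids)}


def _check_pd(M: np.ndarray, name: str) -> np.ndarray:
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        raise ValueError(f"{name} is not positive definite") from None
    return np.linalg.inv(M)


def _record_rinv(design: Design, v, class_weights=None) -> np.ndarray:
    """Per-record inverse residual variance.

    ``v`` may be a scalar (optionally combined with per-class weights so the
    record variance is v / w) or a length-10 vector of per-class variances.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim == 0:
        w = design.record_weights(class_weights)
        return w / float(v)
    if v.size != N_RESIDUAL_CLASSES:
        raise ValueError("residual variance must be scalar or one per DIM class")
    if np.any(v <= 0):
        raise ValueError("residual variances must be positive")
    return 1.0 / v[design.residual_class]


def assemble_mme(design: Design, G, P, v, a_inverse, class_weights=None) -> MMESystem:
    """Assemble the weighted mixed-model equations for given components."""
    G = np.asarray(G, dtype=float)
    P = np.asarray(P, dtype=float)
    Ginv = _check_pd(G, "G (genetic covariance)")
    Pinv = _check_pd(P, "P (permanent-environment covariance)")
    rinv = _record_rinv(design, v, class_weights)

    W = sp.hstack([design.X, design.Z_a, design.Z_pe], format="csr")
    D = sp.diags(rinv)
    nf = design.n_fixed
    ka, kp = design.spec.k_genetic, design.spec.k_pe
    qa = design.n_animals * ka
    K = sp.kron(a_inverse, Ginv, format="csc")
    Kp = sp.kron(sp.identity(design.n_cows, format="csc"), Pinv, format="csc")
    pad = sp.block_diag([sp.csc_matrix((nf, nf)), K, Kp], format="csc")
    C = ((W.T @ D @ W) + pad).tocsc()
    rhs = W.T @ (rinv * design.y)
    blocks = {
        "fixed": slice(0, nf),
        "genetic": slice(nf, nf + qa),
        "pe": slice(nf + qa, nf + qa + design.n_cows * kp),
    }
    return MMESystem(C=C.tocsc(), rhs=rhs, blocks=blocks, design=design)


def solve_mme(system: MMESystem, method: str = "direct", tol: float = 1e-10) -> Solutions:
    """Solve the assembled equations (sparse direct by default)."""
    C, rhs = system.C, system.rhs
    if method == "direct":
        lu = spla.splu(
            C.tocsc(), permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
        theta = lu.solve(rhs)
    elif method == "iterative":
        M = spla.LinearOperator(C.shape, lambda x: x / C.diagonal())
        theta, info = spla.cg(C, rhs, rtol=tol, maxiter=20000, M=M)
        if info != 0:
            raise RuntimeError(f"conjugate-gradient solver did not converge (info={info})")
    else:
        raise ValueError(f"unknown method {method!r}")
    return split_solutions(theta, system.design)


def split_solutions(theta: np.ndarray, design: Design) -> Solutions:
    nf = design.n_fixed
    ka, kp = design.spec.k_genetic, design.spec.k_pe
    qa = design.n_animals * ka
    fixed_rows = [
        {"effect": e, "level": l, "estimate": est}
        for (e, l), est in zip(design.x_labels, theta[:nf])
    ] + [{"effect": e, "level": l, "estimate": 0.0} for e, l in design.dropped]
    fixed = pd.DataFrame(fixed_rows, columns=["effect", "level", "estimate"])
    a = theta[nf : nf + qa].reshape(design.n_animals, ka)
    pe = theta[nf + qa :].reshape(design.n_cows, kp)
    return Solutions(
        fixed=fixed, a=a, pe=pe, animal_ids=list(design.ped.ids),
        cow_ids=list(design.cow_ids), vector=theta,
    )


def compute_rank_x(design_or_x) -> int:
    """Numerical rank of the *unconstrained* fixed-effects design matrix.

    Used as the degrees-of-freedom correction in BIC's sample size
    n = records - rank(X).
    """
    if isinstance(design_or_x, Design):
        d = design_or_x
        # rebuild the full indicator matrix: each dropped level's column is
        # one minus the row-sum of its effect's retained columns, because
        # every record carries exactly one level of each effect
        cols = [d.X]
        for effect, _ in d.dropped:
            keep = [j for j, (e, _) in enumerate(d.x_labels) if e == effect]
            has = (
                np.asarray(d.X[:, keep].sum(axis=1)).ravel()
                if keep else np.zeros(d.n_records)
            )
            cols.append(sp.csr_matrix((1.0 - has)[:, None]))
        X = sp.hstack(cols, format="csr")
    else:
        X = sp.csr_matrix(design_or_x)
    XtX = (X.T @ X).toarray()
    if XtX.size == 0:
        return 0
    eig = np.linalg.eigvalsh(XtX)
    tol = eig.max() * max(X.shape) * np.finfo(float).eps
    return int((eig > tol).sum())



# ---------------------------------------------------------------------------


class MMEWorkspace:
    """Repeated-factorization engine with pattern and ordering reuse.

    REML evaluates the restricted likelihood at many variance-component
    values on the *same* data.  The coefficient-matrix sparsity pattern is
    fixed, so the symbolic work (pattern merge, fill-reducing ordering) is
    done once; each subsequent call only refills values and runs a numeric
    LU (no pivoting beyond the cached symmetric ordering, valid because the
    matrix is positive definite).
    """

    def __init__(self, design: Design, a_inverse):
        self.design = design
        spec = design.spec
        self.ka, self.kp = spec.k_genetic, spec.k_pe
        self.nf = design.n_fixed
        self.qa = design.n_animals * self.ka
        self.qp = design.n_cows * self.kp
        self.dim = self.nf + self.qa + self.qp
        self.W = sp.hstack([design.X, design.Z_a, design.Z_pe], format="csr")
        self.y = design.y

        Ai = sp.coo_matrix(a_inverse)
        ka, kp = self.ka, self.kp
        jj, ll = np.meshgrid(np.arange(ka), np.arange(ka), indexing="ij")
        self._ai_vals = Ai.data
        self._kron_rows = (
            self.nf + (Ai.row[:, None] * ka + jj.ravel()[None, :])
        ).ravel()
        self._kron_cols = (
            self.nf + (Ai.col[:, None] * ka + ll.ravel()[None, :])
        ).ravel()
        base = self.nf + self.qa
        cows = np.arange(design.n_cows)
        jj, ll = np.meshgrid(np.arange(kp), np.arange(kp), indexing="ij")
        self._pe_rows = (base + (cows[:, None] * kp + jj.ravel()[None, :])).ravel()
        self._pe_cols = (base + (cows[:, None] * kp + ll.ravel()[None, :])).ravel()

        self._weights = None
        self._perm = None
        self.set_weights(np.ones(design.n_records))

    # -- data-dependent part -------------------------------------------
    def set_weights(self, record_weights: np.ndarray) -> None:
        """Set per-record residual weights (R0 = diag(1/w), v factored out)."""
        w = np.asarray(record_weights, dtype=float)
        if self._weights is not None and np.array_equal(w, self._weights):
            return
        self._weights = w
        D = sp.diags(w)
        M0 = (self.W.T @ D @ self.W).tocoo()
        self._m0 = M0
        self.rhs0 = self.W.T @ (w * self.y)
        self.ydy = float(self.y @ (w * self.y))
        self.sum_log_w = float(np.sum(np.log(w)))
        self._rows = np.concatenate([M0.row, self._kron_rows, self._pe_rows])
        self._cols = np.concatenate([M0.col, self._kron_cols, self._pe_cols])
        self._mapping = None  # pattern mapping must be rebuilt

    def _build_pattern(self, values: np.ndarray) -> None:
        C = sp.coo_matrix(
            (values, (self._rows, self._cols)), shape=(self.dim, self.dim)
        ).tocsc()
        lu = spla.splu(
            C, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
        self._perm = np.argsort(lu.perm_c)
        inv = np.empty(self.dim, dtype=np.int64)
        inv[self._perm] = np.arange(self.dim)
        pr = inv[self._rows]
        pc = inv[self._cols]
        key = pc.astype(np.int64) * self.dim + pr
        order = np.argsort(key, kind="stable")
        skey = key[order]
        new_group = np.r_[True, skey[1:] != skey[:-1]]
        group_of_sorted = np.cumsum(new_group) - 1
        mapping = np.empty(len(key), dtype=np.int64)
        mapping[order] = group_of_sorted
        self._mapping = mapping
        self._nnz = int(group_of_sorted[-1]) + 1
        ukey = skey[new_group]
        self._indices = (ukey % self.dim).astype(np.int32)
        counts = np.bincount((ukey // self.dim).astype(np.int64), minlength=self.dim)
        self._indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)

    def _values(self, Ginv: np.ndarray, Pinv: np.ndarray) -> np.ndarray:
        kv = (self._ai_vals[:, None] * Ginv.ravel()[None, :]).ravel()
        pv = np.tile(Pinv.ravel(), self.design.n_cows)
        return np.concatenate([self._m0.data, kv, pv])

    def factor(self, Ginv: np.ndarray, Pinv: np.ndarray) -> "MMEFactor":
        """Numeric factorization of C0 = W'D W + blockdiag(0, A⁻¹⊗Γ⁻¹, I⊗Π⁻¹)."""
        vals = self._values(Ginv, Pinv)
        if self._mapping is None or self._perm is None:
            self._build_pattern(vals)
        data = np.bincount(self._mapping, weights=vals, minlength=self._nnz)
        Cp = sp.csc_matrix(
            (data, self._indices, self._indptr), shape=(self.dim, self.dim)
        )
        lu = spla.splu(
            Cp, permc_spec="NATURAL", diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
        return MMEFactor(self, lu)


class MMEFactor:
    def __init__(self, ws: MMEWorkspace, lu):
        self.ws = ws
        self._lu = lu
        self.logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))

    def solve(self, b: np.ndarray) -> np.ndarray:
        p = self.ws._perm
        x = np.empty_like(b, dtype=float)
        x[p] = self._lu.solve(np.asarray(b, dtype=float)[p])
        return x

    def solve_mme(self) -> np.ndarray:
        """Solution of the MME for the workspace's own right-hand side."""
        return self.solve(self.ws.rhs0)
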