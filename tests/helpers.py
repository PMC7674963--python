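"""Shared oracles for the mixed-model tests.

The dense GLS/BLUP oracle works straight from the variance matrix of the
observations, V = Z_a (A x G) Z_a' + Z_pe (I x P) Z_pe' + R, using textbook
formulas — a deliberately different route from the sparse mixed-model
equations it is used to check.
"""

import numpy as np
import pandas as pd

from rrtdm.data import classify_records
from rrtdm.mme import ModelSpec, build_design
from rrtdm.pedigree import build_a_dense, build_a_inverse, topological_sort
from conftest import ped_df

_LOG2PI = np.log(2 * np.pi)


def dense_gls(design, G, P, v, A_dense):
    """Direct GLS fixed effects, BLUP random effects, and REML log-likelihood."""
    X = design.X.toarray()
    Za = design.Z_a.toarray()
    Zp = design.Z_pe.toarray()
    y = design.y
    Sig_a = np.kron(A_dense, G)
    Sig_p = np.kron(np.eye(design.n_cows), P)
    v = np.asarray(v, dtype=float)
    if v.ndim == 0:
        R = np.eye(design.n_records) * float(v)
    else:
        R = np.diag(v[design.residual_class])
    V = Za @ Sig_a @ Za.T + Zp @ Sig_p @ Zp.T + R
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    b = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    resid = y - X @ b
    u_a = Sig_a @ Za.T @ Vinv @ resid
    u_pe = Sig_p @ Zp.T @ Vinv @ resid
    n, r = design.n_records, X.shape[1]
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtVX)
    loglik = -0.5 * ((n - r) * _LOG2PI + ldV + ldX + float(resid @ Vinv @ resid))
    return b, u_a.reshape(-1, G.shape[0]), u_pe.reshape(-1, P.shape[0]), loglik


def tiny_instance(rng, order=1, n_founders=3, n_extra=3, n_cows=3, n_rec_per_cow=(3, 6)):
    """Small random dataset with a connected pedigree and full-rank fixed part.

    Uses two herds and forces one record per herd at the maximum DIM so that
    dropping the last observed DIM level leaves the fixed-effect matrix full
    rank.
    """
    rows = [(f"f{i}", "0", "0") for i in range(n_founders)]
    ids = [r[0] for r in rows]
    for i in range(n_extra):
        s, d = rng.choice(len(ids), 2, replace=False)
        rows.append((f"x{i}", ids[s], ids[d]))
        ids.append(f"x{i}")
    ped = ped_df(rows)
    cows = ids[-n_cows:]

    dim_grid = np.array([5, 45, 95, 155, 215, 260])  # shared DIM levels
    recs = []
    for j, c in enumerate(cows):
        herd = f"H{j % 2 + 1}"
        cal = pd.Timestamp("2014-03-15")
        n_rec = int(rng.integers(*n_rec_per_cow))
        n_rec = min(n_rec, len(dim_grid))
        dims = sorted(rng.choice(dim_grid, n_rec, replace=False).tolist())
        if j < 2:
            dims[-1] = 305  # anchor the dropped DIM level in both herds
        for dim in dims:
            recs.append(
                {
                    "cow_id": c, "herd_id": herd, "calving_date": cal,
                    "test_date": cal + pd.Timedelta(days=int(dim)),
                    "dim": int(dim),
                    "milk_kg": float(np.round(20 + 5 * rng.standard_normal(), 3)),
                    "age_at_calving_months": 24,
                }
            )
    records = classify_records(pd.DataFrame(recs))
    sped = topological_sort(ped)
    design = build_design(records, sped, ModelSpec(order, order))
    return design, build_a_inverse(sped), build_a_dense(sped)


def random_components(rng, k, scale=1.0):
    """Random positive-definite covariance matrix of size k."""
    L = rng.standard_normal((k, k)) * 0.4 + np.eye(k)
    return scale * (L @ L.T + 0.2 * np.eye(k))
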