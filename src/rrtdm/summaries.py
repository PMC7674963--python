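"""Genetic summaries: variance trajectories, breeding values, model scores.

With fitted covariance functions G and P, the day-t variances follow from
the basis vector z_t at that DIM:

    sigma2_g(t) = z_t' G z_t        sigma2_pe(t) = z_t' P z_t

heritability h2(t) = sigma2_g / (sigma2_g + sigma2_pe + sigma2_e) and
repeatability Rep(t) = (sigma2_g + sigma2_pe) / total.  A 305-day breeding
value is the sum of daily genetic effects, EBV305 = sum_t z_t' a = u' a with
u the basis column sums; 305-day heritability uses the variance of that sum,
u' G u, with daily residuals taken independent.

Model comparison uses AIC = -2 logL + 2 p and BIC = -2 logL + p log(n) with
p the number of (co)variance parameters and n = records - rank(X).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .basis import LegendreBasis
from .data import N_RESIDUAL_CLASSES
from .mme import Design, ModelSpec, compute_rank_x
from .reml import REMLResult, VarianceComponents

__all__ = [
    "variance_trajectory",
    "h2_305",
    "rep_305",
    "ebv_305",
    "ebv_daily",
    "count_parameters",
    "model_scores",
    "ModelScore",
    "ParameterCount",
]


def _residual_by_day(components: VarianceComponents, basis: LegendreBasis) -> np.ndarray:
    days = np.arange(basis.dim_min, basis.dim_max + 1)
    cls = np.searchsorted(np.arange(5, 305, 30), days, side="right") - 1
    return components.residual_by_class()[np.clip(cls, 0, N_RESIDUAL_CLASSES - 1)]


def variance_trajectory(
    components: VarianceComponents, basis: LegendreBasis | None = None
) -> pd.DataFrame:
    """Daily variance, heritability and repeatability curves.

    Returns a tidy table with one row per DIM: ``dim, var_g, var_pe, var_e,
    h2, repeatability``.
    """
    basis_g = basis or LegendreBasis(components.G.shape[0] - 1)
    basis_p = LegendreBasis(components.P.shape[0] - 1, basis_g.dim_min, basis_g.dim_max)
    Zg = basis_g.matrix()
    Zp = basis_p.matrix()
    var_g = np.einsum("tj,jk,tk->t", Zg, components.G, Zg)
    var_pe = np.einsum("tj,jk,tk->t", Zp, components.P, Zp)
    var_e = _residual_by_day(components, basis_g)
    total = var_g + var_pe + var_e
    return pd.DataFrame(
        {
            "dim": np.arange(basis_g.dim_min, basis_g.dim_max + 1),
            "var_g": var_g,
            "var_pe": var_pe,
            "var_e": var_e,
            "h2": var_g / total,
            "repeatability": (var_g + var_pe) / total,
        }
    )


def _sum_variances(components: VarianceComponents):
    bg = LegendreBasis(components.G.shape[0] - 1)
    bp = LegendreBasis(components.P.shape[0] - 1)
    ug = bg.lactation_sum()
    up = bp.lactation_sum()
    vg = float(ug @ components.G @ ug)
    vpe = float(up @ components.P @ up)
    ve = float(_residual_by_day(components, bg).sum())
    return vg, vpe, ve


def h2_305(components: VarianceComponents) -> float:
    """Heritability of 305-day yield: u'Gu / (u'Gu + u'Pu + sum_t v(t))."""
    vg, vpe, ve = _sum_variances(components)
    return vg / (vg + vpe + ve)


def rep_305(components: VarianceComponents) -> float:
    """Whole-lactation repeatability: ratio of average daily variances.

    Under the variance-of-the-sum convention used for :func:`h2_305`,
    repeatability would degenerate to ~1 for any parameters, because the
    independent daily residuals almost vanish from the 305-day sum while
    the animal effects accumulate.  The informative whole-lactation
    quantity - and the one whose values line up with reported
    whole-lactation repeatabilities - is the trajectory-average
    (sigma2_g + sigma2_pe) / (sigma2_g + sigma2_pe + sigma2_e).
    """
    tr = variance_trajectory(components)
    num = (tr["var_g"] + tr["var_pe"]).mean()
    return float(num / (num + tr["var_e"].mean()))


def ebv_daily(a: np.ndarray, basis: LegendreBasis) -> np.ndarray:
    """Daily EBVs z_t'a for every DIM; ``a`` is (k,) or (n_animals, k)."""
    a = np.atleast_2d(a)
    out = basis.matrix() @ a.T
    return out[:, 0] if out.shape[1] == 1 else out.T


def ebv_305(a: np.ndarray, basis: LegendreBasis):
    """305-day EBV u'a; vectorized over animals when ``a`` is 2-D."""
    a = np.asarray(a, dtype=float)
    u = basis.lactation_sum()
    if a.ndim == 1:
        if a.size != basis.n_terms:
            raise ValueError("coefficient vector length does not match basis order")
        return float(u @ a)
    if a.shape[1] != basis.n_terms:
        raise ValueError("coefficient matrix width does not match basis order")
    return a @ u


class ParameterCount(NamedTuple):
    n_genetic: int
    n_pe: int
    n_residual: int
    total: int


def count_parameters(spec: ModelSpec) -> ParameterCount:
    """(Co)variance parameters estimated by the model.

    nA = (nr+1)(nr+2)/2 and nPE = (np+1)(np+2)/2 for the symmetric G and P;
    one residual variance when homogeneous, ten when heterogeneous.
    """
    ka, kp = spec.k_genetic, spec.k_pe
    n_g = ka * (ka + 1) // 2
    n_p = kp * (kp + 1) // 2
    n_r = N_RESIDUAL_CLASSES if spec.residual_mode == "heterogeneous" else 1
    return ParameterCount(n_g, n_p, n_r, n_g + n_p + n_r)


@dataclass(frozen=True)
class ModelScore:
    p: int
    n: int
    minus2logl: float
    aic: float
    bic: float


def model_scores(
    fit: REMLResult, design: Design, count_fixed: bool = False
) -> ModelScore:
    """AIC and BIC of a fitted model (natural log; lower is better).

    ``count_fixed`` adds rank(X) to the parameter count p; by default p
    counts only the (co)variance parameters.
    """
    rank_x = compute_rank_x(design)
    n = design.n_records - rank_x
    if n <= 0:
        raise ValueError("BIC sample size n = records - rank(X) must be positive")
    p = count_parameters(design.spec).total
    if count_fixed:
        p += rank_x
    m2 = fit.minus2logl
    return ModelScore(p=p, n=n, minus2logl=m2, aic=m2 + 2 * p, bic=m2 + p * np.log(n))
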