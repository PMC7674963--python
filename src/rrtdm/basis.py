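"""Normalized Legendre polynomial basis over the days-in-milk range.

Random regression test-day models describe each animal's lactation-long
genetic and permanent-environment effects as regressions on Legendre
polynomials of standardized days in milk (DIM).  The basis used here is the
orthonormal scaling ``LP_k(x) = sqrt((2k+1)/2) * P_k(x)`` of the classical
Legendre polynomials ``P_k`` on [-1, 1], so that

    integral_{-1}^{1} LP_j(x) LP_k(x) dx = delta_jk.

DIM t is mapped onto [-1, 1] by the affine standardization
``x = 2 (t - t_min) / (t_max - t_min) - 1`` with t_min = 5 and t_max = 305
for a standard 301-day first lactation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import eval_legendre

__all__ = ["LegendreBasis", "standardize_dim", "lp_value"]

#: Default days-in-milk range of a standard first lactation.
DIM_MIN = 5
DIM_MAX = 305


def standardize_dim(dim, dim_min: int = DIM_MIN, dim_max: int = DIM_MAX):
    """Map DIM onto [-1, 1]: ``x = 2 (dim - dim_min)/(dim_max - dim_min) - 1``.

    Accepts scalars or arrays.  Raises ``ValueError`` for DIM outside the
    closed range.
    """
    dim = np.asarray(dim)
    if np.any(dim < dim_min) or np.any(dim > dim_max):
        raise ValueError(f"DIM outside [{dim_min}, {dim_max}]")
    x = 2.0 * (dim - dim_min) / (dim_max - dim_min) - 1.0
    return float(x) if x.ndim == 0 else x


def lp_value(k: int, x):
    """Orthonormal Legendre polynomial ``LP_k(x) = sqrt((2k+1)/2) P_k(x)``.

    Valid for any order k >= 0 via the stable three-term recurrence behind
    :func:`scipy.special.eval_legendre`.
    """
    if k < 0:
        raise ValueError("polynomial order must be non-negative")
    return np.sqrt((2 * k + 1) / 2.0) * eval_legendre(k, x)


@dataclass(frozen=True)
class LegendreBasis:
    """Basis of ``order + 1`` orthonormal Legendre polynomials on a DIM range.

    Parameters
    ----------
    order
        Highest polynomial index n; the basis holds terms k = 0..n.
    dim_min, dim_max
        Closed DIM range mapped onto [-1, 1].
    """

    order: int
    dim_min: int = DIM_MIN
    dim_max: int = DIM_MAX

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.dim_min >= self.dim_max:
            raise ValueError("dim_min must be < dim_max")

    @property
    def n_terms(self) -> int:
        return self.order + 1

    @property
    def n_days(self) -> int:
        return self.dim_max - self.dim_min + 1

    def standardize(self, dim):
        return standardize_dim(dim, self.dim_min, self.dim_max)

    def vector(self, dim) -> np.ndarray:
        """Covariate vector ``z`` with ``z[k] = LP_k(x(dim))``, k = 0..order."""
        x = self.standardize(dim)
        return np.array([lp_value(k, x) for k in range(self.n_terms)])

    def matrix(self) -> np.ndarray:
        """Basis values for every integer DIM in range, shape (n_days, order+1).

        Row ``t - dim_min`` equals ``vector(t)``.  Cached per basis.
        """
        return _basis_matrix(self.order, self.dim_min, self.dim_max)

    def lactation_sum(self) -> np.ndarray:
        """Column sums ``u_k = sum_t LP_k(x_t)`` over the whole DIM range.

        ``u`` turns per-day regressions into whole-lactation quantities:
        a 305-day breeding value is ``u' a`` and the genetic variance of the
        305-day sum is ``u' G u``.
        """
        return self.matrix().sum(axis=0)


@lru_cache(maxsize=32)
def _basis_matrix(order: int, dim_min: int, dim_max: int) -> np.ndarray:
    days = np.arange(dim_min, dim_max + 1)
    x = standardize_dim(days, dim_min, dim_max)
    out = np.column_stack([lp_value(k, x) for k in range(order + 1)])
    out.setflags(write=False)
    return out
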