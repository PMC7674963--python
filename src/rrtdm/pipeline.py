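"""End-to-end orchestration: prepare data, fit models, compare, validate.

These helpers chain the lower-level modules the way a full genetic
evaluation does: edit and classify the records, sort the pedigree and build
A-inverse, assemble the design, run REML, and derive summaries.  The CLI is
a thin wrapper around this module, and the replicated studies in the test
suite use it directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import FilterRules, apply_filters, classify_records
from .mme import Design, ModelSpec, build_design
from .pedigree import SortedPedigree, build_a_inverse, topological_sort
from .reml import (
    REMLOptions,
    REMLResult,
    VarianceComponents,
    fit_heterogeneous,
    fit_reml,
    residual_variance_table,
)
from .summaries import ModelScore, ebv_305, model_scores, variance_trajectory
from .validate import predictive_correlations, split_by_last_calving_year

__all__ = ["PreparedData", "FitOutput", "prepare", "fit_model", "compare_models",
           "validate_predictive_ability", "ebv_table"]


@dataclass
class PreparedData:
    records: pd.DataFrame           # filtered + classified
    pedigree: SortedPedigree
    a_inverse: sp.csr_matrix
    audit: dict


@dataclass
class FitOutput:
    design: Design
    result: REMLResult
    score: ModelScore
    trajectory: pd.DataFrame
    ebv305: dict                     # animal id -> 305-day EBV


def prepare(
    records: pd.DataFrame, pedigree: pd.DataFrame, rules: FilterRules = FilterRules()
) -> PreparedData:
    """Edit records, classify fixed effects, sort pedigree, build A-inverse."""
    filtered, audit = apply_filters(records, rules)
    classified = classify_records(filtered)
    sped = topological_sort(pedigree)
    return PreparedData(
        records=classified, pedigree=sped, a_inverse=build_a_inverse(sped), audit=audit
    )


def fit_model(
    prep: PreparedData,
    spec: ModelSpec,
    init: VarianceComponents | None = None,
    opts: REMLOptions | None = None,
) -> FitOutput:
    """REML fit of one model (order + residual mode) with all summaries."""
    design = build_design(prep.records, prep.pedigree, spec)
    if spec.residual_mode == "heterogeneous":
        result = fit_heterogeneous(design, init, prep.a_inverse, opts)
    else:
        result = fit_reml(design, init, prep.a_inverse, opts)
    score = model_scores(result, design)
    traj = variance_trajectory(result.components, spec.basis_genetic)
    ebv = ebv_305(result.solutions.a, spec.basis_genetic)
    ebv305 = {aid: float(e) for aid, e in zip(result.solutions.animal_ids, ebv)}
    return FitOutput(design=design, result=result, score=score, trajectory=traj,
                     ebv305=ebv305)


def compare_models(
    prep: PreparedData,
    orders=(1, 2, 3),
    modes=("homogeneous", "heterogeneous"),
    opts: REMLOptions | None = None,
) -> pd.DataFrame:
    """Fit all (order, mode) combinations; rows mirror a model-selection table.

    Fits within a mode are warm-started from the next-lower order (the
    lower-order optimum embeds exactly in the larger parameter space), which
    both speeds convergence and preserves the nested-model likelihood
    ordering.
    """
    rows = []
    for mode in modes:
        init = None
        for order in sorted(orders):
            spec = ModelSpec(order, order, residual_mode=mode)
            out = fit_model(prep, spec, init=_embed(init, order + 1), opts=opts)
            rows.append(
                {
                    "residual_mode": mode,
                    "order": order,
                    "minus2logl": out.score.minus2logl,
                    "p": out.score.p,
                    "n": out.score.n,
                    "aic": out.score.aic,
                    "bic": out.score.bic,
                    "converged": out.result.converged,
                }
            )
            init = out.result.components
    return pd.DataFrame(rows)


def _embed(comps: VarianceComponents | None, k: int, eps: float = 0.02):
    """Embed a lower-order estimate in a k x k parameter space (PD-padded)."""
    if comps is None:
        return None

    def pad(M):
        k0 = M.shape[0]
        if k0 >= k:
            return M[:k, :k]
        out = np.eye(k) * eps * np.trace(M) / k0
        out[:k0, :k0] = M
        return out

    return VarianceComponents(G=pad(comps.G), P=pad(comps.P), residual=comps.residual)


def validate_predictive_ability(
    records: pd.DataFrame,
    pedigree: pd.DataFrame,
    spec: ModelSpec,
    opts: REMLOptions | None = None,
    rules: FilterRules = FilterRules(),
    refit_reduced: bool = False,
    all_animals: bool = False,
) -> dict:
    """Full-vs-reduced EBV305 correlations for one model.

    Variance components are estimated on the full data; the reduced-data
    solutions reuse them (set ``refit_reduced`` to re-estimate).  By default
    correlations are computed over the validation cows (the animals whose
    phenotypes were removed); ``all_animals`` widens them to every recorded
    cow.
    """
    split = split_by_last_calving_year(records)
    prep_full = prepare(split.full, pedigree, rules)
    full_fit = fit_model(prep_full, spec, opts=opts)
    prep_red = prepare(split.reduced, pedigree, rules)
    if refit_reduced:
        red_fit = fit_model(prep_red, spec, opts=opts)
    else:
        design_red = build_design(prep_red.records, prep_red.pedigree, spec)
        red_result = fit_reml(
            design_red,
            init=full_fit.result.components,
            a_inverse=prep_red.a_inverse,
            opts=REMLOptions(max_iter=0),
            class_weights=full_fit.result.components.class_weights,
        )
        ebv = ebv_305(red_result.solutions.a, spec.basis_genetic)
        red_ebv = {a: float(e) for a, e in zip(red_result.solutions.animal_ids, ebv)}
        red_fit = None
    red_ebv305 = red_fit.ebv305 if red_fit is not None else red_ebv
    animals = (
        list(pd.unique(prep_full.records["cow_id"])) if all_animals
        else [c for c in split.validation_cows if c in full_fit.ebv305]
    )
    pearson, spearman = predictive_correlations(full_fit.ebv305, red_ebv305, animals)
    return {
        "order": spec.order_genetic,
        "residual_mode": spec.residual_mode,
        "pearson": pearson,
        "spearman": spearman,
        "n_validation_animals": len(animals),
        "last_year": split.last_year,
        "full_fit": full_fit,
    }


def ebv_table(fit: FitOutput) -> pd.DataFrame:
    """EBV report: one row per pedigree animal with its 305-day EBV."""
    return pd.DataFrame(
        {"animal_id": list(fit.ebv305), "ebv305": list(fit.ebv305.values())}
    )
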