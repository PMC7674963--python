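"""REML likelihood and estimation: closed forms, dense oracle, EM ascent."""

import numpy as np
import pandas as pd
import pytest

import rrtdm as r
from rrtdm.data import classify_records
from rrtdm.mme import ModelSpec, build_design
from rrtdm.pedigree import build_a_dense, build_a_inverse, topological_sort
from rrtdm.reml import (
    REMLOptions,
    VarianceComponents,
    compute_weights,
    estimate_residual_class_variances,
    fit_heterogeneous,
    fit_reml,
    restricted_log_likelihood,
)
from rrtdm.simulate import REFERENCE_RESIDUAL_VARIANCES

from conftest import ped_df
from helpers import dense_gls, random_components, tiny_instance

EPS_I = 1e-12  # variance ratio that switches a random effect "off"


def intercept_only_design(y, dim=100):
    """Records of one cow at one DIM: the fixed part collapses to an intercept."""
    cal = pd.Timestamp("2014-03-15")
    recs = classify_records(
        pd.DataFrame(
            [
                {"cow_id": "c1", "herd_id": "H1", "calving_date": cal,
                 "test_date": cal + pd.Timedelta(days=dim), "dim": dim,
                 "milk_kg": float(v), "age_at_calving_months": 24}
                for v in y
            ]
        )
    )
    sped = topological_sort(ped_df([("c1", "0", "0")]))
    return build_design(recs, sped, ModelSpec(1, 1)), build_a_inverse(sped)


class TestRestrictedLogLikelihood:
    def test_closed_form_two_observations(self):
        """y=(1,2), intercept only, v=0.5: matches the residual-likelihood value."""
        design, a_inv = intercept_only_design([1.0, 2.0])
        comps = VarianceComponents(
            G=EPS_I * np.eye(2), P=EPS_I * np.eye(2), residual=0.5
        )
        ll = restricted_log_likelihood(design, comps, a_inv)
        assert ll == pytest.approx(-1.41894, abs=1e-4)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(0)
        design, a_inv, _ = tiny_instance(rng, order=1)
        comps = VarianceComponents(
            G=random_components(rng, 2), P=random_components(rng, 2), residual=1.5
        )
        ll1 = restricted_log_likelihood(design, comps, a_inv)
        design.y = design.y + 7.0
        ll2 = restricted_log_likelihood(design, comps, a_inv)
        assert ll1 == pytest.approx(ll2, abs=1e-7)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        order = int(rng.integers(1, 3))
        design, a_inv, A = tiny_instance(rng, order=order)
        k = order + 1
        comps = VarianceComponents(
            G=random_components(rng, k, 2.0),
            P=random_components(rng, k, 1.5),
            residual=float(rng.uniform(0.5, 3.0)),
        )
        ll = restricted_log_likelihood(design, comps, a_inv)
        _, _, _, ll_dense = dense_gls(design, comps.G, comps.P, comps.residual, A)
        assert ll == pytest.approx(ll_dense, abs=1e-8)

    def test_heterogeneous_matches_dense_oracle(self):
        rng = np.random.default_rng(17)
        design, a_inv, A = tiny_instance(rng, order=1)
        v10 = rng.uniform(0.8, 2.5, 10)
        comps = VarianceComponents(
            G=random_components(rng, 2), P=random_components(rng, 2), residual=v10
        )
        ll = restricted_log_likelihood(design, comps, a_inv)
        _, _, _, ll_dense = dense_gls(design, comps.G, comps.P, v10, A)
        assert ll == pytest.approx(ll_dense, abs=1e-8)


class TestFitREML:
    def test_no_random_effects_gives_ols_residual_variance(self):
        """With G, P pinned near zero the REML residual is SS_res/(n - rank X)."""
        rng = np.random.default_rng(1)
        design, a_inv, _ = tiny_instance(rng, order=1)
        init = VarianceComponents(G=EPS_I * np.eye(2), P=EPS_I * np.eye(2), residual=1.0)
        res = fit_reml(design, init, a_inv, REMLOptions(max_iter=0))
        X = design.X.toarray()
        beta, *_ = np.linalg.lstsq(X, design.y, rcond=None)
        ss = float(np.sum((design.y - X @ beta) ** 2))
        expected = ss / (design.n_records - design.n_fixed)
        assert res.components.residual_mean == pytest.approx(expected, rel=1e-6)

    def test_em_is_monotone_and_direct_at_least_as_good(self):
        cfg = r.SimulationConfig(
            n_base_sires=8, n_base_dams=20, n_generations=1, sires_per_generation=8,
            true_order=1, n_herds=2, seed=5,
        )
        ds = r.generate_dataset(cfg)
        prep = r.prepare(ds.records, ds.pedigree)
        design = build_design(prep.records, prep.pedigree, ModelSpec(1, 1))
        em = fit_reml(design, a_inverse=prep.a_inverse,
                      opts=REMLOptions(algorithm="em", max_iter=40))
        assert np.all(np.diff(em.history) <= 1e-6), "EM must not decrease logL"
        direct = fit_reml(design, a_inverse=prep.a_inverse, opts=REMLOptions(tol=1e-6))
        assert direct.minus2logl <= em.minus2logl + 1e-3

    def test_em_first_step_small_at_the_truth(self):
        """Starting EM from the generating components barely moves them."""
        cfg = r.SimulationConfig(n_base_dams=35, true_order=2, seed=11)
        ds = r.generate_dataset(cfg)
        prep = r.prepare(ds.records, ds.pedigree)
        design = build_design(prep.records, prep.pedigree, ModelSpec(2, 2))
        truth = VarianceComponents(
            G=ds.true_components.G, P=ds.true_components.P,
            residual=ds.true_components.residual_mean,
        )
        one = fit_reml(design, truth, prep.a_inverse,
                       REMLOptions(algorithm="em", max_iter=1))
        for name in ("G", "P"):
            new = getattr(one.components, name)
            old = getattr(truth, name)
            rel = np.abs(np.diag(new) - np.diag(old)) / np.diag(old)
            assert np.max(rel) < 0.05, f"first EM step moved {name} by {rel}"


class TestResidualClasses:
    def _design_all_classes(self, y_by_class):
        cal = pd.Timestamp("2014-03-15")
        rows = []
        i = 0
        for cls in range(10):
            for yv in y_by_class[cls]:
                dim = 20 + 30 * cls
                rows.append(
                    {"cow_id": "c1", "herd_id": "H1", "calving_date": cal,
                     "test_date": cal + pd.Timedelta(days=dim + i), "dim": dim + i,
                     "milk_kg": float(yv), "age_at_calving_months": 24}
                )
                i = (i + 1) % 3
        recs = classify_records(pd.DataFrame(rows))
        sped = topological_sort(ped_df([("c1", "0", "0")]))
        design = build_design(recs, sped, ModelSpec(1, 1))
        return design

    def test_equal_residuals_give_equal_variances(self):
        design = self._design_all_classes({c: [1.0, -1.0] for c in range(10)})
        from rrtdm.mme import split_solutions

        sols = split_solutions(np.zeros(design.n_fixed + 4), design)
        v = estimate_residual_class_variances(design, sols, model_df=0)
        assert np.allclose(v, v[0])

    def test_inflated_class_gets_larger_variance(self):
        y = {c: [1.0, -1.0] for c in range(10)}
        y[0] = [3.0, -3.0]
        design = self._design_all_classes(y)
        from rrtdm.mme import split_solutions

        sols = split_solutions(np.zeros(design.n_fixed + 4), design)
        v = estimate_residual_class_variances(design, sols, model_df=0)
        assert v[0] > 1.5 * v[1]
        assert np.allclose(v[1:], v[1])

    def test_scale_equivariance_of_class_variances_and_weights(self):
        rng = np.random.default_rng(2)
        y = {c: rng.standard_normal(3).tolist() for c in range(10)}
        design = self._design_all_classes(y)
        from rrtdm.mme import split_solutions

        sols0 = split_solutions(np.zeros(design.n_fixed + 4), design)
        v1 = estimate_residual_class_variances(design, sols0, model_df=0)
        design.y = design.y * 3.0
        v2 = estimate_residual_class_variances(design, sols0, model_df=0)
        assert v2 == pytest.approx(9.0 * v1, rel=1e-9)
        assert compute_weights(v2) == pytest.approx(compute_weights(v1), rel=1e-9)


class TestWeights:
    def test_homogeneous_case(self):
        assert compute_weights([2.0, 2.0, 2.0]) == pytest.approx([1, 1, 1])

    def test_two_class_arithmetic(self):
        assert compute_weights([1.0, 3.0]) == pytest.approx([2.0, 2 / 3], abs=1e-4)

    def test_reference_first_order_column(self):
        """Early-lactation weight from the published order-1 residual profile."""
        v = REFERENCE_RESIDUAL_VARIANCES["lp1"].to_numpy()
        w = compute_weights(v)
        assert v.mean() == pytest.approx(16.07, abs=0.005)
        assert w[0] == pytest.approx(16.07 / 29.20, abs=1e-3)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_weights([1.0, 0.0])


class TestHeterogeneousFit:
    def test_null_case_weights_near_one(self):
        """Truly homogeneous residuals: estimated class weights stay near 1."""
        # ~1,800 cows with complete lactations: every DIM class holds ~2,000
        # records, so each class variance carries ~3% sampling error and the
        # 10% calibration band is a meaningful test
        cfg = r.SimulationConfig(
            n_base_dams=300, true_order=1, residual="homogeneous", seed=21,
            tests_per_cow=(9, 12), first_test_range=(5, 15),
            extraction_margin_days=None,
        )
        ds = r.generate_dataset(cfg)
        prep = r.prepare(ds.records, ds.pedigree)
        design = build_design(prep.records, prep.pedigree,
                              ModelSpec(1, 1, residual_mode="heterogeneous"))
        res = fit_heterogeneous(design, a_inverse=prep.a_inverse,
                                opts=REMLOptions(tol=1e-4, max_iter=30, max_outer=2))
        w = res.components.class_weights
        assert np.all(np.abs(w - 1.0) < 0.10), w
        # overall level agrees with the homogeneous truth
        assert res.components.residual_mean == pytest.approx(
            ds.true_components.residual_mean, rel=0.15
        )
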