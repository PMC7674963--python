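"""Mixed-model equations against the dense GLS/BLUP oracle."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from rrtdm.basis import lp_value
from rrtdm.mme import ModelSpec, assemble_mme, build_design, compute_rank_x, solve_mme
from rrtdm.data import classify_records
from rrtdm.pedigree import topological_sort, build_a_inverse

from conftest import ped_df
from helpers import dense_gls, random_components, tiny_instance


def simple_records(cow_dims, herd="H1"):
    rows = []
    for cow, dims in cow_dims.items():
        cal = pd.Timestamp("2014-03-15")
        for d in dims:
            rows.append(
                {"cow_id": cow, "herd_id": herd, "calving_date": cal,
                 "test_date": cal + pd.Timedelta(days=int(d)), "dim": int(d),
                 "milk_kg": 25.0, "age_at_calving_months": 24}
            )
    return classify_records(pd.DataFrame(rows))


class TestBuildDesign:
    def test_single_record_z_row_is_basis_vector(self):
        sped = topological_sort(ped_df([("c1", "0", "0")]))
        recs = simple_records({"c1": [5, 100, 305]})
        d = build_design(recs, sped, ModelSpec(1, 1))
        row = d.Z_a[0].toarray().ravel()
        nz = row[row != 0]
        x = 2 * (5 - 5) / 300 - 1
        assert nz == pytest.approx([lp_value(0, x), lp_value(1, x)])

    def test_same_cow_shares_pe_block(self):
        sped = topological_sort(ped_df([("c1", "0", "0")]))
        recs = simple_records({"c1": [50, 150, 305]})
        d = build_design(recs, sped, ModelSpec(1, 1))
        assert d.Z_pe.shape[1] == 2
        cols0 = d.Z_pe[0].indices.tolist()
        cols1 = d.Z_pe[1].indices.tolist()
        assert cols0 == cols1
        assert not np.allclose(d.Z_pe[0].data, d.Z_pe[1].data)

    def test_cow_missing_from_pedigree_raises(self):
        sped = topological_sort(ped_df([("c1", "0", "0")]))
        recs = simple_records({"ghost": [50, 150, 305]})
        with pytest.raises(ValueError, match="absent from pedigree"):
            build_design(recs, sped, ModelSpec(1, 1))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_blup_matches_dense_gls(self, seed):
        rng = np.random.default_rng(seed)
        order = int(rng.integers(1, 3))
        design, a_inv, A = tiny_instance(rng, order=order)
        k = order + 1
        G = random_components(rng, k, 2.0)
        P = random_components(rng, k, 1.5)
        v = float(rng.uniform(0.5, 3.0))
        sys_ = assemble_mme(design, G, P, v, a_inv)
        sol = solve_mme(sys_)
        b, u_a, u_pe, _ = dense_gls(design, G, P, v, A)
        fixed_est = sol.fixed.loc[
            sol.fixed.apply(lambda r: (r["effect"], r["level"]) in design.x_labels, axis=1),
            "estimate",
        ].to_numpy()
        assert fixed_est == pytest.approx(b, abs=1e-6)
        assert sol.a == pytest.approx(u_a, abs=1e-6)
        assert sol.pe == pytest.approx(u_pe, abs=1e-6)

    def test_heterogeneous_residual_matches_oracle(self):
        rng = np.random.default_rng(99)
        design, a_inv, A = tiny_instance(rng, order=1)
        G, P = random_components(rng, 2, 2.0), random_components(rng, 2, 1.5)
        v10 = rng.uniform(0.5, 3.0, 10)
        sol = solve_mme(assemble_mme(design, G, P, v10, a_inv))
        _, u_a, u_pe, _ = dense_gls(design, G, P, v10, A)
        assert sol.a == pytest.approx(u_a, abs=1e-6)
        assert sol.pe == pytest.approx(u_pe, abs=1e-6)


class TestMMEProperties:
    def test_scale_invariance_of_solutions(self):
        rng = np.random.default_rng(1)
        design, a_inv, _ = tiny_instance(rng, order=1)
        G, P, v = random_components(rng, 2), random_components(rng, 2), 1.3
        s1 = solve_mme(assemble_mme(design, G, P, v, a_inv))
        s2 = solve_mme(assemble_mme(design, 2 * G, 2 * P, 2 * v, a_inv))
        assert s1.vector == pytest.approx(s2.vector, abs=1e-8)

    def test_zero_observations_zero_random_solutions(self):
        rng = np.random.default_rng(2)
        design, a_inv, _ = tiny_instance(rng, order=1)
        design.y[:] = 0.0
        sol = solve_mme(assemble_mme(design, np.eye(2), np.eye(2), 1.0, a_inv))
        assert np.allclose(sol.a, 0) and np.allclose(sol.pe, 0)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(3)
        design, a_inv, _ = tiny_instance(rng, order=1)
        G, P, v = random_components(rng, 2), random_components(rng, 2), 1.0
        sol = solve_mme(assemble_mme(design, G, P, v, a_inv))
        perm = rng.permutation(design.n_records)
        design2 = design
        import copy

        design2 = copy.copy(design)
        design2.y = design.y[perm]
        design2.X = design.X[perm]
        design2.Z_a = design.Z_a[perm]
        design2.Z_pe = design.Z_pe[perm]
        design2.residual_class = design.residual_class[perm]
        sol2 = solve_mme(assemble_mme(design2, G, P, v, a_inv))
        assert sol.vector == pytest.approx(sol2.vector, abs=1e-9)

    def test_shrinkage_to_zero_with_vanishing_variances(self):
        rng = np.random.default_rng(4)
        design, a_inv, _ = tiny_instance(rng, order=1)
        G, P = random_components(rng, 2), random_components(rng, 2)
        norms = []
        for eps in (1.0, 1e-2, 1e-4):
            sol = solve_mme(assemble_mme(design, eps * G, eps * P, 1.0, a_inv))
            norms.append(np.linalg.norm(sol.a) + np.linalg.norm(sol.pe))
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-2 * norms[0]

    def test_fit_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        design, a_inv, _ = tiny_instance(rng, order=2)
        G, P = random_components(rng, 3), random_components(rng, 3)
        sol = solve_mme(assemble_mme(design, G, P, 0.8, a_inv))
        W = sp.hstack([design.X, design.Z_a, design.Z_pe])
        resid = design.y - W @ sol.vector
        assert design.y == pytest.approx(W @ sol.vector + resid)

    def test_nonpd_g_rejected_by_name(self):
        rng = np.random.default_rng(6)
        design, a_inv, _ = tiny_instance(rng, order=1)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="G"):
            assemble_mme(design, bad, np.eye(2), 1.0, a_inv)

    def test_iterative_matches_direct(self):
        rng = np.random.default_rng(8)
        design, a_inv, _ = tiny_instance(rng, order=1)
        G, P = random_components(rng, 2), random_components(rng, 2)
        sys_ = assemble_mme(design, G, P, 1.0, a_inv)
        s1 = solve_mme(sys_, method="direct")
        s2 = solve_mme(sys_, method="iterative", tol=1e-12)
        assert s1.vector == pytest.approx(s2.vector, abs=1e-6)


class TestRankX:
    def test_single_intercept_column(self):
        X = np.ones((10, 1))
        assert compute_rank_x(X) == 1

    def test_two_factor_full_dummies_confounded(self):
        rng = np.random.default_rng(0)
        hys = rng.integers(0, 2, 30)
        age = rng.integers(0, 2, 30)
        X = np.zeros((30, 4))
        X[np.arange(30), hys] = 1
        X[np.arange(30), 2 + age] = 1
        assert compute_rank_x(X) == 3

    def test_duplicated_column_leaves_rank(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        X2 = np.column_stack([X, X[:, 1]])
        assert compute_rank_x(X) == compute_rank_x(X2) == 2

    def test_design_rank_equals_constrained_columns(self):
        rng = np.random.default_rng(11)
        design, _, _ = tiny_instance(rng, order=1)
        assert compute_rank_x(design) == design.n_fixed
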