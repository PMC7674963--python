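"""The synthetic-herd generator: structure, determinism, and moments."""

import numpy as np
import pandas as pd
import pytest

import rrtdm as r
from rrtdm.basis import LegendreBasis
from rrtdm.pedigree import compute_inbreeding, topological_sort
from rrtdm.simulate import (
    REFERENCE_DIM_CLASS_STATS,
    REFERENCE_RESIDUAL_VARIANCES,
    REFERENCE_RESIDUAL_VARIANCE_TOTALS,
    default_true_components,
    reference_mean_curve,
    simulate_genetic_coefficients,
    simulate_pedigree,
)
from rrtdm.summaries import ebv_305, h2_305, rep_305, variance_trajectory

from conftest import ped_df


class TestPedigree:
    def test_one_generation_count(self):
        cfg = r.SimulationConfig(
            n_base_sires=2, n_base_dams=10, daughters_per_dam=1,
            n_generations=1, sires_per_generation=0,
        )
        ped, cows = simulate_pedigree(cfg, np.random.default_rng(0))
        assert len(ped) == 22
        assert len(cows) == 10

    def test_sorts_without_insertion(self):
        cfg = r.SimulationConfig(n_base_dams=30)
        ped, _ = simulate_pedigree(cfg, np.random.default_rng(1))
        sped = topological_sort(ped)
        assert len(sped) == len(ped)

    def test_every_nonfounder_has_two_known_parents(self):
        cfg = r.SimulationConfig(n_base_dams=20)
        ped, _ = simulate_pedigree(cfg, np.random.default_rng(2))
        nonfounder = ped[~ped["animal_id"].str.match(r"[SD]\d")]
        assert (nonfounder["sire_id"] != "0").all()
        assert (nonfounder["dam_id"] != "0").all()

    def test_inbreeding_appears_under_small_population(self):
        cfg = r.SimulationConfig(
            n_base_sires=3, n_base_dams=10, n_generations=4, sires_per_generation=3
        )
        ped, _ = simulate_pedigree(cfg, np.random.default_rng(3))
        sped = topological_sort(ped)
        F = compute_inbreeding(sped)
        n = len(F)
        assert F[: n // 2].mean() < F[n // 2 :].mean()
        assert F[n // 2 :].mean() > 0


class TestGeneticCoefficients:
    def test_founder_covariance_matches_g(self):
        sped = topological_sort(ped_df([(f"f{i}", "0", "0") for i in range(8000)]))
        G = default_true_components(1).G
        a = simulate_genetic_coefficients(sped, G, np.random.default_rng(4))
        emp = np.cov(a.T)
        assert np.abs(emp - G).max() / np.abs(G).max() < 0.05

    def test_full_sib_covariance_half_g(self):
        rows = []
        for f in range(4000):
            rows += [(f"s{f}", "0", "0"), (f"d{f}", "0", "0"),
                     (f"x{f}", f"s{f}", f"d{f}"), (f"y{f}", f"s{f}", f"d{f}")]
        sped = topological_sort(ped_df(rows))
        G = default_true_components(1).G
        a = simulate_genetic_coefficients(sped, G, np.random.default_rng(5))
        ids = {aid: i for i, aid in enumerate(sped.ids)}
        x = np.array([a[ids[f"x{f}"]] for f in range(4000)])
        y = np.array([a[ids[f"y{f}"]] for f in range(4000)])
        cross = (x - x.mean(0)).T @ (y - y.mean(0)) / (len(x) - 1)
        sym = 0.5 * (cross + cross.T)
        assert np.abs(sym - 0.5 * G).max() < 0.1 * np.abs(G).max()

    def test_offspring_mean_is_midparent(self):
        rows = [("s", "0", "0"), ("d", "0", "0")] + [
            (f"o{i}", "s", "d") for i in range(20000)
        ]
        sped = topological_sort(ped_df(rows))
        G = default_true_components(1).G
        a = simulate_genetic_coefficients(sped, G, np.random.default_rng(6))
        midparent = 0.5 * (a[sped.ids.index("s")] + a[sped.ids.index("d")])
        dev = a[2:] - midparent
        assert np.abs(dev.mean(axis=0)).max() < 0.05


class TestRecords:
    def test_near_zero_variances_reproduce_mean_structure(self):
        k = 3
        cfg = r.SimulationConfig(
            n_base_dams=10, true_order=2,
            true_G=1e-12 * np.eye(k), true_P=1e-12 * np.eye(k),
            true_residual=1e-12, hys_sd=0.0, age_effects=(0, 0, 0, 0), seed=7,
        )
        ds = r.generate_dataset(cfg)
        curve = reference_mean_curve()
        expected = curve[ds.records["dim"].to_numpy() - 5]
        assert np.abs(ds.records["milk_kg"].to_numpy() - expected).max() < 0.01

    def test_residual_class_variances_recovered_empirically(self):
        cfg = r.SimulationConfig(
            n_base_sires=5, n_base_dams=1500, n_generations=1,
            sires_per_generation=0, daughters_per_dam=2, true_order=1,
            true_G=1e-10 * np.eye(2), true_P=1e-10 * np.eye(2),
            hys_sd=0.0, age_effects=(0, 0, 0, 0), seed=8,
            tests_per_cow=(10, 12), first_test_range=(5, 30),
        )
        ds = r.generate_dataset(cfg)
        curve = reference_mean_curve()
        resid = ds.records["milk_kg"].to_numpy() - curve[ds.records["dim"].to_numpy() - 5]
        cls = np.clip((ds.records["dim"].to_numpy() - 5) // 30, 0, 9)
        v_true = ds.true_components.residual_by_class()
        for i in range(10):
            emp = resid[cls == i].var()
            assert emp == pytest.approx(v_true[i], rel=0.10)

    def test_default_scale_and_edit_loss(self, small_dataset):
        ds = small_dataset
        per_cow = ds.records.groupby("cow_id").size()
        assert 5 <= per_cow.mean() <= 11
        assert ds.n_truncated / (len(ds.records) + ds.n_truncated) <= 0.02
        filtered, audit = r.apply_filters(ds.records)
        assert sum(audit.values()) / len(ds.records) <= 0.02

    def test_truth_file_ebv_ties_to_basis_code(self, small_dataset):
        ds = small_dataset
        basis = LegendreBasis(ds.config.true_order)
        i = ds.sorted_pedigree.ids.index(ds.recorded_cows[0])
        assert ds.true_ebv305[ds.recorded_cows[0]] == pytest.approx(
            ebv_305(ds.true_a[i], basis)
        )


class TestDeterminismAndDefaults:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = r.SimulationConfig(n_base_dams=25, seed=9)
        r.generate_dataset(cfg, out_dir=tmp_path / "a")
        r.generate_dataset(cfg, out_dir=tmp_path / "b")
        for name in ["pedigree.csv", "records.csv", "truth_components.json",
                     "truth_ebv.csv", "simulation_config.json"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_reference_residual_totals_are_column_means(self):
        for col, total in REFERENCE_RESIDUAL_VARIANCE_TOTALS.items():
            mean = REFERENCE_RESIDUAL_VARIANCES[col].mean()
            assert mean == pytest.approx(total, abs=0.005)

    def test_default_truth_within_reported_parameter_ranges(self):
        c = default_true_components(3)
        tr = variance_trajectory(c)
        assert 0.14 <= tr["h2"].min() and tr["h2"].max() <= 0.35
        # repeatability overshoots 0.8 slightly on the last lactation days,
        # where the reference residual profile is at its lowest
        assert 0.55 <= tr["repeatability"].min() and tr["repeatability"].max() <= 0.87

    def test_mean_curve_peaks_early_and_declines(self):
        curve = reference_mean_curve()
        peak = int(np.argmax(curve)) + 5
        assert 35 <= peak <= 75
        assert curve[-1] < curve[peak - 5]
        assert abs(curve[45] - 26.6) < 1.0
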