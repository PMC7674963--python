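"""Synthetic herd generator with the exact structure the test-day model assumes.

Real first-lactation test-day datasets of the kind this package targets are
proprietary, so every pipeline stage is exercised on simulated data drawn
from the model's own generative process:

* a multi-generation pedigree under random mating with no selection;
* genetic regression coefficients by Mendelian-sampling recursion,
  ``a_i = (a_sire + a_dam)/2 + m_i`` with ``m_i ~ N(0, d_i G)``, which gives
  the exact ``A (x) G`` covariance;
* cow permanent-environment coefficients ``pe ~ N(0, P)``;
* records ``y = mean_curve(DIM) + HYS + AGE + z'a + z'pe + e`` at roughly
  30-day test intervals, with residual variance per 30-day DIM class.

Default parameter values are anchored to published reference statistics
from a regional first-lactation Holstein evaluation (class means of daily
yield, and the DIM-class residual-variance profile with its elevated early
lactation), scaled so that daily heritability sits around 0.15-0.30 and
repeatability around 0.6-0.8 across the trajectory.  Out-of-range yields
(outside 5-80 kg) are truncated out, mirroring real data editing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .basis import LegendreBasis
from .data import SEASON_OF_MONTH, write_records
from .pedigree import SortedPedigree, topological_sort
from .reml import VarianceComponents
from .summaries import ebv_305

__all__ = [
    "SimulationConfig",
    "default_true_components",
    "reference_mean_curve",
    "simulate_pedigree",
    "simulate_genetic_coefficients",
    "simulate_records",
    "generate_dataset",
    "SimulatedDataset",
    "REFERENCE_DIM_CLASS_STATS",
    "REFERENCE_RESIDUAL_VARIANCES",
]

# ---------------------------------------------------------------------------
# Reference statistics from a published regional Holstein first-lactation
# test-day evaluation; used to anchor simulator defaults at realistic values.

#: Daily-yield summary per 30-day DIM class: N, mean (kg), SD (kg).
REFERENCE_DIM_CLASS_STATS = pd.DataFrame(
    {
        "dim_lower": np.arange(5, 305, 30),
        "dim_upper": np.append(np.arange(35, 305, 30) - 1, 305),
        "n": [28704, 37991, 41787, 43506, 44033, 44781, 45873, 45688, 44373, 42831],
        "mean_kg": [23.7, 26.6, 26.5, 26.0, 25.1, 24.4, 23.7, 22.9, 22.0, 21.4],
        "sd_kg": [7.45, 7.79, 7.92, 7.89, 7.89, 7.93, 7.99, 8.04, 8.10, 8.20],
    }
)

#: Residual variances (kg^2) per DIM class under heterogeneous-residual
#: models of polynomial order 1-5, plus the printed overall means.
REFERENCE_RESIDUAL_VARIANCES = pd.DataFrame(
    {
        "dim_lower": np.arange(5, 305, 30),
        "dim_upper": np.append(np.arange(35, 305, 30) - 1, 305),
        "lp1": [29.20, 17.24, 14.33, 14.92, 15.34, 15.30, 14.06, 12.53, 11.60, 16.21],
        "lp2": [18.76, 15.29, 14.70, 14.12, 12.99, 12.54, 12.63, 12.75, 11.12, 10.38],
        "lp3": [13.95, 15.44, 13.05, 12.18, 12.45, 12.48, 11.57, 11.23, 10.97, 8.64],
        "lp4": [14.54, 14.04, 11.88, 12.23, 11.80, 11.39, 11.43, 11.15, 9.95, 9.57],
        "lp5": [15.32, 12.61, 11.90, 11.40, 11.33, 11.26, 10.54, 10.80, 9.64, 9.80],
    }
)

REFERENCE_RESIDUAL_VARIANCE_TOTALS = {
    "lp1": 16.07, "lp2": 13.53, "lp3": 12.20, "lp4": 11.80, "lp5": 11.46,
}


def reference_mean_curve() -> np.ndarray:
    """Smooth mean lactation curve (kg) for DIM 5..305.

    Monotone-cubic interpolation through the reference DIM-class means at
    their class midpoints, with gently extrapolated endpoints, reproducing
    the canonical rise to a peak near day 50 and slow decline afterwards.
    """
    s = REFERENCE_DIM_CLASS_STATS
    mids = (s["dim_lower"] + s["dim_upper"]) / 2.0
    x = np.concatenate([[5.0], mids, [305.0]])
    y = np.concatenate([[21.5], s["mean_kg"], [21.2]])
    return PchipInterpolator(x, y)(np.arange(5, 306))


_G_DIAG = np.array([20.0, 3.0, 1.5, 1.0, 0.6, 0.4])
_P_DIAG = np.array([34.0, 5.0, 2.5, 1.5, 0.9, 0.6])


def default_true_components(order: int = 3, residual: str = "heterogeneous") -> VarianceComponents:
    """Diagonal-dominant true G and P on a Legendre basis of the given order.

    The scale is chosen so daily h2 is roughly 0.25 mid-lactation and 0.30
    at the lactation edges, with repeatability 0.70-0.80.  The default
    residual profile is the reference order-3 DIM-class pattern (elevated in
    early lactation); ``residual="homogeneous"`` collapses it to its mean.
    """
    k = order + 1
    G = np.diag(_G_DIAG[:k].copy())
    P = np.diag(_P_DIAG[:k].copy())
    if k > 1:
        # mild negative intercept-slope covariance, as seen in lactation data
        G[0, 1] = G[1, 0] = -0.15 * np.sqrt(G[0, 0] * G[1, 1])
        P[0, 1] = P[1, 0] = -0.10 * np.sqrt(P[0, 0] * P[1, 1])
    v = REFERENCE_RESIDUAL_VARIANCES["lp3"].to_numpy(dtype=float)
    if residual == "homogeneous":
        return VarianceComponents(G=G, P=P, residual=float(v.mean()))
    return VarianceComponents(G=G, P=P, residual=v.copy())


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic herd.

    Defaults produce roughly 2,000 recorded cows — every non-founder female
    across two overlapping generations, so dam-daughter pairs both carry
    records — with about eight monthly tests each (~16,000 records) in eight
    herds over six calving years.
    """

    n_base_sires: int = 40
    n_base_dams: int = 335
    n_generations: int = 2
    daughters_per_dam: int = 2
    sires_per_generation: int = 40

    n_herds: int = 8
    first_year: int = 2010
    n_years: int = 6

    true_order: int = 3
    residual: str = "heterogeneous"     # shape of the true residual profile
    true_G: np.ndarray | None = None    # override the default truth
    true_P: np.ndarray | None = None
    true_residual: float | np.ndarray | None = None
    hys_sd: float = 2.0                 # SD of contemporary-group effects, kg
    age_effects: tuple = (0.0, 0.8, 1.4, 1.8)   # kg, by calving-age class
    age_range_months: tuple = (20, 38)

    tests_per_cow: tuple = (6, 10)      # inclusive range
    test_interval_days: int = 30
    interval_jitter_days: int = 3
    first_test_range: tuple = (5, 35)
    milk_min: float = 5.0
    milk_max: float = 80.0
    #: days after the last calving year's end at which the data are
    #: "extracted"; tests beyond this date do not exist yet, so recently
    #: calved cows have partial lactations, as in any real extract
    extraction_margin_days: int | None = 90
    seed: int = 20_201_105

    def true_components(self) -> VarianceComponents:
        base = default_true_components(self.true_order, self.residual)
        return VarianceComponents(
            G=base.G if self.true_G is None else np.asarray(self.true_G, float),
            P=base.P if self.true_P is None else np.asarray(self.true_P, float),
            residual=(
                base.residual if self.true_residual is None
                else (np.asarray(self.true_residual, float)
                      if np.ndim(self.true_residual) else float(self.true_residual))
            ),
        )


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator):
    """Discrete-generation pedigree under random mating, no selection.

    Each generation, every dam produces ``daughters_per_dam`` daughters and
    the population recruits ``sires_per_generation`` young sires, all from
    randomly drawn parents.  Returns ``(pedigree, cow_generation)`` where
    ``cow_generation`` maps every recorded cow — all non-founder females, as
    in a multi-year recording scheme with overlapping cohorts — to her
    generation number 1..n_generations.
    """
    rows = []
    males = [f"S{i + 1}" for i in range(config.n_base_sires)]
    females = [f"D{i + 1}" for i in range(config.n_base_dams)]
    for a in [*males, *females]:
        rows.append((a, "0", "0"))
    counter = 0
    cow_generation: dict[str, int] = {}
    for gen in range(1, config.n_generations + 1):
        new_f, new_m = [], []
        for dam in females:
            for _ in range(config.daughters_per_dam):
                counter += 1
                a = f"C{counter}"
                rows.append((a, str(rng.choice(males)), dam))
                new_f.append(a)
                cow_generation[a] = gen
        for _ in range(config.sires_per_generation):
            counter += 1
            a = f"C{counter}"
            rows.append((a, str(rng.choice(males)), str(rng.choice(females))))
            new_m.append(a)
        males, females = new_m, new_f
    ped = pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id"])
    return ped, cow_generation


def simulate_genetic_coefficients(
    ped: SortedPedigree, G: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Genetic regression coefficients with exact A (x) G covariance.

    Founders are drawn N(0, G); descendants are the parent average plus a
    Mendelian-sampling deviation N(0, d_i G), where d_i accounts for known
    parents and their inbreeding.
    """
    k = G.shape[0]
    L = np.linalg.cholesky(G)
    d = ped.mendelian_variances()
    a = np.zeros((len(ped), k))
    noise = rng.standard_normal((len(ped), k))
    for i in range(len(ped)):
        mean = np.zeros(k)
        if ped.sire[i] >= 0:
            mean += 0.5 * a[ped.sire[i]]
        if ped.dam[i] >= 0:
            mean += 0.5 * a[ped.dam[i]]
        a[i] = mean + np.sqrt(d[i]) * (L @ noise[i])
    return a


def simulate_records(
    ped: SortedPedigree,
    a: np.ndarray,
    recorded_cows: list | dict,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Test-day records for the recorded cows; returns (records, pe, n_truncated).

    ``recorded_cows`` may be a plain list (calving years drawn over the whole
    span) or a cow -> generation mapping, in which case each generation
    calves within its own block of consecutive years, like overlapping
    cohorts in a multi-year recording scheme.
    """
    comps = config.true_components()
    k = comps.G.shape[0]
    basis = LegendreBasis(config.true_order)
    B = basis.matrix()
    mean_curve = reference_mean_curve()
    v_class = comps.residual_by_class()
    Lp = np.linalg.cholesky(comps.P)
    idx = ped.index_of

    generation_of = recorded_cows if isinstance(recorded_cows, dict) else None
    cows = list(recorded_cows)
    n_gen = max(generation_of.values()) if generation_of else 1
    block = max(config.n_years // n_gen, 1)

    extraction_date = None
    if config.extraction_margin_days is not None:
        extraction_date = pd.Timestamp(
            year=config.first_year + config.n_years - 1, month=12, day=31
        ) + pd.Timedelta(days=config.extraction_margin_days)

    hys_effects: dict = {}
    rows = []
    pe_all = np.zeros((len(cows), k))
    n_truncated = 0
    for ci, cow in enumerate(cows):
        herd = int(rng.integers(1, config.n_herds + 1))
        if generation_of is None:
            year = int(rng.integers(config.first_year, config.first_year + config.n_years))
        else:
            g = generation_of[cow]
            lo = config.first_year + (g - 1) * block
            hi = (config.first_year + config.n_years
                  if g == n_gen else lo + block)
            year = int(rng.integers(lo, hi))
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        calving = pd.Timestamp(year=year, month=month, day=day)
        season = SEASON_OF_MONTH[month]
        key = (herd, year, season)
        if key not in hys_effects:
            hys_effects[key] = config.hys_sd * rng.standard_normal()
        age = int(rng.integers(config.age_range_months[0], config.age_range_months[1] + 1))
        age_class = min((max(age, 20) - 20) // 4, 3)
        pe = Lp @ rng.standard_normal(k)
        pe_all[ci] = pe
        n_tests = int(rng.integers(config.tests_per_cow[0], config.tests_per_cow[1] + 1))
        dim = int(rng.integers(config.first_test_range[0], config.first_test_range[1] + 1))
        a_cow = a[idx[cow]]
        for _ in range(n_tests):
            if dim > 305:
                break
            if extraction_date is not None and \
                    calving + pd.Timedelta(days=dim) > extraction_date:
                break
            z = B[dim - 5]
            cls = min((dim - 5) // 30, 9)
            e = np.sqrt(v_class[cls]) * rng.standard_normal()
            y = (
                mean_curve[dim - 5]
                + hys_effects[key]
                + config.age_effects[age_class]
                + z @ a_cow + z @ pe + e
            )
            if config.milk_min <= y <= config.milk_max:
                rows.append(
                    {
                        "cow_id": cow,
                        "herd_id": f"H{herd}",
                        "calving_date": calving,
                        "test_date": calving + pd.Timedelta(days=dim),
                        "dim": dim,
                        "milk_kg": round(float(y), 2),
                        "age_at_calving_months": age,
                    }
                )
            else:
                n_truncated += 1
            step = config.test_interval_days + int(
                rng.integers(-config.interval_jitter_days, config.interval_jitter_days + 1)
            )
            dim += max(step, 1)
    records = pd.DataFrame(rows)
    return records, pe_all, n_truncated


@dataclass
class SimulatedDataset:
    pedigree: pd.DataFrame
    records: pd.DataFrame
    sorted_pedigree: SortedPedigree
    recorded_cows: list
    true_components: VarianceComponents
    true_a: np.ndarray                  # pedigree order
    true_pe: np.ndarray                 # recorded_cows order
    true_ebv305: dict                   # animal id -> 305-d EBV
    n_truncated: int
    config: SimulationConfig


def generate_dataset(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    out_dir=None,
) -> SimulatedDataset:
    """Simulate pedigree + records (+ optionally write them with a truth file).

    The truth file records the true components and every animal's true
    305-day EBV computed with the same basis code the estimator uses, so
    recovery tests are definitionally consistent.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ped_df, cow_generation = simulate_pedigree(config, rng)
    recorded = list(cow_generation)
    sped = topological_sort(ped_df)
    comps = config.true_components()
    a = simulate_genetic_coefficients(sped, comps.G, rng)
    records, pe, n_trunc = simulate_records(sped, a, cow_generation, config, rng)
    basis = LegendreBasis(config.true_order)
    ebv = ebv_305(a, basis)
    true_ebv305 = {aid: float(e) for aid, e in zip(sped.ids, ebv)}
    ds = SimulatedDataset(
        pedigree=ped_df, records=records, sorted_pedigree=sped,
        recorded_cows=recorded, true_components=comps, true_a=a, true_pe=pe,
        true_ebv305=true_ebv305, n_truncated=n_trunc, config=config,
    )
    if out_dir is not None:
        _write_dataset(ds, out_dir)
    return ds


def _write_dataset(ds: SimulatedDataset, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.pedigree.to_csv(out / "pedigree.csv", index=False)
    write_records(ds.records, out / "records.csv")
    truth = {
        "true_order": ds.config.true_order,
        "G": ds.true_components.G.tolist(),
        "P": ds.true_components.P.tolist(),
        "residual": np.atleast_1d(ds.true_components.residual).tolist(),
        "n_truncated": ds.n_truncated,
    }
    (out / "truth_components.json").write_text(json.dumps(truth, indent=1))
    pd.DataFrame(
        {"animal_id": list(ds.true_ebv305), "true_ebv305": list(ds.true_ebv305.values())}
    ).to_csv(out / "truth_ebv.csv", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(ds.config).items()}
    (out / "simulation_config.json").write_text(
        json.dumps(cfg, indent=1, default=lambda o: np.asarray(o).tolist())
    )
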