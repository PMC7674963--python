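import numpy as np
import pandas as pd
import pytest

import rrtdm as r


def ped_df(rows):
    return pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id"])


@pytest.fixture(scope="session")
def small_dataset():
    """~400-cow simulated dataset with order-2 truth, shared across tests."""
    cfg = r.SimulationConfig(n_base_dams=67, true_order=2, seed=11)
    return r.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    return r.prepare(small_dataset.records, small_dataset.pedigree)


def random_pedigree(rng, n):
    """Random acyclic pedigree of n animals with some unknown parents."""
    rows = []
    for i in range(n):
        if i < 3 or rng.random() < 0.25:
            rows.append((f"a{i}", "0", "0"))
        else:
            s, d = rng.integers(0, i, 2)
            rows.append(
                (
                    f"a{i}",
                    f"a{s}" if rng.random() < 0.9 else "0",
                    f"a{d}" if rng.random() < 0.9 else "0",
                )
            )
    return ped_df(rows)
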