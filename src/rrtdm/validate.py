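"""Predictive-ability validation by the full-vs-reduced data design.

Breeding values estimated twice — once from all data, once after removing
the phenotypes of every cow calving in the most recent calendar year — are
compared by Pearson and Spearman correlation over the removed ("validation")
cows.  High correlations mean the model predicts future proofs well from
relatives alone; ranking the candidate models by these correlations is a
direct measure of predictive ability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ValidationSplit", "split_by_last_calving_year", "predictive_correlations"]


@dataclass
class ValidationSplit:
    full: pd.DataFrame
    reduced: pd.DataFrame
    validation_cows: list
    last_year: int


def split_by_last_calving_year(records: pd.DataFrame) -> ValidationSplit:
    """Remove all records of cows whose calving falls in the last calendar year.

    The rule is per cow: a cow calving in the last year loses every record,
    even tests dated after the year boundary.  The pedigree is untouched.
    """
    year = pd.to_datetime(records["calving_date"]).dt.year
    last = int(year.max())
    if int(year.min()) == last:
        raise ValueError("all cows calve in the same year; nothing to train on")
    val_cows = records.loc[year == last, "cow_id"].unique().tolist()
    reduced = records[~records["cow_id"].isin(val_cows)].reset_index(drop=True)
    return ValidationSplit(
        full=records, reduced=reduced, validation_cows=val_cows, last_year=last
    )


def predictive_correlations(ebv_full: dict, ebv_reduced: dict, animals) -> tuple:
    """(Pearson, Spearman) correlation of two EBV sets over given animals."""
    animals = list(animals)
    if len(animals) < 3:
        raise ValueError("need at least 3 animals to correlate")
    x = np.array([ebv_full[a] for a in animals], dtype=float)
    y = np.array([ebv_reduced[a] for a in animals], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("EBV set has zero variance over the validation animals")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman
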