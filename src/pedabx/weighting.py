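"""Post-stratification weights from census and sample composition.

Each child inherits the weight of its stratum (state x sex by default,
optionally refined by birth year): census population count divided by the
number of sampled children in the same stratum.  Weighted summaries then
estimate population quantities from the convenience sample.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STRATA = ("state", "sex")


def compute_weights(
    children: pd.DataFrame,
    census: pd.DataFrame,
    strata: tuple[str, ...] = DEFAULT_STRATA,
) -> pd.DataFrame:
    """One StratumWeight row per stratum present in the sample.

    Columns: the stratum fields, census_count, sample_count,
    weight = census_count / sample_count.  A sample stratum missing from the
    census is an error; census strata with no sampled children are dropped
    with a coverage warning.
    """
    extra = [c for c in strata if c not in census.columns and c != "birth_year"]
    if extra:
        raise ValueError(f"census table lacks stratum columns {extra}")
    sample = children.copy()
    if "birth_year" in strata and "birth_year" not in sample.columns:
        sample["birth_year"] = sample["birth_date"].dt.year

    counts = sample.groupby(list(strata), observed=True).size().rename("sample_count")
    cen = census.copy()
    if "birth_year" in strata and "birth_year" not in cen.columns:
        # census is age-aggregate: split population evenly across birth years
        years = sorted(sample["birth_year"].unique())
        cen = cen.loc[cen.index.repeat(len(years))].reset_index(drop=True)
        cen["birth_year"] = np.tile(years, len(census))
        cen["population_under5"] = cen["population_under5"] / len(years)
    cen_counts = cen.groupby(list(strata), observed=True)["population_under5"].sum()

    missing = counts.index.difference(cen_counts.index)
    if len(missing):
        raise ValueError(
            f"sample strata missing from census table: {list(missing[:5])}"
        )
    uncovered = cen_counts.index.difference(counts.index)
    if len(uncovered):
        warnings.warn(
            f"{len(uncovered)} census strata have no sampled children (coverage gap); "
            "they are excluded from the weight table"
        )

    out = pd.concat(
        [cen_counts.rename("census_count").loc[counts.index], counts], axis=1
    ).reset_index()
    out["weight"] = out["census_count"] / out["sample_count"]
    logger.info("computed %d stratum weights over %s", len(out), strata)
    return out


def attach_weights(
    children: pd.DataFrame,
    weights: pd.DataFrame,
    strata: tuple[str, ...] = DEFAULT_STRATA,
) -> pd.DataFrame:
    """Children with a ``weight`` column inherited from their stratum."""
    sample = children.copy()
    if "birth_year" in strata and "birth_year" not in sample.columns:
        sample["birth_year"] = sample["birth_date"].dt.year
    merged = sample.merge(weights[[*strata, "weight"]], on=list(strata), how="left")
    if merged["weight"].isna().any():
        raise ValueError("some children fall in strata without weights")
    return merged


def weighted_mean(values, weights) -> float:
    """Sum(w*x)/Sum(w); scale-invariant in the weights."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(values) == 0 or len(weights) == 0:
        raise ValueError("weighted_mean of empty input")
    if len(values) != len(weights):
        raise ValueError("values and weights must have equal length")
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    return float(weights @ values / weights.sum())


def weighted_proportion(flags, weights) -> float:
    """Weighted mean of 0/1 flags."""
    return weighted_mean(np.asarray(flags, dtype=float), weights)
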