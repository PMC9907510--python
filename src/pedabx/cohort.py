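"""Claims-table IO, validation, and cohort eligibility filters.

The analysis cohort is children born inside the configured birth window who
are continuously enrolled (no coverage gap, merged across spans) from birth
through day 1825 (age 5), with pharmacy rows restricted to a configured
antibiotic drug-class inclusion list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import HORIZON_DAYS

logger = logging.getLogger(__name__)

TABLE_FILES = {
    "enrollment": "enrollment.csv",
    "outpatient": "outpatient.csv",
    "pharmacy": "pharmacy.csv",
    "census": "census.csv",
}

DEFAULT_ANTIBIOTIC_CLASSES = ("penicillins", "cephalosporins", "macrolides",
                              "sulfonamides", "tetracyclines")


@dataclass
class ClaimsBundle:
    """The four input tables; dates held as pandas datetimes."""

    enrollment: pd.DataFrame
    outpatient: pd.DataFrame
    pharmacy: pd.DataFrame
    census: pd.DataFrame


def _parse_dates(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        if not pd.api.types.is_datetime64_any_dtype(df[c]):
            df[c] = pd.to_datetime(df[c], format="ISO8601")
    return df


def validate_bundle(bundle: ClaimsBundle) -> dict[str, int]:
    """Schema/referential checks; returns per-table row counts for the log."""
    enr, out, pha = bundle.enrollment, bundle.outpatient, bundle.pharmacy
    if (enr["span_start"] > enr["span_end"]).any():
        raise ValueError("enrollment: span_start after span_end")
    known = set(enr["child_id"])
    for name, df in (("outpatient", out), ("pharmacy", pha)):
        orphans = set(df["child_id"]) - known
        if orphans:
            raise ValueError(
                f"{name}: {len(orphans)} child_ids missing from enrollment, "
                f"e.g. {sorted(orphans)[:3]}"
            )
    dx_cols = [c for c in out.columns if c.startswith("dx")]
    if dx_cols:
        any_dx = np.zeros(len(out), dtype=bool)
        for c in dx_cols[1:]:
            any_dx |= out[c].fillna("").astype(str).str.len() > 0
        dx1_empty = out[dx_cols[0]].fillna("").astype(str).str.len() == 0
        bad = int((any_dx & dx1_empty).sum())
        if bad:
            raise ValueError(f"outpatient: {bad} rows with later dx fields but empty dx1")
    counts = {
        "enrollment": len(enr),
        "outpatient": len(out),
        "pharmacy": len(pha),
        "census": len(bundle.census),
    }
    logger.info("validated claims bundle: %s", counts)
    return counts


def read_bundle(directory: str | Path) -> ClaimsBundle:
    """Read the four CSV tables from a directory and validate them."""
    directory = Path(directory)
    enr = pd.read_csv(directory / TABLE_FILES["enrollment"], dtype={"child_id": str})
    out = pd.read_csv(
        directory / TABLE_FILES["outpatient"],
        dtype={"child_id": str, "dx1": str, "dx2": str, "dx3": str, "dx4": str},
        keep_default_na=False,
        na_values=[],
    )
    pha = pd.read_csv(directory / TABLE_FILES["pharmacy"], dtype={"child_id": str})
    cen = pd.read_csv(directory / TABLE_FILES["census"])
    enr = _parse_dates(enr, ["birth_date", "span_start", "span_end"])
    out = _parse_dates(out, ["service_date"])
    pha = _parse_dates(pha, ["fill_date"])
    bundle = ClaimsBundle(enrollment=enr, outpatient=out, pharmacy=pha, census=cen)
    validate_bundle(bundle)
    return bundle


def write_bundle(bundle, directory: str | Path) -> list[Path]:
    """Write the tables (plus ground truth, when present) as CSV; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fname in TABLE_FILES.items():
        df = getattr(bundle, name).copy()
        for c in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[c]):
                df[c] = df[c].dt.strftime("%Y-%m-%d")
        path = directory / fname
        df.to_csv(path, index=False)
        written.append(path)
    gt = getattr(bundle, "ground_truth", None)
    if gt is not None:
        path = directory / "ground_truth.csv"
        gt.to_csv(path, index=False)
        written.append(path)
    return written


def filter_continuously_enrolled(
    bundle: ClaimsBundle,
    birth_year_min: int,
    birth_year_max: int,
    horizon_days: int = HORIZON_DAYS,
    max_gap_days: int = 0,
) -> pd.Index:
    """Child ids whose birth year is in range and whose merged coverage spans
    contain [birth, birth + horizon_days] with gaps of at most ``max_gap_days``.

    Overlapping spans are merged silently; children with missing birth dates
    are excluded with a warning.
    """
    enr = bundle.enrollment
    missing = enr["birth_date"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} enrollment rows lack birth_date; excluded")
        enr = enr[~missing]

    birth = enr.groupby("child_id")["birth_date"].first()
    in_window = (birth.dt.year >= birth_year_min) & (birth.dt.year <= birth_year_max)

    spans = enr[["child_id", "span_start", "span_end"]].sort_values(
        ["child_id", "span_start"], kind="stable"
    )
    gap_tol = pd.Timedelta(days=max_gap_days + 1)  # adjacent days are continuous
    same_child = spans["child_id"].eq(spans["child_id"].shift())
    prev_end = spans.groupby("child_id")["span_end"].cummax().shift()
    new_block = ~(same_child & (spans["span_start"] <= prev_end + gap_tol))
    spans = spans.assign(block=new_block.cumsum())
    merged = spans.groupby(["child_id", "block"], sort=False).agg(
        start=("span_start", "min"), end=("span_end", "max")
    ).reset_index()

    merged = merged.merge(birth.rename("birth"), on="child_id")
    merged["target_end"] = merged["birth"] + pd.to_timedelta(horizon_days, unit="D")
    covered = merged[(merged["start"] <= merged["birth"]) & (merged["end"] >= merged["target_end"])]
    eligible = pd.Index(sorted(set(covered["child_id"]) & set(birth.index[in_window])),
                        name="child_id")
    logger.info(
        "continuous-enrollment filter: %d/%d children eligible", len(eligible), birth.size
    )
    return eligible


def filter_antibiotic_fills(
    pharmacy: pd.DataFrame, antibiotic_classes: tuple[str, ...] | list[str]
) -> pd.DataFrame:
    """Pharmacy rows whose drug_class is in the configured inclusion list."""
    if not len(antibiotic_classes):
        raise ValueError(
            "antibiotic class inclusion list is empty; this would silently zero the analysis"
        )
    keep = pharmacy["drug_class"].isin(list(antibiotic_classes))
    logger.info("antibiotic-class filter: kept %d/%d fills", int(keep.sum()), len(pharmacy))
    return pharmacy[keep].copy()
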