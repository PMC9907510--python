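"""Antibiotic course construction and fill-to-visit attribution.

A *course* is one dispensed antibiotic fill, after collapsing exact same-day
duplicates of the same drug class for the same child.  Each course is linked
to the child's most recent outpatient visit within a 7-day lookback window
(inclusive at both ends: service_date in [fill - 7 d, fill]); ties on the
most recent day resolve to the smallest claim_id.  A course is attributed to
a respiratory infection iff it is linked and the visit's first or second
diagnosis field maps to a respiratory CCS category; otherwise the
attribution is "other" (unlinked courses are always "other").
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import codemap as cm
from .config import HORIZON_DAYS

logger = logging.getLogger(__name__)

LOOKBACK_DAYS = 7

COURSE_COLUMNS = [
    "child_id", "fill_date", "age_days", "drug_class",
    "linked_claim_id", "attribution", "unlinked",
]


def build_courses(
    pharmacy: pd.DataFrame,
    enrollment: pd.DataFrame,
    course_collapse_days: int = 0,
) -> pd.DataFrame:
    """Provisional courses: one per antibiotic fill after same-day same-class dedup.

    Fills before birth or at/after day 1825 are excluded with a warning.
    ``course_collapse_days`` > 0 additionally collapses same-class refills
    within that many days of the previous retained fill (documented knob;
    default 0 keeps every distinct fill day).
    """
    birth = enrollment.groupby("child_id")["birth_date"].first()
    fills = pharmacy.merge(birth.rename("birth_date"), on="child_id", how="left")
    age = (fills["fill_date"] - fills["birth_date"]).dt.days
    bad = (age < 0) | (age >= HORIZON_DAYS)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} fills outside [birth, birth+{HORIZON_DAYS}) excluded"
        )
        fills = fills[~bad]
        age = age[~bad]
    fills = fills.assign(age_days=age.astype(int))
    fills = fills.sort_values(["child_id", "fill_date", "drug_class"], kind="stable")
    courses = fills.drop_duplicates(subset=["child_id", "fill_date", "drug_class"])

    if course_collapse_days > 0:
        keep_idx = []
        for (_cid, _cls), grp in courses.groupby(["child_id", "drug_class"], sort=False):
            last_kept = None
            for idx, a in zip(grp.index, grp["age_days"]):
                if last_kept is None or a - last_kept > course_collapse_days:
                    keep_idx.append(idx)
                    last_kept = a
        courses = courses.loc[sorted(keep_idx)]

    out = courses[["child_id", "fill_date", "age_days", "drug_class"]].reset_index(drop=True)
    logger.info("built %d courses from %d antibiotic fills", len(out), len(pharmacy))
    return out


def link_fill(fill_date, child_visits: pd.DataFrame):
    """Most recent visit claim_id with service_date in [fill-7 d, fill]; None if none.

    Reference implementation of the per-fill rule (the pipeline uses the
    vectorised ``link_courses``); ties on the day resolve to smallest claim_id.
    """
    fill_date = pd.Timestamp(fill_date)
    lo = fill_date - pd.Timedelta(days=LOOKBACK_DAYS)
    window = child_visits[
        (child_visits["service_date"] >= lo) & (child_visits["service_date"] <= fill_date)
    ]
    if not len(window):
        return None
    best_day = window["service_date"].max()
    on_day = window[window["service_date"] == best_day]
    return on_day["claim_id"].min()


def link_courses(courses: pd.DataFrame, outpatient: pd.DataFrame) -> pd.Series:
    """Vectorised most-recent-visit-within-7-days linkage for all courses.

    Returns a Series of linked claim_ids aligned to ``courses`` (NaN when no
    visit falls in the window).
    """
    if not len(courses) or not len(outpatient):
        return pd.Series(np.nan, index=courses.index, name="linked_claim_id")
    # one representative visit per (child, day): smallest claim_id (tie rule)
    visits = outpatient[["claim_id", "child_id", "service_date"]].sort_values(
        ["child_id", "service_date", "claim_id"], kind="stable"
    )
    visits = visits.drop_duplicates(subset=["child_id", "service_date"], keep="first")

    child_codes, uniques = pd.factorize(
        pd.concat([visits["child_id"], courses["child_id"]]), sort=True
    )
    v_child = child_codes[: len(visits)].astype(np.int64)
    c_child = child_codes[len(visits):].astype(np.int64)
    v_day = visits["service_date"].values.astype("datetime64[D]").astype(np.int64)
    c_day = courses["fill_date"].values.astype("datetime64[D]").astype(np.int64)

    span = max(int(v_day.max(initial=0)), int(c_day.max(initial=0))) + 2
    v_key = v_child * span + v_day
    c_key = c_child * span + c_day
    order = np.argsort(v_key, kind="stable")
    v_key = v_key[order]
    v_ids = visits["claim_id"].to_numpy()[order]
    v_child_sorted = v_child[order]
    v_day_sorted = v_day[order]

    pos = np.searchsorted(v_key, c_key, side="right") - 1
    valid = pos >= 0
    linked = np.full(len(courses), np.nan)
    p = np.clip(pos, 0, None)
    same_child = v_child_sorted[p] == c_child
    in_window = (c_day - v_day_sorted[p] <= LOOKBACK_DAYS) & (c_day - v_day_sorted[p] >= 0)
    ok = valid & same_child & in_window
    linked[ok] = v_ids[p[ok]]
    return pd.Series(linked, index=courses.index, name="linked_claim_id")


def classify_course(course: dict | pd.Series, linked_visit, codes: cm.CodeMap) -> dict:
    """One CourseRecord: respiratory iff linked and dx1 or dx2 maps to a
    respiratory CCS; unlinked courses are attribution "other"."""
    rec = dict(course)
    if linked_visit is None:
        rec.update(linked_claim_id=None, attribution="other", unlinked=True)
        return rec
    version = int(linked_visit["icd_version"])
    resp = any(
        cm.is_respiratory(cm.map_icd_to_ccs(linked_visit.get(f), version, codes), codes)
        for f in ("dx1", "dx2")
    )
    rec.update(
        linked_claim_id=linked_visit["claim_id"],
        attribution="respiratory" if resp else "other",
        unlinked=False,
    )
    return rec


def classify_courses(
    courses: pd.DataFrame, outpatient: pd.DataFrame, codes: cm.CodeMap
) -> pd.DataFrame:
    """Link and classify every course; returns the full course table.

    Unmappable diagnosis codes are treated as non-respiratory and counted in
    a log summary.
    """
    courses = courses.copy()
    courses["linked_claim_id"] = link_courses(courses, outpatient)

    visits = outpatient.set_index("claim_id")
    linked = courses["linked_claim_id"].dropna().astype(np.int64)
    sub = visits.loc[linked.unique(), ["dx1", "dx2", "icd_version"]]

    unmapped = 0
    resp_by_claim: dict[int, bool] = {}
    for claim_id, dx1, dx2, ver in sub.itertuples():
        flags = []
        for code in (dx1, dx2):
            if code is None or (isinstance(code, float) and pd.isna(code)) or str(code) == "":
                continue
            ccs = cm.map_icd_to_ccs(code, int(ver), codes)
            if ccs is None:
                unmapped += 1
            flags.append(cm.is_respiratory(ccs, codes))
        resp_by_claim[claim_id] = any(flags)
    if unmapped:
        logger.info("%d dx1/dx2 codes had no CCS mapping; treated as non-respiratory", unmapped)

    is_resp = courses["linked_claim_id"].map(
        lambda c: resp_by_claim.get(int(c), False) if pd.notna(c) else False
    )
    courses["attribution"] = np.where(is_resp, "respiratory", "other")
    courses["unlinked"] = courses["linked_claim_id"].isna()
    return courses[COURSE_COLUMNS]
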