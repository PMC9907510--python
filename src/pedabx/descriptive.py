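"""Cumulative dispensing statistics.

All estimators take the course table, the weighted children table, and an
attribution filter ("all" | "respiratory" | "other").  Age is exact in days
on the grid 0..1825, so the respiratory and other curves sum to the
all-cause curve at every grid point by construction.

Confidence conventions: curves carry normal-approximation CIs for a weighted
mean (matching a two-tailed t test at cohort sizes), while age-band rates
carry exact Poisson CIs from chi-square quantiles, scaled from the
unweighted count to the weighted rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import DAYS_PER_YEAR, HORIZON_DAYS

logger = logging.getLogger(__name__)

ATTRIBUTIONS = ("all", "respiratory", "other")

Z975 = stats.norm.ppf(0.975)


@dataclass
class CurveEstimate:
    """Age-indexed estimate with CI bands on the day grid 0..1825."""

    age_days: np.ndarray
    estimate: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_children: int
    weighted: bool
    curve_id: str = ""

    def at(self, day: int) -> float:
        return float(self.estimate[int(day)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "curve_id": self.curve_id,
                "age_days": self.age_days,
                "estimate": self.estimate,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


@dataclass
class ShareResult:
    """Top-q share of all courses, with fractional boundary allocation."""

    q: float
    threshold_count: int
    boundary_fraction: float
    share: float


def _filter_courses(courses: pd.DataFrame, attribution_filter: str) -> pd.DataFrame:
    if attribution_filter not in ATTRIBUTIONS:
        raise ValueError(f"attribution_filter must be one of {ATTRIBUTIONS}")
    if attribution_filter == "all":
        return courses
    return courses[courses["attribution"] == attribution_filter]


def _weights_of(children: pd.DataFrame) -> np.ndarray:
    if "weight" in children.columns:
        return children["weight"].to_numpy(dtype=float)
    return np.ones(len(children))


def per_child_counts(
    courses: pd.DataFrame,
    children: pd.DataFrame,
    attribution_filter: str = "all",
    max_age_days: int = HORIZON_DAYS,
) -> pd.Series:
    """Courses per child with age_days <= max_age_days (0 for course-free children)."""
    sub = _filter_courses(courses, attribution_filter)
    sub = sub[sub["age_days"] <= max_age_days]
    counts = sub.groupby("child_id").size()
    return counts.reindex(children["child_id"], fill_value=0)


def cumulative_course_curve(
    courses: pd.DataFrame,
    children: pd.DataFrame,
    attribution_filter: str = "all",
) -> CurveEstimate:
    """Weighted mean cumulative courses per child at each age day.

    At day a the estimate is sum_i w_i * N_i(a) / sum_i w_i with N_i(a) the
    child's courses dispensed at age <= a; the CI is the normal-approximation
    band for a weighted mean, se^2 = sum w_i^2 (N_i - mean)^2 / (sum w)^2.
    Running moments are accumulated per event day, so the cost is
    O(courses + grid) rather than O(children x grid).
    """
    if not len(children):
        raise ValueError("empty cohort")
    sub = _filter_courses(courses, attribution_filter)
    w = _weights_of(children)
    W = w.sum()
    W2 = (w**2).sum()
    child_pos = pd.Series(np.arange(len(children)), index=children["child_id"])

    grid = np.arange(HORIZON_DAYS + 1)
    dS1 = np.zeros(HORIZON_DAYS + 1)  # increments of sum w N
    dS2 = np.zeros(HORIZON_DAYS + 1)  # increments of sum w N^2
    dT1 = np.zeros(HORIZON_DAYS + 1)  # increments of sum w^2 N
    dT2 = np.zeros(HORIZON_DAYS + 1)  # increments of sum w^2 N^2

    if len(sub):
        pos = child_pos.loc[sub["child_id"]].to_numpy()
        age = sub["age_days"].to_numpy()
        order = np.argsort(age, kind="stable")
        pos, age = pos[order], age[order]
        # per-child running count n before this event; N^2 increment is 2n+1
        running = np.zeros(len(children), dtype=np.int64)
        wi = w[pos]
        n_before = np.empty(len(pos), dtype=np.int64)
        for j, p in enumerate(pos):  # events already in age order
            n_before[j] = running[p]
            running[p] += 1
        inc2 = 2 * n_before + 1
        np.add.at(dS1, age, wi)
        np.add.at(dS2, age, wi * inc2)
        np.add.at(dT1, age, wi**2)
        np.add.at(dT2, age, wi**2 * inc2)

    S1, S2, T1, T2 = dS1.cumsum(), dS2.cumsum(), dT1.cumsum(), dT2.cumsum()
    mean = S1 / W
    # sum w^2 (N - mean)^2 = T2 - 2 mean T1 + mean^2 W2
    se = np.sqrt(np.maximum(T2 - 2 * mean * T1 + mean**2 * W2, 0.0)) / W
    return CurveEstimate(
        age_days=grid,
        estimate=mean,
        ci_lo=mean - Z975 * se,
        ci_hi=mean + Z975 * se,
        n_children=len(children),
        weighted="weight" in children.columns,
        curve_id=f"cumulative_{attribution_filter}",
    )


def first_course_curve(
    courses: pd.DataFrame,
    children: pd.DataFrame,
    attribution_filter: str = "all",
) -> CurveEstimate:
    """Weighted proportion of children whose first qualifying course is <= a."""
    if not len(children):
        raise ValueError("empty cohort")
    sub = _filter_courses(courses, attribution_filter)
    w = _weights_of(children)
    W = w.sum()
    W2 = (w**2).sum()
    first = sub.groupby("child_id")["age_days"].min()
    first = first.reindex(children["child_id"])

    grid = np.arange(HORIZON_DAYS + 1)
    dS1 = np.zeros(HORIZON_DAYS + 1)
    dT1 = np.zeros(HORIZON_DAYS + 1)
    has = first.notna().to_numpy()
    ages = first.to_numpy()[has].astype(int)
    np.add.at(dS1, ages, w[has])
    np.add.at(dT1, ages, w[has] ** 2)
    S1, T1 = dS1.cumsum(), dT1.cumsum()
    p = S1 / W
    # x binary: sum w^2 (x-p)^2 = T1 (1 - 2p) + p^2 W2
    se = np.sqrt(np.maximum(T1 * (1 - 2 * p) + p**2 * W2, 0.0)) / W
    return CurveEstimate(
        age_days=grid,
        estimate=p,
        ci_lo=np.maximum(p - Z975 * se, 0.0),
        ci_hi=np.minimum(p + Z975 * se, 1.0),
        n_children=len(children),
        weighted="weight" in children.columns,
        curve_id=f"first_course_{attribution_filter}",
    )


def poisson_exact_ci(count: int, person_time: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) CI for a Poisson rate from chi-square quantiles.

    lo = chi2(alpha/2, 2x)/2/PT (0 when x = 0); hi = chi2(1-alpha/2, 2x+2)/2/PT.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if count < 0 or int(count) != count:
        raise ValueError("count must be a nonnegative integer")
    if person_time <= 0:
        raise ValueError("person_time must be positive")
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2 / person_time
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2 / person_time
    return lo, hi


def age_band_rate(
    courses: pd.DataFrame,
    children: pd.DataFrame,
    band: tuple[int, int],
    attribution_filter: str = "all",
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Weighted courses/child/year in an age band, with an exact Poisson CI.

    Rate = weighted courses with age in [start, end) divided by weighted
    person-years (every cohort child contributes the full band, being
    continuously enrolled).  The CI is the exact Poisson interval on the
    unweighted count, scaled to the weighted rate.
    """
    start, end = band
    if not (0 <= start < end <= HORIZON_DAYS):
        raise ValueError(f"band must lie within [0, {HORIZON_DAYS})")
    sub = _filter_courses(courses, attribution_filter)
    in_band = sub[(sub["age_days"] >= start) & (sub["age_days"] < end)]
    w = _weights_of(children)
    child_w = pd.Series(w, index=children["child_id"])
    py_per_child = (end - start) / DAYS_PER_YEAR
    pt_weighted = float(w.sum() * py_per_child)
    pt_unweighted = float(len(children) * py_per_child)
    if pt_weighted <= 0:
        raise ValueError("zero person-time in band")
    count = len(in_band)
    rate_w = float(child_w.loc[in_band["child_id"]].sum()) / pt_weighted
    rate_u = count / pt_unweighted
    lo_u, hi_u = poisson_exact_ci(count, pt_unweighted, alpha)
    scale = rate_w / rate_u if rate_u > 0 else 1.0
    return rate_w, (lo_u * scale, hi_u * scale)


def top_share(per_child: pd.Series | np.ndarray, weights=None, q: float = 0.20) -> ShareResult:
    """Share of all courses received by the top-q (weight) tail of recipients.

    Children are ranked by count descending; weight is accumulated to
    q * sum(w), splitting the boundary child's weight fractionally so the
    share does not depend on tie order.
    """
    counts = np.asarray(per_child, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    w = np.ones(len(counts)) if weights is None else np.asarray(weights, dtype=float)
    total_courses = float(w @ counts)
    if total_courses <= 0:
        raise ValueError("total courses is zero; top share undefined")
    order = np.argsort(-counts, kind="stable")
    c, ww = counts[order], w[order]
    target = q * ww.sum()
    cumw = np.cumsum(ww)
    i = int(np.searchsorted(cumw, target))
    head = float(ww[:i] @ c[:i])
    below = float(cumw[i - 1]) if i > 0 else 0.0
    phi = (target - below) / ww[i] if i < len(ww) else 0.0
    share = (head + (phi * ww[i] * c[i] if i < len(ww) else 0.0)) / total_courses
    return ShareResult(
        q=q,
        threshold_count=int(c[i]) if i < len(c) else int(c[-1]),
        boundary_fraction=float(phi),
        share=float(share),
    )


def count_histogram(per_child: pd.Series | np.ndarray, weights=None) -> pd.Series:
    """Weighted frequency of each per-child count value (sums to sum of weights)."""
    counts = np.asarray(per_child)
    w = np.ones(len(counts)) if weights is None else np.asarray(weights, dtype=float)
    df = pd.DataFrame({"count": counts.astype(int), "w": w})
    return df.groupby("count")["w"].sum().rename("frequency")


@dataclass
class SubgroupSummary:
    """Flagged-vs-unflagged comparison for a chronic-condition set."""

    condition_set: tuple[str, ...]
    n_flagged: int
    n_unflagged: int
    mean_flagged: float
    mean_unflagged: float
    mean_ci_flagged: tuple[float, float]
    mean_ci_unflagged: tuple[float, float]
    prop_flagged: float
    prop_unflagged: float
    curves: dict[str, CurveEstimate] = field(default_factory=dict)


def subgroup_summary(
    children: pd.DataFrame,
    condition_flags: pd.DataFrame,
    condition_set: tuple[str, ...] | list[str],
    courses: pd.DataFrame,
) -> SubgroupSummary:
    """Cumulative curves and age-5 scalars for children with >= 1 condition in
    ``condition_set`` vs those with none.

    ``condition_flags`` is the boolean child x body-system matrix (claims-
    derived or ground truth), indexed by child_id.
    """
    condition_set = tuple(condition_set)
    missing = [c for c in condition_set if c not in condition_flags.columns]
    if missing:
        raise ValueError(f"unknown body systems: {missing}")
    flags = condition_flags.loc[children["child_id"], list(condition_set)]
    flagged_mask = flags.any(axis=1).to_numpy() if condition_set else np.zeros(len(children), bool)

    groups = {}
    for name, mask in (("flagged", flagged_mask), ("unflagged", ~flagged_mask)):
        grp = children[mask]
        if not len(grp):
            raise ValueError(f"subgroup {name!r} for {condition_set} is empty")
        grp_courses = courses[courses["child_id"].isin(set(grp["child_id"]))]
        cum = cumulative_course_curve(grp_courses, grp)
        first = first_course_curve(grp_courses, grp)
        cum.curve_id = f"cumulative_{name}"
        first.curve_id = f"first_course_{name}"
        groups[name] = (grp, cum, first)

    (gf, cumf, firstf), (gu, cumu, firstu) = groups["flagged"], groups["unflagged"]
    day = HORIZON_DAYS
    return SubgroupSummary(
        condition_set=condition_set,
        n_flagged=len(gf),
        n_unflagged=len(gu),
        mean_flagged=cumf.at(day),
        mean_unflagged=cumu.at(day),
        mean_ci_flagged=(float(cumf.ci_lo[day]), float(cumf.ci_hi[day])),
        mean_ci_unflagged=(float(cumu.ci_lo[day]), float(cumu.ci_hi[day])),
        prop_flagged=firstf.at(day),
        prop_unflagged=firstu.at(day),
        curves={
            "cumulative_flagged": cumf,
            "cumulative_unflagged": cumu,
            "first_course_flagged": firstf,
            "first_course_unflagged": firstu,
        },
    )
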