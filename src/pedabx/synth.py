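"""Synthetic pediatric claims generator.

Emulates a commercial insurance claims extract for a birth cohort followed from
birth (day 0) to age 5 (day 1825): enrollment spans, outpatient claims with
2-4 ICD diagnosis fields, pharmacy fills, and a state x sex census table,
plus a ground-truth course table for recovery tests.

The dispensing model: child i's antibiotic courses follow a
piecewise-constant Poisson process on age with intensity
``r(a) * lambda_i * M_i / Z``, where ``r(a)`` is the configured age-band
rate schedule, ``lambda_i ~ Gamma(shape k, mean 1)`` is the child's frailty,
``M_i`` is the product of rate multipliers of the child's chronic
conditions, and ``Z = E[lambda * M]`` (computed analytically from the
config) keeps the population-marginal band rates equal to ``r(a)``.  Each
course is respiratory-attributed i.i.d. with probability ``p_respiratory``,
encoded at emission as a respiratory ICD code in diagnosis field 1 or 2 of
the linked visit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import codemap as cm
from .config import DAYS_PER_YEAR, HORIZON_DAYS, GeneratorConfig
from .mixture import MixtureModel, nb_zero_prob

logger = logging.getLogger(__name__)

__all__ = [
    "calibrate_frailty_shape",
    "calibrate_default_config",
    "mixture_model",
    "sample_children",
    "sample_course_events",
    "emit_claims",
    "simulate",
]

# stage labels for derived RNG streams
_STAGE_CHILDREN, _STAGE_EVENTS, _STAGE_CLAIMS = 1, 2, 3


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage)])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_frailty_shape(total_mean: float, target_zero_prob: float) -> float:
    """Gamma shape k solving ``(k/(k+mu))**k = P0`` by bisection.

    ``(k/(k+mu))**k`` is the zero-class probability of a gamma(k, mean 1)
    mixed Poisson with mean mu; it decreases from 1 (k -> 0) to exp(-mu)
    (k -> inf), so any target strictly inside (exp(-mu), 1) has a unique root.
    """
    if total_mean <= 0:
        raise ValueError("total_mean must be positive")
    lo_bound = float(np.exp(-total_mean))
    if not lo_bound < target_zero_prob < 1.0:
        raise ValueError(
            f"target zero-probability {target_zero_prob} outside the attainable "
            f"open interval (exp(-mu), 1) = ({lo_bound:.6g}, 1); the Poisson "
            "limit is reached only as shape -> infinity"
        )

    def f(k: float) -> float:
        return nb_zero_prob(total_mean, k) - target_zero_prob

    lo, hi = 1e-8, 1.0
    while f(hi) > 0:  # zero-prob still above target: increase k
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("no finite shape reaches the requested zero-probability")
    # bisection to |f| < 1e-10
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < 1e-10:
            return mid
        if fm > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mixture_model(config: GeneratorConfig) -> MixtureModel:
    """Analytic count mixture implied by a config (conditions with multiplier != 1).

    Enumerates condition profiles over the systems whose multiplier differs
    from 1 (independent draws), which keeps the component count 2**s small.
    """
    special = [
        (s, config.condition_prevalences.get(s, 0.0), m)
        for s, m in config.condition_multipliers.items()
        if m != 1.0 and config.condition_prevalences.get(s, 0.0) > 0
    ]
    if len(special) > 12:
        raise ValueError("too many non-unit multipliers to enumerate analytically")
    weights = [1.0]
    mults = [1.0]
    for _s, p, m in special:
        weights = [w * (1 - p) for w in weights] + [w * p for w in weights]
        mults = mults + [mu * m for mu in mults]
    return MixtureModel(
        mu=config.total_mean_courses,
        shape=config.frailty_shape,
        weights=tuple(weights),
        multipliers=tuple(mults),
    )


def calibrate_default_config(
    base: GeneratorConfig,
    target_zero_prob: float,
    target_top_share: float,
    free_system: str = "pulmonary_respiratory",
    q: float = 0.20,
) -> GeneratorConfig:
    """Jointly solve (frailty_shape, free multiplier) against two targets.

    Fixes the free system's prevalence at its configured value and finds the
    (shape k, multiplier m) pair at which the analytic two-group NB mixture
    attains the requested zero-class probability and top-``q`` share of
    courses.  Solved on the analytic mixture (pmf recursion + fractional
    tail sums), never by simulation.  Raises if the share target lies outside
    the frontier attainable at the zero-probability target.
    """
    mu = base.total_mean_courses
    prevalence = base.condition_prevalences.get(free_system, 0.0)
    if prevalence <= 0:
        raise ValueError(f"free system {free_system!r} needs positive prevalence")
    other_special = [
        s
        for s, m in base.condition_multipliers.items()
        if m != 1.0 and s != free_system
    ]
    if other_special:
        raise ValueError(
            f"calibration expects a single free multiplier; also non-unit: {other_special}"
        )

    def zero_floor(m: float) -> float:
        """k -> inf (Poisson) limit of the mixture zero-class probability."""
        z = prevalence * m + (1 - prevalence)
        return prevalence * np.exp(-mu * m / z) + (1 - prevalence) * np.exp(-mu / z)

    def shape_for(m: float) -> float:
        def g(k: float) -> float:
            model = _two_group(mu, k, prevalence, m)
            return model.zero_prob() - target_zero_prob
        return optimize.brentq(g, 1e-6, 1e4, xtol=1e-13, rtol=8.9e-16)

    def share_at(m: float) -> tuple[float, float]:
        k = shape_for(m)
        return _two_group(mu, k, prevalence, m).top_share(q), k

    # frontier scan over the multiplier box for root bracketing / error report;
    # multipliers whose Poisson-limit zero probability already exceeds the
    # target admit no shape and are excluded from the frontier
    m_box = np.concatenate([np.geomspace(0.05, 1.0, 8), np.geomspace(1.0, 60.0, 16)])
    m_grid = np.array([m for m in m_box if zero_floor(m) < target_zero_prob])
    if not len(m_grid):
        raise ValueError(
            f"zero-probability target {target_zero_prob} unattainable for any "
            f"multiplier in [{m_box[0]:.2g}, {m_box[-1]:.2g}]"
        )
    shares = np.array([share_at(m)[0] for m in m_grid])
    if not shares.min() - 1e-9 <= target_top_share <= shares.max() + 1e-9:
        raise ValueError(
            f"top-share target {target_top_share} unattainable at zero-probability "
            f"{target_zero_prob}: attainable frontier is "
            f"[{shares.min():.4f}, {shares.max():.4f}] for multipliers in "
            f"[{m_grid[0]:.2g}, {m_grid[-1]:.2g}]"
        )
    # the share-vs-multiplier curve is U-shaped around m = 1 (both protective
    # and aggravating multipliers add heterogeneity), so the target can admit
    # two roots; solve every bracket and keep the multiplier closest to 1
    diff = shares - target_top_share
    roots = []
    for idx in np.nonzero(np.diff(np.signbit(diff)))[0]:
        roots.append(
            optimize.brentq(
                lambda m: share_at(m)[0] - target_top_share,
                m_grid[idx],
                m_grid[idx + 1],
                xtol=1e-12,
            )
        )
    if abs(diff).min() < 1e-9:  # a grid point (e.g. m = 1 exactly) is a root
        roots.append(float(m_grid[int(abs(diff).argmin())]))
    m_star = min(roots, key=lambda m: abs(np.log(m)))
    k_star = shape_for(m_star)

    model = _two_group(mu, k_star, prevalence, m_star)
    res_zero = abs(model.zero_prob() - target_zero_prob)
    res_share = abs(model.top_share(q) - target_top_share)
    if max(res_zero, res_share) > 1e-6:
        raise RuntimeError(
            f"calibration residuals too large: zero {res_zero:.2e}, share {res_share:.2e}"
        )

    d = base.to_dict()
    d["frailty_shape"] = k_star
    d["condition_multipliers"] = dict(base.condition_multipliers)
    d["condition_multipliers"][free_system] = m_star
    return GeneratorConfig.from_dict(d)


def _two_group(mu: float, shape: float, prevalence: float, multiplier: float) -> MixtureModel:
    return MixtureModel(
        mu=mu,
        shape=shape,
        weights=(prevalence, 1.0 - prevalence),
        multipliers=(multiplier, 1.0),
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_children(config: GeneratorConfig, rng_seed: int | None = None) -> pd.DataFrame:
    """Sample the cohort: one row per child.

    Columns: child_id, sex, state, msa, birth_date, frailty, plus one boolean
    ``cond_<system>`` column per PMCA body system (independent Bernoulli
    draws at the configured prevalences).  Deterministic given (config, seed).
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = _rng(seed, _STAGE_CHILDREN)
    n = config.n_children

    child_id = np.array([f"C{i:07d}" for i in range(n)])
    sexes = np.array(list(config.sex_probs))
    sex = sexes[rng.choice(len(sexes), size=n, p=list(config.sex_probs.values()))]
    states = np.array(list(config.state_probs))
    state = states[rng.choice(len(states), size=n, p=list(config.state_probs.values()))]
    msa = np.char.add(state.astype(str), np.char.add("_MSA", rng.integers(1, 4, n).astype(str)))

    y0, y1 = config.birth_year_range
    year = rng.integers(y0, y1 + 1, size=n)
    day_of_year = rng.integers(0, 365, size=n)
    birth = pd.to_datetime(
        {"year": year, "month": 1, "day": 1}
    ) + pd.to_timedelta(day_of_year, unit="D")

    frailty = rng.gamma(shape=config.frailty_shape, scale=1.0 / config.frailty_shape, size=n)

    df = pd.DataFrame(
        {
            "child_id": child_id,
            "sex": sex,
            "state": state,
            "msa": msa,
            "birth_date": birth,
            "frailty": frailty,
        }
    )
    for system in cm.BODY_SYSTEMS:
        p = config.condition_prevalences.get(system, 0.0)
        df[f"cond_{system}"] = rng.random(n) < p
    return df


def child_multipliers(children: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Per-child product M_i of condition rate multipliers."""
    m = np.ones(len(children))
    for system in cm.BODY_SYSTEMS:
        mult = config.condition_multipliers.get(system, 1.0)
        if mult != 1.0:
            flags = children[f"cond_{system}"].to_numpy()
            m = np.where(flags, m * mult, m)
    return m


def sample_course_events(
    children: pd.DataFrame, config: GeneratorConfig, rng_seed: int | None = None
) -> pd.DataFrame:
    """Ground-truth course events for each child.

    Piecewise-constant Poisson process with per-child intensity
    ``r(a) * frailty * M / Z``; returns columns child_id, event_age_days,
    is_respiratory, visit_emitted, sorted by (child, age).
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = _rng(seed, _STAGE_EVENTS)
    lam = children["frailty"].to_numpy() * child_multipliers(children, config) / config.z_norm

    parts = []
    for start, end, rate in config.age_band_rates:
        if rate == 0:
            continue
        mean = rate * (end - start) / DAYS_PER_YEAR * lam
        counts = rng.poisson(mean)
        total = int(counts.sum())
        if total == 0:
            continue
        idx = np.repeat(np.arange(len(children)), counts)
        ages = rng.integers(start, end, size=total)
        parts.append(
            pd.DataFrame(
                {
                    "child_id": children["child_id"].to_numpy()[idx],
                    "event_age_days": ages,
                }
            )
        )
    if not parts:
        events = pd.DataFrame(
            columns=["child_id", "event_age_days", "is_respiratory", "visit_emitted"]
        ).astype({"event_age_days": int, "is_respiratory": bool, "visit_emitted": bool})
        return events
    events = pd.concat(parts, ignore_index=True)
    events["is_respiratory"] = rng.random(len(events)) < config.p_respiratory
    events["visit_emitted"] = rng.random(len(events)) >= config.unlinked_fill_prob
    events = events.sort_values(["child_id", "event_age_days"], kind="stable").reset_index(
        drop=True
    )
    return events


# ---------------------------------------------------------------------------
# claims emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """The four analysis input tables plus the generator's ground truth."""

    enrollment: pd.DataFrame
    outpatient: pd.DataFrame
    pharmacy: pd.DataFrame
    census: pd.DataFrame
    ground_truth: pd.DataFrame
    children: pd.DataFrame | None = None


def _code_pools(codes: cm.CodeMap) -> dict:
    """Partition fixture ICD codes into respiratory / acute non-respiratory pools
    per ICD version, excluding any code that would PMCA-match a body system."""
    pools: dict = {(v, True): [] for v in (9, 10)}
    pools.update({(v, False): [] for v in (9, 10)})
    for (code, version), ccs in codes.ccs_entries.items():
        if codes.pmca_systems(code, version):
            continue  # chronic codes never used for acute visits
        pools[(version, ccs in codes.respiratory_ccs)].append(code)
    for key, vals in pools.items():
        if not vals:
            raise ValueError(f"fixture crosswalk lacks codes for pool {key}")
        pools[key] = np.array(sorted(vals))
    return pools


def _chronic_code_pools(codes: cm.CodeMap) -> dict:
    """One concrete ICD code per (version, body system), built from PMCA prefixes."""
    out: dict[tuple[int, str], str] = {}
    for prefix, version, system in codes.pmca_entries:
        out.setdefault((version, system), prefix + "0")
    return out


def _icd_version_for(service_dates: pd.Series) -> np.ndarray:
    """ICD-9 before calendar year 2015, ICD-10 after (the coding transition)."""
    return np.where(service_dates.dt.year < 2015, 9, 10)


def emit_claims(
    children: pd.DataFrame,
    events: pd.DataFrame,
    config: GeneratorConfig,
    rng_seed: int | None = None,
    codes: cm.CodeMap | None = None,
) -> SyntheticBundle:
    """Encode ground-truth events into the four claims tables.

    Per event with ``visit_emitted``: one outpatient claim on the event day —
    respiratory events carry a respiratory ICD code in dx1 or dx2 (position
    random) and acute non-respiratory codes elsewhere — and one pharmacy
    fill at event day + lag (lag ~ fill_lag_probs on 0..7 d).  Events without
    a visit emit the fill only.  Decoy visits (no fill, non-respiratory
    acute codes) are added at ``decoy_visit_rate``; each chronic condition a
    child holds emits two visits carrying a matching PMCA code so the
    condition is recoverable from claims; non-antibiotic fills are added at
    ``nonabx_fill_rate``.  Enrollment spans cover birth..birth+1825 for all.
    """
    seed = config.seed if rng_seed is None else rng_seed
    rng = _rng(seed, _STAGE_CLAIMS)
    codes = codes or cm.load_crosswalk()
    pools = _code_pools(codes)
    chronic = _chronic_code_pools(codes)

    unknown = set(events["child_id"]) - set(children["child_id"])
    if unknown:
        raise ValueError(f"events reference unknown children, e.g. {sorted(unknown)[:3]}")

    birth_by_child = children.set_index("child_id")["birth_date"]

    # ---- outpatient: event visits -------------------------------------
    visit_rows = []
    ev = events[events["visit_emitted"]].reset_index(drop=True)
    ev_dates = birth_by_child.loc[ev["child_id"]].reset_index(drop=True) + pd.to_timedelta(
        ev["event_age_days"], unit="D"
    )
    ev_ver = _icd_version_for(ev_dates)
    n_ev = len(ev)
    resp_pos2 = rng.random(n_ev) < 0.5  # respiratory code in dx2 instead of dx1
    has_dx2 = rng.random(n_ev) < 0.6
    has_dx34 = rng.random((n_ev, 2)) < 0.25

    def draw(pool_key, size):
        pool = pools[pool_key]
        return pool[rng.integers(0, len(pool), size=size)]

    dx1 = np.empty(n_ev, dtype=object)
    dx2 = np.full(n_ev, "", dtype=object)
    for version in (9, 10):
        sel = ev_ver == version
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        resp_codes = draw((version, True), n_sel)
        other_codes = draw((version, False), n_sel)
        other2 = draw((version, False), n_sel)
        is_resp = ev["is_respiratory"].to_numpy()[sel]
        pos2 = resp_pos2[sel]
        # respiratory event: resp code in dx1 or dx2; non-resp codes elsewhere
        d1 = np.where(is_resp & ~pos2, resp_codes, other_codes)
        d2 = np.where(
            is_resp & pos2,
            resp_codes,
            np.where(has_dx2[sel] | (is_resp & pos2), other2, ""),
        )
        dx1[sel] = d1
        dx2[sel] = d2
    # third/fourth fields: acute non-respiratory filler (never respiratory)
    dx3 = np.empty(n_ev, dtype=object)
    dx4 = np.empty(n_ev, dtype=object)
    for version in (9, 10):
        sel = ev_ver == version
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        dx3[sel] = np.where(has_dx34[sel, 0], draw((version, False), n_sel), "")
        dx4[sel] = np.where(has_dx34[sel, 1] & has_dx34[sel, 0], draw((version, False), n_sel), "")

    visit_rows.append(
        pd.DataFrame(
            {
                "child_id": ev["child_id"],
                "service_date": ev_dates,
                "dx1": dx1,
                "dx2": dx2,
                "dx3": dx3,
                "dx4": dx4,
                "icd_version": ev_ver,
            }
        )
    )

    # ---- outpatient: decoy visits (no fill) ---------------------------
    if config.decoy_visit_rate > 0:
        mean = config.decoy_visit_rate * HORIZON_DAYS / DAYS_PER_YEAR
        counts = rng.poisson(mean, size=len(children))
        total = int(counts.sum())
        if total:
            idx = np.repeat(np.arange(len(children)), counts)
            ages = rng.integers(0, HORIZON_DAYS, size=total)
            cid = children["child_id"].to_numpy()[idx]
            dates = birth_by_child.loc[cid].reset_index(drop=True) + pd.to_timedelta(
                ages, unit="D"
            )
            ver = _icd_version_for(dates)
            d1 = np.empty(total, dtype=object)
            for version in (9, 10):
                sel = ver == version
                if sel.sum():
                    d1[sel] = draw((version, False), int(sel.sum()))
            visit_rows.append(
                pd.DataFrame(
                    {
                        "child_id": cid,
                        "service_date": dates,
                        "dx1": d1,
                        "dx2": "",
                        "dx3": "",
                        "dx4": "",
                        "icd_version": ver,
                    }
                )
            )

    # ---- outpatient: chronic-condition visits -------------------------
    cond_rows = []
    for system in cm.BODY_SYSTEMS:
        col = f"cond_{system}"
        flagged = children.loc[children[col], "child_id"].to_numpy()
        if not len(flagged):
            continue
        reps = 2  # two qualifying visits per held condition
        cid = np.repeat(flagged, reps)
        ages = rng.integers(0, HORIZON_DAYS, size=len(cid))
        dates = birth_by_child.loc[cid].reset_index(drop=True) + pd.to_timedelta(ages, unit="D")
        ver = _icd_version_for(dates)
        code = np.array(
            [chronic.get((v, system), chronic.get((10, system), "")) for v in ver],
            dtype=object,
        )
        cond_rows.append(
            pd.DataFrame(
                {
                    "child_id": cid,
                    "service_date": dates,
                    "dx1": code,
                    "dx2": "",
                    "dx3": "",
                    "dx4": "",
                    "icd_version": ver,
                }
            )
        )
    outpatient = pd.concat(visit_rows + cond_rows, ignore_index=True)
    outpatient.insert(0, "claim_id", np.arange(len(outpatient)) + 1)

    # ---- pharmacy -----------------------------------------------------
    lags = rng.choice(8, size=len(events), p=list(config.fill_lag_probs))
    fill_dates = birth_by_child.loc[events["child_id"]].reset_index(drop=True) + pd.to_timedelta(
        events["event_age_days"].to_numpy() + lags, unit="D"
    )
    classes = np.array(list(config.abx_class_probs))
    drug_class = classes[
        rng.choice(len(classes), size=len(events), p=list(config.abx_class_probs.values()))
    ]
    pharmacy = pd.DataFrame(
        {
            "child_id": events["child_id"],
            "fill_date": fill_dates,
            "drug_class": drug_class,
            "drug_code": np.char.add("SYN-", drug_class.astype(str)),
        }
    )
    if config.nonabx_fill_rate > 0:
        mean = config.nonabx_fill_rate * HORIZON_DAYS / DAYS_PER_YEAR
        counts = rng.poisson(mean, size=len(children))
        total = int(counts.sum())
        if total:
            idx = np.repeat(np.arange(len(children)), counts)
            cid = children["child_id"].to_numpy()[idx]
            ages = rng.integers(0, HORIZON_DAYS, size=total)
            dates = birth_by_child.loc[cid].reset_index(drop=True) + pd.to_timedelta(
                ages, unit="D"
            )
            pharmacy = pd.concat(
                [
                    pharmacy,
                    pd.DataFrame(
                        {
                            "child_id": cid,
                            "fill_date": dates,
                            "drug_class": "antihistamines",
                            "drug_code": "SYN99999",
                        }
                    ),
                ],
                ignore_index=True,
            )
    pharmacy.insert(0, "claim_id", np.arange(len(pharmacy)) + 1)

    # ---- enrollment and census ----------------------------------------
    enrollment = children[["child_id", "sex", "state", "msa", "birth_date"]].copy()
    enrollment["span_start"] = enrollment["birth_date"]
    enrollment["span_end"] = enrollment["birth_date"] + pd.to_timedelta(HORIZON_DAYS, unit="D")

    census = pd.DataFrame(
        [
            {"state": st, "sex": sx, "population_under5": n}
            for st, by_sex in config.census_counts.items()
            for sx, n in by_sex.items()
        ]
    )

    ground_truth = events[["child_id", "event_age_days", "is_respiratory", "visit_emitted"]].copy()
    return SyntheticBundle(
        enrollment=enrollment,
        outpatient=outpatient,
        pharmacy=pharmacy,
        census=census,
        ground_truth=ground_truth,
    )


def simulate(
    config: GeneratorConfig, rng_seed: int | None = None, codes: cm.CodeMap | None = None
) -> SyntheticBundle:
    """children -> events -> claims, all from one seed (config.seed by default)."""
    seed = config.seed if rng_seed is None else rng_seed
    children = sample_children(config, seed)
    events = sample_course_events(children, config, seed)
    bundle = emit_claims(children, events, config, seed, codes=codes)
    bundle.children = children  # sampled profiles (frailty, condition flags)
    return bundle
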