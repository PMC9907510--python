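"""End-to-end orchestration: simulate -> filter -> link -> weight -> stats -> regress.

Every stage writes its CSV outputs under the run directory and records row
counts and attrition in a RunManifest, so a run is fully reproducible from
(config, seed) and machine-checkable for conservation of records.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import codemap as cm
from . import cohort, descriptive, highuse, linkage, synth, weighting
from .config import HORIZON_DAYS, GeneratorConfig

logger = logging.getLogger(__name__)

#: Conditions found to at least double the top-quintile odds; used for the
#: flagged-vs-unflagged subgroup comparison.
HIGH_ODDS_SYSTEMS = ("pulmonary_respiratory", "otologic", "immunological")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    tool_version: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    attrition: dict[str, dict[str, int]] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def record_attrition(self, stage: str, input_n: int, retained: int) -> None:
        self.attrition[stage] = {
            "input": int(input_n),
            "retained": int(retained),
            "excluded": int(input_n - retained),
        }

    def check_consistency(self) -> None:
        for stage, a in self.attrition.items():
            if a["input"] != a["retained"] + a["excluded"]:
                raise AssertionError(f"attrition inconsistent at stage {stage}: {a}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


@dataclass
class PipelineResult:
    manifest: RunManifest
    children: pd.DataFrame
    courses: pd.DataFrame
    weights: pd.DataFrame
    condition_flags: pd.DataFrame
    curves: dict[str, descriptive.CurveEstimate]
    top_share: descriptive.ShareResult
    histogram: pd.Series
    regression: pd.DataFrame | None
    subgroup: descriptive.SubgroupSummary | None


def run_pipeline(
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    weighted: bool = True,
    bundle=None,
    codes: cm.CodeMap | None = None,
    antibiotic_classes: tuple[str, ...] | None = None,
    with_regression: bool = True,
) -> PipelineResult:
    """Run every stage; pass ``bundle`` to analyse pre-existing tables instead
    of simulating.  Writes outputs only when ``out_dir`` is given."""
    seed = config.seed if seed is None else seed
    codes = codes or cm.load_crosswalk()
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=seed, tool_version=__version__
    )

    # ---- simulate ------------------------------------------------------
    if bundle is None:
        bundle = synth.simulate(config, seed, codes=codes)
    manifest.stage_counts.update(
        enrollment_rows=len(bundle.enrollment),
        outpatient_rows=len(bundle.outpatient),
        pharmacy_rows=len(bundle.pharmacy),
    )

    # ---- cohort filters ------------------------------------------------
    y0, y1 = config.birth_year_range
    eligible = cohort.filter_continuously_enrolled(bundle, y0, y1, HORIZON_DAYS)
    n_children_in = bundle.enrollment["child_id"].nunique()
    manifest.record_attrition("continuous_enrollment", n_children_in, len(eligible))

    classes = antibiotic_classes or tuple(config.abx_class_probs)
    abx = cohort.filter_antibiotic_fills(bundle.pharmacy, classes)
    manifest.record_attrition("antibiotic_class", len(bundle.pharmacy), len(abx))
    abx = abx[abx["child_id"].isin(eligible)]

    enrollment = bundle.enrollment[bundle.enrollment["child_id"].isin(eligible)]
    children = (
        enrollment.groupby("child_id", as_index=False)
        .first()[["child_id", "sex", "state", "msa", "birth_date"]]
        .sort_values("child_id", kind="stable")
        .reset_index(drop=True)
    )

    # ---- linkage -------------------------------------------------------
    courses0 = linkage.build_courses(abx, enrollment)
    courses = linkage.classify_courses(courses0, bundle.outpatient, codes)
    manifest.record_attrition("course_build", len(abx), len(courses0))
    manifest.stage_counts["courses"] = len(courses)

    # ---- weighting -----------------------------------------------------
    weights = weighting.compute_weights(children, bundle.census)
    children_w = weighting.attach_weights(children, weights)
    stats_children = children_w if weighted else children

    # ---- chronic conditions (claims-derived) ---------------------------
    conditions = cm.assign_chronic_conditions(
        bundle.outpatient[bundle.outpatient["child_id"].isin(eligible)], codes
    )
    condition_flags = cm.conditions_to_frame(conditions, children["child_id"])

    # ---- descriptive statistics ----------------------------------------
    curves: dict[str, descriptive.CurveEstimate] = {}
    for attribution in descriptive.ATTRIBUTIONS:
        curves[f"cumulative_{attribution}"] = descriptive.cumulative_course_curve(
            courses, stats_children, attribution
        )
        curves[f"first_course_{attribution}"] = descriptive.first_course_curve(
            courses, stats_children, attribution
        )
    counts = descriptive.per_child_counts(courses, children)
    share_w = descriptive._weights_of(stats_children) if weighted else None
    share = descriptive.top_share(counts, weights=share_w, q=0.20)
    histogram = descriptive.count_histogram(counts, weights=share_w)

    # ---- regression and subgroup ---------------------------------------
    regression = None
    subgroup = None
    if with_regression:
        counts_idx = counts.copy()
        counts_idx.index = children["child_id"]
        try:
            _fit, regression = highuse.highuse_regression(counts_idx, condition_flags)
        except highuse.SeparationError as e:
            logger.warning("high-use regression skipped: %s", e)
        try:
            subgroup = descriptive.subgroup_summary(
                stats_children, condition_flags, HIGH_ODDS_SYSTEMS, courses
            )
        except ValueError as e:
            logger.warning("subgroup summary skipped: %s", e)

    manifest.check_consistency()

    # ---- outputs -------------------------------------------------------
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = cohort.write_bundle(bundle, out_dir)

        cdf = courses.copy()
        cdf["fill_date"] = cdf["fill_date"].dt.strftime("%Y-%m-%d")
        cdf.to_csv(out_dir / "courses.csv", index=False)
        weights.to_csv(out_dir / "weights.csv", index=False)
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            out_dir / "curves.csv", index=False
        )
        histogram.reset_index().to_csv(out_dir / "histogram.csv", index=False)
        _summary_tables(children, counts, share, curves).to_csv(
            out_dir / "summary.csv", index=False
        )
        if regression is not None:
            reg = regression.rename(columns={"term": "body_system"})
            reg.to_csv(out_dir / "regression.csv", index=False)
            written.append(out_dir / "regression.csv")
        written += [
            out_dir / n
            for n in ("courses.csv", "weights.csv", "curves.csv", "histogram.csv", "summary.csv")
        ]
        manifest.outputs = sorted(str(p.name) for p in written)
        manifest.to_json(out_dir / "manifest.json")

    return PipelineResult(
        manifest=manifest,
        children=stats_children,
        courses=courses,
        weights=weights,
        condition_flags=condition_flags,
        curves=curves,
        top_share=share,
        histogram=histogram,
        regression=regression,
        subgroup=subgroup,
    )


def _summary_tables(children, counts, share, curves) -> pd.DataFrame:
    """Cohort composition (by sex, birth year) and headline estimates."""
    rows = [("total_children", "", len(children))]
    for sex, n in children["sex"].value_counts().items():
        rows.append(("n_by_sex", sex, n))
    for year, n in children["birth_date"].dt.year.value_counts().sort_index().items():
        rows.append(("n_by_birth_year", str(year), n))
    day = HORIZON_DAYS
    rows += [
        ("mean_courses_age5", "all", curves["cumulative_all"].at(day)),
        ("mean_courses_age5", "respiratory", curves["cumulative_respiratory"].at(day)),
        ("mean_courses_age5", "other", curves["cumulative_other"].at(day)),
        ("prop_any_course_age5", "all", curves["first_course_all"].at(day)),
        ("prop_any_course_age5", "respiratory", curves["first_course_respiratory"].at(day)),
        ("top20_share", "", share.share),
    ]
    return pd.DataFrame(rows, columns=["measure", "group", "value"])
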