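"""Generator configuration: the study conditions the synthetic cohort emulates.

The default configuration encodes the analysis' empirical anchors: the three
piecewise-constant age-band dispensing rates (0.60, 1.9, 1.2 courses per
child per 365-day year on 0-180, 180-730 and 730-1825 days of age), a 71%
respiratory attribution probability per course, chronic-condition
prevalences for the 19 PMCA body systems, and a gamma-frailty dispersion
jointly calibrated with the pulmonary/respiratory rate multiplier so the
analytic count mixture reproduces a 91% ever-dispensed proportion and a 52%
top-quintile share (see ``pedabx.synth.calibrate_default_config``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .codemap import BODY_SYSTEMS

DAYS_PER_YEAR = 365.0
HORIZON_DAYS = 1825  # age 5 = day 1825; event ages live in [0, 1825)

#: Chronic-condition prevalence per PMCA body system (fraction of children).
DEFAULT_PREVALENCES: dict[str, float] = {
    "pulmonary_respiratory": 0.183,
    "otologic": 0.018,
    "immunological": 0.012,
    "renal": 0.011,
    "gastrointestinal": 0.021,
    "neurological": 0.024,
    "genitourinary": 0.089,
    "hematological": 0.010,
    "cardiac": 0.023,
    "endocrinological": 0.009,
    "metabolic": 0.043,
    "dermatological": 0.068,
    "genetic": 0.003,
    "musculoskeletal": 0.010,
    "craniofacial": 0.072,
    "ophthalmological": 0.091,
    "mental_health": 0.003,
    "malignancy": 0.004,
    "otolaryngological": 0.002,
}

# Calibrated jointly on the analytic NB mixture (zero-class 0.09,
# top-20% share 0.52); reproduced by synth.calibrate_default_config.
DEFAULT_FRAILTY_SHAPE = 1.4345402941372154
DEFAULT_PULMONARY_MULTIPLIER = 2.0480014319983897

#: Synthetic state-level under-5 population (thousands scaled up), used both
#: for census emission and (proportionally) for sampling states.
_STATE_POP: dict[str, int] = {
    "CA": 2531000,
    "TX": 1928000,
    "NY": 1155000,
    "FL": 1073000,
    "IL": 830000,
    "PA": 729000,
    "OH": 721000,
    "GA": 687000,
    "NC": 632000,
    "MI": 596000,
}

DEFAULT_SEX_PROBS = {"F": 0.514, "M": 0.486}

DEFAULT_AGE_BAND_RATES: tuple[tuple[int, int, float], ...] = (
    (0, 180, 0.60),
    (180, 730, 1.9),
    (730, 1825, 1.2),
)

#: Visit-to-fill lag distribution on 0..7 days (most fills same-day/next-day).
DEFAULT_FILL_LAG_PROBS = (0.50, 0.20, 0.10, 0.07, 0.05, 0.04, 0.02, 0.02)

DEFAULT_ABX_CLASS_PROBS = {
    "penicillins": 0.55,
    "cephalosporins": 0.25,
    "macrolides": 0.20,
}


def _default_census() -> dict[str, dict[str, int]]:
    return {
        state: {
            sex: int(round(pop * p))
            for sex, p in DEFAULT_SEX_PROBS.items()
        }
        for state, pop in _STATE_POP.items()
    }


def _default_state_probs() -> dict[str, float]:
    total = sum(_STATE_POP.values())
    return {s: pop / total for s, pop in _STATE_POP.items()}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic claims generator.

    Probabilities are validated to sum to 1 per category; age bands must tile
    [0, 1825) without overlap; the gamma frailty has mean fixed at 1 so
    ``frailty_shape`` is a pure dispersion knob.
    """

    n_children: int = 20_000
    birth_year_range: tuple[int, int] = (2008, 2013)
    sex_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    state_probs: dict[str, float] = field(default_factory=_default_state_probs)
    census_counts: dict[str, dict[str, int]] = field(default_factory=_default_census)
    age_band_rates: tuple[tuple[int, int, float], ...] = DEFAULT_AGE_BAND_RATES
    frailty_shape: float = DEFAULT_FRAILTY_SHAPE
    condition_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    condition_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            s: (DEFAULT_PULMONARY_MULTIPLIER if s == "pulmonary_respiratory" else 1.0)
            for s in BODY_SYSTEMS
        }
    )
    p_respiratory: float = 0.71
    fill_lag_probs: tuple[float, ...] = DEFAULT_FILL_LAG_PROBS
    decoy_visit_rate: float = 2.0
    nonabx_fill_rate: float = 0.5
    unlinked_fill_prob: float = 0.0
    abx_class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABX_CLASS_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        y0, y1 = self.birth_year_range
        if y1 < y0:
            raise ValueError("birth_year_range must be (min, max)")
        for name, probs in (
            ("sex_probs", self.sex_probs),
            ("state_probs", self.state_probs),
            ("abx_class_probs", self.abx_class_probs),
        ):
            vals = list(probs.values())
            if any(p < 0 or p > 1 for p in vals):
                raise ValueError(f"{name} entries must be in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1, got {sum(vals)}")
        if len(self.fill_lag_probs) != 8:
            raise ValueError(
                "fill_lag_probs must have support exactly {0..7} days; "
                "longer lags would break the 7-day linkage window by construction"
            )
        if any(p < 0 for p in self.fill_lag_probs) or abs(sum(self.fill_lag_probs) - 1) > 1e-8:
            raise ValueError("fill_lag_probs must be a probability vector over {0..7}")
        if not 0 <= self.p_respiratory <= 1 or not 0 <= self.unlinked_fill_prob <= 1:
            raise ValueError("p_respiratory and unlinked_fill_prob must be in [0, 1]")
        if self.frailty_shape <= 0:
            raise ValueError("frailty_shape must be positive")
        if self.decoy_visit_rate < 0 or self.nonabx_fill_rate < 0:
            raise ValueError("rates must be >= 0")
        bands = sorted(self.age_band_rates)
        if not bands or bands[0][0] != 0 or bands[-1][1] != HORIZON_DAYS:
            raise ValueError(f"age bands must tile [0, {HORIZON_DAYS})")
        for (s0, e0, r0), (s1, _e1, _r1) in zip(bands, bands[1:]):
            if e0 != s1:
                raise ValueError("age bands must tile [0, 1825) without gaps or overlap")
        if any(r < 0 for _s, _e, r in bands):
            raise ValueError("age-band rates must be >= 0")
        for sysname in self.condition_prevalences:
            if sysname not in BODY_SYSTEMS:
                raise ValueError(f"unknown body system in prevalences: {sysname!r}")
        if any(not 0 <= p <= 1 for p in self.condition_prevalences.values()):
            raise ValueError("condition prevalences must be in [0, 1]")
        if any(m < 0 for m in self.condition_multipliers.values()):
            raise ValueError("condition multipliers must be >= 0")
        for state in self.state_probs:
            if state not in self.census_counts:
                raise ValueError(f"state {state!r} sampled but absent from census_counts")

    # -- derived quantities ----------------------------------------------
    @property
    def total_mean_courses(self) -> float:
        """Expected courses per child over [0, 1825): sum of rate x duration."""
        return sum(
            r * (e - s) / DAYS_PER_YEAR for s, e, r in self.age_band_rates
        )

    @property
    def z_norm(self) -> float:
        """E[M] over independent condition draws: product of (1-p+p*m)."""
        z = 1.0
        for system, p in self.condition_prevalences.items():
            m = self.condition_multipliers.get(system, 1.0)
            z *= 1.0 - p + p * m
        return z

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["birth_year_range"] = list(self.birth_year_range)
        d["age_band_rates"] = [list(b) for b in self.age_band_rates]
        d["fill_lag_probs"] = list(self.fill_lag_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "birth_year_range" in d:
            d["birth_year_range"] = tuple(d["birth_year_range"])
        if "age_band_rates" in d:
            d["age_band_rates"] = tuple(tuple(b) for b in d["age_band_rates"])
        if "fill_lag_probs" in d:
            d["fill_lag_probs"] = tuple(d["fill_lag_probs"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash of the canonicalised config (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(**overrides) -> GeneratorConfig:
    """The shipped default configuration (calibrated study conditions)."""
    cfg = GeneratorConfig()
    if overrides:
        d = cfg.to_dict()
        d.update(overrides)
        cfg = GeneratorConfig.from_dict(d)
    return cfg
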