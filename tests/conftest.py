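import numpy as np
import pandas as pd
import pytest

from pedabx import codemap as cm
from pedabx import synth
from pedabx.config import GeneratorConfig, default_config


@pytest.fixture(scope="session")
def codes() -> cm.CodeMap:
    return cm.load_crosswalk()


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return default_config(n_children=400, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return synth.simulate(small_cfg)


def make_children(n: int, frailty: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Minimal children table: equal frailty, no conditions, common birth date."""
    df = pd.DataFrame(
        {
            "child_id": [f"C{i:07d}" for i in range(n)],
            "sex": np.where(np.arange(n) % 2 == 0, "F", "M"),
            "state": "CA",
            "msa": "CA_MSA1",
            "birth_date": pd.Timestamp("2010-01-01"),
            "frailty": frailty,
        }
    )
    for system in cm.BODY_SYSTEMS:
        df[f"cond_{system}"] = False
    return df


def make_courses(rows) -> pd.DataFrame:
    """Course table from (child_id, age_days, attribution) triples."""
    df = pd.DataFrame(rows, columns=["child_id", "age_days", "attribution"])
    df["fill_date"] = pd.Timestamp("2010-01-01") + pd.to_timedelta(df["age_days"], unit="D")
    df["drug_class"] = "penicillins"
    df["linked_claim_id"] = np.nan
    df["unlinked"] = df["attribution"] == "other"
    return df
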