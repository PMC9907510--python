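"""ICD-9/ICD-10 diagnosis code mapping.

Two classification layers drive the analysis:

* **CCS grouping** — ICD diagnosis codes are mapped to Clinical
  Classifications Software (CCS) categories by exact ``(code, version)``
  lookup, and a configured subset of CCS categories (sinusitis, pneumonia,
  influenza, tonsillitis, acute bronchitis, otitis media, other upper
  respiratory infections) marks a visit as a respiratory infection.
* **PMCA body systems** — chronic-disease ICD codes map, by code *prefix*,
  to one of 19 body systems (Pediatric Medical Complexity Algorithm).  The
  least-conservative reading is used: one qualifying outpatient visit flags
  the child for that system.

The crosswalks shipped under ``pedabx/data`` are small synthetic fixtures
(non-clinical, for tests and simulation); full licensed tables load through
the same three-file schema.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: The 19 PMCA body systems (fixed vocabulary).
BODY_SYSTEMS: tuple[str, ...] = (
    "pulmonary_respiratory",
    "otologic",
    "immunological",
    "renal",
    "gastrointestinal",
    "neurological",
    "genitourinary",
    "hematological",
    "cardiac",
    "endocrinological",
    "metabolic",
    "dermatological",
    "genetic",
    "musculoskeletal",
    "craniofacial",
    "ophthalmological",
    "mental_health",
    "malignancy",
    "otolaryngological",
)

DATA_DIR = Path(__file__).parent / "data"


def normalize_icd(code: str) -> str:
    """Uppercase and strip dots: both dialects appear in claims extracts."""
    return str(code).strip().upper().replace(".", "")


@dataclass
class CodeMap:
    """Validated ICD->CCS crosswalk, respiratory CCS set, and PMCA prefix map."""

    ccs_entries: dict[tuple[str, int], str]
    ccs_labels: dict[str, str]
    respiratory_ccs: frozenset[str]
    pmca_entries: list[tuple[str, int, str]]
    # (version -> prefix -> set of body systems), built once for lookups
    _pmca_index: dict[int, dict[str, set[str]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        idx: dict[int, dict[str, set[str]]] = {9: {}, 10: {}}
        for prefix, version, system in self.pmca_entries:
            if system not in BODY_SYSTEMS:
                raise ValueError(
                    f"unknown body system {system!r}; valid names: {', '.join(BODY_SYSTEMS)}"
                )
            idx.setdefault(version, {}).setdefault(normalize_icd(prefix), set()).add(system)
        self._pmca_index = idx

    def pmca_systems(self, code: str, icd_version: int) -> set[str]:
        """Body systems of the *longest* PMCA prefix matching ``code``."""
        norm = normalize_icd(code)
        prefixes = self._pmca_index.get(int(icd_version), {})
        for ln in range(len(norm), 0, -1):
            hit = prefixes.get(norm[:ln])
            if hit:
                return set(hit)
        return set()


def load_crosswalk(
    ccs_path: str | Path | None = None,
    respiratory_path: str | Path | None = None,
    pmca_path: str | Path | None = None,
) -> CodeMap:
    """Load and validate the three crosswalk files (defaults: shipped fixtures).

    ``ccs_crosswalk.csv``: icd_code, icd_version, ccs_code, ccs_label.
    ``respiratory_ccs.csv``: ccs_code.
    ``pmca_map.csv``: icd_prefix, icd_version, body_system.
    """
    ccs_path = Path(ccs_path) if ccs_path else DATA_DIR / "ccs_crosswalk.csv"
    respiratory_path = (
        Path(respiratory_path) if respiratory_path else DATA_DIR / "respiratory_ccs.csv"
    )
    pmca_path = Path(pmca_path) if pmca_path else DATA_DIR / "pmca_map.csv"

    ccs = pd.read_csv(ccs_path, dtype=str)
    required = {"icd_code", "icd_version", "ccs_code", "ccs_label"}
    if not required.issubset(ccs.columns):
        raise ValueError(f"{ccs_path}: expected columns {sorted(required)}")
    entries: dict[tuple[str, int], str] = {}
    labels: dict[str, str] = {}
    for row in ccs.itertuples(index=False):
        key = (normalize_icd(row.icd_code), int(row.icd_version))
        ccs_code = str(row.ccs_code).strip()
        if key in entries and entries[key] != ccs_code:
            raise ValueError(
                f"conflicting CCS assignment for ICD code {key[0]!r} (version {key[1]}): "
                f"{entries[key]!r} vs {ccs_code!r}"
            )
        entries[key] = ccs_code
        labels[ccs_code] = str(row.ccs_label)

    resp = pd.read_csv(respiratory_path, dtype=str)
    if "ccs_code" not in resp.columns:
        raise ValueError(f"{respiratory_path}: expected column ccs_code")
    respiratory = frozenset(str(c).strip() for c in resp["ccs_code"].dropna())
    if not respiratory:
        warnings.warn("respiratory CCS set is empty; no course will be respiratory-attributed")

    pmca = pd.read_csv(pmca_path, dtype=str)
    pmca_entries: list[tuple[str, int, str]] = []
    if len(pmca):
        required = {"icd_prefix", "icd_version", "body_system"}
        if not required.issubset(pmca.columns):
            raise ValueError(f"{pmca_path}: expected columns {sorted(required)}")
        for row in pmca.itertuples(index=False):
            pmca_entries.append(
                (normalize_icd(row.icd_prefix), int(row.icd_version), str(row.body_system).strip())
            )

    return CodeMap(
        ccs_entries=entries,
        ccs_labels=labels,
        respiratory_ccs=respiratory,
        pmca_entries=pmca_entries,
    )


def map_icd_to_ccs(code: str | None, icd_version: int, codemap: CodeMap) -> str | None:
    """Exact-key CCS lookup; None when the code is absent from the crosswalk."""
    if int(icd_version) not in (9, 10):
        raise ValueError(f"icd_version must be 9 or 10, got {icd_version!r}")
    if code is None or (isinstance(code, float) and pd.isna(code)) or str(code).strip() == "":
        return None
    return codemap.ccs_entries.get((normalize_icd(code), int(icd_version)))


def is_respiratory(ccs_code: str | None, codemap: CodeMap) -> bool:
    """Whether a CCS category is in the respiratory-infection set (None -> False)."""
    if ccs_code is None:
        return False
    return str(ccs_code) in codemap.respiratory_ccs


def assign_chronic_conditions(
    outpatient: pd.DataFrame, codemap: CodeMap
) -> dict[str, set[str]]:
    """Tag children with PMCA body systems from their outpatient diagnoses.

    A child is flagged for system j iff at least one outpatient claim carries
    at least one diagnosis (any dx field) whose longest matching PMCA prefix
    maps to j.  Children with no matching claims map to the empty set.
    """
    dx_cols = [c for c in outpatient.columns if c.startswith("dx")]
    out: dict[str, set[str]] = {}
    if not len(outpatient) or not codemap.pmca_entries:
        return out
    # cache per (code, version) since claims repeat few distinct codes
    cache: dict[tuple[str, int], frozenset[str]] = {}
    cols = outpatient[["child_id", "icd_version", *dx_cols]]
    for row in cols.itertuples(index=False):
        child = row.child_id
        version = int(row.icd_version)
        for code in row[2:]:
            if code is None or (isinstance(code, float) and pd.isna(code)) or code == "":
                continue
            key = (str(code), version)
            systems = cache.get(key)
            if systems is None:
                systems = frozenset(codemap.pmca_systems(key[0], version))
                cache[key] = systems
            if systems:
                out.setdefault(child, set()).update(systems)
    return out


def conditions_to_frame(
    conditions: dict[str, set[str]], child_ids: pd.Series | list[str]
) -> pd.DataFrame:
    """Boolean child x body-system indicator matrix over the given children."""
    ids = pd.Index(child_ids, name="child_id")
    data = {
        system: [system in conditions.get(cid, ()) for cid in ids]
        for system in BODY_SYSTEMS
    }
    return pd.DataFrame(data, index=ids)
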