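"""Analysis-ready phenotypes from raw codes, medication text, and labs.

Builds, per individual: the phecode set mapped from ICD-10 codes, flags for
the five ADH1-relevant phecode categories, a count of ADH1-associated
medications parsed from free-text prescription strings, hypocalcemia /
hyperphosphatemia flags against fixed normal limits (calcium LLN 2.2 mM,
phosphate ULN 1.45 mM, strict comparisons), and eGFR from the 2012 CKD-EPI
cystatin C equation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .simulate import LLN_CALCIUM_MM, ULN_PHOSPHATE_MM

logger = logging.getLogger(__name__)

#: The five phecode categories treated as ADH1-associated.  The epilepsy
#: phecodes are collapsed into a single category for sub-scoring.
ADH1_PHECODE_CATEGORIES: dict[str, frozenset[str]] = {
    "hypoparathyroidism": frozenset({"252.2"}),
    "calcium_phosphorus_disorder": frozenset({"275.5"}),
    "tetany": frozenset({"350.1"}),
    "paresthesia": frozenset({"687.4"}),
    "epilepsy": frozenset({"345.0", "345.1", "345.11", "345.12"}),
}

#: Phecodes counted as "directly suggestive" of an ADH1 diagnosis when
#: estimating code-based penetrance (hypocalcemia / calcium-phosphorus
#: disorder and hypoparathyroidism).
ADH1_DX_SUGGESTIVE_PHECODES: frozenset[str] = frozenset({"252.2", "275.5"})


def load_phecode_map(path=None) -> pd.DataFrame:
    """Load an ICD-10 -> phecode map (columns ``icd10``, ``phecode``, ``label``).

    Without ``path``, loads the bundled synthetic subset covering the
    ADH1-relevant codes plus common background diagnoses.
    """
    if path is None:
        path = resources.files("adh1score.data") / "phecode_map_subset.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"icd10", "phecode"} - set(df.columns)
    if missing:
        raise ValueError(f"phecode map missing columns: {sorted(missing)}")
    bad = df.index[df["icd10"].isna() | df["phecode"].isna()]
    if len(bad):
        raise ValueError(
            "malformed phecode map rows (1-based line numbers): "
            f"{[int(i) + 2 for i in bad]}"
        )
    df["icd10"] = df["icd10"].map(normalize_icd10)
    return df


def load_medication_keywords(path=None) -> list[str]:
    if path is None:
        path = resources.files("adh1score.data") / "adh1_medication_keywords.txt"
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def normalize_icd10(code: str) -> str:
    """Uppercase and strip dots, so e.g. ``e83.5`` -> ``E835``."""
    return code.strip().upper().replace(".", "")


def map_icd_to_phecodes(icd10_codes, phecode_map: pd.DataFrame) -> set[str]:
    """Map a set of ICD-10 codes to phecodes by longest-prefix match.

    Codes are normalized (uppercased, dot-insensitive) and matched against
    the map first on their 4-character prefix, then 3-character, so a
    truncated or over-specific code still resolves deterministically.
    Unmapped codes are ignored with a logged warning.
    """
    lookup = dict(zip(phecode_map["icd10"], phecode_map["phecode"]))
    out: set[str] = set()
    for code in icd10_codes:
        norm = normalize_icd10(code)
        hit = None
        for prefix_len in (len(norm), 4, 3):
            hit = lookup.get(norm[:prefix_len])
            if hit is not None:
                break
        if hit is None:
            logger.warning("ICD-10 code %r not present in phecode map; ignored", code)
        else:
            out.add(hit)
    return out


_PTH_WORD = re.compile(r"(?<![a-z])pth(?![a-z])")


def count_adh1_medications(medication_strings, keywords=None) -> int:
    """Number of medication strings matching any ADH1-relevant keyword.

    Matching is case-insensitive substring matching, except that the
    keyword ``PTH`` only matches as a whole word (so it does not fire
    inside unrelated tokens).  Each medication string counts at most once.
    """
    if keywords is None:
        keywords = load_medication_keywords()
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    kw = [k.lower() for k in keywords]
    count = 0
    for s in medication_strings:
        low = s.lower()
        for k in kw:
            matched = bool(_PTH_WORD.search(low)) if k == "pth" else (k in low)
            if matched:
                count += 1
                break
    return count


def egfr_cystatin_c(cystatin_c: float, age: float, sex: str) -> float:
    """eGFR (mL/min/1.73 m^2) from the 2012 CKD-EPI cystatin C equation.

    ``133 * min(Scys/0.8, 1)^-0.499 * max(Scys/0.8, 1)^-1.328 * 0.996^age``,
    times 0.932 for females.
    """
    if not cystatin_c > 0:
        raise ValueError("cystatin C must be positive")
    if age < 0:
        raise ValueError("age must be non-negative")
    ratio = cystatin_c / 0.8
    egfr = 133.0 * min(ratio, 1.0) ** -0.499 * max(ratio, 1.0) ** -1.328 * 0.996 ** age
    if sex == "female":
        egfr *= 0.932
    return egfr


def flag_labs(calcium, phosphate, lln: float = LLN_CALCIUM_MM,
              uln: float = ULN_PHOSPHATE_MM):
    """Strict below-LLN / above-ULN flags; a missing lab yields ``None``."""
    hypo = None if calcium is None or (isinstance(calcium, float) and np.isnan(calcium)) \
        else bool(calcium < lln)
    hyper = None if phosphate is None or (isinstance(phosphate, float) and np.isnan(phosphate)) \
        else bool(phosphate > uln)
    return hypo, hyper


def collapse_measurements(values, policy: str = "mean"):
    """Collapse repeated lab measurements to one value.

    ``mean`` averages across repeats; ``first`` takes the earliest (list
    order).  An empty list yields ``None`` (missing).
    """
    values = [v for v in values if v is not None and not (isinstance(v, float) and np.isnan(v))]
    if not values:
        return None
    if policy == "mean":
        return float(np.mean(values))
    if policy == "first":
        return float(values[0])
    raise ValueError(f"unknown collapse policy {policy!r}")


@dataclass
class PhenotypeVector:
    """Derived phenotypes for one individual."""

    individual_id: str
    phecodes: set[str] = field(default_factory=set)
    adh1_phecode_flags: dict[str, bool] = field(default_factory=dict)
    adh1_medication_count: int = 0
    hypocalcemia_flag: bool | None = None
    hyperphosphatemia_flag: bool | None = None
    egfr: float | None = None


def phenotype_vector(individual_id: str, icd10_codes, medication_strings,
                     calcium, phosphate, cystatin_c, age, sex,
                     phecode_map: pd.DataFrame, keywords,
                     lln: float = LLN_CALCIUM_MM,
                     uln: float = ULN_PHOSPHATE_MM) -> PhenotypeVector:
    phecodes = map_icd_to_phecodes(icd10_codes, phecode_map)
    flags = {cat: bool(phecodes & members)
             for cat, members in ADH1_PHECODE_CATEGORIES.items()}
    hypo, hyper = flag_labs(calcium, phosphate, lln=lln, uln=uln)
    egfr = None
    if cystatin_c is not None and not (isinstance(cystatin_c, float) and np.isnan(cystatin_c)):
        egfr = egfr_cystatin_c(cystatin_c, age, sex)
    return PhenotypeVector(
        individual_id=individual_id,
        phecodes=phecodes,
        adh1_phecode_flags=flags,
        adh1_medication_count=count_adh1_medications(medication_strings, keywords),
        hypocalcemia_flag=hypo,
        hyperphosphatemia_flag=hyper,
        egfr=egfr,
    )


def build_phenotypes(individuals: pd.DataFrame,
                     phecode_map: pd.DataFrame | None = None,
                     keywords=None,
                     lln: float = LLN_CALCIUM_MM,
                     uln: float = ULN_PHOSPHATE_MM) -> pd.DataFrame:
    """Vectorized phenotype construction for a whole individual table.

    Expects the fixture schema (``icd10_codes`` / ``medications`` as
    semicolon-joined strings).  Returns one row per individual with the
    phecode set, the five ADH1 category flags (``cat_<name>`` columns), the
    ADH1 medication count, strict lab flags, an ADH1-dx-suggestive flag, and
    eGFR.
    """
    if phecode_map is None:
        phecode_map = load_phecode_map()
    if keywords is None:
        keywords = load_medication_keywords()

    lookup = dict(zip(phecode_map["icd10"], phecode_map["phecode"]))

    def _map_codes(joined: str) -> frozenset[str]:
        if not joined:
            return frozenset()
        out = set()
        for code in joined.split(";"):
            norm = normalize_icd10(code)
            for prefix_len in (len(norm), 4, 3):
                hit = lookup.get(norm[:prefix_len])
                if hit is not None:
                    out.add(hit)
                    break
        return frozenset(out)

    codes_raw = individuals["icd10_codes"].fillna("").astype(str)
    # memoize: code combinations repeat heavily across a cohort
    phecodes = codes_raw.map({s: _map_codes(s) for s in codes_raw.unique()})

    meds_raw = individuals["medications"].fillna("").astype(str)
    med_cache = {
        s: count_adh1_medications(s.split(";") if s else [], keywords)
        for s in meds_raw.unique()
    }
    med_count = meds_raw.map(med_cache)

    out = pd.DataFrame({
        "individual_id": individuals["individual_id"].to_numpy(),
        "stratum": individuals["stratum"].to_numpy(),
        "phecodes": phecodes.to_numpy(),
        "adh1_medication_count": med_count.to_numpy(),
    })
    for cat, members in ADH1_PHECODE_CATEGORIES.items():
        out[f"cat_{cat}"] = [bool(p & members) for p in out["phecodes"]]
    out["dx_suggestive"] = [bool(p & ADH1_DX_SUGGESTIVE_PHECODES) for p in out["phecodes"]]

    cal = individuals["calcium"].to_numpy(dtype=float)
    phos = individuals["phosphate"].to_numpy(dtype=float)
    out["hypocalcemia_flag"] = pd.array(cal < lln, dtype="boolean")
    out.loc[np.isnan(cal), "hypocalcemia_flag"] = pd.NA
    out["hyperphosphatemia_flag"] = pd.array(phos > uln, dtype="boolean")
    out.loc[np.isnan(phos), "hyperphosphatemia_flag"] = pd.NA

    cys = individuals["cystatin_c"].to_numpy(dtype=float)
    age = individuals["age"].to_numpy(dtype=float)
    female = (individuals["sex"] == "female").to_numpy()
    ratio = cys / 0.8
    with np.errstate(invalid="ignore"):
        egfr = (133.0 * np.minimum(ratio, 1.0) ** -0.499
                * np.maximum(ratio, 1.0) ** -1.328 * 0.996 ** age)
    egfr = np.where(female, egfr * 0.932, egfr)
    out["egfr"] = egfr
    if "has_full_records" in individuals.columns:
        out["has_full_records"] = individuals["has_full_records"].to_numpy()
    return out
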