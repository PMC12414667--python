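"""Carrier frequency, penetrance, excess symptom burden, allelic series.

All count-based quantities (frequencies, penetrances, excess burden) are
computed in exact rational arithmetic (:class:`fractions.Fraction`) and only
converted to float at the end, so e.g. a carrier frequency is *exactly*
``n_carriers / cohort_n * 100,000``.

Excess burden answers "how many diagnosed individuals does this variant set
add on top of the background diagnosis rate?": with ``observed`` affected
carriers out of ``n_carriers``, and a baseline phenotype rate estimated
among non-carriers, ``excess = max(0, observed - n_carriers * baseline)``,
scaled per 100,000 cohort members.  Negative excess is surfaced in a
diagnostics field, never in the headline number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class BurdenEstimate:
    n_carriers: int
    cohort_n: int
    frequency_per_100k: float
    observed_affected: int | None = None
    expected_affected: float | None = None
    excess: float | None = None
    excess_per_100k: float | None = None
    raw_excess: float | None = None          # may be negative; diagnostics only
    lab_penetrance: float | None = None
    dx_penetrance: float | None = None


def carrier_frequency(n_carriers: int, cohort_n: int) -> float:
    """Carriers per 100,000 cohort members, exact."""
    if n_carriers < 0 or cohort_n <= 0:
        raise ValueError("counts must be non-negative with a positive cohort size")
    return float(Fraction(n_carriers, cohort_n) * 100_000)


def lab_penetrance(carrier_values, limit: float, direction: str) -> float | None:
    """Fraction of carrier lab values strictly beyond ``limit``.

    ``direction="below"`` counts values < limit (hypocalcemia against the
    calcium LLN); ``"above"`` counts values > limit (hyperphosphatemia
    against the phosphate ULN).  Missing values are excluded; an empty list
    is missing (``None``), not zero.
    """
    vals = [v for v in carrier_values
            if v is not None and not (isinstance(v, float) and np.isnan(v))]
    if not vals:
        return None
    if direction == "below":
        hits = sum(1 for v in vals if v < limit)
    elif direction == "above":
        hits = sum(1 for v in vals if v > limit)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(Fraction(hits, len(vals)))


def dx_penetrance(carrier_phenotypes: pd.DataFrame,
                  phecode_categories=("hypoparathyroidism", "calcium_phosphorus_disorder"),
                  require_full_records: bool = True) -> float | None:
    """Fraction of evaluable carriers with a diagnosis directly suggestive
    of ADH1 (>=1 phecode in the given categories).

    Carriers are evaluable when their medical-record coverage flag
    (``has_full_records``) is set — code absence is only informative for
    individuals whose records were actually captured.  Zero evaluable
    carriers yields ``None``.
    """
    df = carrier_phenotypes
    if require_full_records and "has_full_records" in df.columns:
        df = df[df["has_full_records"].astype(bool)]
    if df.empty:
        return None
    flag_cols = [f"cat_{c}" for c in phecode_categories]
    hits = int(df[flag_cols].any(axis=1).sum())
    return float(Fraction(hits, len(df)))


def excess_burden(observed_affected: int, n_carriers: int,
                  baseline_rate: float, cohort_n: int) -> BurdenEstimate:
    """Excess affected carriers over the background rate, per 100,000."""
    if not 0.0 <= baseline_rate <= 1.0:
        raise ValueError("baseline_rate must be in [0, 1]")
    if observed_affected > n_carriers:
        raise ValueError("observed affected carriers cannot exceed carrier count")
    if observed_affected < 0 or n_carriers < 0 or cohort_n <= 0:
        raise ValueError("counts must be non-negative with a positive cohort size")
    baseline = Fraction(baseline_rate).limit_denominator(10**12)
    expected = Fraction(n_carriers) * baseline
    raw = Fraction(observed_affected) - expected
    excess = max(raw, Fraction(0))
    return BurdenEstimate(
        n_carriers=n_carriers,
        cohort_n=cohort_n,
        frequency_per_100k=carrier_frequency(n_carriers, cohort_n),
        observed_affected=observed_affected,
        expected_affected=float(expected),
        excess=float(excess),
        excess_per_100k=float(excess / cohort_n * 100_000),
        raw_excess=float(raw),
    )


def baseline_phenotype_rate(phenotypes: pd.DataFrame, carrier_ids,
                            flag_col: str = "dx_suggestive") -> float:
    """Background rate of the phenotype among non-carriers of any scored
    variant, pooled over the cohort."""
    noncarrier = ~phenotypes["individual_id"].isin(set(carrier_ids))
    sub = phenotypes.loc[noncarrier, flag_col]
    if sub.empty:
        raise ValueError("no non-carriers available for the baseline rate")
    return float(sub.astype(bool).mean())


# ---------------------------------------------------------------------------
# allelic series
# ---------------------------------------------------------------------------

def allelic_series_summary(variant_table: pd.DataFrame) -> pd.DataFrame:
    """Per-class summary of the calcium allelic series.

    Input columns: ``variant_id``, ``series_class`` (disjoint labels such
    as common-GWAS / score-above-threshold / known-ADH1 / known-FHH1),
    ``calcium_beta`` (mM), ``maf``.  Returns one row per non-empty class
    with the variant count, median beta, and frequency range — the
    boxplot-ready table for effect size versus allele frequency.  Empty
    classes are omitted with a warning.
    """
    required = {"variant_id", "series_class", "calcium_beta", "maf"}
    missing = required - set(variant_table.columns)
    if missing:
        raise ValueError(f"allelic series table missing columns: {sorted(missing)}")
    rows = []
    for cls, grp in variant_table.groupby("series_class", sort=True):
        grp = grp.dropna(subset=["calcium_beta"])
        if grp.empty:
            logger.warning("allelic-series class %r has no usable variants; omitted", cls)
            continue
        rows.append({
            "series_class": cls,
            "n_variants": len(grp),
            "median_calcium_beta": float(grp["calcium_beta"].median()),
            "maf_min": float(grp["maf"].min()),
            "maf_max": float(grp["maf"].max()),
        })
    return pd.DataFrame(rows, columns=["series_class", "n_variants",
                                       "median_calcium_beta", "maf_min", "maf_max"])


def cross_cohort_concordance(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                             threshold: float,
                             betas_c: pd.DataFrame | None = None) -> dict:
    """Overlap of above-threshold calls between two cohorts.

    ``scores_a``/``scores_b``: columns ``variant_id``, ``variant_score``.
    Reports counts above threshold in A only, B only, and both; when a
    third cohort's calcium betas are supplied (columns ``variant_id``,
    ``calcium_beta_a``, ``calcium_beta_c``), also the fraction of shared
    variants with the same effect direction there.
    """
    a = scores_a.drop_duplicates("variant_id").set_index("variant_id")["variant_score"]
    b = scores_b.drop_duplicates("variant_id").set_index("variant_id")["variant_score"]
    shared = a.index.intersection(b.index)
    above_a = set(a.index[a > threshold])
    above_b = set(b.index[b > threshold])
    report = {
        "n_shared_variants": int(len(shared)),
        "above_in_a_only": int(len(above_a - above_b)),
        "above_in_b_only": int(len(above_b - above_a)),
        "above_in_both": int(len(above_a & above_b)),
        "threshold": float(threshold),
    }
    if betas_c is not None and len(betas_c):
        same = np.sign(betas_c["calcium_beta_a"]) == np.sign(betas_c["calcium_beta_c"])
        report["fraction_same_direction_in_c"] = float(same.mean())
    return report
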