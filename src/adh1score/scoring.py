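"""The ADH1 score: weighted, direction-constrained sub-score aggregation.

Each candidate variant receives, per ancestry stratum, a weighted sum of
sub-scores measuring how strongly its carriers look like ADH1 cases:

====================  ======  =====================================================
component             weight  fires when (binary grading)
====================  ======  =====================================================
serum calcium         3.0     carrier OLS p <= alpha AND beta < 0 (GoF lowers Ca)
serum phosphate       1.0     carrier OLS p <= alpha AND beta > 0 (GoF raises P)
each dx category      1.0     >=1 carrier has a category phecode AND Fisher p <= alpha
medication use        1.0     >=1 carrier on an ADH1 medication AND Fisher p <= alpha
hotspot location      0.5     protein residue within 116-136 or 819-837
in-silico ensemble    0.2     fraction of predictors calling deleterious > 0.5
====================  ======  =====================================================

Calcium carries the largest weight because hypocalcemia is the defining
phenotype; phosphate gets less (only ~50% of strongly affected carriers are
hyperphosphatemic).  The five diagnosis categories are hypoparathyroidism,
calcium/phosphorus disorder, tetany, paresthesia, and epilepsy (collapsed).

Two grading modes are provided.  ``binary`` (the default for variant
reporting) is the auditable weight-times-indicator rule above.  ``graded``
replaces each significance indicator by the continuous, capped factor
``min(1, log(p) / log(alpha))`` (still direction-gated) and grades the
in-silico component by the ensemble fraction itself; the graded score's
continuous null distribution is what makes empirical-percentile threshold
calibration attain its nominal specificity (see the calibration module).

The variant-level score is the maximum across strata: a variant is a
candidate wherever any single cohort pushes it over threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import CarrierOLS, _fisher_cached
from .phenotypes import ADH1_PHECODE_CATEGORIES

logger = logging.getLogger(__name__)

DX_CATEGORIES = tuple(ADH1_PHECODE_CATEGORIES)


@dataclass(frozen=True)
class ScoreWeights:
    w_calcium: float = 3.0
    w_phosphate: float = 1.0
    w_dx_category: float = 1.0
    w_medication: float = 1.0
    w_hotspot: float = 0.5
    w_insilico: float = 0.2
    nominal_alpha: float = 0.05
    hotspot_ranges: tuple[tuple[int, int], ...] = ((116, 136), (819, 837))

    def __post_init__(self):
        for name in ("w_calcium", "w_phosphate", "w_dx_category",
                     "w_medication", "w_hotspot", "w_insilico"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for lo, hi in self.hotspot_ranges:
            if lo > hi or lo < 1:
                raise ValueError("hotspot ranges must be well-ordered, 1-based")


@dataclass
class SubScoreVector:
    """Per-component contributions whose exact sum is the stratum score."""

    variant_id: str
    stratum: str
    calcium: float = 0.0
    phosphate: float = 0.0
    dx: dict[str, float] = field(default_factory=lambda: {c: 0.0 for c in DX_CATEGORIES})
    medication: float = 0.0
    hotspot: float = 0.0
    insilico: float = 0.0

    @property
    def total(self) -> float:
        return (self.calcium + self.phosphate + sum(self.dx.values())
                + self.medication + self.hotspot + self.insilico)

    def as_row(self) -> dict:
        row = {
            "variant_id": self.variant_id,
            "stratum": self.stratum,
            "sub_calcium": self.calcium,
            "sub_phosphate": self.phosphate,
        }
        for cat in DX_CATEGORIES:
            row[f"sub_dx_{cat}"] = self.dx[cat]
        row["sub_medication"] = self.medication
        row["sub_hotspot"] = self.hotspot
        row["sub_insilico"] = self.insilico
        row["total"] = self.total
        return row


#: sub-score component column names, in fixed order (used by calibration)
COMPONENT_COLUMNS = (
    ["sub_calcium", "sub_phosphate"]
    + [f"sub_dx_{c}" for c in DX_CATEGORIES]
    + ["sub_medication", "sub_hotspot", "sub_insilico"]
)


def hotspot_flag(protein_position: int,
                 ranges=ScoreWeights().hotspot_ranges) -> bool:
    """True when the 1-based residue lies within a known GoF hotspot
    interval (inclusive bounds)."""
    if protein_position < 1:
        raise ValueError("protein position must be >= 1")
    return any(lo <= protein_position <= hi for lo, hi in ranges)


#: Width of the graded-credit window: partial credit is given for p-values
#: within this factor above alpha (on the log scale), none beyond it.
GRADED_WINDOW = 5.0


def _grade(p: float, alpha: float, window: float = GRADED_WINDOW) -> float:
    """Continuous significance factor in [0, 1].

    Full credit at p <= alpha, ramping linearly on the log-p scale down to
    zero at p = window * alpha.  Clearly null p-values therefore contribute
    nothing (unlike a ramp anchored at p = 1, which hands substantial
    partial credit to chance-level associations), while the score remains
    continuous through the significance boundary.
    """
    if not np.isfinite(p) or p <= 0:
        return 1.0
    if p >= window * alpha:
        return 0.0
    return min(1.0, np.log(window * alpha / p) / np.log(window))


def _assoc_component(result, weight: float, direction: int,
                     alpha: float, mode: str) -> float:
    """Direction-gated component value for a quantitative association."""
    if result is None:
        logger.debug("missing association result; component scored 0")
        return 0.0
    beta, p = result[0], result[2]
    if direction * beta <= 0:
        return 0.0
    if mode == "binary":
        return weight if p <= alpha else 0.0
    return weight * _grade(p, alpha)


def calcium_subscore(beta: float, p: float, weights: ScoreWeights,
                     mode: str = "binary") -> float:
    """Fires only for calcium-*lowering* association (GoF direction)."""
    return _assoc_component((beta, None, p), weights.w_calcium, -1,
                            weights.nominal_alpha, mode)


def phosphate_subscore(beta: float, p: float, weights: ScoreWeights,
                       mode: str = "binary") -> float:
    """Fires only for phosphate-*raising* association."""
    return _assoc_component((beta, None, p), weights.w_phosphate, +1,
                            weights.nominal_alpha, mode)


def insilico_subscore(fraction_deleterious: float, weights: ScoreWeights,
                      mode: str = "binary") -> float:
    """Binary: strict-majority deleterious consensus; graded: weight times
    the ensemble fraction itself."""
    if fraction_deleterious is None or not np.isfinite(fraction_deleterious):
        return 0.0
    if not 0.0 <= fraction_deleterious <= 1.0:
        raise ValueError("fraction_deleterious must be in [0, 1]")
    if mode == "binary":
        return weights.w_insilico if fraction_deleterious > 0.5 else 0.0
    return weights.w_insilico * fraction_deleterious


def _binary_component(any_carrier: bool, p: float, weight: float,
                      alpha: float, mode: str) -> float:
    if not any_carrier:
        return 0.0
    if mode == "binary":
        return weight if p <= alpha else 0.0
    return weight * _grade(p, alpha)


def dx_medication_subscores(carrier_phenotypes, enrichment_p: dict,
                            weights: ScoreWeights, mode: str = "binary"):
    """Diagnosis-category and medication components from carrier phenotypes.

    ``carrier_phenotypes`` is a list of :class:`~adh1score.phenotypes.PhenotypeVector`
    for the variant's carriers; ``enrichment_p`` maps each diagnosis
    category (and ``"medication"``) to its carrier-enrichment Fisher p.  A
    category scores its weight iff at least one carrier exhibits it AND the
    enrichment is significant at the nominal alpha.
    """
    if not carrier_phenotypes:
        raise ValueError("carrier list must be non-empty")
    alpha = weights.nominal_alpha
    dx = {}
    for cat in DX_CATEGORIES:
        any_carrier = any(pv.adh1_phecode_flags.get(cat, False)
                          for pv in carrier_phenotypes)
        dx[cat] = _binary_component(any_carrier, enrichment_p.get(cat, 1.0),
                                    weights.w_dx_category, alpha, mode)
    any_med = any(pv.adh1_medication_count >= 1 for pv in carrier_phenotypes)
    medication = _binary_component(any_med, enrichment_p.get("medication", 1.0),
                                   weights.w_medication, alpha, mode)
    return dx, medication


# ---------------------------------------------------------------------------
# cohort-level scoring
# ---------------------------------------------------------------------------

def hard_filter(variants: pd.DataFrame, stratum: str,
                maf_cutoff: float = 0.01) -> pd.Series:
    """Candidate mask: protein-altering consequence and rare in the stratum
    (0 < MAF < cutoff).  Sequencing-QC filters are assumed applied upstream."""
    ok_cons = variants["consequence"].isin(["missense", "nonsense", "frameshift"])
    maf = variants[f"maf_{stratum}"]
    return ok_cons & (maf > 0) & (maf < maf_cutoff)


def score_cohort(variants: pd.DataFrame, individuals: pd.DataFrame,
                 phenotypes: pd.DataFrame, weights: ScoreWeights | None = None,
                 mode: str = "binary", maf_cutoff: float = 0.01,
                 apply_hard_filter: bool = False,
                 collect_associations: bool = False):
    """Score every variant in every stratum where it has carriers.

    Returns ``(scores, associations)``: ``scores`` has one row per
    (variant, stratum) with each sub-score component, the stratum total,
    and the variant-level score (max across strata); ``associations`` (when
    requested) holds the underlying per-phenotype statistics.

    With ``apply_hard_filter`` the consequence/MAF candidate filter is
    applied first; leave it off to score synonymous variants for null
    calibration.
    """
    if weights is None:
        weights = ScoreWeights()
    if mode not in ("binary", "graded"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    alpha = weights.nominal_alpha
    pcs = [f"pc{i}" for i in range(1, 11)]

    phen = phenotypes.set_index("individual_id")
    rows: list[dict] = []
    assoc_rows: list[dict] = []

    for stratum, ind_s in individuals.groupby("stratum", sort=True):
        maf_col = f"maf_{stratum}"
        in_stratum = variants[maf_col] > 0
        cand = variants[in_stratum & (variants[maf_col] < maf_cutoff)]
        if apply_hard_filter:
            cand = cand[hard_filter(variants, stratum, maf_cutoff)[cand.index]]
        if cand.empty:
            continue

        ind_s = ind_s.reset_index(drop=True)
        id_to_row = {iid: i for i, iid in enumerate(ind_s["individual_id"])}
        cov = np.column_stack(
            [np.ones(len(ind_s)), ind_s["age"].to_numpy(dtype=float),
             (ind_s["sex"] == "female").to_numpy(dtype=float)]
            + [ind_s[c].to_numpy(dtype=float) for c in pcs]
        )

        labs = {}
        for lab, direction, weight in (("calcium", -1, weights.w_calcium),
                                       ("phosphate", +1, weights.w_phosphate)):
            vals = ind_s[lab].to_numpy(dtype=float)
            measured = np.flatnonzero(~np.isnan(vals))
            ols = CarrierOLS(vals[measured], cov[measured]) if len(measured) else None
            pos_of = np.full(len(ind_s), -1)
            pos_of[measured] = np.arange(len(measured))
            labs[lab] = (ols, pos_of, direction, weight)

        phen_s = phen.loc[ind_s["individual_id"]]
        cat_flags = {cat: phen_s[f"cat_{cat}"].to_numpy(dtype=bool)
                     for cat in DX_CATEGORIES}
        med_flag = (phen_s["adh1_medication_count"] >= 1).to_numpy(dtype=bool)
        n_total = len(ind_s)
        cat_totals = {cat: int(cat_flags[cat].sum()) for cat in DX_CATEGORIES}
        med_total = int(med_flag.sum())

        for _, var in cand.iterrows():
            carriers = [id_to_row[c] for c in var["carriers"].split(",")
                        if c in id_to_row]
            if not carriers:
                continue
            carriers = np.array(carriers, dtype=int)
            ssv = SubScoreVector(variant_id=var["variant_id"], stratum=stratum)

            for lab, (ols, pos_of, direction, weight) in labs.items():
                res = None
                if ols is not None:
                    cpos = pos_of[carriers]
                    cpos = cpos[cpos >= 0]
                    if len(cpos):
                        res = ols.carrier_beta(cpos)
                value = _assoc_component(res, weight, direction, alpha, mode)
                if lab == "calcium":
                    ssv.calcium = value
                else:
                    ssv.phosphate = value
                if collect_associations and res is not None:
                    assoc_rows.append({
                        "variant_id": var["variant_id"], "stratum": stratum,
                        "phenotype": lab, "kind": "quantitative",
                        "beta": res[0], "se": res[1], "p_value": res[2],
                        "n_carriers": len(carriers), "method": "ols",
                    })

            k = len(carriers)
            for cat in DX_CATEGORIES:
                a = int(cat_flags[cat][carriers].sum())
                c = cat_totals[cat] - a
                p = _fisher_cached(a, k - a, c, n_total - k - c) if a else 1.0
                ssv.dx[cat] = _binary_component(a >= 1, p, weights.w_dx_category,
                                                alpha, mode)
                if collect_associations and a:
                    assoc_rows.append({
                        "variant_id": var["variant_id"], "stratum": stratum,
                        "phenotype": f"dx_{cat}", "kind": "binary",
                        "beta": np.nan, "se": np.nan, "p_value": p,
                        "n_carriers": k, "method": "fisher",
                    })
            a = int(med_flag[carriers].sum())
            c = med_total - a
            p = _fisher_cached(a, k - a, c, n_total - k - c) if a else 1.0
            ssv.medication = _binary_component(a >= 1, p, weights.w_medication,
                                               alpha, mode)

            if hotspot_flag(int(var["protein_position"]), weights.hotspot_ranges):
                ssv.hotspot = weights.w_hotspot
            ssv.insilico = insilico_subscore(
                float(var["insilico_fraction_deleterious"]), weights, mode)
            rows.append(ssv.as_row())

    scores = pd.DataFrame(rows, columns=["variant_id", "stratum"] + COMPONENT_COLUMNS + ["total"])
    if len(scores):
        scores["variant_score"] = scores.groupby("variant_id")["total"].transform("max")
    else:
        scores["variant_score"] = pd.Series(dtype=float)
    associations = pd.DataFrame(assoc_rows) if collect_associations else None
    return scores, associations


def adh1_score(variant_row: pd.Series, subscores: list[SubScoreVector]) -> float:
    """Variant-level ADH1 score: the maximum stratum total.

    Raises when the variant has no scored stratum (no carriers anywhere).
    """
    if not subscores:
        raise ValueError(f"variant {variant_row['variant_id']} has no carriers in any stratum")
    return max(s.total for s in subscores)
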