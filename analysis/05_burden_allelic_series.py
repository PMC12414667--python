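#!/usr/bin/env python
"""Penetrance, carrier frequency, excess symptom burden, and the allelic
series of calcium effects.

Takes the above-threshold novel candidates from the calibrated score,
estimates their carrier frequency per 100,000, lab- and diagnosis-based
penetrance, and the excess number of diagnosed carriers over the
non-carrier baseline; summarizes the calcium allelic series by class.
"""

import json

import pandas as pd

import common
from adh1score import burden
from adh1score import io as aio
from adh1score import phenotypes

scores = pd.read_csv(common.PIPELINE_DIR / "scores_graded.tsv", sep="\t")
assoc = pd.read_csv(common.PIPELINE_DIR / "associations.tsv", sep="\t")
variants = aio.read_variant_table(common.COHORT_DIR / "variants.tsv")
individuals = aio.read_individual_table(common.COHORT_DIR / "individuals.tsv")
truth = aio.read_truth_table(common.COHORT_DIR / "truth.tsv")
threshold = json.loads(
    (common.RESULTS / "04_calibration.json").read_text())["empirical"]["threshold"]

phen = phenotypes.build_phenotypes(individuals)
var_level = (scores.drop_duplicates("variant_id")[["variant_id", "variant_score"]]
             .merge(variants, on="variant_id"))
coding = var_level["consequence"].isin(["missense", "nonsense", "frameshift"])
novel_hits = var_level[coding & (var_level["variant_score"] > threshold)
                       & (var_level["known_status"] == "novel")]

cohort_n = len(individuals)
hit_carriers = sorted({c for s in novel_hits["carriers"] for c in s.split(",") if c})
all_scored = {c for s in var_level.loc[coding, "carriers"]
              for c in s.split(",") if c}

phen_idx = phen.set_index("individual_id")
carrier_phen = phen_idx.loc[hit_carriers].reset_index()
carrier_cal = individuals.set_index("individual_id").loc[hit_carriers, "calcium"]
baseline = burden.baseline_phenotype_rate(phen, all_scored)
observed = int(carrier_phen["dx_suggestive"].sum())
est = burden.excess_burden(observed, len(hit_carriers), baseline, cohort_n)

report = {
    "threshold": threshold,
    "n_candidate_variants": int(len(novel_hits)),
    "n_carriers": len(hit_carriers),
    "cohort_n": cohort_n,
    "frequency_per_100k": round(est.frequency_per_100k, 2),
    "lab_penetrance_hypocalcemia": round(
        burden.lab_penetrance(carrier_cal.tolist(), 2.2, "below"), 4),
    "dx_penetrance": round(burden.dx_penetrance(carrier_phen), 4),
    "baseline_dx_rate": round(baseline, 5),
    "observed_affected": est.observed_affected,
    "expected_affected": round(est.expected_affected, 2),
    "excess": round(est.excess, 2),
    "excess_per_100k": round(est.excess_per_100k, 3),
}
(common.RESULTS / "05_burden.json").write_text(json.dumps(report, indent=2) + "\n")

# allelic series: best-stratum calcium beta per variant, class from truth/score
cal = (assoc[assoc["phenotype"] == "calcium"]
       .sort_values(["variant_id", "p_value"]).drop_duplicates("variant_id"))
cls_map = truth.set_index("variant_id")["class_label"]
maf_cols = [c for c in variants.columns if c.startswith("maf_")]
maf = variants.set_index("variant_id")[maf_cols].max(axis=1)
series = pd.DataFrame({
    "variant_id": cal["variant_id"],
    "series_class": cal["variant_id"].map(cls_map),
    "calcium_beta": cal["beta"].to_numpy(),
    "maf": cal["variant_id"].map(maf),
})
summary = burden.allelic_series_summary(series)
summary.to_csv(common.RESULTS / "05_allelic_series.tsv", sep="\t", index=False,
               float_format="%.4g")

print(f"{len(novel_hits)} novel candidate variants above threshold "
      f"{threshold:.2f}; {len(hit_carriers)} carriers "
      f"({report['frequency_per_100k']} per 100,000)")
print(f"  hypocalcemia penetrance among carriers: "
      f"{report['lab_penetrance_hypocalcemia']:.0%}; diagnosis-code "
      f"penetrance: {report['dx_penetrance']:.0%} (underdiagnosis gap)")
print(f"  excess diagnosed carriers over baseline ({baseline:.2%}): "
      f"{report['excess']} ({report['excess_per_100k']} per 100,000)")
print("allelic series (median calcium beta by class):")
print(summary.to_string(index=False))
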