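#!/usr/bin/env python
"""Replicate-level operating characteristics of the calibrated score.

Self-contained Monte-Carlo studies (independent of the 01-05 cohort):
held-out specificity of the 98th-percentile threshold, and pooled
sensitivity for established-pathogenic-scale GoF variants across replicate
cohorts.  A reduced-replicate version of what scripts/acceptance.py
computes at full scale.
"""

import json

import common
from adh1score import evaluation

spec = evaluation.specificity_study(seed=common.SEED)
sens = evaluation.sensitivity_study(seed=common.SEED, n_replicates=12)

report = {"specificity_study": spec, "sensitivity_study": sens}
out = common.RESULTS / "06_operating_characteristics.json"
out.write_text(json.dumps(report, indent=2) + "\n")

print(f"held-out specificity: {spec['specificity']:.3f} "
      f"(target percentile 0.98; threshold {spec['threshold']:.3f}, "
      f"n={spec['n_heldout']})")
print(f"pooled sensitivity for known-scale GoF variants: "
      f"{sens['sensitivity']:.3f} over {sens['n_replicates']} replicates "
      f"({sens['n_positives']} positives)")
print(f"report: {out}")
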