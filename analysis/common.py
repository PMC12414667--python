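"""Shared paths and the analysis operating point for the numbered drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
COHORT_DIR = SCRATCH / "cohort"
PIPELINE_DIR = SCRATCH / "pipeline"

SEED = 17
N_PER_STRATUM = 30_000
STRATA = ("EUR", "SAS")
N_SYNONYMOUS = 800
N_NEUTRAL = 100
SCORE_MODE = "graded"   # continuous null -> calibrated percentile threshold
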