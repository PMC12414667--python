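"""End-to-end driver: phenotypes -> associations -> scores -> threshold -> burden.

``run_pipeline`` consumes a fixture directory (the layout written by
:func:`adh1score.simulate.write_fixture`) plus a :class:`~adh1score.io.RunConfig`
and writes every stage output with a manifest of checksums, so reruns with
the same inputs, config, and seed are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .burden import (
    allelic_series_summary,
    baseline_phenotype_rate,
    carrier_frequency,
    dx_penetrance,
    excess_burden,
    lab_penetrance,
)
from .calibration import build_null, resolve_threshold
from .io import RunConfig, read_individual_table, read_variant_table
from .phenotypes import build_phenotypes
from .scoring import score_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _apply_measurement_policy(individuals: pd.DataFrame, labs_long: pd.DataFrame,
                              policy: str) -> pd.DataFrame:
    """Collapse long-format repeated labs into the individual table columns."""
    from .phenotypes import collapse_measurements
    individuals = individuals.copy()
    ordered = labs_long.sort_values("date", kind="stable")
    for lab in ("calcium", "phosphate"):
        sub = ordered[ordered["lab"] == lab]
        collapsed = sub.groupby("individual_id")["value"].agg(
            lambda v: collapse_measurements(list(v), policy))
        individuals[lab] = individuals["individual_id"].map(collapsed)
    return individuals


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory.

    Outputs: ``phenotypes.tsv``, ``associations.tsv``, ``scores.tsv``,
    ``calibration.json`` (+ ``null_draws.tsv``), ``burden.json``,
    ``allelic_series.tsv``, and ``manifest.json``.  Output is a pure
    function of (fixture, config, seed).
    """
    fixture = Path(config.fixture_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    variants_path = fixture / "variants.tsv"
    if not variants_path.exists():
        variants_path = fixture / "variants.vcf"
    variants = read_variant_table(variants_path)
    individuals = read_individual_table(fixture / "individuals.tsv")
    labs_long_path = fixture / "labs_long.tsv"
    if labs_long_path.exists():
        individuals = _apply_measurement_policy(
            individuals, pd.read_csv(labs_long_path, sep="\t"),
            config.measurement_policy)
    logger.info("inputs: %d variants, %d individuals", len(variants), len(individuals))

    # -- phenotype mapping ---------------------------------------------------
    phen = build_phenotypes(individuals, lln=config.lln_calcium,
                            uln=config.uln_phosphate)
    phen_out = phen.copy()
    phen_out["phecodes"] = [";".join(sorted(p)) for p in phen_out["phecodes"]]
    _write(phen_out, out / "phenotypes.tsv")

    # -- association + scoring ----------------------------------------------
    weights = config.score_weights()
    scores, assoc = score_cohort(
        variants, individuals, phen, weights=weights, mode=config.score_mode,
        maf_cutoff=config.maf_cutoff, collect_associations=True,
    )
    logger.info("scored %d variant-stratum pairs", len(scores))
    _write(assoc, out / "associations.tsv")
    _write(scores, out / "scores.tsv")

    # -- threshold calibration ------------------------------------------------
    syn_ids = set(variants.loc[variants["consequence"] == "synonymous", "variant_id"])
    syn_scores = scores[scores["variant_id"].isin(syn_ids)]
    null = None
    if config.threshold_mode == "empirical":
        null = build_null(syn_scores, B=config.n_null_draws,
                          percentile=config.percentile, seed=config.seed,
                          mode=config.null_resampling)
        pd.DataFrame({"draw": null.draws}).to_csv(
            out / "null_draws.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    threshold_info = resolve_threshold(config.threshold_mode, null)
    threshold = threshold_info["threshold"]
    (out / "calibration.json").write_text(json.dumps(threshold_info, indent=2, sort_keys=True))
    logger.info("threshold (%s mode): %.4g", config.threshold_mode, threshold)

    # -- burden + allelic series ----------------------------------------------
    variant_level = (scores.drop_duplicates("variant_id")
                     [["variant_id", "variant_score"]]
                     .merge(variants[["variant_id", "consequence", "known_status",
                                      "n_carriers", "carriers"]], on="variant_id"))
    coding = variant_level["consequence"].isin(["missense", "nonsense", "frameshift"])
    above = variant_level["variant_score"] > threshold
    novel_hits = variant_level[coding & above
                               & (variant_level["known_status"] == "novel")]

    cohort_n = len(individuals)
    hit_carriers: set[str] = set()
    for c in novel_hits["carriers"]:
        hit_carriers.update(c.split(","))
    hit_carriers.discard("")

    all_scored_carriers: set[str] = set()
    for c in variant_level.loc[coding, "carriers"]:
        all_scored_carriers.update(c.split(","))
    all_scored_carriers.discard("")

    phen_idx = phen.set_index("individual_id")
    carrier_phen = phen_idx.loc[sorted(hit_carriers & set(phen_idx.index))].reset_index()
    carrier_cal = individuals.set_index("individual_id").loc[
        sorted(hit_carriers & set(phen_idx.index)), "calcium"]

    burden_report = {
        "threshold": threshold,
        "n_candidate_variants": int(len(novel_hits)),
        "n_carriers": len(hit_carriers),
        "cohort_n": cohort_n,
        "frequency_per_100k": carrier_frequency(len(hit_carriers), cohort_n)
        if hit_carriers else 0.0,
        "lab_penetrance_hypocalcemia": lab_penetrance(
            carrier_cal.tolist(), config.lln_calcium, "below") if len(carrier_cal) else None,
        "dx_penetrance": dx_penetrance(carrier_phen) if len(carrier_phen) else None,
    }
    if hit_carriers:
        baseline = baseline_phenotype_rate(phen, all_scored_carriers)
        observed = int(carrier_phen["dx_suggestive"].sum())
        est = excess_burden(observed, len(hit_carriers), baseline, cohort_n)
        burden_report.update({
            "baseline_dx_rate": baseline,
            "observed_affected": est.observed_affected,
            "expected_affected": est.expected_affected,
            "excess": est.excess,
            "excess_per_100k": est.excess_per_100k,
            "raw_excess": est.raw_excess,
        })
    (out / "burden.json").write_text(json.dumps(burden_report, indent=2, sort_keys=True))

    series = _allelic_series_table(variants, assoc, variant_level, threshold)
    _write(allelic_series_summary(series), out / "allelic_series.tsv")
    _write(series, out / "allelic_series_variants.tsv")

    from . import __version__ as pkg_version
    manifest = {
        "package_version": pkg_version,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()).hexdigest(),
        "outputs": {},
    }
    for f in sorted(out.glob("*")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _allelic_series_table(variants: pd.DataFrame, assoc: pd.DataFrame,
                          variant_level: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Boxplot-ready allelic-series table: one row per variant with its
    series class, best-stratum calcium beta, and maximum stratum MAF."""
    cal = assoc[assoc["phenotype"] == "calcium"]
    best = (cal.sort_values(["variant_id", "p_value"])
            .drop_duplicates("variant_id")[["variant_id", "beta"]]
            .rename(columns={"beta": "calcium_beta"}))
    maf_cols = [c for c in variants.columns if c.startswith("maf_")]
    maf = variants[["variant_id"]].copy()
    maf["maf"] = variants[maf_cols].max(axis=1)

    df = (variant_level[["variant_id", "variant_score", "known_status", "consequence"]]
          .merge(best, on="variant_id", how="left")
          .merge(maf, on="variant_id", how="left"))

    def classify(row):
        if row["known_status"] == "known_adh1":
            return "known_adh1"
        if row["known_status"] == "known_fhh1":
            return "known_fhh1"
        if row["consequence"] in ("missense", "nonsense", "frameshift") \
                and row["variant_score"] > threshold:
            return "score_gt_threshold"
        return "below_threshold"

    df["series_class"] = df.apply(classify, axis=1)
    return df[["variant_id", "series_class", "calcium_beta", "maf", "variant_score"]]
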