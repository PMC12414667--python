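"""Readers, writers, run configuration, and relatedness exclusion.

Variant tables are accepted either as the documented TSV schema or as VCF
(coordinates 1-based, annotations in INFO); individual tables are TSV.
Everything round-trips losslessly against :func:`adh1score.simulate.write_fixture`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger(__name__)

_VARIANT_REQUIRED = [
    "variant_id", "chrom", "pos", "ref", "alt", "consequence",
    "protein_position", "known_status", "insilico_fraction_deleterious",
    "n_carriers", "carriers",
]
_PROTEIN_CODING = ("missense", "nonsense", "frameshift")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant table from TSV or VCF, validating the schema.

    Ref/alt alleles are normalized to uppercase; duplicate variant ids are
    rejected; protein-coding consequences must carry a positive 1-based
    protein position.  Errors name the offending line numbers.
    """
    path = Path(path)
    if path.suffix == ".vcf" or str(path).endswith(".vcf.gz"):
        df = _read_variant_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "carriers": str})
        df["carriers"] = df["carriers"].fillna("")
    missing = [c for c in _VARIANT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} missing columns: {missing}")
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    dup = df["variant_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate variant ids at lines {[int(i) + 2 for i in df.index[dup]]}"
        )
    coding = df["consequence"].isin(_PROTEIN_CODING)
    bad = coding & (df["protein_position"].isna() | (df["protein_position"] < 1))
    if bad.any():
        raise ValueError(
            "protein-coding rows without a valid protein_position at lines "
            f"{[int(i) + 2 for i in df.index[bad]]}"
        )
    df["protein_position"] = df["protein_position"].astype(int)
    return df


_VCF_INFO_FIELDS = [
    ("CSQ", "String", "Consequence class"),
    ("PPOS", "Integer", "1-based protein residue position"),
    ("KNOWN", "String", "known_adh1|known_fhh1|novel"),
    ("FDEL", "Float", "Fraction of in-silico predictor ensemble calling deleterious"),
    ("NCARR", "Integer", "Number of heterozygous carriers"),
    ("CARRIERS", "String", "Comma-separated carrier individual ids"),
]


def write_variant_vcf(variants: pd.DataFrame, path: str | Path,
                      strata: list[str]) -> Path:
    """Write the variant table as a minimal, valid VCF 4.2 with annotations
    in INFO (per-stratum frequencies as ``AF_<stratum>``)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##contig=<ID=3,length=198295559>"]
    for name, typ, desc in _VCF_INFO_FIELDS:
        lines.append(f'##INFO=<ID={name},Number=1,Type={typ},Description="{desc}">')
    for s in strata:
        lines.append(f'##INFO=<ID=AF_{s},Number=1,Type=Float,'
                     f'Description="Minor allele frequency in stratum {s}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for _, row in variants.iterrows():
        info = [
            f"CSQ={row['consequence']}",
            f"PPOS={int(row['protein_position'])}",
            f"KNOWN={row['known_status']}",
            f"FDEL={row['insilico_fraction_deleterious']:.6g}",
            f"NCARR={int(row['n_carriers'])}",
            f"CARRIERS={row['carriers']}" if row["carriers"] else "CARRIERS=.",
        ]
        for s in strata:
            info.append(f"AF_{s}={row[f'maf_{s}']:.8g}")
        lines.append("\t".join([
            str(row["chrom"]), str(int(row["pos"])), row["variant_id"],
            row["ref"], row["alt"], ".", "PASS", ";".join(info),
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path


def _read_variant_vcf(path: Path) -> pd.DataFrame:
    rows = []
    strata: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        strata = [k[3:] for k in vcf.header.info.keys() if k.startswith("AF_")]
        for rec in vcf:
            carriers = rec.info.get("CARRIERS", ".")
            if isinstance(carriers, tuple):
                # pysam splits comma-separated String INFO values
                carriers = ",".join(carriers)
            row = {
                "variant_id": rec.id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "consequence": rec.info.get("CSQ"),
                "protein_position": int(rec.info.get("PPOS", 0)),
                "known_status": rec.info.get("KNOWN"),
                "insilico_fraction_deleterious": float(rec.info.get("FDEL", np.nan)),
                "n_carriers": int(rec.info.get("NCARR", 0)),
                "carriers": "" if carriers in (".", None) else carriers,
            }
            for s in strata:
                row[f"maf_{s}"] = float(rec.info.get(f"AF_{s}", 0.0))
            rows.append(row)
    cols = _VARIANT_REQUIRED + [f"maf_{s}" for s in strata]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# individual / auxiliary tables
# ---------------------------------------------------------------------------

def read_individual_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "stratum": str})
    required = {"individual_id", "stratum", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"individual table {path} missing columns: {sorted(missing)}")
    for col in ("icd10_codes", "medications"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# relatedness exclusion
# ---------------------------------------------------------------------------

def exclude_relatives(pairs: pd.DataFrame, individual_ids,
                      cutoff: float = 0.0884) -> set[str]:
    """Greedy removal of close relatives from kinship pairs.

    ``pairs`` has columns ``id1``, ``id2``, ``kinship``.  While any retained
    pair exceeds the cutoff (0.0884 is the standard KING second-degree
    boundary), the member with the most above-cutoff partners is removed
    (ties broken by lexicographic id, so hubs of star families go first and
    the result is deterministic).  No retained pair exceeds the cutoff on
    return.
    """
    if (pairs["id1"] == pairs["id2"]).any():
        raise ValueError("kinship table contains self-pairs")
    retained = set(individual_ids)
    over = pairs[pairs["kinship"] > cutoff]
    adj: dict[str, set[str]] = {}
    for i1, i2 in zip(over["id1"], over["id2"]):
        adj.setdefault(i1, set()).add(i2)
        adj.setdefault(i2, set()).add(i1)
    active = {k: set(v) for k, v in adj.items() if k in retained}
    for k in active:
        active[k] &= retained
    while True:
        live = {k: v for k, v in active.items() if v}
        if not live:
            break
        victim = min(live, key=lambda k: (-len(live[k]), k))
        retained.discard(victim)
        for other in live[victim]:
            active[other].discard(victim)
        active.pop(victim, None)
    return retained


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Constants default to the analysis operating point: LLN calcium 2.2 mM,
    ULN phosphate 1.45 mM, MAF cutoff 0.01, nominal alpha 0.05, 98th
    percentile null with B = 10,000 draws, KING kinship exclusion at
    0.0884.
    """

    fixture_dir: str
    output_dir: str
    seed: int
    lln_calcium: float = 2.2
    uln_phosphate: float = 1.45
    maf_cutoff: float = 0.01
    nominal_alpha: float = 0.05
    percentile: float = 98.0
    n_null_draws: int = 10_000
    kinship_exclusion_cutoff: float = 0.0884
    score_mode: str = "binary"            # binary | graded
    null_resampling: str = "independent"  # independent | joint
    threshold_mode: str = "empirical"     # empirical | fixed
    measurement_policy: str = "mean"      # mean | first
    # optional overrides of the sub-score weights / hotspot ranges, keyed by
    # the ScoreWeights field names (w_calcium, hotspot_ranges, ...)
    weights: dict = field(default_factory=dict)

    def score_weights(self):
        from .scoring import ScoreWeights
        overrides = dict(self.weights)
        if "hotspot_ranges" in overrides:
            overrides["hotspot_ranges"] = tuple(
                tuple(r) for r in overrides["hotspot_ranges"])
        return ScoreWeights(nominal_alpha=self.nominal_alpha, **overrides)

    def __post_init__(self) -> None:
        self.score_weights()  # validates weight overrides eagerly
        for name in ("lln_calcium", "uln_phosphate", "maf_cutoff",
                     "nominal_alpha", "percentile", "n_null_draws",
                     "kinship_exclusion_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.score_mode not in ("binary", "graded"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        if self.null_resampling not in ("independent", "joint"):
            raise ValueError(f"unknown null_resampling {self.null_resampling!r}")
        if self.threshold_mode not in ("empirical", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.measurement_policy not in ("mean", "first"):
            raise ValueError(f"unknown measurement_policy {self.measurement_policy!r}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys before any stage runs."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = {"fixture_dir", "output_dir", "seed"} - set(raw)
    if missing:
        raise ValueError(f"config missing required keys: {sorted(missing)}")
    return RunConfig(**raw)
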