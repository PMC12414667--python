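"""Synthetic biobank generator with a known *CASR*-like allelic series.

The generator emulates the genotype-phenotype architecture relevant to ADH1
discovery in a population biobank: rare variants with 1 to ~120 heterozygous
carriers each, carrier serum-calcium shifts spanning strong familial
gain-of-function effects (about -0.65 to -0.10 mM) down to intermediate
(~-0.1 mM) and null effects, phosphate shifts coupled in the opposite
direction (hyperphosphatemia co-occurs in roughly half of strongly
hypocalcemic carriers), threshold-driven diagnosis codes with incomplete
penetrance, and synonymous variants with exactly zero effect.  Ground truth
(class label and true shift per variant) is returned alongside the cohort so
that threshold calibration, sensitivity/specificity, and allelic-series
recovery can all be evaluated against a known answer.

Design notes
------------
* Carriers are heterozygous only by default; the realized per-stratum minor
  allele frequency is therefore exactly ``carriers / (2 * n_individuals)``.
* Diagnosis codes are conditioned on the *realized* serum calcium, not on the
  genotype: anyone whose biological calcium falls below the lower limit of
  normal may be diagnosed, carriers simply get there far more often.  This
  reproduces the empirical pattern that code-based penetrance lags lab-based
  penetrance.
* Serum labs are missing at random for a configurable fraction of
  individuals, emulating incomplete biochemistry/EHR lab coverage in real
  biobanks.
* For a fixed seed all outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# CaSR protein length (residues); hotspot intervals are 1-based inclusive.
CASR_PROTEIN_LENGTH = 1078
GOF_HOTSPOT_RANGES = ((116, 136), (819, 837))

# Lower/upper limits of normal used throughout (mM).
LLN_CALCIUM_MM = 2.2
ULN_PHOSPHATE_MM = 1.45

VALID_CLASSES = ("gof_known", "gof_intermediate", "lof", "neutral", "synonymous")

#: Per-variant (carrier calcium shift in mM, heterozygous carrier count)
#: pairs characteristic of previously reported ADH1 gain-of-function *CASR*
#: variants observed in large biobanks.  The set deliberately includes
#: weak-effect members (-0.10, -0.18, +0.12 mM): established pathogenic
#: variants are not uniformly strong in population data, and sensitivity
#: estimates are only honest when the positive class reflects that.
KNOWN_GOF_EFFECT_PROFILE = (
    (-0.24, 1),
    (-0.24, 3),
    (-0.19, 2),
    (-0.43, 1),
    (-0.10, 2),
    (-0.18, 1),
    (-0.23, 1),
    (-0.65, 1),
    (0.12, 1),
    (-0.23, 1),
    (-0.29, 2),
    (-0.34, 1),
    (-0.36, 1),
)

# ICD-10 code pools used when assigning diagnoses.  Keys of the first dict
# are the five ADH1-relevant phecode categories.
ADH1_ICD10_CODES = {
    "hypoparathyroidism": ("E20", "E20.8", "E20.9"),
    "calcium_phosphorus_disorder": ("E83.5",),
    "tetany": ("R29.0",),
    "paresthesia": ("R20.2",),
    "epilepsy": ("G40.3", "G40.9"),
}
BACKGROUND_ICD10_CODES = (
    "I10", "E11.9", "J45.9", "K21.0", "M54.5", "F32.9", "N39.0", "E78.0",
)

ADH1_MEDICATION_STRINGS = (
    "calcitriol 0.25mcg capsule",
    "alfacalcidol 1mcg",
    "colecalciferol 800iu tablet",
    "calcium carbonate 1.25g",
    "calcichew d3 tablet",
    "teriparatide 20mcg injection",
)
BACKGROUND_MEDICATION_STRINGS = (
    "aspirin 75mg", "atorvastatin 20mg", "metformin 500mg", "omeprazole 20mg",
)


@dataclass
class VariantClassSpec:
    """Specification of one simulated variant class.

    Parameters
    ----------
    class_label:
        One of ``gof_known``, ``gof_intermediate``, ``lof``, ``neutral``,
        ``synonymous``.
    n_variants:
        Number of variants to simulate in this class.
    carrier_count_range:
        Inclusive (low, high) range of heterozygous carrier counts.
    carrier_count_dist:
        ``"sfs"`` draws counts with probability proportional to 1/k (the
        neutral site-frequency spectrum, heavily weighted toward
        singletons), ``"uniform"`` draws uniformly.
    calcium_shift_mM:
        (mean, sd) of the per-variant carrier calcium shift.  Negative for
        gain-of-function classes, positive for loss-of-function, exactly
        zero for neutral/synonymous.
    phosphate_shift_mM:
        (mean, sd) of the phosphate shift a carrier receives when the
        variant's calcium shift equals -0.30 mM; the realized phosphate
        shift is scaled proportionally to the variant's calcium shift (and
        opposite in sign), reflecting that hyperphosphatemia tracks the
        severity of hypocalcemia.
    diagnosis_penetrance:
        Probability that a *hypocalcemic* carrier of this class receives an
        ADH1-suggestive diagnosis code.
    hotspot_fraction:
        Fraction of variants placed inside the known gain-of-function
        hotspot residue intervals; ``None`` positions residues uniformly
        (hotspots then occur at their ~3.7% chance rate).
    insilico_deleterious_prob:
        Probability that the in-silico predictor ensemble leans deleterious
        for a variant of this class.
    effect_table:
        Optional explicit list of (calcium shift, carrier count) pairs;
        variants cycle through it deterministically.  Overrides
        ``calcium_shift_mM`` and the carrier-count sampler.
    """

    class_label: str
    n_variants: int
    carrier_count_range: tuple[int, int] = (1, 30)
    carrier_count_dist: str = "sfs"
    calcium_shift_mM: tuple[float, float] = (0.0, 0.0)
    phosphate_shift_mM: tuple[float, float] = (0.0, 0.0)
    diagnosis_penetrance: float = 0.5
    hotspot_fraction: float | None = None
    insilico_deleterious_prob: float = 0.1
    effect_table: tuple[tuple[float, int], ...] | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in VALID_CLASSES:
            raise ValueError(f"unknown variant class {self.class_label!r}")
        lo, hi = self.carrier_count_range
        if lo < 1 or hi < lo:
            raise ValueError("carrier_count_range must be positive and ordered")
        mean, sd = self.calcium_shift_mM
        if sd < 0:
            raise ValueError("calcium shift sd must be non-negative")
        if self.class_label in ("neutral", "synonymous"):
            if self.effect_table is not None or mean != 0.0 or sd != 0.0:
                raise ValueError(f"{self.class_label} variants must have zero effect")
            if self.phosphate_shift_mM != (0.0, 0.0):
                raise ValueError(f"{self.class_label} variants must have zero effect")
        elif self.effect_table is None:
            if self.class_label.startswith("gof") and mean >= 0:
                raise ValueError("gain-of-function calcium shift must be negative")
            if self.class_label == "lof" and mean <= 0:
                raise ValueError("loss-of-function calcium shift must be positive")
        if not 0.0 <= self.diagnosis_penetrance <= 1.0:
            raise ValueError("diagnosis_penetrance must be in [0, 1]")
        if not 0.0 <= self.insilico_deleterious_prob <= 1.0:
            raise ValueError("insilico_deleterious_prob must be in [0, 1]")
        if self.hotspot_fraction is not None and not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ValueError("hotspot_fraction must be in [0, 1]")
        if self.consequence is None:
            self.consequence = "synonymous" if self.class_label == "synonymous" else "missense"


@dataclass
class LabBaseline:
    """Population baselines for the serum labs (mM).

    Defaults put ~2% of non-carriers below the 2.2 mM calcium LLN and ~3.5%
    above the 1.45 mM phosphate ULN, matching the tails seen in unselected
    biobank participants.
    """

    calcium_mean_mM: float = 2.385
    calcium_sd_mM: float = 0.09
    phosphate_mean_mM: float = 1.16
    phosphate_sd_mM: float = 0.16

    def __post_init__(self) -> None:
        if self.calcium_sd_mM <= 0 or self.phosphate_sd_mM <= 0:
            raise ValueError("lab baseline standard deviations must be positive")


@dataclass
class CovariateModel:
    """Linear effects of age, sex, and genetic PCs on the serum labs."""

    calcium_age: float = -5e-4      # mM per year
    calcium_female: float = 0.02    # mM, female vs male
    calcium_pc: float = 0.002       # mM per PC unit (same loading, all 10 PCs)
    phosphate_age: float = 5e-4
    phosphate_female: float = 0.05
    phosphate_pc: float = 0.0


@dataclass
class SimulationConfig:
    """Full description of one synthetic biobank."""

    n_individuals: int
    strata: tuple[str, ...]
    variant_classes: tuple[VariantClassSpec, ...]
    seed: int
    lab_baseline: LabBaseline = field(default_factory=LabBaseline)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    # Lab measurement coverage: fraction of individuals with a recorded value.
    calcium_measured_rate: float = 0.93
    phosphate_measured_rate: float = 0.85
    cystatin_measured_rate: float = 0.85
    # Diagnosis generation (conditional on realized hypocalcemia).
    dx_given_hypocalcemia: float = 0.5
    symptom_given_dx: float = 0.4
    background_dx_rates: dict = field(default_factory=lambda: {
        "hypoparathyroidism": 0.001,
        "calcium_phosphorus_disorder": 0.003,
        "tetany": 0.001,
        "paresthesia": 0.015,
        "epilepsy": 0.010,
    })
    med_given_dx: float = 0.6
    background_adh1_med_rate: float = 0.005
    background_med_rate: float = 0.4
    records_coverage_rate: float = 0.45
    # Repeated lab measurements (within-person variance is an assumption:
    # real within-person repeat variability is not well characterized here).
    n_lab_repeats: int = 1
    within_person_lab_sd: float = 0.05
    lln_calcium: float = LLN_CALCIUM_MM
    uln_phosphate: float = ULN_PHOSPHATE_MM

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if not self.strata:
            raise ValueError("at least one stratum is required")
        for spec in self.variant_classes:
            lo, hi = spec.carrier_count_range
            counts = [hi]
            if spec.effect_table is not None:
                counts = [k for _, k in spec.effect_table]
            if max(counts) > self.n_individuals:
                raise ValueError(
                    f"carrier count for class {spec.class_label!r} exceeds "
                    f"n_individuals={self.n_individuals}"
                )
        for name in ("calcium_measured_rate", "phosphate_measured_rate",
                     "cystatin_measured_rate", "dx_given_hypocalcemia",
                     "med_given_dx", "records_coverage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_lab_repeats < 1:
            raise ValueError("n_lab_repeats must be >= 1")


@dataclass
class Cohort:
    """A simulated cohort: variant table, individual table, and ground truth."""

    variants: pd.DataFrame
    individuals: pd.DataFrame
    truth: pd.DataFrame
    labs_long: pd.DataFrame | None
    config: SimulationConfig


def _sample_carrier_counts(rng: np.random.Generator, spec: VariantClassSpec) -> np.ndarray:
    lo, hi = spec.carrier_count_range
    ks = np.arange(lo, hi + 1)
    if spec.carrier_count_dist == "sfs":
        w = 1.0 / ks
    elif spec.carrier_count_dist == "uniform":
        w = np.ones_like(ks, dtype=float)
    else:
        raise ValueError(f"unknown carrier_count_dist {spec.carrier_count_dist!r}")
    return rng.choice(ks, size=spec.n_variants, p=w / w.sum())


def _sample_protein_positions(rng: np.random.Generator, spec: VariantClassSpec) -> np.ndarray:
    n = spec.n_variants
    if spec.hotspot_fraction is None:
        return rng.integers(1, CASR_PROTEIN_LENGTH + 1, size=n)
    hotspot_residues = np.concatenate(
        [np.arange(lo, hi + 1) for lo, hi in GOF_HOTSPOT_RANGES]
    )
    outside = np.setdiff1d(np.arange(1, CASR_PROTEIN_LENGTH + 1), hotspot_residues)
    in_hot = rng.random(n) < spec.hotspot_fraction
    pos = np.empty(n, dtype=int)
    pos[in_hot] = rng.choice(hotspot_residues, size=int(in_hot.sum()))
    pos[~in_hot] = rng.choice(outside, size=int((~in_hot).sum()))
    return pos


def _sample_insilico_fraction(rng: np.random.Generator, spec: VariantClassSpec) -> np.ndarray:
    """Fraction of an in-silico predictor ensemble calling the variant
    deleterious.  A continuous mixture of two Beta distributions: with
    probability ``insilico_deleterious_prob`` the ensemble leans deleterious
    (Beta(8, 2), mostly above 0.5), otherwise benign (Beta(2, 8))."""
    deleterious = rng.random(spec.n_variants) < spec.insilico_deleterious_prob
    frac = rng.beta(2.0, 8.0, size=spec.n_variants)
    frac[deleterious] = rng.beta(8.0, 2.0, size=int(deleterious.sum()))
    return frac


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a biobank cohort with known ground truth.

    Returns a :class:`Cohort` whose ``variants`` table carries per-stratum
    minor-allele frequencies, carrier lists, consequence class, protein
    position, and the in-silico ensemble summary; whose ``individuals`` table
    carries demographics, 10 genetic PCs, serum labs (NaN when unmeasured),
    ICD-10 codes, and free-text medication strings; and whose ``truth`` table
    maps every variant to its class and true calcium shift.
    """
    rng = np.random.default_rng(config.seed)
    strata = list(config.strata)
    n = config.n_individuals
    base = config.lab_baseline
    cov = config.covariate_model

    # ---- individuals ------------------------------------------------------
    frames = []
    per_stratum_index: dict[str, pd.Index] = {}
    for stratum in strata:
        ids = np.array([f"{stratum}_{i:06d}" for i in range(n)])
        age = rng.integers(40, 71, size=n).astype(float)
        female = rng.random(n) < 0.54
        pcs = rng.normal(0.0, 1.0, size=(n, 10))
        cystatin = np.exp(rng.normal(np.log(0.90), 0.15, size=n))
        cal_mean = (
            base.calcium_mean_mM
            + cov.calcium_age * (age - 55.0)
            + cov.calcium_female * female
            + cov.calcium_pc * pcs.sum(axis=1)
        )
        phos_mean = (
            base.phosphate_mean_mM
            + cov.phosphate_age * (age - 55.0)
            + cov.phosphate_female * female
            + cov.phosphate_pc * pcs.sum(axis=1)
        )
        cal = rng.normal(cal_mean, base.calcium_sd_mM)
        phos = rng.normal(phos_mean, base.phosphate_sd_mM)
        df = pd.DataFrame({
            "individual_id": ids,
            "stratum": stratum,
            "age": age,
            "sex": np.where(female, "female", "male"),
        })
        for j in range(10):
            df[f"pc{j + 1}"] = pcs[:, j]
        df["_calcium_latent"] = cal
        df["_phosphate_latent"] = phos
        df["cystatin_c"] = cystatin
        frames.append(df)
    individuals = pd.concat(frames, ignore_index=True)
    for stratum in strata:
        per_stratum_index[stratum] = individuals.index[individuals["stratum"] == stratum]

    # ---- variants ---------------------------------------------------------
    var_rows = []
    truth_rows = []
    cal_shift_per_ind = np.zeros(len(individuals))
    phos_shift_per_ind = np.zeros(len(individuals))
    dx_pen_per_ind = np.full(len(individuals), config.dx_given_hypocalcemia)
    is_carrier = np.zeros(len(individuals), dtype=bool)

    pos0 = 122_184_000  # arbitrary genomic anchor on chromosome 3
    bases = np.array(list("ACGT"))
    vidx = 0
    for spec in config.variant_classes:
        if spec.n_variants == 0:
            continue
        if spec.effect_table is not None:
            pairs = [spec.effect_table[i % len(spec.effect_table)]
                     for i in range(spec.n_variants)]
            shifts = np.array([s for s, _ in pairs])
            counts = np.array([k for _, k in pairs], dtype=int)
        else:
            counts = _sample_carrier_counts(rng, spec)
            mean, sd = spec.calcium_shift_mM
            if spec.class_label in ("neutral", "synonymous"):
                shifts = np.zeros(spec.n_variants)
            else:
                shifts = rng.normal(mean, sd, size=spec.n_variants)
                # class sign is part of the ground truth contract
                if spec.class_label.startswith("gof"):
                    shifts = -np.abs(shifts)
                else:
                    shifts = np.abs(shifts)
        ppos = _sample_protein_positions(rng, spec)
        insilico = _sample_insilico_fraction(rng, spec)
        home = rng.choice(len(strata), size=spec.n_variants)
        phos_mean, phos_sd = spec.phosphate_shift_mM

        for i in range(spec.n_variants):
            vidx += 1
            stratum = strata[home[i]]
            k = int(counts[i])
            carrier_pos = rng.choice(per_stratum_index[stratum], size=k, replace=False)
            shift = float(shifts[i])
            if spec.class_label in ("neutral", "synonymous"):
                phos_shift = 0.0
            else:
                # phosphate moves opposite to calcium, scaled to shift size
                phos_shift = float(-shift / 0.30 * phos_mean + rng.normal(0.0, phos_sd))
            cal_shift_per_ind[carrier_pos] += shift
            phos_shift_per_ind[carrier_pos] += phos_shift
            is_carrier[carrier_pos] = True
            dx_pen_per_ind[carrier_pos] = np.maximum(
                dx_pen_per_ind[carrier_pos], spec.diagnosis_penetrance
            )
            ref, alt = rng.choice(bases, size=2, replace=False)
            known_status = {
                "gof_known": "known_adh1",
                "lof": "known_fhh1",
            }.get(spec.class_label, "novel")
            row = {
                "variant_id": f"3:{pos0 + vidx * 7}:{ref}:{alt}",
                "chrom": "3",
                "pos": pos0 + vidx * 7,
                "ref": ref,
                "alt": alt,
                "consequence": spec.consequence,
                "protein_position": int(ppos[i]),
                "known_status": known_status,
                "insilico_fraction_deleterious": float(insilico[i]),
                "n_carriers": k,
                "carriers": ",".join(sorted(individuals.loc[carrier_pos, "individual_id"])),
            }
            for s in strata:
                row[f"maf_{s}"] = (k / (2.0 * n)) if s == stratum else 0.0
            var_rows.append(row)
            truth_rows.append({
                "variant_id": row["variant_id"],
                "class_label": spec.class_label,
                "true_calcium_shift": shift,
                "true_phosphate_shift": phos_shift,
            })

    variant_cols = [
        "variant_id", "chrom", "pos", "ref", "alt", "consequence",
        "protein_position", "known_status", "insilico_fraction_deleterious",
        "n_carriers", "carriers",
    ] + [f"maf_{s}" for s in strata]
    variants = pd.DataFrame(var_rows, columns=variant_cols)
    truth = pd.DataFrame(
        truth_rows,
        columns=["variant_id", "class_label", "true_calcium_shift", "true_phosphate_shift"],
    )

    # ---- realized labs ----------------------------------------------------
    cal_real = individuals["_calcium_latent"].to_numpy() + cal_shift_per_ind
    phos_real = individuals["_phosphate_latent"].to_numpy() + phos_shift_per_ind
    hypocalcemic = cal_real < config.lln_calcium

    m = len(individuals)
    cal_measured = rng.random(m) < config.calcium_measured_rate
    phos_measured = rng.random(m) < config.phosphate_measured_rate
    cys_measured = rng.random(m) < config.cystatin_measured_rate

    labs_long = None
    if config.n_lab_repeats > 1:
        nrep = config.n_lab_repeats
        cal_reps = cal_real[None, :] + rng.normal(0.0, config.within_person_lab_sd, size=(nrep, m))
        phos_reps = phos_real[None, :] + rng.normal(0.0, config.within_person_lab_sd, size=(nrep, m))
        rows = []
        ids_arr = individuals["individual_id"].to_numpy()
        for lab, reps, mask in (("calcium", cal_reps, cal_measured),
                                ("phosphate", phos_reps, phos_measured)):
            for i in np.flatnonzero(mask):
                for r in range(nrep):
                    rows.append((ids_arr[i], lab, float(reps[r, i]), f"2015-{r + 1:02d}-01"))
        labs_long = pd.DataFrame(rows, columns=["individual_id", "lab", "value", "date"])
        cal_obs = np.where(cal_measured, cal_reps.mean(axis=0), np.nan)
        phos_obs = np.where(phos_measured, phos_reps.mean(axis=0), np.nan)
    else:
        cal_obs = np.where(cal_measured, cal_real, np.nan)
        phos_obs = np.where(phos_measured, phos_real, np.nan)

    individuals["calcium"] = cal_obs
    individuals["phosphate"] = phos_obs
    individuals.loc[~cys_measured, "cystatin_c"] = np.nan

    # ---- diagnosis codes and medications ----------------------------------
    dx_event = hypocalcemic & (rng.random(m) < dx_pen_per_ind)
    codes: list[list[str]] = [[] for _ in range(m)]
    dx_suggestive = np.zeros(m, dtype=bool)
    for i in np.flatnonzero(dx_event):
        cat = "calcium_phosphorus_disorder" if rng.random() < 0.65 else "hypoparathyroidism"
        codes[i].append(str(rng.choice(ADH1_ICD10_CODES[cat])))
        dx_suggestive[i] = True
        if rng.random() < config.symptom_given_dx:
            sym = str(rng.choice(["tetany", "paresthesia", "epilepsy"]))
            codes[i].append(str(rng.choice(ADH1_ICD10_CODES[sym])))
    for cat, rate in config.background_dx_rates.items():
        hit = rng.random(m) < rate
        for i in np.flatnonzero(hit):
            codes[i].append(str(rng.choice(ADH1_ICD10_CODES[cat])))
            if cat in ("hypoparathyroidism", "calcium_phosphorus_disorder"):
                dx_suggestive[i] = True
    n_bg = rng.poisson(1.2, size=m)
    for i in np.flatnonzero(n_bg):
        codes[i].extend(rng.choice(BACKGROUND_ICD10_CODES, size=n_bg[i]).tolist())

    meds: list[list[str]] = [[] for _ in range(m)]
    adh1_med = (dx_suggestive & (rng.random(m) < config.med_given_dx)) | (
        rng.random(m) < config.background_adh1_med_rate
    )
    for i in np.flatnonzero(adh1_med):
        k = 1 + int(rng.random() < 0.4)
        meds[i].extend(rng.choice(ADH1_MEDICATION_STRINGS, size=k, replace=False).tolist())
    bg_med = rng.random(m) < config.background_med_rate
    for i in np.flatnonzero(bg_med):
        meds[i].append(str(rng.choice(BACKGROUND_MEDICATION_STRINGS)))

    individuals["icd10_codes"] = [";".join(sorted(set(c))) for c in codes]
    individuals["medications"] = [";".join(sorted(set(s))) for s in meds]
    individuals["has_full_records"] = rng.random(m) < config.records_coverage_rate
    individuals = individuals.drop(columns=["_calcium_latent", "_phosphate_latent"])

    return Cohort(variants=variants, individuals=individuals, truth=truth,
                  labs_long=labs_long, config=config)


# ---------------------------------------------------------------------------
# fixture output
# ---------------------------------------------------------------------------

_FIXTURE_SCHEMA = {
    "variants": {
        "file": "variants.tsv or variants.vcf",
        "columns": {
            "variant_id": "chrom:pos:ref:alt",
            "consequence": "missense|nonsense|frameshift|synonymous|other",
            "protein_position": "1-based residue index",
            "known_status": "known_adh1|known_fhh1|novel",
            "insilico_fraction_deleterious": "fraction of predictor ensemble calling deleterious, [0,1]",
            "n_carriers": "heterozygous carrier count",
            "carriers": "comma-separated individual ids",
            "maf_<stratum>": "carriers/(2*n_individuals), per stratum",
        },
    },
    "individuals": {
        "file": "individuals.tsv",
        "columns": {
            "individual_id": "unique id",
            "stratum": "ancestry stratum label",
            "age": "years",
            "sex": "female|male",
            "pc1..pc10": "genetic principal components",
            "calcium": "serum calcium, mM (empty when unmeasured)",
            "phosphate": "serum phosphate, mM",
            "cystatin_c": "serum cystatin C, mg/L",
            "icd10_codes": "semicolon-separated ICD-10 codes",
            "medications": "semicolon-separated free-text medication strings",
            "has_full_records": "True when in-patient + primary-care records are both present",
        },
    },
    "truth": {
        "file": "truth.tsv",
        "columns": {
            "variant_id": "matches variants table",
            "class_label": "|".join(VALID_CLASSES),
            "true_calcium_shift": "mM",
            "true_phosphate_shift": "mM",
        },
    },
}


def write_fixture(cohort: Cohort, directory: str | Path,
                  variant_format: str = "tsv") -> dict[str, Path]:
    """Write a cohort to ``directory`` as plain-text fixture files.

    Emits ``variants.tsv`` (or ``variants.vcf``), ``individuals.tsv``,
    ``truth.tsv``, ``config.yaml`` and a ``schema.json`` documenting every
    column.  Round-trips losslessly through :mod:`adh1score.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if variant_format == "tsv":
        paths["variants"] = directory / "variants.tsv"
        cohort.variants.to_csv(paths["variants"], sep="\t", index=False, float_format="%.10g")
    elif variant_format == "vcf":
        from .io import write_variant_vcf
        paths["variants"] = directory / "variants.vcf"
        write_variant_vcf(cohort.variants, paths["variants"],
                          strata=list(cohort.config.strata))
    else:
        raise ValueError(f"unknown variant_format {variant_format!r}")

    paths["individuals"] = directory / "individuals.tsv"
    cohort.individuals.to_csv(paths["individuals"], sep="\t", index=False, float_format="%.10g")
    paths["truth"] = directory / "truth.tsv"
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    if cohort.labs_long is not None:
        paths["labs_long"] = directory / "labs_long.tsv"
        cohort.labs_long.to_csv(paths["labs_long"], sep="\t", index=False, float_format="%.10g")

    paths["config"] = directory / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(_config_to_dict(cohort.config), fh, sort_keys=True)
    paths["schema"] = directory / "schema.json"
    with open(paths["schema"], "w") as fh:
        json.dump(_FIXTURE_SCHEMA, fh, indent=2)
    return paths


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["strata"] = list(d["strata"])
    d["variant_classes"] = [
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in c.items()}
        for c in d["variant_classes"]
    ]
    for c in d["variant_classes"]:
        if c.get("effect_table") is not None:
            c["effect_table"] = [list(p) for p in c["effect_table"]]
    return d


# ---------------------------------------------------------------------------
# canonical architectures
# ---------------------------------------------------------------------------

def known_gof_class(n_variants: int | None = None) -> VariantClassSpec:
    """The established-pathogenic gain-of-function class, parameterized by
    the per-variant (shift, carrier count) profile of reported ADH1 variants."""
    profile = KNOWN_GOF_EFFECT_PROFILE
    if n_variants is None:
        n_variants = len(profile)
    return VariantClassSpec(
        class_label="gof_known",
        n_variants=n_variants,
        effect_table=profile,
        phosphate_shift_mM=(0.30, 0.05),
        diagnosis_penetrance=0.5,
        hotspot_fraction=0.15,
        insilico_deleterious_prob=0.9,
    )


def default_architecture(n_synonymous: int = 200,
                         n_neutral: int = 50) -> tuple[VariantClassSpec, ...]:
    """Paper-scale allelic-series architecture: strong familial GoF variants,
    intermediate-effect GoF variants, loss-of-function (FHH1-like) variants
    that *raise* calcium, effect-free rare missense, and synonymous nulls."""
    return (
        known_gof_class(),
        VariantClassSpec(
            class_label="gof_intermediate",
            n_variants=9,
            carrier_count_range=(3, 120),
            calcium_shift_mM=(-0.08, 0.04),
            phosphate_shift_mM=(0.30, 0.05),
            diagnosis_penetrance=0.5,
            hotspot_fraction=0.05,
            insilico_deleterious_prob=0.7,
        ),
        VariantClassSpec(
            class_label="lof",
            n_variants=6,
            carrier_count_range=(1, 40),
            calcium_shift_mM=(0.12, 0.05),
            phosphate_shift_mM=(0.15, 0.05),
            diagnosis_penetrance=0.5,
            insilico_deleterious_prob=0.8,
        ),
        VariantClassSpec(
            class_label="neutral",
            n_variants=n_neutral,
            carrier_count_range=(1, 30),
            insilico_deleterious_prob=0.15,
        ),
        VariantClassSpec(
            class_label="synonymous",
            n_variants=n_synonymous,
            carrier_count_range=(1, 30),
            insilico_deleterious_prob=0.05,
        ),
    )
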