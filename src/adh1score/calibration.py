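"""Empirical-null threshold calibration and classifier performance.

The detection threshold for the ADH1 score is set from a null distribution
built by resampling sub-scores of synonymous variants: synonymous changes
cannot alter CaSR function, so their association sub-scores reflect pure
chance.  Each null draw sums one value per component, sampled independently
(with replacement) from that component's empirical distribution across the
synonymous set; the threshold is the empirical percentile (default 98th) of
the draws, so by construction ~98% of null scores fall at or below it.  A
joint mode (resampling whole sub-score vectors, preserving inter-component
correlation) is available behind the ``mode`` argument.

Percentile convention: the lower empirical order statistic, i.e. the draw at
1-based rank ``ceil(percentile/100 * B)`` after sorting — no interpolation,
so the at-or-below-threshold mass among the draws is exactly
``ceil(0.98*B)/B`` (up to ties) regardless of the numeric stack.

A fixed-threshold mode (1.5 score units) is provided for reproducing
published operating points without re-deriving the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import COMPONENT_COLUMNS

#: Published operating threshold for the ADH1 score (score units).
PAPER_FIXED_THRESHOLD = 1.5


@dataclass
class NullDistribution:
    draws: np.ndarray
    B: int
    percentile: float
    threshold: float
    seed: int
    mode: str

    def fraction_at_or_below(self) -> float:
        return float(np.mean(self.draws <= self.threshold))


@dataclass
class ClassifierPerformance:
    sensitivity: float | None
    specificity: float | None
    n_positives: int
    n_negatives: int
    threshold: float


def build_null(synonymous_subscores: pd.DataFrame, B: int = 10_000,
               percentile: float = 98.0, seed: int = 0,
               mode: str = "independent") -> NullDistribution:
    """Resample synonymous-variant sub-scores into a null score distribution.

    ``synonymous_subscores`` is a scores table (one row per synonymous
    variant-stratum) carrying the standard component columns.  Requires at
    least 10 synonymous rows and B >= 1,000; deterministic given ``seed``.
    """
    comp = synonymous_subscores[list(COMPONENT_COLUMNS)].to_numpy(dtype=float)
    if comp.shape[0] == 0:
        raise ValueError("empty synonymous set")
    if comp.shape[0] < 10:
        raise ValueError("need at least 10 synonymous variants to build a null")
    if B < 1_000:
        raise ValueError("B must be at least 1,000")
    rng = np.random.default_rng(seed)
    n = comp.shape[0]
    if mode == "independent":
        draws = np.zeros(B)
        for j in range(comp.shape[1]):
            draws += comp[rng.integers(0, n, size=B), j]
    elif mode == "joint":
        draws = comp[rng.integers(0, n, size=B)].sum(axis=1)
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    rank = math.ceil(percentile / 100.0 * B)  # 1-based lower order statistic
    threshold = float(np.sort(draws)[rank - 1])
    return NullDistribution(draws=draws, B=B, percentile=percentile,
                            threshold=threshold, seed=seed, mode=mode)


def sens_spec(scores, labels, threshold: float) -> ClassifierPerformance:
    """Sensitivity/specificity of ``score > threshold`` as the positive call.

    ``labels`` are ``"positive"`` / ``"negative"``.  A metric whose class is
    absent is ``None`` (undefined), never zero.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == "positive"
    neg = labels == "negative"
    sensitivity = float(np.mean(scores[pos] > threshold)) if pos.any() else None
    specificity = float(np.mean(scores[neg] <= threshold)) if neg.any() else None
    return ClassifierPerformance(sensitivity=sensitivity, specificity=specificity,
                                 n_positives=int(pos.sum()), n_negatives=int(neg.sum()),
                                 threshold=threshold)


def fixed_threshold_mode(config=None) -> float:
    """The published fixed operating threshold (1.5), bypassing the null."""
    return PAPER_FIXED_THRESHOLD


def resolve_threshold(mode: str, null: NullDistribution | None = None) -> dict:
    """Threshold plus provenance for the run manifest."""
    if mode == "fixed":
        return {"mode": "fixed", "threshold": fixed_threshold_mode()}
    if mode == "empirical":
        if null is None:
            raise ValueError("empirical threshold mode requires a null distribution")
        return {"mode": "empirical", "threshold": null.threshold,
                "percentile": null.percentile, "B": null.B, "seed": null.seed,
                "resampling": null.mode}
    raise ValueError(f"unknown threshold mode {mode!r}")
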