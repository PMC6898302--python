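"""Diagnostic cutoffs at fixed specificity, eye classification, and HPA staging.

Cutoffs are placed 1.65 / 2.33 standard deviations below the normal-group
mean, targeting 95% / 99% specificity under normality. Decibel-scaled
parameters (VF_MD, NFL_MD) are approximately normal only on the linear
scale, so their cutoffs are computed on ``10**(x/10)`` and mapped back to
dB; thickness parameters are computed natively in µm.

Severity staging follows the modified Hodapp-Parrish-Anderson scheme:
stage 1 (early) MD ≥ −6 dB, stage 2 (moderate) −12 ≤ MD < −6 dB,
stage 3 (severe) MD < −12 dB; stage 0 is pre-perimetric glaucoma
(abnormal disc, normal field), distinguishable from stage 1 only with the
caller's perimetric-normality flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DB_PARAMETERS",
    "DiagnosticCutoffs",
    "StageLabel",
    "specificity_cutoffs",
    "classify_eye",
    "hpa_stage",
    "binarize_stage",
    "staging_f1",
    "ks_normality",
]

#: Parameter kinds whose cutoffs are computed on the linear (10^(x/10)) scale.
DB_PARAMETERS = frozenset({"vf_md", "nfl_md"})

Z95 = 1.65
Z99 = 2.33

STAGES = ("stage0_PPG", "stage1_early", "stage2_moderate", "stage3_severe")


@dataclass(frozen=True)
class DiagnosticCutoffs:
    """95%/99%-specificity cutoffs for one parameter (lower = more diseased)."""

    cutoff95: float
    cutoff99: float
    scale_used: str            # "linear-transformed" | "native"
    parameter_kind: str
    z95: float = Z95
    z99: float = Z99

    def __post_init__(self) -> None:
        if not self.cutoff99 <= self.cutoff95:
            raise ValueError("cutoff99 must not exceed cutoff95")


@dataclass(frozen=True)
class StageLabel:
    stage: str
    basis: str                 # "VF" | "NFL_MD"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


def specificity_cutoffs(normal_values: Sequence[float], parameter_kind: str,
                        *, min_n: int = 20) -> DiagnosticCutoffs:
    """Cutoffs at mean − 1.65·SD and mean − 2.33·SD of the normal group.

    ``parameter_kind`` in :data:`DB_PARAMETERS` triggers the linear-scale
    detour (dB → 10^(x/10) → cutoff → dB); anything else is computed on the
    native scale. SD uses the n−1 (sample) denominator.
    """
    values = np.asarray(normal_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 normal values")
    if values.size < min_n:
        warnings.warn(
            f"only {values.size} normal eyes; cutoffs are unstable below {min_n}",
            stacklevel=2,
        )
    is_db = parameter_kind.lower() in DB_PARAMETERS
    work = 10.0 ** (values / 10.0) if is_db else values
    mean = work.mean()
    sd = work.std(ddof=1)
    c95 = mean - Z95 * sd
    c99 = mean - Z99 * sd
    if is_db:
        if c95 <= 0 or c99 <= 0:
            raise ValueError(
                "linear-scale cutoff is non-positive; the normal group is too "
                "variable for a dB back-transform"
            )
        c95 = 10.0 * np.log10(c95)
        c99 = 10.0 * np.log10(c99)
        scale = "linear-transformed"
    else:
        scale = "native"
    return DiagnosticCutoffs(cutoff95=float(c95), cutoff99=float(c99),
                             scale_used=scale, parameter_kind=parameter_kind)


def classify_eye(value: float, cutoffs: DiagnosticCutoffs) -> str:
    """Classify one eye against the cutoffs: lower values are abnormal.

    Returns ``"normal"``, ``"abnormal@95"`` or ``"abnormal@99"`` (nested:
    abnormal@99 implies abnormal@95).
    """
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    if value < cutoffs.cutoff99:
        return "abnormal@99"
    if value < cutoffs.cutoff95:
        return "abnormal@95"
    return "normal"


def hpa_stage(md: float, basis: str = "VF", *, ppg: bool = False) -> StageLabel:
    """Modified Hodapp-Parrish-Anderson stage from a mean deviation in dB.

    ``ppg=True`` marks a perimetrically normal eye with structural damage
    (stage 0); by MD alone, stages 0 and 1 are indistinguishable and MD ≥ −6
    maps to stage 1.
    """
    if not np.isfinite(md):
        raise ValueError("md must be finite")
    if md >= -6.0:
        stage = "stage0_PPG" if ppg else "stage1_early"
    elif md >= -12.0:
        stage = "stage2_moderate"
    else:
        stage = "stage3_severe"
    return StageLabel(stage=stage, basis=basis)


def binarize_stage(md: float) -> str:
    """Two-level staging at −6 dB: ``"stage0_1"`` (MD ≥ −6) vs ``"stage2_3"``."""
    if not np.isfinite(md):
        raise ValueError("md must be finite")
    return "stage0_1" if md >= -6.0 else "stage2_3"


def staging_f1(tp: int, fn: int, fp: int, tn: int, *, positive: str = "stage0_1") -> float:
    """F1 score for staging agreement from a 2×2 table.

    The table is oriented with the *positive* class = mild (stage 0–1) by
    default: tp = both mild, fn = truth mild / predicted advanced, fp =
    truth advanced / predicted mild. ``positive="stage2_3"`` swaps the
    orientation. Degenerate denominators yield 0 with a warning.
    """
    counts = (tp, fn, fp, tn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if positive == "stage2_3":
        tp, fn, fp, tn = tn, fp, fn, tp
    elif positive != "stage0_1":
        raise ValueError("positive must be 'stage0_1' or 'stage2_3'")
    if tp + fn == 0:
        raise ValueError("no positive ground-truth cases")
    if tp == 0:
        warnings.warn("zero true positives; F1 defined as 0", stacklevel=2)
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov–Smirnov test against a fitted normal (reporting utility only).

    Returns ``(statistic, p_value)``. Never used as a gate: cutoff
    computation assumes normality regardless.
    """
    v = np.asarray(values, dtype=float)
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance")
    stat, p = stats.kstest((v - v.mean()) / v.std(ddof=1), "norm")
    return float(stat), float(p)
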