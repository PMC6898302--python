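"""Decibel transform, weighted logarithmic average, and NFL_MD calibration.

The core structure-function chain is

    NFL_dB(i)  = 10 * log10( (t_i - f_i) / (N_i - f_i) )     (clamped below)
    NFL_WLA    = (1/52) * sum_i  w_i * NFL_dB(i)
    NFL_MD     = b1 * NFL_WLA + b2 * NFL_WLA**2              (zero intercept)

where t_i is the measured sector thickness, N_i the covariate-specific
normative reference, f_i the floor, and w_i the VF-area weights. Sector
losses are clamped at −12.8 dB before averaging (thickness at or below the
floor maps to the clamp). NFL_MD is the OCT-based estimate of the visual
field mean deviation; the published calibration is b1 = 0.864,
b2 = −0.075 per dB.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .normative import NormativeModel, floor_value, reference_thickness
from .sectors import SECTOR_ORDER, mirror_sectors, validate_sector_keys
from .weights import WeightScheme

__all__ = [
    "SectorProfile",
    "DecibelProfile",
    "CalibrationModel",
    "CalibrationFit",
    "to_decibel",
    "profile_to_decibel",
    "weighted_log_average",
    "nfl_md",
    "fit_calibration",
    "diffuse_loss_db",
]

#: Operating range of NFL_WLA over which the default quadratic is monotone.
WLA_OPERATING_RANGE = (-12.8, 3.0)


@dataclass(frozen=True)
class SectorProfile:
    """One eye's 16 sector NFL thicknesses (µm) with covariates.

    Profiles are stored in right-eye (OD) orientation; pass
    ``laterality="OS"`` to mirror a left-eye profile at construction.
    """

    eye_id: str
    thickness: Mapping[str, float]
    age: float
    axial_length: float
    laterality: str = "OD"

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        thick = dict(self.thickness)
        if self.laterality == "OS":
            thick = mirror_sectors(thick)
        validate_sector_keys(thick, context=f"thickness profile for eye {self.eye_id!r}")
        for sector, t in thick.items():
            if not (t > 0 and math.isfinite(t)):
                raise ValueError(
                    f"eye {self.eye_id!r} sector {sector}: thickness must be positive, got {t}"
                )
        object.__setattr__(self, "thickness", thick)

    def as_array(self) -> np.ndarray:
        return np.array([self.thickness[s] for s in SECTOR_ORDER], dtype=float)


@dataclass(frozen=True)
class DecibelProfile:
    """Per-sector NFL loss in decibels (0 dB = normative reference)."""

    loss_db: Mapping[str, float]
    clamp: float = -12.8

    def __post_init__(self) -> None:
        validate_sector_keys(self.loss_db, context="decibel profile")
        for sector, v in self.loss_db.items():
            if not math.isfinite(v):
                raise ValueError(f"sector {sector}: non-finite dB value")
            if v < self.clamp - 1e-12:
                raise ValueError(f"sector {sector}: {v} dB below clamp {self.clamp}")

    def as_array(self) -> np.ndarray:
        return np.array([self.loss_db[s] for s in SECTOR_ORDER], dtype=float)

    def __getitem__(self, sector: str) -> float:
        return self.loss_db[sector]


def to_decibel(thickness, reference, floor, clamp: float = -12.8):
    """Convert NFL thickness (µm) to loss in dB relative to the normative reference.

    ``10*log10((t - f)/(N - f))`` clamped below at *clamp*; thickness at or
    below the floor maps to exactly the clamp. Accepts scalars or arrays
    (broadcast); scalar inputs return a float.

    Raises
    ------
    ValueError
        If any reference does not exceed its floor, or a floor is negative.
    """
    t = np.asarray(thickness, dtype=float)
    N = np.asarray(reference, dtype=float)
    f = np.asarray(floor, dtype=float)
    if np.any(f < 0):
        raise ValueError("floor must be non-negative")
    if np.any(N <= f):
        raise ValueError("reference must exceed floor")
    num = t - f
    with np.errstate(divide="ignore", invalid="ignore"):
        db = np.where(num > 0, 10.0 * np.log10(np.maximum(num, 1e-300) / (N - f)), clamp)
    db = np.maximum(db, clamp)
    if db.ndim == 0:
        return float(db)
    return db


def profile_to_decibel(profile: SectorProfile, model: NormativeModel) -> DecibelProfile:
    """Apply the decibel transform to every sector of a profile.

    Each sector uses its own covariate-specific reference N(age, AL) and
    axial-length-adjusted floor.
    """
    loss = {}
    for sector in SECTOR_ORDER:
        try:
            N = reference_thickness(sector, profile.age, profile.axial_length, model)
            f = floor_value(sector, profile.axial_length, model)
            loss[sector] = to_decibel(profile.thickness[sector], N, f,
                                      clamp=model.db_floor_clamp)
        except ValueError as exc:
            raise ValueError(f"sector {sector}: {exc}") from exc
    return DecibelProfile(loss_db=loss, clamp=model.db_floor_clamp)


def weighted_log_average(db: DecibelProfile, weights: WeightScheme) -> float:
    """NFL_WLA: VF-area-weighted mean sector loss, (1/52) Σ w_i · dB_i."""
    values = db.as_array()
    w = weights.as_array()
    return float(np.dot(w, values) / w.sum())


@dataclass(frozen=True)
class CalibrationModel:
    """Zero-intercept quadratic mapping NFL_WLA (dB) to NFL_MD (dB).

    The intercept is identically zero: an average-normal thickness profile
    corresponds to an average-normal visual field by construction. The
    default coefficients are the published all-participant fit.
    """

    b1: float = 0.864
    b2: float = -0.075
    provenance: str = "published-fit"

    def __post_init__(self) -> None:
        # strict monotonicity over the operating range: b1 + 2*b2*x > 0
        lo, hi = WLA_OPERATING_RANGE
        for x in (lo, hi):
            if self.b1 + 2.0 * self.b2 * x <= 0:
                raise ValueError(
                    f"quadratic not strictly increasing on {WLA_OPERATING_RANGE}: "
                    f"derivative {self.b1 + 2 * self.b2 * x:.3f} at {x} dB"
                )

    def __call__(self, wla):
        x = np.asarray(wla, dtype=float)
        out = self.b1 * x + self.b2 * x**2
        return float(out) if out.ndim == 0 else out


def nfl_md(wla, calib: CalibrationModel | None = None):
    """NFL_MD in dB from a weighted logarithmic average.

    Warns outside the [−12.8, +3] dB operating range where the quadratic's
    monotonicity is guaranteed.
    """
    calib = calib or CalibrationModel()
    arr = np.asarray(wla, dtype=float)
    lo, hi = WLA_OPERATING_RANGE
    if np.any(arr < lo) or np.any(arr > hi):
        warnings.warn(
            f"NFL_WLA outside the calibrated operating range {WLA_OPERATING_RANGE} dB",
            stacklevel=2,
        )
    return calib(wla)


@dataclass(frozen=True)
class CalibrationFit:
    """Result of :func:`fit_calibration`."""

    model: CalibrationModel
    fold_models: tuple[CalibrationModel, ...]
    fold_assignment: np.ndarray       # fold index per eye
    oof_predictions: np.ndarray       # out-of-fold NFL_MD per eye


def _fit_quadratic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    X = np.column_stack([x, x**2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[0]), float(beta[1])


def fit_calibration(wla_values: Sequence[float], vf_md_values: Sequence[float],
                    participant_ids: Sequence, n_folds: int = 5,
                    seed: int = 20191206) -> CalibrationFit:
    """Fit the zero-intercept quadratic NFL_WLA → VF_MD with grouped cross-validation.

    Folds partition *participants* (both eyes of one participant always land
    in the same fold, so no eye is predicted by a fit that saw its fellow
    eye). Out-of-fold predictions are pooled and returned next to the
    all-data fit.
    """
    x = np.asarray(wla_values, dtype=float)
    y = np.asarray(vf_md_values, dtype=float)
    pid = np.asarray(participant_ids)
    if not (x.shape == y.shape == pid.shape):
        raise ValueError("wla_values, vf_md_values and participant_ids must align")
    if x.size < 10:
        raise ValueError("need at least 10 eyes to calibrate")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all NFL_WLA values identical")

    b1, b2 = _fit_quadratic(x, y)
    model = CalibrationModel(b1=b1, b2=b2, provenance="fitted")

    rng = np.random.default_rng(seed)
    participants = np.unique(pid)
    order = rng.permutation(len(participants))
    fold_of_participant = {
        participants[idx]: i % n_folds for i, idx in enumerate(order)
    }
    fold_assignment = np.array([fold_of_participant[p] for p in pid])

    oof = np.full_like(x, np.nan)
    fold_models = []
    for k in range(n_folds):
        train = fold_assignment != k
        test = ~train
        if not test.any():
            fold_models.append(model)
            continue
        if np.ptp(x[train]) == 0:
            raise ValueError(f"degenerate training design in fold {k}")
        fb1, fb2 = _fit_quadratic(x[train], y[train])
        fm = CalibrationModel(b1=fb1, b2=fb2, provenance=f"fold-{k}")
        fold_models.append(fm)
        oof[test] = fm(x[test])
    return CalibrationFit(model=model, fold_models=tuple(fold_models),
                          fold_assignment=fold_assignment, oof_predictions=oof)


def diffuse_loss_db(loss_fraction: float) -> float:
    """Simple dB equivalent of a uniform diffuse loss, without floor subtraction.

    ``10*log10(1 - loss_fraction)`` — e.g. a 5% uniform thinning gives
    −0.22 dB. This is the floor-free reading of diffuse loss; the full
    floor-subtracted pipeline penalises the same thinning more strongly
    (−0.37 dB with the default floor fraction). Both behaviours are
    intentional; see the methods note.
    """
    if not (0.0 <= loss_fraction < 1.0):
        raise ValueError("loss_fraction must be in [0, 1)")
    return 10.0 * math.log10(1.0 - loss_fraction)
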