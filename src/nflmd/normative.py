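"""Normative reference model for peripapillary NFL thickness.

Each sector (and the overall / inferior-quadrant summaries) has an affine
normative model

    N(age, AL) = intercept + age_slope * age + axlen_slope * AL

fitted in a normal population. The reference covariates are age 50 years
and axial length 23.6 mm. End-stage glaucomatous sectors retain a residual
thickness (glial and scar tissue); that floor is modelled as a fixed
fraction of the normative reference (default 0.45). The floor is adjusted
for axial length but not age: its reference term is evaluated at the
reference age regardless of the eye's age.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

from .sectors import SECTOR_ORDER, SUMMARY_PARAMETERS

__all__ = [
    "NormativeCoefficients",
    "NormativeModel",
    "load_default_model",
    "load_model_json",
    "reference_thickness",
    "adjust_to_reference",
    "floor_value",
    "estimate_floor_percentage",
    "fit_normative_coefficients",
]

_VALID_SECTORS = set(SECTOR_ORDER) | set(SUMMARY_PARAMETERS)

AGE_RANGE = (18.0, 100.0)
AXLEN_RANGE = (18.0, 30.0)


@dataclass(frozen=True)
class NormativeCoefficients:
    """Affine normative model for one sector: N = a + b_age*age + b_AL*AL (µm)."""

    sector_id: str
    intercept: float
    age_slope: float
    axlen_slope: float

    def predict(self, age: float, axial_length: float) -> float:
        return self.intercept + self.age_slope * age + self.axlen_slope * axial_length


@dataclass(frozen=True)
class NormativeModel:
    """Normative references, floor fraction and decibel clamp for one device/population.

    Parameters
    ----------
    coefficients
        Mapping sector_id -> :class:`NormativeCoefficients`; must contain the
        16 sectors plus ``overall`` and ``inferior_quadrant``.
    reference_age, reference_axial_length
        Covariates the normative values are quoted at (years / mm).
    floor_fraction
        Residual thickness in end-stage damage as a fraction of the
        normative reference, in [0, 1).
    db_floor_clamp
        Lower clamp for sector loss in decibels (negative).
    """

    coefficients: Mapping[str, NormativeCoefficients]
    reference_age: float = 50.0
    reference_axial_length: float = 23.6
    floor_fraction: float = 0.45
    db_floor_clamp: float = -12.8

    def __post_init__(self) -> None:
        missing = _VALID_SECTORS - set(self.coefficients)
        if missing:
            raise ValueError(f"normative table incomplete, missing: {sorted(missing)}")
        if not (0.0 <= self.floor_fraction < 1.0):
            raise ValueError("floor_fraction must be in [0, 1)")
        if not self.db_floor_clamp < 0:
            raise ValueError("db_floor_clamp must be negative")
        for sid in self.coefficients:
            ref = self.coefficients[sid].predict(self.reference_age, self.reference_axial_length)
            if ref <= 0:
                raise ValueError(f"non-positive reference thickness for sector {sid!r}")

    def with_floor_fraction(self, floor_fraction: float) -> "NormativeModel":
        return replace(self, floor_fraction=floor_fraction)

    # convenience method forms of the module-level operations
    def reference_thickness(self, sector: str, age: float | None = None,
                            axial_length: float | None = None) -> float:
        age = self.reference_age if age is None else age
        axial_length = self.reference_axial_length if axial_length is None else axial_length
        return reference_thickness(sector, age, axial_length, self)

    def floor_value(self, sector: str, axial_length: float | None = None) -> float:
        axial_length = self.reference_axial_length if axial_length is None else axial_length
        return floor_value(sector, axial_length, self)


def _coef(sector: str, model: NormativeModel) -> NormativeCoefficients:
    try:
        return model.coefficients[sector]
    except KeyError:
        raise KeyError(
            f"unknown sector label {sector!r}; expected one of {sorted(_VALID_SECTORS)}"
        ) from None


def _warn_covariates(age: float, axial_length: float) -> None:
    if not (AGE_RANGE[0] <= age <= AGE_RANGE[1]):
        warnings.warn(f"age {age} y outside plausible range {AGE_RANGE}", stacklevel=3)
    if not (AXLEN_RANGE[0] <= axial_length <= AXLEN_RANGE[1]):
        warnings.warn(
            f"axial length {axial_length} mm outside plausible range {AXLEN_RANGE}",
            stacklevel=3,
        )


def reference_thickness(sector: str, age: float, axial_length: float,
                        model: NormativeModel) -> float:
    """Normative NFL thickness N(age, AL) in µm for one sector.

    Raises if the predicted thickness is non-positive (covariates far outside
    the model's domain).
    """
    coef = _coef(sector, model)
    _warn_covariates(age, axial_length)
    value = coef.predict(age, axial_length)
    if value <= 0:
        raise ValueError(
            f"normative model predicts non-positive thickness ({value:.1f} µm) "
            f"for sector {sector!r} at age={age}, AL={axial_length}"
        )
    return value


def adjust_to_reference(thickness: float, sector: str, age: float,
                        axial_length: float, model: NormativeModel) -> float:
    """Map a measured thickness to the reference covariates (age 50 y, AL 23.6 mm).

    Removes the modelled covariate effect so eyes of different age and axial
    length are comparable on a common scale (used for cutoff computation):
    ``t - b_age*(age - 50) - b_AL*(AL - 23.6)``. Identity at the reference
    covariates.
    """
    coef = _coef(sector, model)
    _warn_covariates(age, axial_length)
    return (
        thickness
        - coef.age_slope * (age - model.reference_age)
        - coef.axlen_slope * (axial_length - model.reference_axial_length)
    )


def floor_value(sector: str, axial_length: float, model: NormativeModel) -> float:
    """Floor thickness in µm: floor_fraction × reference at the eye's axial length.

    The floor is adjusted for axial length only; the age term is evaluated at
    the reference age.
    """
    return model.floor_fraction * reference_thickness(
        sector, model.reference_age, axial_length, model
    )


def estimate_floor_percentage(severe_profiles: Iterable, model: NormativeModel,
                              stat: str = "mean") -> float:
    """Estimate the floor fraction from end-stage eyes.

    For each severe eye (caller applies the severity selection, e.g.
    VF_MD < −12 dB) the sector with the lowest thickness *as a fraction of its
    covariate-specific normative reference* is taken as end-stage; the
    per-eye worst-sector residual fractions are then pooled (mean by default,
    ``stat="median"`` available).

    Parameters
    ----------
    severe_profiles
        Iterable of :class:`~nflmd.decibel.SectorProfile`.

    Returns
    -------
    float
        Pooled residual fraction in (0, 1).
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    worst: list[float] = []
    for prof in severe_profiles:
        ratios = []
        for sector in SECTOR_ORDER:
            t = prof.thickness[sector]
            if t <= 0:
                raise ValueError(
                    f"non-positive thickness {t} µm in sector {sector} of eye {prof.eye_id!r}"
                )
            ref = reference_thickness(sector, prof.age, prof.axial_length, model)
            ratios.append(t / ref)
        worst.append(min(ratios))
    if not worst:
        raise ValueError("estimate_floor_percentage requires at least one severe eye")
    arr = np.asarray(worst, dtype=float)
    return float(np.mean(arr) if stat == "mean" else np.median(arr))


def fit_normative_coefficients(sector_id: str, thickness: np.ndarray, age: np.ndarray,
                               axial_length: np.ndarray) -> NormativeCoefficients:
    """Generic least-squares fit of the affine normative model from a normal cohort.

    Utility only — the shipped coefficient table is the canonical reference.
    """
    thickness = np.asarray(thickness, float)
    X = np.column_stack([np.ones_like(thickness), np.asarray(age, float),
                         np.asarray(axial_length, float)])
    beta, *_ = np.linalg.lstsq(X, thickness, rcond=None)
    return NormativeCoefficients(sector_id, float(beta[0]), float(beta[1]), float(beta[2]))


def _model_from_dict(doc: dict) -> NormativeModel:
    coefs = {
        row["sector_id"]: NormativeCoefficients(
            row["sector_id"], float(row["intercept"]),
            float(row["age_slope"]), float(row["axlen_slope"]),
        )
        for row in doc["coefficients"]
    }
    return NormativeModel(
        coefficients=coefs,
        reference_age=float(doc.get("reference_age_years", 50.0)),
        reference_axial_length=float(doc.get("reference_axial_length_mm", 23.6)),
        floor_fraction=float(doc.get("floor_fraction", 0.45)),
        db_floor_clamp=float(doc.get("db_floor_clamp", -12.8)),
    )


def load_model_json(path) -> NormativeModel:
    """Load a normative model from a JSON document (same schema as the packaged one)."""
    with open(path, "r", encoding="utf-8") as fh:
        return _model_from_dict(json.load(fh))


def load_default_model() -> NormativeModel:
    """The packaged normative model (published coefficient table, floor 0.45, clamp −12.8 dB)."""
    text = resources.files("nflmd.data").joinpath("normative_coefficients.json").read_text()
    return _model_from_dict(json.loads(text))
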