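"""Seeded synthetic paired OCT/VF cohorts.

The generator emulates the statistical structure the NFL_MD method
assumes, so the whole pipeline is testable without clinical data:

* per-eye healthy sector thickness = normative reference × a shared
  lognormal eye-size factor (CV 0.085, the normal-population thickness CV);
* glaucomatous damage as a hidden per-sector *survival* in [0, 1]
  (diffuse component plus focal arcuate dips centred on the
  inferotemporal / superotemporal bundles, where early damage concentrates);
* measured thickness = floor + survival × (healthy − floor), times
  multiplicative lognormal measurement noise (CV 0.05 per sector);
* VF_MD = VF-area-weighted decibel survival plus Gaussian test-retest
  noise (SD 0.7 dB), so structure-function coupling is log-linear by
  construction — the model the NFL_MD transform assumes;
* visits add a linear progression trend in dB and fresh noise.

Ground-truth survival is emitted in a sidecar table so downstream
statistics can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import VisitSeries
from .decibel import SectorProfile
from .normative import NormativeModel, load_default_model, reference_thickness
from .sectors import OS_MIRROR, SECTOR_ORDER
from .weights import WeightScheme, load_default_weights

__all__ = [
    "CohortConfig",
    "simulate_cohort",
    "simulate_end_stage_eyes",
    "simulate_visit_series",
]

_SECTOR_CENTER = {s: (i * 22.5 + 11.25) for i, s in enumerate(SECTOR_ORDER)}
_INFERIOR_QUADRANT = ("IN2", "IN1", "IT1", "IT2")
#: survival floor used when taking logs for the VF (−35 dB, below the HFA range)
_SURV_EPS = 10.0 ** (-3.5)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults encode the population the method targets: normal-eye
    thickness CV 8.5%, sector measurement CV 5%, VF test-retest SD 0.7 dB,
    floor at 45% of the reference, 4 visits 6 months apart.
    """

    n_normal: int = 100
    n_ppg: int = 100
    n_pg: int = 100
    floor_fraction_true: float = 0.45
    eye_scale_cv: float = 0.085
    sector_measurement_cv: float = 0.05
    vf_test_retest_sd: float = 0.7
    focal_weight: float = 0.7      # share of glaucomatous loss that is focal
    visits: int = 4
    visit_interval: float = 0.5    # years
    progression_slope: float = -0.3   # dB/year, glaucoma eyes
    mean_age: float = 60.0
    sd_age: float = 9.5
    mean_axial_length: float = 24.0
    sd_axial_length: float = 1.3
    two_eye_prob: float = 0.6      # second eye of a participant enrolled
    qc_fail_rate: float = 0.03     # visits given a failing QC field
    seed: int = 20191206

    def __post_init__(self) -> None:
        for name in ("eye_scale_cv", "sector_measurement_cv", "vf_test_retest_sd",
                     "qc_fail_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_normal", "n_ppg", "n_pg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.visits < 1:
            raise ValueError("visits must be >= 1")
        if not (0.0 <= self.floor_fraction_true < 1.0):
            raise ValueError("floor_fraction_true must be in [0, 1)")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative mean-one lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _focal_bump(center_deg: float, width_deg: float) -> np.ndarray:
    """Gaussian dip profile over the 16 sector centres (circular distance)."""
    theta = np.array([_SECTOR_CENTER[s] for s in SECTOR_ORDER])
    d = np.abs(theta - center_deg)
    d = np.minimum(d, 360.0 - d)
    return np.exp(-0.5 * (d / width_deg) ** 2)


def _draw_survival(group: str, severity: float, focal_weight: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Hidden per-sector nerve-fiber survival for one eye.

    ``severity`` in [0, 1] scales the total loss; the focal component sits
    on the inferotemporal and/or superotemporal bundles.
    """
    if group == "normal":
        return np.ones(len(SECTOR_ORDER))
    arcuate_centers = {"IT": _SECTOR_CENTER["IT1"], "ST": _SECTOR_CENTER["ST1"]}
    if group == "ppg":
        diffuse = 0.08 * severity
        depth = 0.15 + 0.30 * severity
        widths = (12.0, 20.0)
        both_prob = 0.15
    else:  # perimetric glaucoma: loss spans early to severe stages
        diffuse = 0.55 * severity * (1.0 - focal_weight) / 0.3 if focal_weight < 1 else 0.0
        diffuse = min(diffuse, 0.6)
        depth = min(1.0, 0.35 + 0.75 * severity)
        widths = (15.0, 15.0 + 45.0 * severity)
        both_prob = 0.2 + 0.6 * severity
    hemis = ["IT"] if rng.random() > 0.5 else ["ST"]
    if rng.random() < both_prob:
        hemis = ["IT", "ST"]
    survival = np.full(len(SECTOR_ORDER), 1.0 - diffuse)
    for h in hemis:
        center = arcuate_centers[h] + rng.uniform(-10.0, 10.0)
        width = rng.uniform(*widths)
        survival *= 1.0 - depth * _focal_bump(center, width)
    return np.clip(survival, 0.0, 1.0)


def _weighted_vf_md(survival: np.ndarray, weights: WeightScheme) -> float:
    w = weights.as_array()
    db = 10.0 * np.log10(np.maximum(survival, _SURV_EPS))
    return float(np.dot(w, db) / w.sum())


def simulate_cohort(config: CohortConfig, model: NormativeModel | None = None,
                    weights: WeightScheme | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a longitudinal paired OCT/VF cohort.

    Returns
    -------
    visits, truth
        ``visits`` holds one row per eye-visit in the CSV dialect the
        pipeline reads (sector columns in the eye's native orientation;
        left eyes are mirrored back at ingest). ``truth`` is the hidden
        ground-truth sidecar (per-sector survival in OD orientation,
        noise-free VF_MD, eye scale) for parameter-recovery checks.
    """
    model = model or load_default_model()
    weights = weights or load_default_weights()
    rng = np.random.default_rng(config.seed)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    pid_counter = 0
    groups = (("normal", config.n_normal), ("ppg", config.n_ppg), ("pg", config.n_pg))
    for group, n_eyes in groups:
        made = 0
        while made < n_eyes:
            pid_counter += 1
            pid = f"P{pid_counter:04d}"
            age = float(np.clip(rng.normal(config.mean_age, config.sd_age), 30.0, 90.0))
            axlen = float(np.clip(rng.normal(config.mean_axial_length,
                                             config.sd_axial_length), 21.0, 27.0))
            eyes_here = 2 if (rng.random() < config.two_eye_prob and made + 1 < n_eyes) else 1
            for e in range(eyes_here):
                laterality = "OD" if e == 0 else "OS"
                eye_id = f"{pid}-{laterality}"
                scale = float(_lognormal_factor(rng, config.eye_scale_cv))
                reference = np.array([
                    reference_thickness(s, age, axlen, model) for s in SECTOR_ORDER
                ])
                healthy = reference * scale
                floor = config.floor_fraction_true * healthy
                severity = float(rng.uniform(0.0, 1.0))
                survival0 = _draw_survival(group, severity, config.focal_weight, rng)
                prog = 0.0
                if group != "normal":
                    prog = float(min(0.0, rng.normal(config.progression_slope, 0.15)))
                for v in range(config.visits):
                    t = v * config.visit_interval
                    # progression: uniform survival decline of `prog` dB/year
                    survival = np.clip(survival0 * 10.0 ** (prog * t / 10.0), 0.0, 1.0)
                    noise = _lognormal_factor(rng, config.sector_measurement_cv,
                                              size=len(SECTOR_ORDER))
                    thickness = (floor + survival * (healthy - floor)) * noise
                    thickness = np.maximum(thickness, 1.0)
                    vf_true = _weighted_vf_md(survival, weights)
                    vf_md = vf_true + float(rng.normal(0.0, config.vf_test_retest_sd))
                    if group == "normal":
                        vf_md = min(vf_md, 2.5)  # normals stay near 0 dB
                    db_dev = 10.0 * np.log10(np.maximum(survival, _SURV_EPS)) - vf_true
                    psd = float(np.sqrt(np.dot(weights.as_array(), db_dev**2)
                                        / weights.as_array().sum()))
                    psd = max(0.2, psd + float(rng.normal(0.0, 0.15)))
                    ght = "ONL" if group == "pg" else "WNL"

                    ssi = float(np.clip(rng.normal(60.0, 8.0), 38.0, 90.0))
                    decen = float(np.abs(rng.normal(0.0, 0.18)))
                    decen = min(decen, 0.74)
                    fixation = float(rng.uniform(0.0, 0.12))
                    fp = float(rng.uniform(0.0, 0.15))
                    fn = float(rng.uniform(0.0, 0.15))
                    cataract = int(rng.choice([0, 1, 2], p=[0.5, 0.35, 0.15]))
                    bcva = float(np.clip(rng.normal(0.0, 0.06), -0.1, 0.17))
                    if rng.random() < config.qc_fail_rate:
                        which = rng.integers(0, 4)
                        if which == 0:
                            ssi = float(rng.uniform(20.0, 37.0))
                        elif which == 1:
                            decen = float(rng.uniform(0.76, 1.2))
                        elif which == 2:
                            fixation = float(rng.uniform(0.15, 0.4))
                        else:
                            fp = float(rng.uniform(0.33, 0.6))

                    sector_values = dict(zip(SECTOR_ORDER, thickness))
                    if laterality == "OS":   # write in native (mirrored) orientation
                        sector_values = {OS_MIRROR[k]: v for k, v in sector_values.items()}
                    row = {
                        "participant_id": pid, "eye_id": eye_id,
                        "laterality": laterality, "group": group,
                        "visit": v, "visit_time": t,
                        "age": age, "axial_length": axlen,
                        **{s: float(sector_values[s]) for s in SECTOR_ORDER},
                        "overall_nflt": float(thickness.mean()),
                        "inferior_nflt": float(np.mean(
                            [thickness[SECTOR_ORDER.index(s)] for s in _INFERIOR_QUADRANT])),
                        "vf_md": vf_md, "vf_psd": psd, "ght": ght,
                        "ssi": ssi, "decentration_mm": decen,
                        "fixation_loss": fixation, "false_pos": fp, "false_neg": fn,
                        "cataract_grade": cataract, "bcva_logmar": bcva,
                    }
                    rows.append(row)
                    truth_rows.append({
                        "participant_id": pid, "eye_id": eye_id, "group": group,
                        "visit": v, "visit_time": t, "eye_scale": scale,
                        "progression_slope": prog, "vf_md_true": vf_true,
                        **{f"{s}_survival": float(survival[SECTOR_ORDER.index(s)])
                           for s in SECTOR_ORDER},
                    })
                made += 1
                if made >= n_eyes:
                    break
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_end_stage_eyes(n_eyes: int, model: NormativeModel | None = None,
                            floor_fraction: float | None = None,
                            measurement_cv: float = 0.02,
                            eye_scale_cv: float = 0.0,
                            seed: int = 20191206) -> list[SectorProfile]:
    """Severe-glaucoma eyes whose worst sector sits exactly at the floor.

    Supports floor-percentage recovery experiments: one arcuate sector has
    survival 0 (thickness = floor × reference, up to multiplicative noise),
    the rest have survival in [0.2, 0.5]. With ``measurement_cv=0`` and
    ``eye_scale_cv=0`` the worst-sector residual equals the floor fraction
    exactly.
    """
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    model = model or load_default_model()
    ff = model.floor_fraction if floor_fraction is None else floor_fraction
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_eyes):
        age = float(np.clip(rng.normal(65.0, 9.0), 40.0, 90.0))
        axlen = float(np.clip(rng.normal(24.0, 1.3), 21.0, 27.0))
        scale = float(_lognormal_factor(rng, eye_scale_cv))
        worst = str(rng.choice(["IT1", "ST1"]))
        thickness = {}
        for s in SECTOR_ORDER:
            ref = reference_thickness(s, age, axlen, model) * scale
            surv = 0.0 if s == worst else float(rng.uniform(0.2, 0.5))
            value = (ff * ref + surv * (1.0 - ff) * ref)
            value *= float(_lognormal_factor(rng, measurement_cv))
            thickness[s] = max(value, 1.0)
        profiles.append(SectorProfile(eye_id=f"SEV{i:04d}", thickness=thickness,
                                      age=age, axial_length=axlen))
    return profiles


def simulate_visit_series(n_eyes: int, noise_sd: float, slope: float = 0.0,
                          baseline: float = 0.0, visits: int = 4,
                          visit_interval: float = 0.5,
                          seed: int = 20191206) -> list[VisitSeries]:
    """Visit series with a linear true trend plus independent Gaussian noise.

    Both the ``nfl_md`` and ``vf_md`` channels receive the same generating
    trend with independent noise draws, so either can be fed to
    reproducibility estimators; the pooled RMS regression residual
    converges to ``noise_sd`` as eyes accumulate.
    """
    if visits < 2:
        raise ValueError("visits must be >= 2")
    rng = np.random.default_rng(seed)
    times = np.arange(visits) * visit_interval
    series = []
    for i in range(n_eyes):
        true = baseline + slope * times
        series.append(VisitSeries(
            eye_id=f"E{i:04d}", participant_id=f"P{i:04d}", times=times,
            nfl_md=true + rng.normal(0.0, noise_sd, size=visits),
            vf_md=true + rng.normal(0.0, noise_sd, size=visits),
        ))
    return series
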