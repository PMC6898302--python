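"""Tabular I/O, quality-control filtering, and the scoring pipeline.

The single ingest dialect is a UTF-8 comma-separated file with one row per
eye-visit. Mandatory columns: ``participant_id, eye_id, laterality,
visit_time, age, axial_length``, the 16 sector thickness columns
(``TU1`` … ``TL1``, µm, in the eye's native orientation), ``overall_nflt,
inferior_nflt`` (µm) and ``vf_md`` (dB). Optional columns: ``visit, group,
vf_psd, ght`` and the QC fields (``ssi, decentration_mm, fixation_loss,
false_pos, false_neg, cataract_grade, bcva_logmar``).

QC exclusion rules mirror the study protocol: scans with SSI ≤ 37 or
decentration > 0.75 mm, fields with ≥ 15% fixation losses or ≥ 33% false
positives/negatives, and eyes with cataract grade > 2 or acuity worse
than 20/30 are excluded, each with a logged rule id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import VisitSeries
from .decibel import (CalibrationModel, SectorProfile, nfl_md, profile_to_decibel,
                      weighted_log_average)
from .normative import NormativeModel, load_default_model
from .sectors import SECTOR_ORDER, mirror_sectors
from .weights import WeightScheme, load_default_weights

__all__ = [
    "MANDATORY_COLUMNS",
    "QC_COLUMNS",
    "QCRules",
    "read_visits",
    "write_visits",
    "qc_filter",
    "select_consecutive_visits",
    "profiles_from_frame",
    "score_frame",
    "series_from_frame",
]

log = logging.getLogger("nflmd")

MANDATORY_COLUMNS: tuple[str, ...] = (
    "participant_id", "eye_id", "laterality", "visit_time", "age", "axial_length",
    *SECTOR_ORDER, "overall_nflt", "inferior_nflt", "vf_md",
)
QC_COLUMNS: tuple[str, ...] = (
    "ssi", "decentration_mm", "fixation_loss", "false_pos", "false_neg",
    "cataract_grade", "bcva_logmar",
)
_NUMERIC = ("visit_time", "age", "axial_length", *SECTOR_ORDER,
            "overall_nflt", "inferior_nflt", "vf_md")


def read_visits(path) -> pd.DataFrame:
    """Read and validate an eye-visit CSV.

    Checks the header, coerces numeric columns (reporting offending line
    numbers), and requires positive sector thicknesses. Sector columns are
    kept in native orientation; :func:`profiles_from_frame` mirrors left
    eyes when profiles are built.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines[:10]}")
        df[col] = coerced
    neg = (df[list(SECTOR_ORDER)] <= 0).any(axis=1)
    if neg.any():
        lines = (df.index[neg] + 2).tolist()
        raise ValueError(f"{path}: non-positive sector thickness at line(s) {lines[:10]}")
    bad_lat = ~df["laterality"].isin(["OD", "OS"])
    if bad_lat.any():
        lines = (df.index[bad_lat] + 2).tolist()
        raise ValueError(f"{path}: laterality must be OD/OS at line(s) {lines[:10]}")
    return df


def write_visits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


@dataclass(frozen=True)
class QCRules:
    """Quality-control exclusion thresholds (defaults follow the study protocol)."""

    min_ssi: float = 37.0              # exclude SSI <= this
    max_decentration: float = 0.75     # exclude > this (mm)
    max_fixation_loss: float = 0.15    # exclude >= this (fraction)
    max_false_positive: float = 0.33   # exclude >= this
    max_false_negative: float = 0.33   # exclude >= this
    max_cataract_grade: float = 2.0    # exclude > this
    max_bcva_logmar: float = 0.18      # exclude worse (higher) than ~20/30

    def violations(self, row: pd.Series) -> list[str]:
        rules = (
            ("ssi", lambda v: v <= self.min_ssi, "ssi_low"),
            ("decentration_mm", lambda v: v > self.max_decentration, "decentration_high"),
            ("fixation_loss", lambda v: v >= self.max_fixation_loss, "fixation_loss_high"),
            ("false_pos", lambda v: v >= self.max_false_positive, "false_positive_high"),
            ("false_neg", lambda v: v >= self.max_false_negative, "false_negative_high"),
            ("cataract_grade", lambda v: v > self.max_cataract_grade, "cataract_dense"),
            ("bcva_logmar", lambda v: v > self.max_bcva_logmar, "acuity_poor"),
        )
        hits = []
        for col, bad, rule_id in rules:
            if col not in row.index or pd.isna(row[col]):
                continue
            if bad(float(row[col])):
                hits.append(rule_id)
        return hits


def qc_filter(df: pd.DataFrame, rules: QCRules | None = None,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split eye-visit rows into retained and excluded per the QC rules.

    Returns ``(retained, exclusion_log)``; the log has one row per excluded
    visit with the triggered rule ids, so every filter decision can be
    reconstructed. Rules whose column is absent are skipped with a warning.
    """
    rules = rules or QCRules()
    absent = [c for c in QC_COLUMNS if c not in df.columns]
    if absent:
        warnings.warn(f"QC columns absent, rules skipped: {absent}", stacklevel=2)
    flags = df.apply(rules.violations, axis=1)
    excluded_mask = flags.map(bool)
    exclusions = pd.DataFrame({
        "row": df.index[excluded_mask],
        "eye_id": df.loc[excluded_mask, "eye_id"],
        "visit_time": df.loc[excluded_mask, "visit_time"]
        if "visit_time" in df.columns else np.nan,
        "rules": flags[excluded_mask].map(",".join),
    }).reset_index(drop=True)
    for _, row in exclusions.iterrows():
        log.info("QC exclusion: eye %s visit %s (%s)", row["eye_id"],
                 row["visit_time"], row["rules"])
    return df.loc[~excluded_mask].copy(), exclusions


def select_consecutive_visits(df: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Earliest *k* visits with complete paired OCT + VF data, per eye.

    Rows with any missing sector thickness or VF_MD are not counted; eyes
    with fewer than *k* complete visits are dropped with a log entry.
    """
    required = [*SECTOR_ORDER, "vf_md"]
    complete = df[required].notna().all(axis=1)
    out = []
    for eye_id, g in df[complete].groupby("eye_id", sort=False):
        g = g.sort_values("visit_time")
        if len(g) < k:
            log.info("eye %s skipped: only %d complete visits (< %d)", eye_id, len(g), k)
            continue
        out.append(g.iloc[:k])
    if not out:
        return df.iloc[0:0].copy()
    return pd.concat(out, axis=0).reset_index(drop=True)


def profiles_from_frame(df: pd.DataFrame) -> list[SectorProfile]:
    """One :class:`SectorProfile` per row (left eyes mirrored to OD orientation)."""
    profiles = []
    for _, row in df.iterrows():
        thickness = {s: float(row[s]) for s in SECTOR_ORDER}
        profiles.append(SectorProfile(
            eye_id=str(row["eye_id"]), thickness=thickness,
            age=float(row["age"]), axial_length=float(row["axial_length"]),
            laterality=str(row["laterality"]),
        ))
    return profiles


def score_frame(df: pd.DataFrame, model: NormativeModel | None = None,
                weights: WeightScheme | None = None,
                calibration: CalibrationModel | None = None) -> pd.DataFrame:
    """Append per-sector dB, NFL_WLA and NFL_MD columns to an eye-visit table.

    Sector losses appear as ``<sector>_db`` (OD orientation); the summary
    columns are ``nfl_wla`` and ``nfl_md_db``, rounded to 2 decimals in the
    output (full precision is used internally for the summary chain).
    """
    model = model or load_default_model()
    weights = weights or load_default_weights()
    calibration = calibration or CalibrationModel()
    out = df.copy()
    db_cols = {f"{s}_db": [] for s in SECTOR_ORDER}
    wla_col, md_col = [], []
    for prof in profiles_from_frame(df):
        db = profile_to_decibel(prof, model)
        for s in SECTOR_ORDER:
            db_cols[f"{s}_db"].append(round(db[s], 2))
        wla = weighted_log_average(db, weights)
        wla_col.append(round(wla, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md_col.append(round(nfl_md(wla, calibration), 2))
    for name, values in db_cols.items():
        out[name] = values
    out["nfl_wla"] = wla_col
    out["nfl_md_db"] = md_col
    return out


def series_from_frame(scored: pd.DataFrame, stage_from: str = "vf_md",
                      ) -> list[VisitSeries]:
    """Group a scored table into per-eye :class:`VisitSeries`.

    The stage label is taken from each eye's visit-mean of ``stage_from``
    (``"vf_md"`` or ``"nfl_md_db"``); pre-perimetric eyes (``group`` column
    equal to ``"ppg"``) get stage 0.
    """
    from .diagnostics import hpa_stage

    series = []
    for eye_id, g in scored.groupby("eye_id", sort=False):
        g = g.sort_values("visit_time")
        if len(g) < 2:
            log.info("eye %s skipped: fewer than 2 visits", eye_id)
            continue
        md = float(g[stage_from].mean())
        ppg = "group" in g.columns and (g["group"].iloc[0] == "ppg")
        stage = hpa_stage(md, basis="VF" if stage_from == "vf_md" else "NFL_MD",
                          ppg=ppg).stage
        series.append(VisitSeries(
            eye_id=str(eye_id), participant_id=str(g["participant_id"].iloc[0]),
            times=g["visit_time"].to_numpy(float),
            vf_md=g["vf_md"].to_numpy(float),
            nfl_md=g["nfl_md_db"].to_numpy(float),
            overall_nflt=g["overall_nflt"].to_numpy(float),
            inferior_nflt=g["inferior_nflt"].to_numpy(float),
            stage=stage,
        ))
    return series
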