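"""VF-area weights for the 16 peripapillary sectors.

Each weight is the visual-field area (counted in 24-2 test points, 52 in
total after excluding the blind spot) whose nerve-fiber bundles traverse a
given peripapillary sector, following a modified Garway-Heath scheme whose
six disc sectors are split into eight by superior/inferior divisions. The
packaged canonical scheme carries these counts already interpolated onto
the 16 equal 22.5° sectors; :func:`interpolate_weights` derives a scheme
from eight-sector counts by arc-overlap allocation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .sectors import SECTOR_ARCS, SECTOR_ORDER, validate_sector_keys

__all__ = [
    "WeightScheme",
    "load_default_weights",
    "load_weights_json",
    "interpolate_weights",
    "DEFAULT_EIGHT_SECTOR_ARCS",
    "WEIGHT_TOTAL",
]

#: The weights of a valid scheme sum to the number of 24-2 test points.
WEIGHT_TOTAL = 52.0

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class WeightScheme:
    """Sixteen non-negative VF-area weights summing to 52.

    ``source`` records provenance: ``figure-constants`` for the packaged
    canonical scheme, ``interpolated`` for schemes derived from
    eight-sector counts.
    """

    weights: Mapping[str, float]
    source: str = "figure-constants"

    def __post_init__(self) -> None:
        validate_sector_keys(self.weights, context="weight scheme")
        arr = self.as_array()
        if np.any(arr < 0):
            raise ValueError("weights must be non-negative")
        total = float(arr.sum())
        if abs(total - WEIGHT_TOTAL) > _SUM_TOL:
            raise ValueError(f"weights must sum to {WEIGHT_TOTAL}, got {total!r}")

    def as_array(self) -> np.ndarray:
        """Weights as a vector in canonical sector order."""
        return np.array([self.weights[s] for s in SECTOR_ORDER], dtype=float)

    def __getitem__(self, sector: str) -> float:
        return self.weights[sector]

    def to_json(self, path) -> None:
        doc = {"schema": "nflmd-vf-area-weights", "version": 1,
               "source": self.source, "weights": dict(self.weights)}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)


def load_weights_json(path) -> WeightScheme:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return WeightScheme(weights=doc["weights"], source=doc.get("source", "figure-constants"))


def load_default_weights() -> WeightScheme:
    """The packaged canonical 16-sector weight scheme (sum 52)."""
    text = resources.files("nflmd.data").joinpath("vf_area_weights.json").read_text()
    doc = json.loads(text)
    return WeightScheme(weights=doc["weights"], source=doc.get("source", "figure-constants"))


#: Default arcs (degrees, OD orientation, 0° temporal horizontal) for the
#: eight modified Garway-Heath sectors: the six Garway-Heath disc sectors
#: with the temporal and nasal sectors split at the horizontal.
DEFAULT_EIGHT_SECTOR_ARCS: dict[str, tuple[float, float]] = {
    "TU": (0.0, 40.0),
    "ST": (40.0, 80.0),
    "SN": (80.0, 120.0),
    "NU": (120.0, 180.0),
    "NL": (180.0, 230.0),
    "IN": (230.0, 270.0),
    "IT": (270.0, 310.0),
    "TL": (310.0, 360.0),
}


def _arc_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Overlap in degrees of two arcs on the circle (each spanning < 360°)."""

    def _segments(arc):
        lo, hi = arc[0] % 360.0, arc[1]
        span = (arc[1] - arc[0]) % 360.0
        if span == 0.0 and arc[1] != arc[0]:
            span = 360.0
        hi = lo + span
        if hi <= 360.0:
            return [(lo, hi)]
        return [(lo, 360.0), (0.0, hi - 360.0)]

    total = 0.0
    for alo, ahi in _segments(a):
        for blo, bhi in _segments(b):
            total += max(0.0, min(ahi, bhi) - max(alo, blo))
    return total


def interpolate_weights(eight_counts: Mapping[str, float],
                        sector_arcs: Mapping[str, tuple[float, float]] | None = None,
                        *, allow_renormalize: bool = False) -> WeightScheme:
    """Spread eight-sector VF-point counts onto the 16 equal sectors.

    Each eight-sector count is distributed over the 22.5° sectors in
    proportion to arc overlap (uniform density within each eight-sector),
    so the total is conserved.

    Parameters
    ----------
    eight_counts
        VF test-point count per modified Garway-Heath sector; must sum to 52
        unless ``allow_renormalize``.
    sector_arcs
        (start, end) degrees per eight-sector; arcs must partition the
        circle. Defaults to :data:`DEFAULT_EIGHT_SECTOR_ARCS`.
    """
    arcs = dict(DEFAULT_EIGHT_SECTOR_ARCS if sector_arcs is None else sector_arcs)
    if set(arcs) != set(eight_counts):
        raise ValueError("eight_counts and sector_arcs must have identical keys")

    spans = {k: (hi - lo) % 360.0 or 360.0 for k, (lo, hi) in arcs.items()}
    if abs(sum(spans.values()) - 360.0) > 1e-6:
        raise ValueError("sector arcs must partition the 360° circle")

    total = float(sum(eight_counts.values()))
    if abs(total - WEIGHT_TOTAL) > _SUM_TOL:
        if not allow_renormalize:
            raise ValueError(
                f"eight-sector counts sum to {total}, expected {WEIGHT_TOTAL} "
                "(pass allow_renormalize=True to rescale)"
            )
        scale = WEIGHT_TOTAL / total
    else:
        scale = 1.0

    weights = {}
    for label in SECTOR_ORDER:
        w = 0.0
        for zone, arc in arcs.items():
            overlap = _arc_overlap(SECTOR_ARCS[label], arc)
            if overlap > 0:
                w += eight_counts[zone] * scale * overlap / spans[zone]
        weights[label] = w
    # guard against accumulated float drift so the scheme validates exactly
    drift = WEIGHT_TOTAL - sum(weights.values())
    if abs(drift) > _SUM_TOL:
        raise ValueError("interpolation failed to conserve total weight")
    return WeightScheme(weights=weights, source="interpolated")
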