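"""Peripapillary sector conventions.

The 3.4-mm peripapillary circle is divided into 16 equal 22.5° sectors.
Labels follow the clinical TSNIT-style naming: first letter is the
quadrant (T temporal, S superior, N nasal, I inferior), second letter the
half toward which the sector leans (U upper, L lower for temporal/nasal;
T temporal, N nasal for superior/inferior), and the digit indexes distance
from the quadrant boundary.

Angles are in right-eye (OD) orientation with 0° at the temporal horizontal,
increasing counter-clockwise (superiorly). Left-eye (OS) profiles are
mirrored across the horizontal at ingest so that superotemporal and
inferotemporal labels stay anatomically consistent.
"""

from __future__ import annotations

from typing import Mapping

#: Sector labels in circular order, starting at the temporal horizontal and
#: proceeding superiorly (TSNIT direction for a right eye).
SECTOR_ORDER: tuple[str, ...] = (
    "TU1", "TU2", "ST2", "ST1", "SN1", "SN2", "NU2", "NU1",
    "NL1", "NL2", "IN2", "IN1", "IT1", "IT2", "TL2", "TL1",
)

#: Summary parameters that share the normative table with the 16 sectors.
SUMMARY_PARAMETERS: tuple[str, ...] = ("overall", "inferior_quadrant")

#: (start, end) arc of each sector in degrees, OD orientation.
SECTOR_ARCS: dict[str, tuple[float, float]] = {
    label: (i * 22.5, (i + 1) * 22.5) for i, label in enumerate(SECTOR_ORDER)
}

# Mirror across the horizontal meridian: angle -> (360 - angle) mod 360.
_MIRROR_PAIRS = (
    ("TU1", "TL1"), ("TU2", "TL2"), ("ST2", "IT2"), ("ST1", "IT1"),
    ("SN1", "IN1"), ("SN2", "IN2"), ("NU2", "NL2"), ("NU1", "NL1"),
)
OS_MIRROR: dict[str, str] = {}
for _a, _b in _MIRROR_PAIRS:
    OS_MIRROR[_a] = _b
    OS_MIRROR[_b] = _a


def mirror_sectors(values: Mapping[str, float]) -> dict[str, float]:
    """Mirror a per-sector mapping across the horizontal meridian.

    Converts a left-eye (OS) profile to right-eye (OD) orientation (the
    operation is its own inverse). Keys that are not sector labels (e.g.
    ``overall``) are passed through unchanged.
    """
    return {OS_MIRROR.get(k, k): v for k, v in values.items()}


def validate_sector_keys(values: Mapping[str, float], *, context: str = "profile") -> None:
    """Raise ``ValueError`` unless *values* has exactly the 16 sector keys."""
    keys = set(values)
    expected = set(SECTOR_ORDER)
    if keys != expected:
        missing = sorted(expected - keys)
        extra = sorted(keys - expected)
        parts = []
        if missing:
            parts.append(f"missing sectors {missing}")
        if extra:
            parts.append(f"unexpected keys {extra}")
        raise ValueError(f"invalid {context}: " + "; ".join(parts))
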