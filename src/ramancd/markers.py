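"""Phe-normalized band-area ratio markers and the threshold decision rule.

The phenylalanine ring-breathing band near 1003 cm^-1 is insensitive to
its micro-environment and serves as an internal intensity standard: the
amide I and CH2-scissoring areas are divided by it, giving the two
dimensionless diagnostic markers

    r1450 = A_1450 / A_1003        r1650 = A_1650 / A_1003.

A subject tests positive on a marker when the ratio strictly exceeds the
marker's cutoff; a value exactly at the cutoff is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .deconvolution import BandFit, band_area
from .exceptions import NormalizationError

__all__ = ["MarkerRecord", "compute_markers", "classify", "markers_from_fits", "marker_table"]

MARKER_NAMES = ("r1450", "r1650")


@dataclass(frozen=True)
class MarkerRecord:
    """The two normalized area ratios for one subject."""

    subject_id: str
    r1450: float
    r1650: float
    label: str = "unknown"


def compute_markers(
    area1650: float,
    area1450: float,
    area1003: float,
    subject_id: str = "",
    label: str = "unknown",
) -> MarkerRecord:
    """Form both ratio markers from the three band areas.

    Raises :class:`NormalizationError` when the internal-standard area is
    non-positive or non-finite — such a subject cannot be normalized.
    """
    if not math.isfinite(area1003) or area1003 <= 0:
        raise NormalizationError(
            f"subject {subject_id or '<unknown>'}: Phe area A1003={area1003!r} "
            "must be finite and > 0"
        )
    if not (math.isfinite(area1650) and math.isfinite(area1450)):
        raise NormalizationError(
            f"subject {subject_id or '<unknown>'}: non-finite band area "
            f"(A1650={area1650!r}, A1450={area1450!r})"
        )
    return MarkerRecord(
        subject_id=subject_id,
        r1450=area1450 / area1003,
        r1650=area1650 / area1003,
        label=label,
    )


def markers_from_fits(fits: dict[str, BandFit], subject_id: str = "", label: str = "unknown") -> MarkerRecord:
    """Markers straight from the per-window deconvolution results."""
    return compute_markers(
        area1650=band_area(fits["amideI"]),
        area1450=band_area(fits["ch2"]),
        area1003=band_area(fits["phe"]),
        subject_id=subject_id or fits["phe"].subject_id,
        label=label,
    )


def classify(record: MarkerRecord, cutoff1450: float, cutoff1650: float) -> dict[str, str]:
    """Per-marker decision: positive iff ratio > cutoff (strictly).

    A ratio exactly equal to its cutoff classifies negative.
    """
    for name, c in (("cutoff1450", cutoff1450), ("cutoff1650", cutoff1650)):
        if not math.isfinite(c):
            raise ValueError(f"{name} must be finite, got {c!r}")
    return {
        "r1450": "positive" if record.r1450 > cutoff1450 else "negative",
        "r1650": "positive" if record.r1650 > cutoff1650 else "negative",
    }


def marker_table(records: list[MarkerRecord]) -> pd.DataFrame:
    """Tidy per-subject marker table (subject_id, r1450, r1650, label)."""
    return pd.DataFrame(
        [(r.subject_id, r.r1450, r.r1650, r.label) for r in records],
        columns=["subject_id", "r1450", "r1650", "label"],
    )
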