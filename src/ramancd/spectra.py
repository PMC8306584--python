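"""Spectrum container and wavenumber-grid construction.

A :class:`Spectrum` stores one subject's Raman measurement as a strictly
increasing wavenumber axis (cm^-1) with matched intensities (arbitrary
units), plus a subject identifier and a disease label. Files recorded in
descending wavenumber order are re-sorted to this canonical order on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DataError

LABELS = ("CD", "nonCD", "unknown")


@dataclass
class Spectrum:
    """One subject's spectrum on a strictly increasing wavenumber grid.

    Parameters
    ----------
    wavenumbers : array-like of float
        Spectral axis in cm^-1, strictly increasing, length >= 2.
    intensities : array-like of float
        Measured intensities (arbitrary units), same length as the axis.
    subject_id : str
        Identifier for the subject the spectrum belongs to.
    label : {"CD", "nonCD", "unknown"}
        Disease class, if known.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    subject_id: str = ""
    label: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise DataError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise DataError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size < 2:
            raise DataError("a spectrum needs at least 2 points")
        diffs = np.diff(self.wavenumbers)
        if np.any(diffs < 0):  # descending input: canonicalise
            order = np.argsort(self.wavenumbers, kind="stable")
            self.wavenumbers = self.wavenumbers[order]
            self.intensities = self.intensities[order]
            diffs = np.diff(self.wavenumbers)
        if np.any(diffs == 0):
            dup = self.wavenumbers[:-1][diffs == 0][0]
            raise DataError(f"duplicate wavenumber {dup!r}")
        if self.label not in LABELS:
            raise DataError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def restrict(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum with wavenumbers in the closed interval [lo, hi]."""
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if mask.sum() < 2:
            raise DataError(f"fewer than 2 points in [{lo}, {hi}]")
        return Spectrum(
            self.wavenumbers[mask],
            self.intensities[mask],
            subject_id=self.subject_id,
            label=self.label,
            meta=dict(self.meta),
        )


def make_grid(grid_min: float, grid_max: float, grid_step: float) -> np.ndarray:
    """Evenly spaced wavenumber grid from grid_min up to (at most) grid_max.

    Mirrors a spectrometer axis: points grid_min, grid_min + step, ...,
    never exceeding grid_max. The default acquisition grid, 400 to
    3100 cm^-1 at 1.9285 cm^-1 resolution, yields 1401 points.

    Raises
    ------
    ConfigError
        If grid_min >= grid_max or grid_step <= 0.
    """
    if not (grid_min < grid_max):
        raise ConfigError(f"grid_min ({grid_min}) must be < grid_max ({grid_max})")
    if not (grid_step > 0):
        raise ConfigError(f"grid_step must be positive, got {grid_step}")
    n = int(np.floor((grid_max - grid_min) / grid_step + 1e-9)) + 1
    return grid_min + grid_step * np.arange(n)
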