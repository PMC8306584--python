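"""Synthetic serum Raman cohort generator.

Real patient sera are not publicly available, so this module generates
labelled spectra whose statistical structure matches what the downstream
analysis assumes: a fixed library of Gaussian vibrational bands on the
400-3100 cm^-1 grid, per-subject log-normal amplitude variation, a smooth
fluorescence-like polynomial baseline, and exposure-averaged Gaussian
noise. Disease status acts multiplicatively on the amide I (~1650 cm^-1)
and CH2-scissoring (~1450 cm^-1) band amplitudes, so the Phe-normalized
area ratios separate the classes.

The generative model for subject s with label L is::

    I_s(nu) = baseline(nu) + sum_i a_{s,i} exp(-(nu - c_i)^2 / (2 sigma_i^2))
              + eps(nu)

where a_{s,i} is log-normal with mean amplitude_mean_i * class_effect_i
(the effect applied only when L = CD) and coefficient of variation
amplitude_cv_i, and eps has per-point standard deviation
noise_sd / sqrt(n_exposures) - the variance reduction obtained by
averaging repeated exposures.

Determinism: each subject draws from ``default_rng(seed + subject_index)``,
so cohorts are extensible without reshuffling earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigError
from .spectra import Spectrum, make_grid

__all__ = [
    "BandSpec",
    "CohortConfig",
    "default_band_library",
    "generate_spectrum",
    "generate_cohort",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian vibrational band in the simulator's library.

    ``class_effect`` multiplies the mean amplitude for CD-class subjects
    (1.0 = band unaffected by disease status).
    """

    center: float
    amplitude_mean: float
    width_sigma: float
    amplitude_cv: float = 0.0
    class_effect: float = 1.0

    def __post_init__(self) -> None:
        if not (400.0 <= self.center <= 3100.0):
            raise ConfigError(f"band center {self.center} outside [400, 3100]")
        if not (self.width_sigma > 0):
            raise ConfigError("width_sigma must be positive")
        if self.amplitude_mean < 0:
            raise ConfigError("amplitude_mean must be >= 0")
        if self.amplitude_cv < 0:
            raise ConfigError("amplitude_cv must be >= 0")
        if not (self.class_effect > 0):
            raise ConfigError("class_effect must be positive")


def default_band_library(
    amplitude_cv: float = 0.12, class_effect: float = 2.0
) -> tuple[BandSpec, ...]:
    """The serum band set used by default cohorts.

    Centers and assignments follow the main vibrational bands seen in
    serum (disulfide 520, tryptophan 759, tyrosine doublet 830/850,
    phenylalanine 1003, amide III ~1300, CH2 scissoring ~1450, amide II
    ~1550, amide I ~1650, C-H stretch ~2935 cm^-1). Widths and relative
    amplitudes are fixed conventions of the simulator. The disease effect
    multiplies the 1650 and 1450 band amplitudes only; the Phe internal
    standard at 1003 cm^-1 is class-independent by construction.
    """
    cv, eff = amplitude_cv, class_effect
    return (
        BandSpec(520.0, 1.5, 6.0, cv),
        BandSpec(759.0, 2.0, 5.0, cv),
        BandSpec(830.0, 1.8, 5.0, cv),
        BandSpec(850.0, 2.0, 5.0, cv),
        BandSpec(1003.0, 6.0, 4.0, cv),
        BandSpec(1300.0, 3.0, 10.0, cv),
        BandSpec(1450.0, 5.0, 9.0, cv, class_effect=eff),
        BandSpec(1550.0, 2.0, 10.0, cv),
        BandSpec(1650.0, 6.0, 12.0, cv, class_effect=eff),
        BandSpec(2935.0, 8.0, 12.0, cv),
    )


@dataclass
class CohortConfig:
    """Simulation parameters for one synthetic cohort.

    Defaults emulate the study conditions: 21 CD and 27 non-CD subjects,
    the 3100-400 cm^-1 grid at 1.9285 cm^-1 resolution, spectra averaged
    over 32 exposures, and a gentle quadratic fluorescence baseline.
    """

    n_cd: int = 21
    n_noncd: int = 27
    grid_min: float = 400.0
    grid_max: float = 3100.0
    grid_step: float = 1.9285
    band_library: tuple[BandSpec, ...] = field(default_factory=default_band_library)
    baseline_coeffs: tuple[float, ...] = (0.1, -3.0e-5, 5.0e-9)
    noise_sd: float = 0.05
    n_exposures: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cd < 0 or self.n_noncd < 0:
            raise ConfigError("group sizes must be >= 0")
        if not (self.grid_min < self.grid_max):
            raise ConfigError("grid_min must be < grid_max")
        if not (self.grid_step > 0):
            raise ConfigError("grid_step must be positive")
        if self.n_exposures < 1:
            raise ConfigError("n_exposures must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        self.band_library = tuple(
            b if isinstance(b, BandSpec) else BandSpec(**b) for b in self.band_library
        )

    def with_(self, **kwargs) -> "CohortConfig":
        """Copy of the config with the given fields replaced."""
        return replace(self, **kwargs)

    def grid(self) -> np.ndarray:
        return make_grid(self.grid_min, self.grid_max, self.grid_step)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    # parametrise so E[X] = mean and SD[X]/E[X] = cv
    s2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * s2
    return mu, np.sqrt(s2)


def generate_spectrum(
    config: CohortConfig, label: str, seed_offset: int = 0
) -> Spectrum:
    """Draw one subject's spectrum under the generative model.

    ``seed_offset`` is the subject index; the subject's random stream is
    ``default_rng(config.seed + seed_offset)``, making every spectrum
    reproducible in isolation.
    """
    if label not in ("CD", "nonCD"):
        raise ConfigError(f"label must be 'CD' or 'nonCD', got {label!r}")
    rng = np.random.default_rng(config.seed + seed_offset)
    nu = config.grid()
    signal = np.polynomial.polynomial.polyval(nu, config.baseline_coeffs)
    for band in config.band_library:
        mean = band.amplitude_mean
        if label == "CD":
            mean *= band.class_effect
        if band.amplitude_cv > 0 and mean > 0:
            mu, s = _lognormal_params(mean, band.amplitude_cv)
            amp = rng.lognormal(mu, s)
        else:
            amp = mean
            rng.lognormal(0.0, 1.0)  # keep the stream aligned across configs
        signal = signal + amp * np.exp(
            -((nu - band.center) ** 2) / (2.0 * band.width_sigma**2)
        )
    if config.noise_sd > 0:
        signal = signal + rng.normal(
            0.0, config.noise_sd / np.sqrt(config.n_exposures), size=nu.size
        )
    return Spectrum(nu, signal, subject_id=f"S{seed_offset:03d}", label=label)


def generate_cohort(config: CohortConfig) -> list[Spectrum]:
    """Generate the full labelled cohort: n_cd CD spectra then n_noncd nonCD.

    Deterministic under a fixed ``config.seed``; subject i always sees the
    stream ``seed + i`` regardless of group sizes.
    """
    cohort: list[Spectrum] = []
    for i in range(config.n_cd):
        cohort.append(generate_spectrum(config, "CD", seed_offset=i))
    for j in range(config.n_noncd):
        cohort.append(generate_spectrum(config, "nonCD", seed_offset=config.n_cd + j))
    return cohort
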