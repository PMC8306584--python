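"""Multi-Gaussian band deconvolution of the diagnostic windows.

Three spectral windows carry the diagnostic information: the amide I
region (1550-1750 cm^-1), the CH2-scissoring region (1400-1500 cm^-1)
and the phenylalanine internal-standard region (990-1015 cm^-1). Each
window is fitted with a sum of Gaussian components by nonlinear least
squares, deliberately *without* a baseline term: raw intensities are
fitted as-is, and the quantity carried downstream is the overall band
area

    A = sum_i a_i * sigma_i * sqrt(2 pi),

the analytic integral of the fitted Gaussian mixture.

Component counts default to 4 (amide I), 3 (CH2) and 1 (Phe); the area is
weakly sensitive to this choice on smooth bands, and counts are
overridable per window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .exceptions import ConfigError, DataError, WindowError
from .spectra import Spectrum

__all__ = [
    "WindowDef",
    "GaussianComponent",
    "BandFit",
    "DEFAULT_WINDOWS",
    "DEFAULT_K",
    "extract_window",
    "initial_peaks",
    "fit_gaussians",
    "band_area",
    "deconvolve_spectrum",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class WindowDef:
    """A named diagnostic window [lo, hi] in cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ConfigError(f"window {self.name}: lo ({self.lo}) must be < hi ({self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: amide I, CH2 scissoring and Phe internal-standard windows
DEFAULT_WINDOWS = (
    WindowDef("amideI", 1550.0, 1750.0),
    WindowDef("ch2", 1400.0, 1500.0),
    WindowDef("phe", 990.0, 1015.0),
)

#: default Gaussian component count per window
DEFAULT_K = {"amideI": 4, "ch2": 3, "phe": 1}


@dataclass(frozen=True)
class GaussianComponent:
    """One fitted Gaussian peak: a * exp(-(nu - c)^2 / (2 sigma^2))."""

    center: float
    amplitude: float
    sigma: float

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * SQRT_2PI

    def __call__(self, nu: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((nu - self.center) ** 2) / (2 * self.sigma**2))


@dataclass
class BandFit:
    """Result of fitting one window: components, analytic area, fit quality."""

    window: WindowDef
    components: tuple[GaussianComponent, ...]
    rss: float
    converged: bool
    n_points: int = 0
    subject_id: str = ""

    @property
    def area(self) -> float:
        return sum(c.area for c in self.components)

    def model(self, nu: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(nu, dtype=float))
        for c in self.components:
            out = out + c(nu)
        return out


def extract_window(spectrum: Spectrum, window: WindowDef, min_points: int = 8) -> Spectrum:
    """Restrict a spectrum to one diagnostic window (closed interval).

    Raises :class:`WindowError` if fewer than ``min_points`` grid points
    fall inside the window.
    """
    mask = (spectrum.wavenumbers >= window.lo) & (spectrum.wavenumbers <= window.hi)
    n = int(mask.sum())
    if n < min_points:
        raise WindowError(
            f"window {window.name} [{window.lo}, {window.hi}] covers {n} grid "
            f"points; need at least {min_points}"
        )
    return Spectrum(
        spectrum.wavenumbers[mask],
        spectrum.intensities[mask],
        subject_id=spectrum.subject_id,
        label=spectrum.label,
        meta=dict(spectrum.meta),
    )


def initial_peaks(window_spectrum: Spectrum, k: int) -> list[GaussianComponent]:
    """Starting components for the fit.

    Centers sit at the k most prominent local maxima (ties broken toward
    lower wavenumber); if the signal has fewer maxima, remaining centers
    are spread uniformly across the window. Start amplitudes are the local
    intensities and every start sigma is window_width / (4 k).
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    nu, y = window_spectrum.wavenumbers, window_spectrum.intensities
    if k > nu.size:
        raise ConfigError(f"k={k} exceeds the {nu.size} points in the window")
    width = nu[-1] - nu[0]
    sigma0 = width / (4.0 * k)

    idx, props = find_peaks(y, prominence=0.0)
    if idx.size:
        prom = props["prominences"]
        # stable sort on (-prominence, wavenumber): equal prominence -> lower nu first
        order = np.lexsort((nu[idx], -prom))
        idx = idx[order]
    centers = list(nu[idx[:k]])
    amps = list(y[idx[:k]])
    n_missing = k - len(centers)
    if n_missing > 0:
        # uniform spread over the window for the remainder
        fill = nu[0] + (np.arange(1, n_missing + 1) / (n_missing + 1)) * width
        centers.extend(fill)
        amps.extend(np.interp(fill, nu, y))
    comps = [
        GaussianComponent(float(c), float(max(a, 0.0)), sigma0)
        for c, a in zip(centers, amps)
    ]
    comps.sort(key=lambda g: g.center)
    return comps


def fit_gaussians(
    window_spectrum: Spectrum,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> BandFit:
    """Fit a k-component Gaussian mixture to one window, no baseline term.

    Bounds keep amplitudes within [0, 1.5 * max intensity], sigmas between
    the grid step and half the window width, and allow centers to drift at
    most 10% of the window width beyond its edges (a soft bound that
    avoids edge artifacts while keeping the analytic area meaningful: an
    unbounded component sitting outside the window, or one much wider
    than it, can carry arbitrary analytic area that the data never
    constrain). Non-convergence is reported via ``converged=False``,
    never raised.
    """
    nu, y = window_spectrum.wavenumbers, window_spectrum.intensities
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(nu)):
        raise DataError("window contains NaN/inf intensities")
    starts = initial_peaks(window_spectrum, k)

    width = nu[-1] - nu[0]
    step = float(np.min(np.diff(nu)))
    margin = 0.1 * width
    sigma_max = width / 2.0
    amp_max = 1.5 * float(np.max(np.abs(y))) + 1e-12
    lo_b, hi_b = [], []
    p0 = []
    for g in starts:
        p0 += [
            min(g.amplitude, 0.99 * amp_max),
            g.center,
            max(min(g.sigma, sigma_max), step),
        ]
        lo_b += [0.0, nu[0] - margin, step]
        hi_b += [amp_max, nu[-1] + margin, sigma_max]

    def residuals(p: np.ndarray) -> np.ndarray:
        a = p[0::3][:, None]
        c = p[1::3][:, None]
        s = p[2::3][:, None]
        model = (a * np.exp(-((nu[None, :] - c) ** 2) / (2 * s**2))).sum(axis=0)
        return model - y

    def jacobian(p: np.ndarray) -> np.ndarray:
        J = np.empty((nu.size, p.size))
        for i in range(k):
            a, c, s = p[3 * i], p[3 * i + 1], p[3 * i + 2]
            d = nu - c
            g = np.exp(-(d**2) / (2 * s**2))
            J[:, 3 * i] = g
            J[:, 3 * i + 1] = a * g * d / s**2
            J[:, 3 * i + 2] = a * g * d**2 / s**3
        return J

    res = least_squares(
        residuals,
        np.asarray(p0),
        jac=jacobian,
        bounds=(lo_b, hi_b),
        ftol=tol,
        xtol=1e-9,
        gtol=1e-12,
        max_nfev=max_iter,
        method="trf",
    )
    comps = tuple(
        sorted(
            (
                GaussianComponent(float(c), float(a), float(s))
                for a, c, s in zip(res.x[0::3], res.x[1::3], res.x[2::3])
            ),
            key=lambda g: g.center,
        )
    )
    rss = float(2.0 * res.cost)
    converged = bool(res.success)
    return BandFit(
        window=WindowDef("window", nu[0], nu[-1])
        if not isinstance(window_spectrum.meta.get("window"), WindowDef)
        else window_spectrum.meta["window"],
        components=comps,
        rss=rss,
        converged=converged,
        n_points=nu.size,
        subject_id=window_spectrum.subject_id,
    )


def band_area(fit: BandFit) -> float:
    """Overall band area of a converged fit, sum_i a_i sigma_i sqrt(2 pi).

    Refuses unconverged fits so that silently bad areas cannot propagate
    into the markers.
    """
    if not fit.converged:
        raise DataError(
            f"fit for window [{fit.window.lo}, {fit.window.hi}] did not converge "
            f"(rss={fit.rss:.3g}, {len(fit.components)} components)"
        )
    return fit.area


def deconvolve_spectrum(
    spectrum: Spectrum,
    windows: tuple[WindowDef, ...] = DEFAULT_WINDOWS,
    k_by_window: dict[str, int] | None = None,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> dict[str, BandFit]:
    """Fit every diagnostic window of one spectrum; keys are window names."""
    k_map = dict(DEFAULT_K)
    if k_by_window:
        k_map.update(k_by_window)
    fits: dict[str, BandFit] = {}
    for w in windows:
        sub = extract_window(spectrum, w)
        sub.meta["window"] = w
        fit = fit_gaussians(sub, k=k_map.get(w.name, 1), max_iter=max_iter, tol=tol)
        fit.window = w
        fits[w.name] = fit
    return fits
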