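"""STED line-profile analysis of RecA filament width.

A filament is modelled as a cylinder whose fluorophores sit in a thin shell
at its surface (outer radius d/2, shell thickness 3 nm by default, the length
of an antibody-coupled label). The intensity profile measured perpendicular
to the filament axis is the line-of-sight projection of that annular cross
section convolved with the microscope point-spread function, which for the
STED system is Lorentzian. ``forward_fwhm`` evaluates that forward model on
a fine grid; ``invert_diameter`` root-finds the diameter whose predicted
profile width matches an observed Gaussian-fit FWHM — a model-based
deconvolution of the measured width.

All lengths in nanometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit


@dataclass(frozen=True)
class PsfModel:
    """Lorentzian point-spread function, parameterised by its FWHM W (nm)."""

    fwhm: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("PSF FWHM must be positive")


@dataclass
class WidthEstimate:
    """Result of deconvolving an observed profile width."""

    observed_fwhm: float
    psf_fwhm: float
    shell_thickness: float
    diameter: float
    diameter_sd: float | None = None

    def to_dict(self) -> dict:
        return {
            "observed_fwhm_nm": self.observed_fwhm,
            "psf_fwhm_nm": self.psf_fwhm,
            "shell_thickness_nm": self.shell_thickness,
            "diameter_nm": self.diameter,
            "diameter_sd_nm": self.diameter_sd,
        }


def lorentzian(x: np.ndarray, amplitude: float, center: float, fwhm: float,
               offset: float = 0.0) -> np.ndarray:
    """Lorentzian with unit peak at the center scaled by ``amplitude``."""
    hw = fwhm / 2.0
    return amplitude * hw * hw / ((x - center) ** 2 + hw * hw) + offset


def gaussian(x: np.ndarray, amplitude: float, center: float, fwhm: float,
             offset: float = 0.0) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def _fit_peak(positions, intensities, model, p0) -> tuple[float, np.ndarray]:
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if positions.size < 7:
        raise ValueError("need at least 7 samples spanning the peak")
    span = intensities.max() - intensities.min()
    if span <= 0 or span < 1e-6 * abs(intensities.max()):
        raise RuntimeError("flat profile: peak fit cannot converge")
    try:
        popt, _ = curve_fit(model, positions, intensities, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"peak fit did not converge: {exc}") from exc
    if popt[2] <= 0 or popt[0] <= 0:
        raise RuntimeError("peak fit converged to a non-physical solution")
    return float(abs(popt[2])), popt


def _initial_guess(positions, intensities):
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    off = float(intensities.min())
    amp = float(intensities.max() - off)
    center = float(positions[np.argmax(intensities)])
    above = positions[intensities - off > amp / 2.0]
    width = float(above.max() - above.min()) if above.size > 1 else float(
        positions[1] - positions[0]
    )
    return [amp, center, max(width, 1e-3), off]


def fit_lorentzian(positions, intensities) -> float:
    """Least-squares Lorentzian fit; returns the FWHM (nm)."""
    fwhm, _ = _fit_peak(positions, intensities, lorentzian,
                        _initial_guess(positions, intensities))
    return fwhm


def average_two_pixels(positions, intensities) -> tuple[np.ndarray, np.ndarray]:
    """Average adjacent pixel pairs, the preprocessing applied before Gaussian fits."""
    p = np.asarray(positions, dtype=float)
    v = np.asarray(intensities, dtype=float)
    n = (p.size // 2) * 2
    return p[:n].reshape(-1, 2).mean(axis=1), v[:n].reshape(-1, 2).mean(axis=1)


def fit_gaussian(positions, intensities, two_pixel_average: bool = False) -> float:
    """Gaussian fit of a filament profile; returns the FWHM (nm).

    Measured profiles are averaged over two pixels *across* the scan lines
    (along the filament axis) for noise reduction, which does not broaden the
    transverse profile; synthetic 1D profiles arrive already reduced. The
    optional along-profile pair averaging is provided for raw traces but is
    off by default because it widens the profile by the pixel boxcar.
    """
    if two_pixel_average:
        positions, intensities = average_two_pixels(positions, intensities)
    fwhm, _ = _fit_peak(positions, intensities, gaussian,
                        _initial_guess(positions, intensities))
    return fwhm


def shell_projection(x: np.ndarray, diameter: float, shell: float) -> np.ndarray:
    """Line-of-sight projection of an annular cross section.

    Outer radius a = diameter/2, inner radius b = max(a − shell, 0); the
    projected intensity at transverse offset x is the chord length through
    the annulus, 2(√(a²−x²) − √(b²−x²)).
    """
    a = diameter / 2.0
    b = max(a - shell, 0.0)
    xx = np.asarray(x, dtype=float)
    outer = np.sqrt(np.clip(a * a - xx * xx, 0.0, None))
    inner = np.sqrt(np.clip(b * b - xx * xx, 0.0, None))
    return 2.0 * (outer - inner)


def _profile_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM by linear interpolation of the half-maximum crossings."""
    ymax = y.max()
    if ymax <= 0:
        raise RuntimeError("profile has no positive peak")
    half = ymax / 2.0
    above = y >= half
    if not above.any():
        raise RuntimeError("no samples above half maximum")
    i0, i1 = np.argmax(above), len(above) - 1 - np.argmax(above[::-1])
    if i0 == 0 or i1 == len(y) - 1:
        raise RuntimeError("profile grid too narrow: half maximum not bracketed")
    xl = np.interp(half, [y[i0 - 1], y[i0]], [x[i0 - 1], x[i0]])
    xr = np.interp(half, [y[i1 + 1], y[i1]], [x[i1 + 1], x[i1]])
    return float(xr - xl)


def forward_profile(
    diameter: float,
    shell: float = 3.0,
    psf_fwhm: float = 35.0,
    grid_nm: float = 0.5,
    extent_nm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted line profile: shell projection convolved with the Lorentzian PSF.

    ``diameter = 0`` is the point-source limit and returns the bare PSF. The
    grid spacing must resolve both the shell and the PSF (≤ 1 nm).
    """
    if diameter < 0 or shell < 0:
        raise ValueError("diameter and shell must be non-negative")
    if psf_fwhm <= 0:
        raise ValueError("psf_fwhm must be positive")
    if grid_nm > 1.0:
        raise RuntimeError("grid resolution failure: need grid_nm <= 1 nm")
    if extent_nm is None:
        extent_nm = 6.0 * psf_fwhm + 2.0 * diameter + 50.0
    x = np.arange(-extent_nm, extent_nm + grid_nm / 2, grid_nm)
    psf = lorentzian(x, 1.0, 0.0, psf_fwhm)
    proj = shell_projection(x, diameter, shell) if diameter > 0 and shell > 0 else None
    if proj is None or proj.max() <= 0:
        # point-source limit (or diameter below the grid resolution)
        y = psf.copy()
    else:
        y = np.convolve(proj, psf, mode="same") * grid_nm
    return x, y / y.max()


def forward_fwhm(
    diameter: float,
    shell: float = 3.0,
    psf_fwhm: float = 35.0,
    grid_nm: float = 0.5,
) -> float:
    """FWHM of the forward-model profile; monotone increasing in diameter."""
    x, y = forward_profile(diameter, shell, psf_fwhm, grid_nm)
    return _profile_fwhm(x, y)


def invert_diameter(
    observed_fwhm: float,
    psf_fwhm: float = 35.0,
    shell: float = 3.0,
    observed_sd: float | None = None,
    psf_sd: float | None = None,
    n_mc: int = 200,
    seed: int = 0,
    tolerance_nm: float = 0.5,
) -> WidthEstimate:
    """Diameter whose forward-model FWHM equals the observed FWHM.

    If the observed width is below the PSF width (beyond ``tolerance_nm``)
    the filament is unresolved and the diameter is reported as 0 with a
    warning. When input standard deviations are given, the uncertainty of
    the diameter is propagated by Monte Carlo resampling of the two widths.
    """
    if observed_fwhm <= 0:
        raise ValueError("observed_fwhm must be positive")

    def solve(obs: float, psf: float) -> float:
        base = forward_fwhm(0.0, shell, psf)
        if obs <= base + 1e-9:
            return 0.0
        hi = max(4.0 * (obs - psf), 2.0 * shell, 10.0)
        while forward_fwhm(hi, shell, psf) < obs:
            hi *= 2.0
            if hi > 1e5:
                raise RuntimeError("diameter inversion failed to bracket the root")
        return brentq(lambda d: forward_fwhm(d, shell, psf) - obs, 0.0, hi,
                      xtol=tolerance_nm / 4.0)

    if observed_fwhm < psf_fwhm - tolerance_nm:
        warnings.warn(
            "observed FWHM below the PSF FWHM: filament unresolved, diameter set to 0",
            stacklevel=2,
        )
        diameter = 0.0
    else:
        diameter = solve(observed_fwhm, psf_fwhm)

    diameter_sd = None
    if observed_sd is not None or psf_sd is not None:
        rng = np.random.default_rng(seed)
        obs_draws = observed_fwhm + (observed_sd or 0.0) * rng.standard_normal(n_mc)
        psf_draws = psf_fwhm + (psf_sd or 0.0) * rng.standard_normal(n_mc)
        samples = []
        for o, p in zip(obs_draws, psf_draws):
            if o <= 0 or p <= 0:
                continue
            samples.append(solve(o, p) if o >= p - tolerance_nm else 0.0)
        diameter_sd = float(np.std(samples, ddof=1)) if len(samples) > 1 else None

    return WidthEstimate(observed_fwhm, psf_fwhm, shell, float(diameter), diameter_sd)
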