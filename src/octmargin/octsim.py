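"""Spectral-domain OCT source physics: axial resolution and a minimal
A-line simulator/reconstructor used to validate it.

For a Gaussian source spectrum with center wavelength lambda0 and FWHM
bandwidth dlambda, the theoretical axial resolution (round-trip coherence
length, in air) is

    dz = (2 ln2 / pi) * lambda0**2 / dlambda

The simulator produces interferometric spectral fringes for point
reflectors — Gaussian envelope modulated by cos(2 k z + phi(k)) — with
optional group-velocity-dispersion phase and a nonlinear wavelength grid,
and the reconstructor inverts both (k-space resampling, envelope removal,
conjugate dispersion phase, FFT) to recover the depth profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SourceSpectrum",
    "ALine",
    "axial_resolution",
    "simulate_interferogram",
    "reconstruct_aline",
    "psf_fwhm",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SourceSpectrum:
    """Gaussian OCT light source sampled on a wavelength grid.

    Attributes
    ----------
    center_nm : float
        Central wavelength lambda0 in nm.
    fwhm_nm : float
        Full width at half maximum bandwidth in nm.
    n_samples : int
        Spectral sample count; grid spans +/- `span_sigma` Gaussian sigma.
    span_sigma : float
        Half-width of the sampled grid in units of the Gaussian sigma.
    """

    center_nm: float = 1310.0
    fwhm_nm: float = 100.0
    n_samples: int = 2048
    span_sigma: float = 3.0

    def __post_init__(self):
        if self.center_nm <= 0:
            raise ValueError("center wavelength must be positive")
        if self.fwhm_nm <= 0:
            raise ValueError("bandwidth must be positive")
        if self.n_samples < 16:
            raise ValueError("need at least 16 spectral samples")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm / _FWHM_PER_SIGMA

    @property
    def wavelengths_nm(self) -> np.ndarray:
        half = self.span_sigma * self.sigma_nm
        return np.linspace(self.center_nm - half, self.center_nm + half,
                           self.n_samples)

    def envelope(self, wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
        """Gaussian power envelope on the given (default: own) grid."""
        lam = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return np.exp(-0.5 * ((lam - self.center_nm) / self.sigma_nm) ** 2)


@dataclass(frozen=True)
class ALine:
    """One-sided depth-resolved magnitude profile."""

    depth_um: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.depth_um, dtype=float)
        m = np.asarray(self.magnitude, dtype=float)
        if z.shape != m.shape:
            raise ValueError("depth axis and magnitude must share shape")
        if np.any(m < 0):
            raise ValueError("magnitude must be non-negative")
        dz = np.diff(z)
        if z.size > 1 and not np.allclose(dz, dz[0]):
            raise ValueError("depth axis must be uniform")
        object.__setattr__(self, "depth_um", z)
        object.__setattr__(self, "magnitude", m)


def axial_resolution(spectrum: SourceSpectrum) -> float:
    """Theoretical axial resolution in air, micrometres.

    (2 ln2 / pi) * lambda0^2 / dlambda, homogeneous of degree 1 in
    (lambda0, dlambda) jointly.
    """
    dz_nm = (2.0 * np.log(2.0) / np.pi) * spectrum.center_nm ** 2 / spectrum.fwhm_nm
    return dz_nm / 1000.0


def _sample_grid(spectrum: SourceSpectrum, k_nonlinearity: float) -> np.ndarray:
    """Detector wavelength grid, optionally warped to emulate a
    spectrometer that is nonlinear in wavenumber."""
    lam = spectrum.wavelengths_nm
    if k_nonlinearity == 0.0:
        return lam
    # quadratic warp of the normalized coordinate, monotone for |a| < 0.5
    u = (lam - lam[0]) / (lam[-1] - lam[0])
    warped = u + k_nonlinearity * u * (1.0 - u)
    return lam[0] + warped * (lam[-1] - lam[0])


def simulate_interferogram(reflectors, spectrum: SourceSpectrum,
                           dispersion_coeff: float = 0.0,
                           k_nonlinearity: float = 0.0) -> np.ndarray:
    """Spectral fringes for a set of point reflectors.

    Parameters
    ----------
    reflectors : list of (depth_um, reflectivity)
        Point reflectors; depths >= 0 um, reflectivities in [0, 1].
    dispersion_coeff : float
        Quadratic (group-velocity) dispersion phase coefficient in
        rad/(rad/nm)^2: phi(k) = c2 * (k - k0)^2.
    k_nonlinearity : float
        Warp amplitude of the detector wavelength grid (0 = linear).

    Returns
    -------
    ndarray
        S(lambda) * (1 + sum_r 2 sqrt(R_r) cos(2 k z_r + phi(k))) sampled
        on the (possibly warped) detector grid.
    """
    if len(reflectors) == 0:
        raise ValueError("at least one reflector is required")
    lam = _sample_grid(spectrum, k_nonlinearity)
    k = 2.0 * np.pi / lam  # rad/nm
    k0 = 2.0 * np.pi / spectrum.center_nm
    envelope = spectrum.envelope(lam)
    fringes = np.ones_like(lam)
    phi = dispersion_coeff * (k - k0) ** 2
    for depth_um, refl in reflectors:
        if depth_um < 0:
            raise ValueError("reflector depth must be non-negative")
        if not 0 <= refl <= 1:
            raise ValueError("reflectivity must be in [0, 1]")
        z_nm = depth_um * 1000.0
        fringes = fringes + 2.0 * np.sqrt(refl) * np.cos(2.0 * k * z_nm + phi)
    return envelope * fringes


def reconstruct_aline(fringes: np.ndarray, spectrum: SourceSpectrum,
                      compensate_dispersion: bool = False,
                      dispersion_coeff: float = 0.0,
                      k_nonlinearity: float = 0.0,
                      zero_pad: int = 4) -> ALine:
    """Reconstruct a depth profile from spectral fringes.

    Steps: resample to a uniform wavenumber grid, remove the source
    envelope (DC term), apply the conjugate dispersion phase when
    ``compensate_dispersion`` is set, Fourier transform, and return the
    one-sided magnitude with a calibrated depth axis.
    """
    fringes = np.asarray(fringes, dtype=float)
    lam_det = _sample_grid(spectrum, k_nonlinearity)
    if fringes.shape != lam_det.shape:
        raise ValueError("fringes must be sampled on the spectrum's grid")

    k_det = 2.0 * np.pi / lam_det
    order = np.argsort(k_det)
    k_sorted, f_sorted = k_det[order], fringes[order]
    k_uni = np.linspace(k_sorted[0], k_sorted[-1], fringes.size)
    f_uni = np.interp(k_uni, k_sorted, f_sorted)

    # remove the DC envelope term: S(k) on the uniform-k grid
    lam_uni = 2.0 * np.pi / k_uni
    env = spectrum.envelope(lam_uni)
    signal = f_uni - env

    analytic = _analytic_signal(signal)
    if compensate_dispersion and dispersion_coeff != 0.0:
        k0 = 2.0 * np.pi / spectrum.center_nm
        analytic = analytic * np.exp(-1j * dispersion_coeff * (k_uni - k0) ** 2)

    n = fringes.size * max(1, int(zero_pad))
    spectrum_fft = np.fft.fft(analytic, n=n)
    magnitude = np.abs(spectrum_fft[: n // 2])

    dk = k_uni[1] - k_uni[0]  # rad/nm
    # fringe cos(2 k z) has frequency 2z cycles per (2 pi rad of k);
    # FFT bin m corresponds to z = m * pi / (n * dk) (nm)
    depth_nm = np.arange(n // 2) * np.pi / (n * dk)
    return ALine(depth_um=depth_nm / 1000.0, magnitude=magnitude)


def _analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal via one-sided spectrum (Hilbert transform)."""
    n = x.size
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1: n // 2] = 2.0
    else:
        h[1: (n + 1) // 2] = 2.0
    return np.fft.ifft(X * h)


def psf_fwhm(aline: ALine) -> float:
    """Full width at half maximum of the A-line peak, micrometres.

    Linear interpolation between samples on both flanks.  Raises if the
    profile has no peak (flat line).
    """
    m = aline.magnitude
    z = aline.depth_um
    if np.ptp(m) == 0:
        raise ValueError("flat profile has no peak")
    i = int(np.argmax(m))
    half = m[i] / 2.0

    # walk left
    j = i
    while j > 0 and m[j] > half:
        j -= 1
    if m[j] > half:
        left = z[0]
    else:
        left = np.interp(half, [m[j], m[j + 1]], [z[j], z[j + 1]])

    j = i
    while j < m.size - 1 and m[j] > half:
        j += 1
    if m[j] > half:
        right = z[-1]
    else:
        right = np.interp(half, [m[j], m[j - 1]], [z[j], z[j - 1]])

    width = right - left
    if width <= 0:
        # delta-like single-sample peak
        width = z[1] - z[0] if z.size > 1 else 0.0
    return float(width)
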