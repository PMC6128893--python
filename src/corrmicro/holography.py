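"""Near-field holography: Fresnel propagation, CTF inversion, RAAR retrieval.

The sample is treated as a pure phase object: the exit wave is
``exp(i*phi)`` with ``phi <= 0`` (phase advance of hard X-rays in matter,
``phi = -k*delta*t``).  Free-space propagation over the effective distance
turns phase into measurable intensity contrast.  Phase retrieval proceeds
in two stages, mirroring common practice at holo-tomography endstations:

1. a linearized contrast-transfer-function (CTF) inversion, valid for weak
   phases, used both as a direct estimate and to derive a support mask;
2. iterative refinement with relaxed averaged alternating reflections
   (RAAR) enforcing the measured hologram modulus, the support, and the
   pure-phase (unit amplitude, non-positive phase) object constraint.

Sign conventions, fixed for reproducibility: forward DFT kernel
``exp(-i 2 pi nu . r)`` (numpy default) and propagator multiplier
``exp(-i pi lambda d |nu|^2)``, so the weak-object transfer of phase to
intensity contrast is ``I - 1 = 2 * F^-1[ sin(chi) * F[phi] ]`` with
``chi = pi lambda d |nu|^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .geometry import OpticalGeometry

MM_TO_NM = 1e6


@dataclass
class Hologram:
    """Flat-field-normalized near-field intensity (empty beam -> 1)."""

    intensity: np.ndarray
    geometry: OpticalGeometry

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram must be a 2D array")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")


@dataclass
class PhaseMap:
    """Reconstructed phase in radians, sampled at the effective pixel size."""

    phase: np.ndarray
    pixel_size: float  # nm

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase map must be finite everywhere")


class SamplingError(ValueError):
    """Propagator kernel would alias on the given grid."""


def _freq_grids(shape: tuple[int, int], pixel_size: float):
    ny = np.fft.fftfreq(shape[0], d=pixel_size)
    nx = np.fft.fftfreq(shape[1], d=pixel_size)
    return np.meshgrid(ny, nx, indexing="ij")


def check_sampling(
    shape: tuple[int, int], pixel_size: float, wavelength: float, distance: float
) -> None:
    """Raise :class:`SamplingError` if the Fresnel transfer function aliases.

    The kernel phase ``chi = pi lambda d |nu|^2`` must change by less than
    pi between adjacent frequency samples at the edge of the grid, which
    reduces to ``lambda * |d| < N * p**2`` (all lengths in nm).
    """
    n = min(shape)
    if wavelength * abs(distance) >= n * pixel_size**2:
        raise SamplingError(
            f"Fresnel propagator aliased: lambda*d = {wavelength * abs(distance):.3g} nm^2 "
            f"exceeds N*p^2 = {n * pixel_size**2:.3g} nm^2; "
            "enlarge the grid or reduce the propagation distance"
        )


def fresnel_propagate(
    field: np.ndarray,
    pixel_size: float,
    wavelength: float,
    distance: float,
) -> np.ndarray:
    """Angular-spectrum (Fresnel transfer function) propagation.

    Parameters
    ----------
    field : complex 2D array
        Wave field in the source plane.
    pixel_size, wavelength, distance : float
        All in nm; ``distance`` may be negative (back-propagation).

    Returns the complex field after propagation.  Energy is conserved
    exactly (the multiplier is unimodular), and propagation by ``d`` then
    ``-d`` is the identity.
    """
    field = np.asarray(field, dtype=complex)
    if field.ndim != 2:
        raise ValueError("field must be 2D")
    if pixel_size <= 0 or wavelength <= 0:
        raise ValueError("pixel size and wavelength must be positive")
    if distance == 0:
        return field.copy()
    check_sampling(field.shape, pixel_size, wavelength, distance)
    ny, nx = _freq_grids(field.shape, pixel_size)
    kernel = np.exp(-1j * np.pi * wavelength * distance * (ny**2 + nx**2))
    return np.fft.ifft2(np.fft.fft2(field) * kernel)


def _chi(shape: tuple[int, int], pixel_size: float, wavelength: float, distance: float):
    ny, nx = _freq_grids(shape, pixel_size)
    return np.pi * wavelength * distance * (ny**2 + nx**2)


def ctf_phase_retrieval(
    holo: Hologram,
    alpha_low: float = 1e-3,
    alpha_high: float = 1e-1,
    zero_border: int = 0,
) -> PhaseMap:
    """Linearized (weak-phase) CTF inversion of a normalized hologram.

    phi_hat(nu) = F[I - 1] * sin(chi) / (2 sin^2(chi) + alpha(nu)),
    chi = pi lambda z_eff |nu|^2.

    ``alpha`` is a two-level Tikhonov regularizer: ``alpha_low`` below the
    first CTF maximum (chi < pi/2, where low frequencies are weakly
    transferred) and ``alpha_high`` above (where zero crossings of sin chi
    amplify noise).

    The DC Fourier coefficient carries no contrast (sin chi = 0 at nu=0),
    so the inversion recovers the phase only up to a global offset.  If
    ``zero_border`` > 0, the offset is fixed by forcing the mean phase
    over a border frame of that pixel width to zero — valid whenever the
    object does not touch the edge of the field of view.
    """
    geom = holo.geometry
    if geom.z_eff <= 0:
        raise ValueError("z_eff must be positive: no contrast transfer at contact")
    pixel = geom.pixel_size_eff
    lam = geom.wavelength
    z_nm = geom.z_eff * MM_TO_NM
    chi = _chi(holo.intensity.shape, pixel, lam, z_nm)
    sin_chi = np.sin(chi)
    alpha = np.where(chi < np.pi / 2, alpha_low, alpha_high)
    spectrum = np.fft.fft2(holo.intensity - 1.0)
    phase = np.fft.ifft2(spectrum * sin_chi / (2.0 * sin_chi**2 + alpha)).real
    if zero_border > 0:
        border = np.zeros(phase.shape, dtype=bool)
        border[:zero_border, :] = border[-zero_border:, :] = True
        border[:, :zero_border] = border[:, -zero_border:] = True
        phase = phase - phase[border].mean()
    return PhaseMap(phase=phase, pixel_size=pixel)


def estimate_support(
    phase_ctf: PhaseMap,
    smoothing_fwhm: float = 6.0,
    threshold_fraction: float = 0.1,
    dilation: int = 4,
) -> np.ndarray:
    """Support mask from a (CTF) phase estimate.

    Smooth with a Gaussian of the given FWHM (pixels), threshold at
    ``threshold_fraction`` times the most negative phase, keep the largest
    connected component, then morphologically close and dilate.
    """
    sigma = smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    smooth = ndimage.gaussian_filter(phase_ctf.phase, sigma)
    phi_min = smooth.min()
    if phi_min >= 0:
        raise ValueError("empty support: phase estimate has no negative values")
    mask = smooth < threshold_fraction * phi_min
    if not mask.any():
        raise ValueError("empty support after thresholding")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_closing(mask, structure=morphology.disk(3))
    if dilation > 0:
        mask = ndimage.binary_dilation(mask, structure=morphology.disk(dilation))
    return mask


@dataclass
class RAARResult:
    phase_map: PhaseMap
    residuals: np.ndarray  # relative magnitude residual per iteration
    field: np.ndarray = field(repr=False, default=None)


def raar_reconstruct(
    holo: Hologram,
    support: np.ndarray,
    beta: float | Sequence[float] = 0.99,
    n_iter: int = 500,
    init: PhaseMap | None = None,
    enforce_nonpositive: bool = True,
) -> RAARResult:
    """RAAR iterative phase retrieval with support + pure-phase constraints.

    The iterate ``u`` lives in the object plane.  The modulus projector
    ``P_M`` propagates to the detector, replaces the modulus by
    ``sqrt(I)`` and back-propagates; the object projector ``P_S`` sets the
    modulus to 1 everywhere, the phase to 0 outside the support and (by
    default) clips the phase to <= 0 inside.  The update is

        u <- beta * 0.5 * (R_S R_M + I) u + (1 - beta) * P_M u

    with reflectors ``R = 2P - I``.  ``beta`` is either a constant or a
    per-iteration schedule (any sequence, cycled through by index and
    clamped at its last value).  Values near 1 give the fastest
    convergence on consistent (noiseless) data; for Poisson-noisy
    holograms, where the constraint sets do not intersect, a more relaxed
    beta around 0.5-0.8 keeps the iteration bounded.  Returns the final
    object phase and the per-iteration relative magnitude residual
    ``|| |D u| - sqrt(I) || / || sqrt(I) ||``.
    """
    support = np.asarray(support, dtype=bool)
    if support.shape != holo.intensity.shape:
        raise ValueError("support shape must match hologram")
    if not support.any():
        raise ValueError("support must be nonempty")
    if init is None:
        init = ctf_phase_retrieval(holo)
    geom = holo.geometry
    pixel = geom.pixel_size_eff
    lam = geom.wavelength
    z_nm = geom.z_eff * MM_TO_NM
    sqrt_i = np.sqrt(holo.intensity)
    sqrt_i_norm = np.linalg.norm(sqrt_i)

    def project_modulus(u):
        det = fresnel_propagate(u, pixel, lam, z_nm)
        mod = np.abs(det)
        det = np.where(mod > 0, sqrt_i * det / np.where(mod > 0, mod, 1.0), sqrt_i)
        return fresnel_propagate(det, pixel, lam, -z_nm)

    def project_object(u):
        phi = np.angle(u)
        phi = np.where(support, phi, 0.0)
        if enforce_nonpositive:
            phi = np.minimum(phi, 0.0)
        return np.exp(1j * phi)

    def residual(u):
        det = fresnel_propagate(u, pixel, lam, z_nm)
        return np.linalg.norm(np.abs(det) - sqrt_i) / sqrt_i_norm

    if np.isscalar(beta):
        betas = [float(beta)] * n_iter
    else:
        betas = list(beta)
        betas += [betas[-1]] * max(n_iter - len(betas), 0)
    u = np.exp(1j * init.phase)
    residuals = []
    res0 = residual(u)
    for it in range(n_iter):
        b = betas[it]
        pm = project_modulus(u)
        rm = 2.0 * pm - u
        rs = 2.0 * project_object(rm) - rm
        u = b * 0.5 * (rs + u) + (1.0 - b) * pm
        res = residual(u)
        residuals.append(res)
        if res > 10.0 * max(res0, 1e-12):
            raise RuntimeError(
                f"RAAR diverged: residual {res:.3g} exceeds 10x initial {res0:.3g}"
            )
    # final object-domain projection for a clean pure-phase output
    u = project_object(u)
    phase = np.where(support, np.angle(u), 0.0)
    return RAARResult(
        phase_map=PhaseMap(phase=phase, pixel_size=pixel),
        residuals=np.asarray(residuals),
        field=u,
    )
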