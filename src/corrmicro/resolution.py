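"""Resolution estimation from power-spectral-density noise-floor cross-overs.

For each imaging modality the azimuthally averaged power spectral
density (PSD) of the image is computed as a function of the scattering
vector ``q = 2 pi nu``.  The decaying signal part is fitted with a power
law ``I(q_r) = a q_r^b + c`` and the flat high-q tail with a constant
noise floor ``bgr``; the cross-over ``q_i`` solving ``a q_i^b = bgr``
separates trustworthy structure from noise, and ``d_cr = pi / q_i`` is
the smallest structure size that can be attributed to signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PSDCurve:
    q: np.ndarray  # nm^-1, strictly increasing
    psd: np.ndarray  # arbitrary units, >= 0
    modality: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("PSD must be non-negative")


@dataclass
class PowerLawFit:
    a: float
    b: float  # exponent, < 0 for a decaying signal
    bgr: float  # noise floor
    q_i: float  # cross-over, nm^-1 (nan if invalid)
    d_cr: float  # nm, pi / q_i
    signal_range: tuple[float, float]
    noise_range: tuple[float, float]
    valid: bool = True


def power_spectral_density(
    image: np.ndarray,
    pixel_size: float,
    window: str | None = "hann",
    n_bins: int | None = None,
    modality: str = "",
) -> PSDCurve:
    """Azimuthally averaged PSD of a 2D image, on a q = 2 pi nu axis.

    The image is mean-subtracted, optionally Hann-windowed, Fourier
    transformed; |F|^2 / Npix is averaged in radial frequency bins of
    width 1/(N * pixel_size).  Without windowing the unbinned 2D PSD sums
    to variance * Npix (Parseval).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValueError("image must be 2D and at least 16x16")
    data = image - image.mean()
    if window == "hann":
        wr = np.hanning(image.shape[0])
        wc = np.hanning(image.shape[1])
        data = data * np.outer(wr, wc)
    elif window is not None:
        raise ValueError("window must be None or 'hann'")
    psd2 = np.abs(np.fft.fft2(data)) ** 2 / data.size
    ny = np.fft.fftfreq(image.shape[0], d=pixel_size)
    nx = np.fft.fftfreq(image.shape[1], d=pixel_size)
    nu = np.sqrt(ny[:, None] ** 2 + nx[None, :] ** 2)
    n = min(image.shape)
    d_nu = 1.0 / (n * pixel_size)
    n_bins = n // 2 if n_bins is None else n_bins
    idx = np.clip((nu / d_nu + 0.5).astype(int), 0, n_bins)
    keep = idx < n_bins
    sums = np.bincount(idx[keep], weights=psd2[keep], minlength=n_bins)
    cnts = np.bincount(idx[keep], minlength=n_bins)
    profile = sums[:n_bins] / np.maximum(cnts[:n_bins], 1)
    q = 2.0 * np.pi * d_nu * np.arange(n_bins)
    # drop the DC bin: q must be strictly positive for log-log fits
    return PSDCurve(q=q[1:], psd=profile[1:], modality=modality)


def psd2d(image: np.ndarray) -> np.ndarray:
    """Unbinned 2D power spectrum |FFT|^2 / Npix of the mean-subtracted image."""
    data = np.asarray(image, dtype=float)
    data = data - data.mean()
    return np.abs(np.fft.fft2(data)) ** 2 / data.size


def fit_power_law(
    psd: PSDCurve,
    signal_range: tuple[float, float],
    noise_range: tuple[float, float],
) -> PowerLawFit:
    """Fit I(q) = a q^b in ``signal_range`` and a constant floor in
    ``noise_range``; solve a q_i^b = bgr for the cross-over.

    The power law is fitted by least squares on log(PSD) vs log(q).  A
    non-decaying signal fit (b >= 0) is flagged invalid.
    """
    if signal_range[1] > noise_range[0] and noise_range[1] > signal_range[0]:
        raise ValueError("signal and noise ranges must not overlap")
    q, p = psd.q, psd.psd
    sig = (q >= signal_range[0]) & (q <= signal_range[1]) & (p > 0)
    noi = (q >= noise_range[0]) & (q <= noise_range[1])
    if sig.sum() < 5 or noi.sum() < 5:
        raise ValueError("each fit range needs at least 5 usable points")
    b, log_a = np.polyfit(np.log(q[sig]), np.log(p[sig]), 1)
    a = float(np.exp(log_a))
    bgr = float(np.mean(p[noi]))
    if b >= 0 or bgr <= 0:
        return PowerLawFit(
            a=a, b=float(b), bgr=bgr, q_i=np.nan, d_cr=np.nan,
            signal_range=signal_range, noise_range=noise_range, valid=False,
        )
    q_i = float((bgr / a) ** (1.0 / b))
    return PowerLawFit(
        a=a, b=float(b), bgr=bgr, q_i=q_i, d_cr=float(np.pi / q_i),
        signal_range=signal_range, noise_range=noise_range, valid=True,
    )


def diffraction_limit(wavelength_fl: float, na: float) -> float:
    """Abbe diffraction limit d_min = lambda_fl / (2 NA) in nm."""
    if wavelength_fl <= 0:
        raise ValueError("wavelength must be positive")
    if not 0.0 < na <= 1.7:
        raise ValueError("NA must be in (0, 1.7]")
    return wavelength_fl / (2.0 * na)
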