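"""Scanning-SAXS processing: q-calibration, masks, dark field, anisotropy.

A focused beam (~300 nm spot) raster-scans the specimen with a step of
~1 um; at every position a far-field small-angle diffraction pattern is
recorded on a photon-counting detector behind a beamstop.  Per-frame
reductions implemented here:

* dark field — masked sum of diffracted counts (strong for dense,
  strongly scattering regions such as the nucleus);
* PCA anisotropy — the intensity-weighted second-moment matrix of the
  momentum transfer ``q`` is eigen-decomposed; the normalized eigenvalue
  difference ``omega = (l1 - l2)/(l1 + l2)`` measures how streak-like the
  pattern is and the principal eigenvector gives the streak direction,
  which is perpendicular to the real-space fiber direction;
* azimuthally averaged 1D profiles I(|q|).

Moments are taken about q = 0 without mean subtraction: small-angle
patterns of real-valued densities are Friedel-symmetric, so the centroid
vanishes up to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# calibration and geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class QCalibration:
    """Detector-to-scattering-vector calibration.

    beam_center : (row, col) detector pixel of the direct beam (fractional
        values allowed); distance_mm : sample-detector distance;
    pixel_size_um : detector pixel; wavelength_nm : X-ray wavelength.
    """

    beam_center: tuple[float, float]
    distance_mm: float
    pixel_size_um: float = 172.0
    wavelength_nm: float = 0.08984

    def __post_init__(self):
        if self.distance_mm <= 0:
            raise ValueError("detector distance must be positive")
        if self.pixel_size_um <= 0 or self.wavelength_nm <= 0:
            raise ValueError("pixel size and wavelength must be positive")


def fft_q_calibration(
    n_det: int,
    sample_pixel_nm: float,
    wavelength_nm: float,
    det_pixel_um: float = 172.0,
) -> QCalibration:
    """Calibration consistent with an FFT-simulated far field.

    Chooses the detector distance so that the small-angle q-per-pixel of
    the physical formula equals the reciprocal grid spacing
    ``2*pi/(n_det * sample_pixel)`` of a discrete Fourier transform of an
    exit wave sampled at ``sample_pixel_nm``.
    """
    distance_nm = det_pixel_um * 1e3 * n_det * sample_pixel_nm / wavelength_nm
    return QCalibration(
        beam_center=(n_det // 2, n_det // 2),
        distance_mm=distance_nm * 1e-6,
        pixel_size_um=det_pixel_um,
        wavelength_nm=wavelength_nm,
    )


def q_map(cal: QCalibration, shape: tuple[int, int]):
    """Per-pixel momentum transfer (q_y, q_z, |q|) in nm^-1.

    |q| = (4 pi / lambda) sin(atan(r / D) / 2) at radial detector
    distance r; components point along the detector axes (q_y along
    columns, q_z along rows).
    """
    rows = np.arange(shape[0])[:, None] - cal.beam_center[0]
    cols = np.arange(shape[1])[None, :] - cal.beam_center[1]
    p_nm = cal.pixel_size_um * 1e3
    d_nm = cal.distance_mm * 1e6
    r_nm = np.hypot(rows, cols) * p_nm
    qabs = (4.0 * np.pi / cal.wavelength_nm) * np.sin(0.5 * np.arctan(r_nm / d_nm))
    r_px = np.hypot(rows, cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        qy = np.where(r_px > 0, qabs * cols / np.where(r_px > 0, r_px, 1.0), 0.0)
        qz = np.where(r_px > 0, qabs * rows / np.where(r_px > 0, r_px, 1.0), 0.0)
    return qy, qz, qabs


def compose_mask(
    shape: tuple[int, int],
    beamstop: tuple[tuple[float, float], float] | None = None,
    gaps: list[tuple[int, int]] | None = None,
    bad_pixels: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Boolean validity mask (True = usable pixel).

    ``beamstop`` is ((row, col), radius_px) of an excluded disc; ``gaps``
    are (row_start, row_stop) horizontal inter-module stripes;
    ``bad_pixels`` an explicit list.  Exclusions intersect commutatively.
    """
    mask = np.ones(shape, dtype=bool)
    if beamstop is not None:
        (cr, cc), radius = beamstop
        rows = np.arange(shape[0])[:, None] - cr
        cols = np.arange(shape[1])[None, :] - cc
        mask &= rows**2 + cols**2 > radius**2
    if gaps:
        for r0, r1 in gaps:
            if not (0 <= r0 <= r1 <= shape[0]):
                raise ValueError(f"gap rows ({r0}, {r1}) outside frame")
            mask[r0:r1, :] = False
    if bad_pixels:
        for r, c in bad_pixels:
            mask[r, c] = False
    return mask


def default_mask(
    shape: tuple[int, int],
    beamstop_radius: float = 20.0,
    gap_width: int = 17,
) -> np.ndarray:
    """Centered beamstop disc plus two horizontal module-gap stripes."""
    n = shape[0]
    center = (shape[0] / 2, shape[1] / 2)
    beamstop = (center, beamstop_radius) if beamstop_radius > 0 else None
    gaps = []
    if gap_width > 0:
        g1, g2 = n // 4, 3 * n // 4
        gaps = [(g1, min(g1 + gap_width, n)), (g2, min(g2 + gap_width, n))]
    return compose_mask(shape, beamstop=beamstop, gaps=gaps)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class DetectorFrame:
    counts: np.ndarray  # integer photon counts
    mask: np.ndarray  # True = valid
    exposure: float = 1.0  # s

    def __post_init__(self):
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask shape must match counts")


@dataclass(frozen=True)
class ScanGrid:
    """Raster grid of beam positions in the sample frame (um)."""

    shape: tuple[int, int]  # (n_z rows, n_y cols)
    step_um: float = 1.0
    origin_um: tuple[float, float] = (0.0, 0.0)  # (y, z) of first position

    def positions(self) -> np.ndarray:
        """(N, 2) array of (y, z) positions in um, row-major order."""
        zz, yy = np.meshgrid(
            np.arange(self.shape[0]), np.arange(self.shape[1]), indexing="ij"
        )
        y = self.origin_um[0] + yy * self.step_um
        z = self.origin_um[1] + zz * self.step_um
        return np.stack([y.ravel(), z.ravel()], axis=1)


@dataclass
class ScanStack:
    """Stack of diffraction frames on a raster scan grid."""

    counts: np.ndarray  # (n_z, n_y, det, det)
    mask: np.ndarray  # (det, det) shared validity mask
    grid: ScanGrid
    calibration: QCalibration
    exposure: float = 1.0
    empty: np.ndarray | None = None  # (n_z, n_y) True where beam missed sample

    def __post_init__(self):
        if self.counts.shape[:2] != self.grid.shape:
            raise ValueError("frame stack does not match scan grid")
        if self.empty is None:
            self.empty = np.zeros(self.grid.shape, dtype=bool)

    def frame(self, iz: int, iy: int) -> DetectorFrame:
        return DetectorFrame(self.counts[iz, iy], self.mask, self.exposure)


@dataclass
class DarkFieldMap:
    """Masked-sum diffraction intensity per scan position, in photons."""

    values: np.ndarray  # photons
    exposure: float = 1.0
    step_um: float = 1.0

    @property
    def rates(self) -> np.ndarray:
        """Dark field in photons/s."""
        return self.values / self.exposure


@dataclass
class AnisotropyResult:
    omega: float
    theta_recip: float  # deg in [0, 180), nan if isotropic
    theta_real: float
    lam1: float
    lam2: float
    valid: bool


@dataclass
class AnisotropyMap:
    """Per-scan-point PCA anisotropy over the raster grid."""

    omega: np.ndarray
    theta_recip: np.ndarray
    theta_real: np.ndarray
    lam1: np.ndarray
    lam2: np.ndarray
    valid: np.ndarray  # bool: dark-field threshold passed and PCA defined
    step_um: float = 1.0


# --------------------------------------------------------------------------
# reductions
# --------------------------------------------------------------------------


def subtract_background(
    counts: np.ndarray, background_frames: list[np.ndarray] | np.ndarray
) -> np.ndarray:
    """Subtract the mean of the background frames, clipping at zero."""
    bg = np.asarray(background_frames, dtype=float)
    if bg.ndim == 2:
        bg = bg[None]
    if bg.shape[0] == 0:
        raise ValueError("need at least one background frame")
    if bg.shape[1:] != np.shape(counts):
        raise ValueError("background frame shape mismatch")
    return np.clip(np.asarray(counts, dtype=float) - bg.mean(axis=0), 0.0, None)


def darkfield(stack: ScanStack, mask: np.ndarray | None = None) -> DarkFieldMap:
    """Dark-field map: exact masked sum of counts per scan position."""
    mask = stack.mask if mask is None else np.asarray(mask, dtype=bool)
    if mask.shape != stack.counts.shape[2:]:
        raise ValueError("mask shape must match frames")
    values = stack.counts[:, :, mask].sum(axis=2)
    return DarkFieldMap(
        values=values.astype(float), exposure=stack.exposure, step_um=stack.grid.step_um
    )


def threshold_map(df: DarkFieldMap, i_df: float = 7.5e5) -> np.ndarray:
    """Validity mask over the scan grid: dark-field rate above ``i_df`` ph/s."""
    return df.rates > i_df


def pca_anisotropy(
    counts: np.ndarray,
    mask: np.ndarray,
    qmap: tuple[np.ndarray, np.ndarray, np.ndarray],
    q_range: tuple[float, float] | None = (0.0, 0.8),
) -> AnisotropyResult:
    """PCA of the intensity-weighted momentum-transfer second moments.

    Returns the anisotropy degree ``omega = (l1 - l2)/(l1 + l2)``
    (eigenvalues l1 >= l2 >= 0 of the weighted covariance about q = 0),
    the principal direction ``theta_recip`` in reciprocal space and its
    real-space counterpart ``theta_real = theta_recip + 90 (mod 180)``.
    Weights are the masked, non-negative counts inside the optional |q|
    annulus.
    """
    qy, qz, qabs = qmap
    w = np.where(mask, np.clip(np.asarray(counts, dtype=float), 0.0, None), 0.0)
    if q_range is not None:
        w = np.where((qabs >= q_range[0]) & (qabs <= q_range[1]), w, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        return AnisotropyResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    cyy = float(np.sum(w * qy * qy) / wsum)
    czz = float(np.sum(w * qz * qz) / wsum)
    cyz = float(np.sum(w * qy * qz) / wsum)
    cov = np.array([[cyy, cyz], [cyz, czz]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    total = lam1 + lam2
    if total <= 0:
        return AnisotropyResult(np.nan, np.nan, np.nan, lam1, lam2, False)
    omega = (lam1 - lam2) / total
    if (lam1 - lam2) / total < 1e-12:
        # isotropic: direction undefined
        return AnisotropyResult(0.0, np.nan, np.nan, lam1, lam2, True)
    v = evecs[:, 1]  # (q_y, q_z) components of the principal axis
    theta_recip = float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)
    theta_real = (theta_recip + 90.0) % 180.0
    return AnisotropyResult(omega, theta_recip, theta_real, lam1, lam2, True)


def anisotropy_map(
    stack: ScanStack,
    threshold: float = 7.5e5,
    q_range: tuple[float, float] | None = (0.0, 0.8),
    background: np.ndarray | None = None,
) -> AnisotropyMap:
    """PCA anisotropy at every scan point passing the dark-field threshold."""
    qmap = q_map(stack.calibration, stack.counts.shape[2:])
    df = darkfield(stack)
    passed = threshold_map(df, threshold)
    nz, ny = stack.grid.shape
    out = {
        k: np.full((nz, ny), np.nan)
        for k in ("omega", "theta_recip", "theta_real", "lam1", "lam2")
    }
    valid = np.zeros((nz, ny), dtype=bool)
    for iz in range(nz):
        for iy in range(ny):
            if not passed[iz, iy] or stack.empty[iz, iy]:
                continue
            counts = stack.counts[iz, iy]
            if background is not None:
                counts = subtract_background(counts, background)
            res = pca_anisotropy(counts, stack.mask, qmap, q_range)
            out["omega"][iz, iy] = res.omega
            out["theta_recip"][iz, iy] = res.theta_recip
            out["theta_real"][iz, iy] = res.theta_real
            out["lam1"][iz, iy] = res.lam1
            out["lam2"][iz, iy] = res.lam2
            valid[iz, iy] = res.valid
    return AnisotropyMap(
        omega=out["omega"],
        theta_recip=out["theta_recip"],
        theta_real=out["theta_real"],
        lam1=out["lam1"],
        lam2=out["lam2"],
        valid=valid,
        step_um=stack.grid.step_um,
    )


def azimuthal_average(
    counts: np.ndarray,
    mask: np.ndarray,
    qmap: tuple[np.ndarray, np.ndarray, np.ndarray],
    n_bins: int = 64,
    q_range: tuple[float, float] | None = None,
):
    """Azimuthally averaged 1D profile I(|q|) over valid pixels.

    Returns (q_centers, profile, n_pixels_per_bin); empty bins are NaN.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    _, _, qabs = qmap
    valid = np.asarray(mask, dtype=bool)
    q = qabs[valid]
    i = np.asarray(counts, dtype=float)[valid]
    if q_range is None:
        q_range = (0.0, float(q.max()))
    edges = np.linspace(q_range[0], q_range[1], n_bins + 1)
    idx = np.clip(np.digitize(q, edges) - 1, 0, n_bins - 1)
    keep = (q >= q_range[0]) & (q <= q_range[1])
    sums = np.bincount(idx[keep], weights=i[keep], minlength=n_bins)
    npix = np.bincount(idx[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = np.where(npix > 0, sums / np.maximum(npix, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, profile, npix
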