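"""Synthetic adherent-cell phantom and simulated raw data for all modalities.

The phantom emulates a freeze-dried cardiac tissue cell on a flat
substrate, in 2D projection: a low-density cytoplasm envelope (soft
ellipse elongated along the cell's main axis), a denser elliptical
nucleus (projected ellipsoid profile), and a network of straight
filament bundles with Gaussian cross-sections whose orientations scatter
around the main axis.  A configurable fraction of the filaments carries
fluorescent label; the nucleus and envelope are unlabeled, so the
fluorescence channel sees only part of what the X-ray channels see —
the point of correlative imaging.

From a single ground-truth phantom the module simulates
* confocal / STED fluorescence images (Gaussian PSF + Poisson noise),
* in-line near-field holograms (pure-phase object, Fresnel propagation
  in the effective parallel-beam geometry, Poisson noise),
* scanning-SAXS raster scans (focused Gaussian beam, far-field
  intensity by FFT, beamstop/gap mask, Poisson noise).

All randomness flows through ``numpy.random.default_rng(seed)``:
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import OpticalGeometry
from .holography import Hologram, SamplingError, check_sampling, fresnel_propagate
from .resample import rebin
from .saxs import QCalibration, ScanGrid, ScanStack, default_mask, fft_q_calibration

MM_TO_NM = 1e6
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BeamProfile:
    """Nano-focused X-ray beam: Gaussian focal spot and flux."""

    fwhm_y: float = 300.0  # nm, horizontal intensity FWHM
    fwhm_z: float = 300.0  # nm, vertical intensity FWHM
    flux: float = 1.1e11  # photons/s
    exposure: float = 0.05  # s per scan point

    def __post_init__(self):
        if min(self.fwhm_y, self.fwhm_z, self.flux, self.exposure) <= 0:
            raise ValueError("beam parameters must be strictly positive")


@dataclass(frozen=True)
class FilamentTruth:
    """Ground-truth filament segment (endpoints in nm, sample frame)."""

    p1: tuple[float, float]  # (y, z) nm
    p2: tuple[float, float]
    orientation: float  # deg in [0, 180), from +y axis
    width: float  # nm (FWHM of the Gaussian cross-section)
    labeled: bool


@dataclass(frozen=True)
class NucleusParams:
    center: tuple[float, float]  # (y, z) nm
    semi_axes: tuple[float, float]  # (a_y, a_z) nm
    scale: float  # peak projected density


@dataclass
class CellPhantom:
    """Ground-truth projected density, phase, label map and filaments."""

    density: np.ndarray  # projected electron density, arbitrary units >= 0
    phase: np.ndarray  # radians, phase = -phase_scale * density <= 0
    label_map: np.ndarray  # fluorophore density, > 0 only on labeled filaments
    true_filaments: list[FilamentTruth]
    nucleus: NucleusParams
    pixel_size: float  # nm
    phase_scale: float
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        return (self.shape[1] * self.pixel_size, self.shape[0] * self.pixel_size)


@dataclass
class FluorescenceImage:
    counts: np.ndarray  # integer photon counts
    pixel_size: float  # nm
    psf_fwhm: float  # nm
    mode: str  # "confocal" | "sted"

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------


def _elliptical_rho(yy, zz, center, semi_axes, angle_deg=0.0):
    """Normalized elliptical radius (1 on the boundary)."""
    dy, dz = yy - center[0], zz - center[1]
    if angle_deg:
        a = np.radians(angle_deg)
        dy, dz = dy * np.cos(a) + dz * np.sin(a), -dy * np.sin(a) + dz * np.cos(a)
    return np.sqrt((dy / semi_axes[0]) ** 2 + (dz / semi_axes[1]) ** 2)


def _chord_endpoints(center, direction, ell_center, semi_axes, angle_deg):
    """Intersection parameters of the line center + t*direction with an ellipse."""
    a = np.radians(angle_deg)
    rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    c = rot @ (np.asarray(center) - np.asarray(ell_center))
    d = rot @ np.asarray(direction)
    inv = np.array(semi_axes, dtype=float)
    c, d = c / inv, d / inv
    # |c + t d|^2 = 1
    aa = d @ d
    bb = 2.0 * (c @ d)
    cc = c @ c - 1.0
    disc = bb * bb - 4.0 * aa * cc
    if disc <= 0:
        return None
    t1 = (-bb - np.sqrt(disc)) / (2.0 * aa)
    t2 = (-bb + np.sqrt(disc)) / (2.0 * aa)
    return t1, t2


def make_cell_phantom(
    n_filaments: int = 30,
    orientation_spread: float = 15.0,
    label_fraction: float = 0.7,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 40.0,
    seed: int = 0,
    main_axis: float = 30.0,
    filament_width: tuple[float, float] = (100.0, 400.0),
    filament_amp: float = 0.5,
    envelope_amp: float = 0.15,
    nucleus_scale: float = 1.0,
    nucleus_texture_amp: float = 0.25,
    nucleus_texture_nm: float = 150.0,
    phase_scale: float = 0.4,
) -> CellPhantom:
    """Generate a seeded synthetic cell phantom.

    Filament orientations are drawn from a wrapped normal around
    ``main_axis`` with standard deviation ``orientation_spread`` (deg);
    widths (FWHM) uniformly from ``filament_width`` (nm).  Exactly
    ``round(label_fraction * n_filaments)`` filaments contribute to the
    fluorophore map.
    """
    if min(shape) < 64:
        raise ValueError("grid must be at least 64x64")
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    if not 0.0 <= label_fraction <= 1.0:
        raise ValueError("label_fraction must be in [0, 1]")
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    rng = np.random.default_rng(seed)
    nz, ny = shape
    extent_y, extent_z = ny * pixel_size, nz * pixel_size
    zz, yy = np.meshgrid(
        (np.arange(nz) + 0.5) * pixel_size,
        (np.arange(ny) + 0.5) * pixel_size,
        indexing="ij",
    )
    cell_center = (extent_y / 2.0, extent_z / 2.0)
    cell_axes = (0.42 * extent_y, 0.30 * extent_z)

    # cytoplasm envelope: flat plateau, soft super-Gaussian edge
    rho = _elliptical_rho(yy, zz, cell_center, cell_axes, main_axis)
    density = envelope_amp * np.exp(-(rho**4))

    # nucleus: projected ellipsoid profile sqrt(1 - rho^2)
    nucleus = NucleusParams(
        center=cell_center,
        semi_axes=(0.13 * extent_y, 0.10 * extent_z),
        scale=nucleus_scale,
    )
    rho_n = _elliptical_rho(yy, zz, nucleus.center, nucleus.semi_axes)
    nuc_profile = np.clip(1.0 - rho_n**2, 0.0, None)
    density += nucleus.scale * np.sqrt(nuc_profile)

    # chromatin-like granularity confined to the nucleus: without it a
    # smooth nucleus scatters only below the beamstop cutoff, whereas in
    # cells the nucleus is the strongest dark-field feature
    if nucleus_texture_amp > 0:
        texture = ndimage.gaussian_filter(
            rng.standard_normal(shape), nucleus_texture_nm * FWHM_TO_SIGMA / pixel_size
        )
        texture /= max(texture.std(), 1e-12)
        density += nucleus_texture_amp * texture * nuc_profile

    # filaments: straight chords of the cell ellipse, Gaussian cross-section
    n_labeled = int(round(label_fraction * n_filaments))
    labeled_idx = set(rng.permutation(n_filaments)[:n_labeled].tolist())
    label_map = np.zeros(shape)
    filaments: list[FilamentTruth] = []
    for k in range(n_filaments):
        theta = (main_axis + orientation_spread * rng.standard_normal()) % 180.0
        width = rng.uniform(*filament_width)
        # anchor point uniform in the (shrunk) cell ellipse
        r = np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        a = np.radians(main_axis)
        u = 0.85 * r * np.array([cell_axes[0] * np.cos(phi), cell_axes[1] * np.sin(phi)])
        anchor = np.array(cell_center) + np.array(
            [u[0] * np.cos(a) - u[1] * np.sin(a), u[0] * np.sin(a) + u[1] * np.cos(a)]
        )
        direction = np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
        ts = _chord_endpoints(anchor, direction, cell_center, cell_axes, main_axis)
        if ts is None:
            continue
        t1, t2 = ts
        p1 = anchor + t1 * direction
        p2 = anchor + t2 * direction
        sigma = width * FWHM_TO_SIGMA
        # signed coordinates along/perpendicular to the segment
        du = (yy - anchor[0]) * direction[0] + (zz - anchor[1]) * direction[1]
        dv = -(yy - anchor[0]) * direction[1] + (zz - anchor[1]) * direction[0]
        along = np.clip(du - t2, 0.0, None) + np.clip(t1 - du, 0.0, None)
        footprint = filament_amp * np.exp(-(dv**2 + along**2) / (2.0 * sigma**2))
        density += footprint
        if k in labeled_idx:
            label_map += footprint
        filaments.append(
            FilamentTruth(
                p1=(float(p1[0]), float(p1[1])),
                p2=(float(p2[0]), float(p2[1])),
                orientation=float(theta),
                width=float(width),
                labeled=k in labeled_idx,
            )
        )

    density = np.clip(density, 0.0, None)
    return CellPhantom(
        density=density,
        phase=-phase_scale * density,
        label_map=label_map,
        true_filaments=filaments,
        nucleus=nucleus,
        pixel_size=pixel_size,
        phase_scale=phase_scale,
        seed=seed,
    )


# --------------------------------------------------------------------------
# fluorescence simulation
# --------------------------------------------------------------------------


def render_fluorescence(
    phantom: CellPhantom,
    psf_fwhm: float = 343.0,
    photon_budget: float = 200.0,
    mode: str = "confocal",
    seed: int = 0,
    noiseless: bool = False,
) -> FluorescenceImage:
    """Image the fluorophore map with a Gaussian PSF and Poisson noise.

    ``photon_budget`` is the mean count at the brightest pixel.  The
    confocal PSF FWHM defaults to the diffraction limit of the instrument
    (343 nm); STED images use a smaller ``psf_fwhm``.
    """
    if psf_fwhm <= 0:
        raise ValueError("psf_fwhm must be positive")
    if photon_budget <= 0:
        raise ValueError("photon_budget must be positive")
    sigma_px = psf_fwhm * FWHM_TO_SIGMA / phantom.pixel_size
    expected = ndimage.gaussian_filter(phantom.label_map, sigma_px)
    peak = expected.max()
    if peak > 0:
        expected = expected * (photon_budget / peak)
    if noiseless:
        counts = expected
    else:
        counts = np.random.default_rng(seed).poisson(expected).astype(np.int64)
    return FluorescenceImage(
        counts=counts, pixel_size=phantom.pixel_size, psf_fwhm=psf_fwhm, mode=mode
    )


# --------------------------------------------------------------------------
# holography simulation
# --------------------------------------------------------------------------


def simulate_hologram_from_phase(
    phase: np.ndarray,
    geom: OpticalGeometry,
    photon_budget: float | None = 5000.0,
    seed: int = 0,
) -> Hologram:
    """Propagate a pure-phase exit wave to the detector plane.

    ``phase`` is assumed sampled at the geometry's effective pixel size.
    ``photon_budget`` is the mean photon count per detector pixel of the
    empty beam; ``None`` gives the noiseless intensity expectation.  The
    returned hologram is flat-field normalized (empty beam -> 1).
    """
    lam = geom.wavelength
    p_eff = geom.pixel_size_eff
    z_nm = geom.z_eff * MM_TO_NM
    fresnel_px = p_eff**2 / (lam * z_nm)
    if not 1e-4 <= fresnel_px <= 10.0:
        raise SamplingError(
            f"per-pixel Fresnel number {fresnel_px:.3g} outside [1e-4, 10]"
        )
    check_sampling(phase.shape, p_eff, lam, z_nm)
    field_det = fresnel_propagate(np.exp(1j * phase), p_eff, lam, z_nm)
    intensity = np.abs(field_det) ** 2
    if photon_budget is not None:
        if photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        rng = np.random.default_rng(seed)
        intensity = rng.poisson(intensity * photon_budget) / photon_budget
    return Hologram(intensity=intensity, geometry=geom)


def simulate_hologram(
    phantom: CellPhantom,
    geom: OpticalGeometry,
    photon_budget: float | None = 5000.0,
    shape: tuple[int, int] | None = None,
    offset_px: tuple[int, int] = (0, 0),
    seed: int = 0,
) -> Hologram:
    """Simulate the in-line hologram of a phantom.

    The phantom phase is resampled from its native grid onto the
    effective pixel size of the (cone-beam) geometry, embedded centered
    (plus an optional integer ``offset_px`` = (rows, cols), emulating a
    stage offset between modalities) in a ``shape`` field of view, and
    propagated over the effective distance.
    """
    if shape is None:
        shape = phantom.shape
    phase = rebin(phantom.phase, phantom.pixel_size, geom.pixel_size_eff, "mean")
    canvas = np.zeros(shape)
    r0 = (shape[0] - phase.shape[0]) // 2 + offset_px[0]
    c0 = (shape[1] - phase.shape[1]) // 2 + offset_px[1]
    # clip the paste region to the canvas
    rs, cs = max(r0, 0), max(c0, 0)
    re = min(r0 + phase.shape[0], shape[0])
    ce = min(c0 + phase.shape[1], shape[1])
    if re > rs and ce > cs:
        canvas[rs:re, cs:ce] = phase[rs - r0 : re - r0, cs - c0 : ce - c0]
    return simulate_hologram_from_phase(canvas, geom, photon_budget, seed)


# --------------------------------------------------------------------------
# scanning-SAXS simulation
# --------------------------------------------------------------------------


def _beam_amplitude(n: int, pixel_size: float, beam: BeamProfile) -> np.ndarray:
    """Unit-power Gaussian illumination amplitude on an n x n window."""
    z = (np.arange(n) - n / 2 + 0.5) * pixel_size
    sig_y = beam.fwhm_y * FWHM_TO_SIGMA
    sig_z = beam.fwhm_z * FWHM_TO_SIGMA
    gy = np.exp(-(z**2) / (2.0 * sig_y**2))
    gz = np.exp(-(z**2) / (2.0 * sig_z**2))
    intensity = np.outer(gz, gy)
    intensity /= intensity.sum()
    return np.sqrt(intensity)


def simulate_scan_saxs(
    phantom: CellPhantom,
    beam: BeamProfile,
    scan: ScanGrid,
    background_rate: float = 10.0,
    det_size: int = 128,
    beamstop_radius: float = 20.0,
    gap_width: int = 17,
    det_pixel_um: float = 172.0,
    wavelength_nm: float = 0.08984,
    seed: int = 0,
    noiseless: bool = False,
) -> ScanStack:
    """Raster-scan far-field diffraction of the phantom.

    At each scan position the Gaussian beam illuminates a ``det_size``
    window of the pure-phase exit wave; the far-field intensity is the
    squared modulus of its 2D Fourier transform (fftshifted so the direct
    beam sits at the window center), scaled to ``flux * exposure``
    incident photons, plus a uniform background of ``background_rate``
    (counts/pixel/s) times the exposure, Poisson sampled, with beamstop
    and inter-module gaps masked out.
    Positions whose window misses the phantom entirely are flagged empty.
    """
    if scan.step_um * 1e3 < phantom.pixel_size:
        raise ValueError("scan step must be at least one phantom pixel")
    rng = np.random.default_rng(seed)
    amp = _beam_amplitude(det_size, phantom.pixel_size, beam)
    mask = default_mask((det_size, det_size), beamstop_radius, gap_width)
    cal = fft_q_calibration(det_size, phantom.pixel_size, wavelength_nm, det_pixel_um)
    photons = beam.flux * beam.exposure
    nz, ny = scan.shape
    counts = np.zeros(
        (nz, ny, det_size, det_size), dtype=float if noiseless else np.int64
    )
    empty = np.zeros((nz, ny), dtype=bool)
    half = det_size // 2
    pr, pc = phantom.shape
    positions = scan.positions().reshape(nz, ny, 2)
    for iz in range(nz):
        for iy in range(ny):
            y_um, z_um = positions[iz, iy]
            col = int(round(y_um * 1e3 / phantom.pixel_size))
            row = int(round(z_um * 1e3 / phantom.pixel_size))
            if not (0 <= row < pr and 0 <= col < pc):
                empty[iz, iy] = True
            window = np.zeros((det_size, det_size))
            rs, re = max(row - half, 0), min(row + half, pr)
            cs, ce = max(col - half, 0), min(col + half, pc)
            if re > rs and ce > cs:
                window[
                    rs - (row - half) : re - (row - half),
                    cs - (col - half) : ce - (col - half),
                ] = phantom.phase[rs:re, cs:ce]
            exit_wave = amp * np.exp(1j * window)
            far = np.fft.fftshift(np.fft.fft2(exit_wave, norm="ortho"))
            expected = np.abs(far) ** 2 * photons + background_rate * beam.exposure
            if noiseless:
                frame = expected
            else:
                frame = rng.poisson(expected)
            counts[iz, iy] = np.where(mask, frame, 0)
    return ScanStack(
        counts=counts,
        mask=mask,
        grid=scan,
        calibration=cal,
        exposure=beam.exposure,
        empty=empty,
    )


# --------------------------------------------------------------------------
# ground-truth utilities
# --------------------------------------------------------------------------


def single_filament_cells(
    phantom: CellPhantom,
    scan: ScanGrid,
    dominance: float = 0.9,
    nucleus_exclusion: float = 1.5,
) -> dict[tuple[int, int], float]:
    """Scan cells dominated by a single true filament.

    Samples every ground-truth segment densely, accumulates per-cell
    length contributions per filament, and returns ``{(iz, iy): true
    orientation}`` for cells where one filament carries at least
    ``dominance`` of the total filament length in the cell and the cell
    center lies outside ``nucleus_exclusion`` nuclear radii.  Used to
    validate the SAXS principal directions against ground truth.
    """
    step_nm = scan.step_um * 1e3
    y0, z0 = scan.origin_um[0] * 1e3, scan.origin_um[1] * 1e3
    ds = step_nm / 20.0
    cells: dict[tuple[int, int], dict[int, float]] = {}
    for k, f in enumerate(phantom.true_filaments):
        p1, p2 = np.array(f.p1), np.array(f.p2)
        length = np.linalg.norm(p2 - p1)
        n = max(int(length / ds), 1)
        ts = (np.arange(n) + 0.5) / n
        pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
        iy = np.round((pts[:, 0] - y0) / step_nm).astype(int)
        iz = np.round((pts[:, 1] - z0) / step_nm).astype(int)
        w = length / n
        for cy, cz in zip(iy, iz):
            if 0 <= cz < scan.shape[0] and 0 <= cy < scan.shape[1]:
                cells.setdefault((cz, cy), {})
                cells[(cz, cy)][k] = cells[(cz, cy)].get(k, 0.0) + w
    out: dict[tuple[int, int], float] = {}
    nuc = phantom.nucleus
    for (cz, cy), contribs in cells.items():
        total = sum(contribs.values())
        k_best, w_best = max(contribs.items(), key=lambda kv: kv[1])
        if w_best < dominance * total:
            continue
        yc = y0 + cy * step_nm
        zc = z0 + cz * step_nm
        rho = np.sqrt(
            ((yc - nuc.center[0]) / nuc.semi_axes[0]) ** 2
            + ((zc - nuc.center[1]) / nuc.semi_axes[1]) ** 2
        )
        if rho < nucleus_exclusion:
            continue
        out[(cz, cy)] = phantom.true_filaments[k_best].orientation
    return out
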