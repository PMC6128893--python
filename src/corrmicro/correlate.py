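"""Registration and cross-modality agreement.

The three modalities live on different grids (fluorescence at the
phantom/STED pixel, holographic phase at the effective detector pixel,
SAXS maps at the scan step).  ``rebin`` puts images on a common pixel
size, ``register_translation`` recovers the translational offset by
phase cross-correlation with sub-pixel refinement, and
``orientation_agreement`` compares traced filament orientations with
the real-space principal axes of the SAXS anisotropy map, scan point by
scan point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .filaments import FilamentSet, circular_distance, circular_mean_orientation
from .resample import rebin  # re-exported
from .saxs import AnisotropyMap, ScanGrid

__all__ = [
    "RegistrationTransform",
    "rebin",
    "register_translation",
    "orientation_agreement",
]


@dataclass(frozen=True)
class RegistrationTransform:
    """Translation (+ optional isotropic scale) mapping moving -> reference."""

    shift_y: float  # nm (columns)
    shift_z: float  # nm (rows)
    pixel_size: float  # nm of the common grid
    scale: float = 1.0
    score: float = 1.0  # normalized cross-correlation at the optimum

    @property
    def shift_px(self) -> tuple[float, float]:
        """(rows, cols) shift in pixels of the common grid."""
        return (self.shift_z / self.pixel_size, self.shift_y / self.pixel_size)


def register_translation(
    reference: np.ndarray,
    moving: np.ndarray,
    pixel_size: float = 1.0,
    upsampling: int = 100,
) -> RegistrationTransform:
    """Sub-pixel translation between two images on the same grid.

    Uses Fourier phase cross-correlation with local upsampling; the
    returned shift moves ``moving`` onto ``reference``.  The score is the
    Pearson correlation after applying the recovered shift.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("images must share a shape; rebin first")
    if reference.std() == 0 or moving.std() == 0:
        raise ValueError("cannot register a flat (zero-variance) image")
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsampling, normalization=None
    )
    shifted = np.fft.ifftn(
        ndimage.fourier_shift(np.fft.fftn(moving), shift)
    ).real
    score = float(np.corrcoef(reference.ravel(), shifted.ravel())[0, 1])
    return RegistrationTransform(
        shift_y=float(shift[1]) * pixel_size,
        shift_z=float(shift[0]) * pixel_size,
        pixel_size=pixel_size,
        score=score,
    )


def _segments_per_scan_cell(
    fs: FilamentSet,
    transform: RegistrationTransform | None,
    grid: ScanGrid,
    pixel_size_nm: float,
):
    """Accumulate filament length and orientations per scan cell.

    Segments are sampled densely; each sample point is mapped from image
    pixels to sample-frame nm (optionally translated by the registration
    transform) and binned into the step-size square centered on each scan
    node.
    """
    step_nm = grid.step_um * 1e3
    y0_nm = grid.origin_um[0] * 1e3
    z0_nm = grid.origin_um[1] * 1e3
    cells: dict[tuple[int, int], dict] = {}
    ds = step_nm / 20.0
    for seg in fs.segments:
        p1 = np.array(seg.p1) * pixel_size_nm
        p2 = np.array(seg.p2) * pixel_size_nm
        if transform is not None:
            offset = np.array([transform.shift_y, transform.shift_z])
            p1, p2 = p1 + offset, p2 + offset
        length = np.linalg.norm(p2 - p1)
        n_samples = max(int(length / ds), 1)
        ts = (np.arange(n_samples) + 0.5) / n_samples
        pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
        iy = np.round((pts[:, 0] - y0_nm) / step_nm).astype(int)
        iz = np.round((pts[:, 1] - z0_nm) / step_nm).astype(int)
        w = length / n_samples
        for cy, cz in zip(iy, iz):
            if 0 <= cz < grid.shape[0] and 0 <= cy < grid.shape[1]:
                cell = cells.setdefault((cz, cy), {"w": [], "th": []})
                cell["w"].append(w)
                cell["th"].append(seg.orientation)
    return cells


def orientation_agreement(
    fs: FilamentSet,
    aniso: AnisotropyMap,
    grid: ScanGrid,
    pixel_size_nm: float,
    transform: RegistrationTransform | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-scan-point angle between filament and SAXS principal directions.

    For every valid scan point whose step-size square contains at least
    one traced filament sample, computes the circular distance (in
    [0, 90] deg) between the length-weighted mean filament orientation
    and the real-space SAXS principal axis ``theta_real``.  Returns a
    table and summary statistics (median, fraction below 20 deg).
    """
    cells = _segments_per_scan_cell(fs, transform, grid, pixel_size_nm)
    rows = []
    for (iz, iy), cell in sorted(cells.items()):
        if not aniso.valid[iz, iy] or np.isnan(aniso.theta_real[iz, iy]):
            continue
        mean_th = circular_mean_orientation(
            np.array(cell["th"]), np.array(cell["w"])
        )
        d = circular_distance(mean_th, aniso.theta_real[iz, iy])
        rows.append(
            {
                "iz": iz, "iy": iy,
                "filament_theta_deg": mean_th,
                "saxs_theta_real_deg": aniso.theta_real[iz, iy],
                "delta_theta_deg": d,
                "omega": aniso.omega[iz, iy],
                "filament_length_nm": float(np.sum(cell["w"])),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        summary = {
            "n_points": int(len(table)),
            "median_delta_theta_deg": float(table["delta_theta_deg"].median()),
            "fraction_below_20deg": float((table["delta_theta_deg"] < 20).mean()),
        }
    else:
        summary = {
            "n_points": 0,
            "median_delta_theta_deg": float("nan"),
            "fraction_below_20deg": float("nan"),
        }
    return table, summary
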