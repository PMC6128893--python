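import dataclasses

import numpy as np
import pytest

from corrmicro import BeamProfile, ScanGrid, make_cell_phantom
from corrmicro.phantom import (
    CellPhantom,
    NucleusParams,
    render_fluorescence,
    simulate_hologram,
    simulate_scan_saxs,
    single_filament_cells,
)


def _empty_phantom(shape=(128, 128), pixel_size=40.0):
    return make_cell_phantom(
        n_filaments=0, label_fraction=0.0, shape=shape, pixel_size=pixel_size,
        seed=0, envelope_amp=0.0, nucleus_scale=0.0, nucleus_texture_amp=0.0,
    )


class TestPhantomGeneration:
    def test_empty_network(self):
        cell = make_cell_phantom(
            n_filaments=0, label_fraction=0.0, shape=(128, 128), seed=0
        )
        assert np.all(cell.label_map == 0)
        assert cell.density.max() > 0  # nucleus + envelope remain
        assert len(cell.true_filaments) == 0

    def test_seed_determinism_bit_identical(self):
        a = make_cell_phantom(shape=(128, 128), seed=42)
        b = make_cell_phantom(shape=(128, 128), seed=42)
        assert np.array_equal(a.density, b.density)
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.label_map, b.label_map)
        assert a.true_filaments == b.true_filaments

    def test_basic_invariants(self, small_phantom):
        cell = small_phantom
        assert np.all(cell.density >= 0)
        assert np.all(cell.label_map >= 0)
        np.testing.assert_allclose(cell.phase, -cell.phase_scale * cell.density)
        n_lab = sum(f.labeled for f in cell.true_filaments)
        assert n_lab == round(0.7 * 30)

    def test_orientation_spread_sampling_distribution(self):
        """Circular std of filament orientations ~ requested spread."""
        spreads = []
        for seed in range(100):
            cell = make_cell_phantom(
                n_filaments=20, orientation_spread=15.0, shape=(128, 128),
                pixel_size=80.0, seed=seed,
            )
            th = np.radians(2.0 * np.array([f.orientation for f in cell.true_filaments]))
            r = np.hypot(np.cos(th).mean(), np.sin(th).mean())
            spreads.append(np.degrees(np.sqrt(-2.0 * np.log(r))) / 2.0)
        assert abs(np.mean(spreads) - 15.0) < 3.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_cell_phantom(shape=(32, 32))
        with pytest.raises(ValueError):
            make_cell_phantom(pixel_size=-1.0)
        with pytest.raises(ValueError):
            make_cell_phantom(label_fraction=1.5)
        with pytest.raises(ValueError):
            make_cell_phantom(n_filaments=-1)


class TestFluorescence:
    def test_no_label_gives_no_counts(self):
        img = render_fluorescence(_empty_phantom(), psf_fwhm=343.0, seed=1)
        assert np.all(img.counts == 0)

    def test_budget_linearity(self, small_phantom):
        lo = render_fluorescence(small_phantom, 343.0, 1e3, seed=3)
        hi = render_fluorescence(small_phantom, 343.0, 2e3, seed=4)
        assert hi.counts.sum() / lo.counts.sum() == pytest.approx(2.0, rel=0.01)

    def test_impulse_response_fwhm(self):
        cell = _empty_phantom()
        label = np.zeros(cell.shape)
        label[64, 64] = 1.0
        point = dataclasses.replace(cell, label_map=label)
        psf_fwhm = 343.0  # nm = 8.575 px at 40 nm
        img = render_fluorescence(point, psf_fwhm, 1000.0, noiseless=True)
        profile = img.counts[64]
        half = profile.max() / 2.0
        above = np.nonzero(profile >= half)[0]
        fwhm_px = above[-1] - above[0] + 1
        assert abs(fwhm_px * cell.pixel_size - psf_fwhm) <= cell.pixel_size

    def test_invalid_budget(self, small_phantom):
        with pytest.raises(ValueError):
            render_fluorescence(small_phantom, 343.0, photon_budget=0.0)


class TestHologramSimulation:
    def test_zero_phantom_gives_unit_hologram(self, geom256):
        holo = simulate_hologram(
            _empty_phantom((256, 256)), geom256, photon_budget=None
        )
        np.testing.assert_allclose(holo.intensity, 1.0, atol=1e-10)

    def test_seed_reproducibility(self, small_phantom, geom256):
        a = simulate_hologram(small_phantom, geom256, seed=9)
        b = simulate_hologram(small_phantom, geom256, seed=9)
        assert np.array_equal(a.intensity, b.intensity)

    def test_poisson_statistics_of_empty_beam(self, geom256):
        """Mean 1, variance 1/budget: chi^2 within normal bounds at
        alpha = 0.01 for at least 95% of seeds."""
        cell = _empty_phantom((256, 256))
        budget, n_pix = 2000.0, 256 * 256
        passes = 0
        for seed in range(20):
            holo = simulate_hologram(
                cell, geom256, photon_budget=budget, shape=(256, 256), seed=seed
            )
            chi2 = np.sum((holo.intensity - 1.0) ** 2) * budget
            z = (chi2 - n_pix) / np.sqrt(2.0 * n_pix)
            passes += abs(z) < 2.576
        assert passes >= 18


class TestScanSaxs:
    def test_background_only_off_cell(self):
        cell = make_cell_phantom(shape=(256, 256), seed=2)
        beam = BeamProfile(exposure=0.05)
        grid = ScanGrid(shape=(1, 1), step_um=1.0, origin_um=(0.4, 0.4))
        stack = simulate_scan_saxs(
            cell, beam, grid, background_rate=10.0, det_size=128, seed=0,
            noiseless=True,
        )
        frame = stack.counts[0, 0]
        mean_valid = frame[stack.mask].mean()
        assert mean_valid == pytest.approx(10.0 * 0.05, rel=0.02)

    def test_outside_positions_flagged_empty(self, small_phantom):
        beam = BeamProfile()
        grid = ScanGrid(shape=(1, 2), step_um=1.0, origin_um=(-8.0, -8.0))
        stack = simulate_scan_saxs(small_phantom, beam, grid, det_size=64, seed=0)
        assert stack.empty[0, 0]

    def test_horizontal_fiber_scatters_vertically(self):
        """A fiber along +y diffracts into a vertical streak: the
        principal reciprocal axis is within 5 degrees of vertical."""
        from corrmicro import pca_anisotropy, q_map

        base = _empty_phantom((256, 256))
        zz = np.arange(256)[:, None] - 128.0
        density = 0.5 * np.exp(-(zz**2) / (2.0 * 2.5**2)) * np.ones((1, 256))
        fiber = dataclasses.replace(
            base, density=density, phase=-0.4 * density
        )
        beam = BeamProfile()
        grid = ScanGrid(shape=(1, 1), step_um=1.0, origin_um=(5.12, 5.12))
        stack = simulate_scan_saxs(fiber, beam, grid, det_size=128, seed=0)
        qmap = q_map(stack.calibration, (128, 128))
        res = pca_anisotropy(stack.counts[0, 0], stack.mask, qmap)
        assert res.valid and res.omega > 0.5
        assert min(abs(res.theta_recip - 90.0), abs(res.theta_recip - 90.0 - 180.0)) < 5.0
        assert min(res.theta_real, 180.0 - res.theta_real) < 5.0

    def test_exposure_linearity(self, small_phantom):
        grid = ScanGrid(shape=(1, 1), step_um=1.0, origin_um=(5.0, 5.0))
        s1 = simulate_scan_saxs(
            small_phantom, BeamProfile(exposure=0.05), grid, det_size=64,
            noiseless=True,
        )
        s2 = simulate_scan_saxs(
            small_phantom, BeamProfile(exposure=0.10), grid, det_size=64,
            noiseless=True,
        )
        assert s2.counts.sum() == pytest.approx(2.0 * s1.counts.sum(), rel=1e-10)

    def test_parseval_noiseless_unmasked(self, small_phantom):
        beam = BeamProfile(exposure=0.05)
        grid = ScanGrid(shape=(1, 1), step_um=1.0, origin_um=(5.0, 5.0))
        stack = simulate_scan_saxs(
            small_phantom, beam, grid, background_rate=0.0, det_size=128,
            beamstop_radius=0.0, gap_width=0, noiseless=True,
        )
        total = stack.counts[0, 0].sum()
        expected = beam.flux * beam.exposure  # unit-power illumination
        assert abs(total - expected) / expected < 1e-10

    def test_step_smaller_than_pixel_rejected(self, small_phantom):
        grid = ScanGrid(shape=(2, 2), step_um=0.01)
        with pytest.raises(ValueError):
            simulate_scan_saxs(small_phantom, BeamProfile(), grid)


def test_single_filament_cells_returns_true_orientations(small_phantom):
    grid = ScanGrid(shape=(10, 10), step_um=1.0, origin_um=(0.12, 0.12))
    cells = single_filament_cells(small_phantom, grid)
    true_orients = {f.orientation for f in small_phantom.true_filaments}
    assert all(th in true_orients for th in cells.values())
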