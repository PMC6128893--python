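import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrmicro import (
    QCalibration,
    azimuthal_average,
    compose_mask,
    pca_anisotropy,
    q_map,
    subtract_background,
    threshold_map,
)
from corrmicro.saxs import DarkFieldMap, ScanGrid, ScanStack, darkfield, fft_q_calibration


@pytest.fixture(scope="module")
def cal9():
    """Calibration with the beam center at the exact center of a 9x9 frame."""
    return QCalibration(beam_center=(4.0, 4.0), distance_mm=5000.0,
                        pixel_size_um=172.0, wavelength_nm=0.08984)


class TestQMap:
    def test_beam_center_pixel_is_origin(self, cal9):
        qy, qz, qabs = q_map(cal9, (9, 9))
        assert qabs[4, 4] == 0.0
        assert qy[4, 4] == 0.0 and qz[4, 4] == 0.0

    def test_known_radial_value(self):
        # r = 100 px * 172 um = 17.2 mm at D = 5 m, lambda = 0.08984 nm
        cal = QCalibration(beam_center=(0.0, 0.0), distance_mm=5000.0,
                           pixel_size_um=172.0, wavelength_nm=0.08984)
        _, _, qabs = q_map(cal, (1, 101))
        assert qabs[0, 100] == pytest.approx(0.2406, abs=2e-4)

    def test_small_angle_limit(self):
        cal = QCalibration(beam_center=(0.0, 0.0), distance_mm=5000.0,
                           pixel_size_um=172.0, wavelength_nm=0.08984)
        _, _, qabs = q_map(cal, (1, 200))
        r_nm = np.arange(200) * 172e3
        approx = 2.0 * np.pi * r_nm / (cal.wavelength_nm * cal.distance_mm * 1e6)
        small = (r_nm > 0) & (r_nm / (cal.distance_mm * 1e6) < 1e-2)
        rel = np.abs(qabs[0, small] - approx[small]) / approx[small]
        assert rel.max() < 1e-4

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            QCalibration(beam_center=(0, 0), distance_mm=0.0)


class TestMask:
    def test_no_exclusions(self):
        assert compose_mask((16, 16)).all()

    def test_beamstop_disc_area(self):
        mask = compose_mask((128, 128), beamstop=((64, 64), 20.0))
        excluded = (~mask).sum()
        assert abs(excluded - np.pi * 400) < 2 * np.pi * 20 + 10  # within the rim

    def test_masks_compose_commutatively(self):
        both = compose_mask((64, 64), beamstop=((32, 32), 5.0), gaps=[(10, 14)])
        a = compose_mask((64, 64), beamstop=((32, 32), 5.0))
        b = compose_mask((64, 64), gaps=[(10, 14)])
        assert np.array_equal(both, a & b)

    def test_gap_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            compose_mask((32, 32), gaps=[(20, 40)])


class TestBackgroundSubtraction:
    def test_self_subtraction_is_zero(self):
        frame = np.arange(16.0).reshape(4, 4)
        assert np.all(subtract_background(frame, [frame]) == 0)

    def test_zero_background_is_identity(self):
        frame = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(
            subtract_background(frame, [np.zeros((4, 4))]), frame
        )

    def test_constant_offset_removed_within_poisson_error(self):
        rng = np.random.default_rng(5)
        signal, b = 50.0, 20.0
        frame = rng.poisson(signal + b, size=(32, 32)).astype(float)
        bg = rng.poisson(b, size=(100, 32, 32)).astype(float)
        corrected = subtract_background(frame, bg)
        # sd of the mean residual: frame noise + averaged background noise
        se = np.sqrt((signal + b + b / 100.0) / frame.size)
        assert abs(corrected.mean() - signal) < 4 * se


class TestDarkField:
    def _stack(self, counts, mask, exposure=1.0):
        nz, ny = counts.shape[:2]
        return ScanStack(
            counts=counts, mask=mask,
            grid=ScanGrid(shape=(nz, ny)),
            calibration=QCalibration((0, 0), 1000.0),
            exposure=exposure,
        )

    def test_ones_frame(self):
        counts = np.ones((1, 1, 16, 16), dtype=int)
        mask = np.zeros((16, 16), dtype=bool)
        mask.ravel()[:100] = True
        df = darkfield(self._stack(counts, mask))
        assert df.values[0, 0] == 100

    def test_all_masked_gives_zero(self):
        counts = np.ones((1, 1, 8, 8), dtype=int)
        df = darkfield(self._stack(counts, np.zeros((8, 8), dtype=bool)))
        assert df.values[0, 0] == 0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 1000, size=(2, 3, 16, 16))
        mask = rng.random((16, 16)) > 0.3
        df = darkfield(self._stack(counts, mask))
        for iz in range(2):
            for iy in range(3):
                acc = 0
                for r in range(16):
                    for c in range(16):
                        if mask[r, c]:
                            acc += counts[iz, iy, r, c]
                assert df.values[iz, iy] == acc

    def test_additive_over_mask_partition(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 100, size=(1, 1, 16, 16))
        mask = np.ones((16, 16), dtype=bool)
        part = rng.random((16, 16)) > 0.5
        stack = self._stack(counts, mask)
        total = darkfield(stack).values
        a = darkfield(stack, mask=part).values
        b = darkfield(stack, mask=~part).values
        assert np.array_equal(total, a + b)


def _bruteforce_pca(counts, mask, qy, qz):
    sw = syy = szz = syz = 0.0
    for r in range(counts.shape[0]):
        for c in range(counts.shape[1]):
            if not mask[r, c] or counts[r, c] <= 0:
                continue
            w = counts[r, c]
            sw += w
            syy += w * qy[r, c] ** 2
            szz += w * qz[r, c] ** 2
            syz += w * qy[r, c] * qz[r, c]
    cyy, czz, cyz = syy / sw, szz / sw, syz / sw
    half = 0.5 * (cyy + czz)
    d = np.sqrt((0.5 * (cyy - czz)) ** 2 + cyz**2)
    lam1, lam2 = half + d, half - d
    theta = 0.5 * np.degrees(np.arctan2(2.0 * cyz, cyy - czz)) % 180.0
    return lam1, lam2, (lam1 - lam2) / (lam1 + lam2), theta


class TestPCA:
    def test_matches_bruteforce_closed_form(self, cal9):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 500, size=(9, 9))
        mask = rng.random((9, 9)) > 0.2
        mask[4, 4] = True
        qy, qz, _ = q_map(cal9, (9, 9))
        res = pca_anisotropy(counts, mask, q_map(cal9, (9, 9)), q_range=None)
        lam1, lam2, omega, theta = _bruteforce_pca(counts, mask, qy, qz)
        assert res.lam1 == pytest.approx(lam1, abs=1e-12 * lam1)
        assert res.lam2 == pytest.approx(lam2, abs=1e-12 * lam1)
        assert res.omega == pytest.approx(omega, abs=1e-12)
        assert res.theta_recip == pytest.approx(theta, abs=1e-9)

    def test_circularly_symmetric_pattern_is_isotropic(self, cal9):
        _, _, qabs = q_map(cal9, (9, 9))
        counts = np.exp(-(qabs**2) / (2 * 0.1**2)) * 100
        res = pca_anisotropy(counts, np.ones((9, 9), bool), q_map(cal9, (9, 9)),
                             q_range=None)
        assert res.valid
        assert res.omega == 0.0
        assert np.isnan(res.theta_recip)

    def test_line_along_qy_axis(self, cal9):
        counts = np.zeros((9, 9))
        counts[4, :] = 10.0  # the beam-center row: q_z = 0, q_y varies
        counts[4, 4] = 0.0
        res = pca_anisotropy(counts, np.ones((9, 9), bool), q_map(cal9, (9, 9)),
                             q_range=None)
        assert res.omega == pytest.approx(1.0, abs=1e-12)
        assert res.theta_recip == pytest.approx(0.0, abs=1e-9)
        assert res.theta_real == pytest.approx(90.0, abs=1e-9)

    def test_rotation_equivariance(self, cal9):
        rng = np.random.default_rng(11)
        counts = rng.integers(1, 100, size=(9, 9)).astype(float)
        qmap = q_map(cal9, (9, 9))
        mask = np.ones((9, 9), bool)
        res = pca_anisotropy(counts, mask, qmap, q_range=None)
        res_rot = pca_anisotropy(np.rot90(counts), mask, qmap, q_range=None)
        assert res_rot.omega == pytest.approx(res.omega, abs=1e-12)
        d = abs((res_rot.theta_recip - res.theta_recip) % 180.0)
        assert min(d, 180.0 - d) == pytest.approx(90.0, abs=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_omega_invariant_under_intensity_scaling(self, cal9, scale):
        rng = np.random.default_rng(13)
        counts = rng.integers(1, 100, size=(9, 9)).astype(float)
        qmap = q_map(cal9, (9, 9))
        mask = np.ones((9, 9), bool)
        a = pca_anisotropy(counts, mask, qmap, q_range=None)
        b = pca_anisotropy(counts * scale, mask, qmap, q_range=None)
        assert 0.0 <= a.omega <= 1.0
        assert b.omega == pytest.approx(a.omega, rel=1e-9)

    def test_empty_weights_flagged_invalid(self, cal9):
        res = pca_anisotropy(np.zeros((9, 9)), np.ones((9, 9), bool),
                             q_map(cal9, (9, 9)), q_range=None)
        assert not res.valid


class TestThreshold:
    def test_threshold_separates_background_from_cell(self):
        df = DarkFieldMap(values=np.array([[1e5, 8e5]]), exposure=1.0)
        valid = threshold_map(df, i_df=7.5e5)
        assert valid.tolist() == [[False, True]]

    def test_zero_threshold_keeps_positive(self):
        df = DarkFieldMap(values=np.array([[0.0, 1.0, 5.0]]), exposure=1.0)
        assert threshold_map(df, 0.0).tolist() == [[False, True, True]]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(17)
        df = DarkFieldMap(values=rng.random((8, 8)) * 1e6, exposure=1.0)
        lo = threshold_map(df, 2e5)
        hi = threshold_map(df, 6e5)
        assert np.all(lo | ~hi)  # raising the threshold never adds pixels


class TestAzimuthalAverage:
    def test_constant_frame(self):
        cal = fft_q_calibration(64, 40.0, 0.08984)
        qmap = q_map(cal, (64, 64))
        q, prof, npix = azimuthal_average(
            np.full((64, 64), 7.0), np.ones((64, 64), bool), qmap, n_bins=16
        )
        assert np.allclose(prof[npix > 0], 7.0)

    def test_isotropic_gaussian_profile(self):
        cal = fft_q_calibration(128, 40.0, 0.08984)
        qmap = q_map(cal, (128, 128))
        s = 0.02
        frame = np.exp(-(qmap[2] ** 2) / (2 * s**2))
        q, prof, npix = azimuthal_average(
            frame, np.ones((128, 128), bool), qmap, n_bins=32
        )
        expected = np.exp(-(q**2) / (2 * s**2))
        good = (npix > 10) & (expected > 1e-3)
        assert np.abs(prof[good] - expected[good]).max() < 0.05

    def test_wedge_mask_stability_for_isotropic_input(self):
        cal = fft_q_calibration(128, 40.0, 0.08984)
        qmap = q_map(cal, (128, 128))
        frame = 1.0 / (1.0 + (qmap[2] / 0.02) ** 2)
        full = np.ones((128, 128), bool)
        wedge = full.copy()
        zz, yy = np.meshgrid(*[np.arange(128) - 64.0] * 2, indexing="ij")
        wedge[(np.degrees(np.arctan2(zz, yy)) % 360.0) < 45.0] = False
        _, p_full, n_full = azimuthal_average(frame, full, qmap, n_bins=24)
        _, p_wedge, n_wedge = azimuthal_average(frame, wedge, qmap, n_bins=24)
        both = (n_full > 20) & (n_wedge > 10)
        assert np.abs(p_full[both] - p_wedge[both]).max() < 0.02

    def test_too_few_bins_rejected(self):
        cal = fft_q_calibration(16, 40.0, 0.08984)
        with pytest.raises(ValueError):
            azimuthal_average(np.ones((16, 16)), np.ones((16, 16), bool),
                              q_map(cal, (16, 16)), n_bins=1)
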