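"""OCTA reconstruction: phase differences, bulk removal, aggregation,
filtering/projection, interscan-time selection."""

import numpy as np
import pytest

from vesselquant import octa, octsim
from vesselquant.io import ROI


def make_series(v=0.0, dt=0.160, n_rep=4, bulk=None, phase_noise=0.0,
                seed=0, shape=(6, 10), intensity=None, velocity=None):
    inten = np.ones(shape) if intensity is None else intensity
    vel = np.full(shape, float(v)) if velocity is None else velocity
    ph = octsim.FlowPhantom(inten, vel, bulk_offsets_rad=bulk,
                            phase_noise_sigma=phase_noise)
    acq = octsim.AcquisitionParams(inter_repeat_time_s=dt, n_repeats=n_rep)
    return octsim.simulate_bm_series(ph, acq, seed=seed)


class TestPhaseDifference:
    def test_static_series_gives_zero_frames(self):
        frames = octa.phase_difference(make_series(v=0.0), 1)
        assert frames.shape == (3, 6, 10)
        np.testing.assert_allclose(frames, 0.0, atol=1e-12)

    @pytest.mark.parametrize("j", [1, 2, 3])
    def test_doppler_frames_match_closed_form_at_any_separation(self, j):
        v, dt = 100.0, 0.030
        s = make_series(v=v, dt=dt)
        frames = octa.phase_difference(s, j)
        assert frames.shape[0] == s.n_repeats - j
        expect = octsim.wrap_phase(j * octsim.doppler_phase_rad(v, dt))
        np.testing.assert_allclose(frames, expect, atol=1e-9)
        assert np.all(frames > -np.pi) and np.all(frames <= np.pi)

    def test_out_of_range_separation_rejected(self):
        s = make_series()
        for j in (0, 4, -1):
            with pytest.raises(ValueError):
                octa.phase_difference(s, j)


class TestDebulk:
    def test_common_mode_offset_removed_exactly(self):
        c = 1.1
        s = make_series(v=0.0, bulk=np.array([0.0, c, 2 * c, 3 * c]))
        frames = octa.phase_difference(s, 1)
        corrected, mask = octa.unwrap_and_debulk(frames, s.intensity(), 0.5)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-9)
        assert mask.all()

    def test_doppler_preserved_when_static_pixels_dominate(self):
        # vessel occupies 2 of 6 depth pixels; bulk offsets vary per repeat
        vel = np.zeros((6, 10))
        vel[2:4] = 100.0
        bulk = np.array([0.0, 0.9, -0.4, 0.3])
        s_bulk = make_series(dt=0.030, bulk=bulk, velocity=vel)
        s_free = make_series(dt=0.030, bulk=None, velocity=vel)
        cb, _ = octa.unwrap_and_debulk(octa.phase_difference(s_bulk, 1),
                                       s_bulk.intensity(), 0.5)
        cf, _ = octa.unwrap_and_debulk(octa.phase_difference(s_free, 1),
                                       s_free.intensity(), 0.5)
        np.testing.assert_allclose(cb, cf, atol=1e-9)

    def test_subthreshold_pixels_masked_to_zero_contrast(self):
        inten = np.ones((6, 10))
        inten[:, 7:] = 0.01  # noise columns
        s = make_series(intensity=inten, phase_noise=0.3, seed=2)
        frames = octa.phase_difference(s, 1)
        corrected, mask = octa.unwrap_and_debulk(frames, s.intensity(), 0.5)
        contrast = octa.aggregate_contrast(corrected, mask)
        assert np.all(contrast[:, 7:] == 0.0)
        assert contrast[:, :7].max() > 0


class TestAggregate:
    def test_zero_frames_give_zero_contrast(self):
        frames = np.zeros((3, 4, 5))
        assert octa.aggregate_contrast(frames).max() == 0.0
        assert octa.aggregate_contrast(frames, method="variance").max() == 0.0

    def test_constant_doppler_mean_abs_vs_variance(self):
        s = make_series(v=100.0, dt=0.030)
        frames = octa.phase_difference(s, 1)
        expect = abs(octsim.wrap_phase(octsim.doppler_phase_rad(100.0, 0.030)))
        np.testing.assert_allclose(octa.aggregate_contrast(frames), expect,
                                   atol=1e-9)
        # constant differences across frames have zero variance
        np.testing.assert_allclose(
            octa.aggregate_contrast(frames, method="variance"), 0.0, atol=1e-9)

    def test_uniform_random_phase_variance_approaches_pi2_over_3(self, rng):
        frames = rng.uniform(-np.pi, np.pi, size=(10_000, 3, 3))
        var = octa.aggregate_contrast(frames, method="variance")
        np.testing.assert_allclose(var, np.pi ** 2 / 3, rtol=0.05)


class TestDenoiseAndProject:
    def test_all_zero_volume_projects_to_zero(self):
        av = octa.AngiogramVolume(np.zeros((4, 8, 6)), 0.16)
        m = octa.denoise_and_project(av, 1, directional=False)
        assert m.pixels.max() == 0.0

    def test_single_bright_column_projects_to_single_pixel(self):
        c = np.zeros((5, 8, 6))
        c[:, 3, 2] = 1.0  # bright along depth at (x=3, y=2)
        av = octa.AngiogramVolume(c, 0.16)
        m = octa.denoise_and_project(av, 0, directional=False)
        assert m.pixels[2, 3] == 1.0
        assert (m.pixels > 0).sum() == 1

    def test_median_removes_salt_but_keeps_wide_vessel(self):
        from scipy.ndimage import median_filter
        from skimage.morphology import disk

        img = np.zeros((40, 40))
        img[16:23, :] = 1.0          # 7-px-wide vessel
        img[5, 5] = img[30, 33] = 1.0  # isolated salt pixels
        av = octa.AngiogramVolume(img[None].transpose(0, 2, 1), 0.16)
        m = octa.denoise_and_project(av, 3, directional=False)
        assert m.pixels[5, 5] == 0.0 and m.pixels[30, 33] == 0.0
        assert m.pixels[19, 20] > 0
        # brute-force oracle: scipy median with the same disk footprint
        oracle = median_filter(img, footprint=disk(3), mode="nearest")
        np.testing.assert_allclose(m.pixels, oracle / oracle.max())

    def test_projection_idempotent_on_flat_volume(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 1, size=(1, 8, 6))
        av = octa.AngiogramVolume(c, 0.16)
        once = octa.project_max(av)
        again = octa.project_max(
            octa.AngiogramVolume(once.pixels.T[None], 0.16))
        np.testing.assert_array_equal(once.pixels, again.pixels)

    def test_auto_threshold_requires_background(self):
        av = octa.AngiogramVolume(np.ones((2, 4, 4)), 0.16)
        with pytest.raises(ValueError, match="background"):
            octa.denoise_and_project(av, 0, directional=False, threshold="auto")


class TestBulkInvariance:
    def test_enface_map_invariant_to_per_frame_offsets(self):
        rng = np.random.default_rng(3)
        inten = np.full((6, 20, 10), 0.5)
        vel = np.zeros((6, 20, 10))
        vel[2:4, 5:8] = 100.0
        acq = octsim.AcquisitionParams(0.160, 4)
        bulk = rng.uniform(-0.5, 0.5, size=(10, 4))
        kw = dict(phase_noise_sigma=0.1, amplitude_noise_sigma=0.02, seed=9)
        v0 = octsim.simulate_bm_volume(inten, vel, acq, None, **kw)
        v1 = octsim.simulate_bm_volume(inten, vel, acq, bulk, **kw)
        m0 = octa.denoise_and_project(octa.reconstruct_volume(v0, 1, 0.2), 3)
        m1 = octa.denoise_and_project(octa.reconstruct_volume(v1, 1, 0.2), 3)
        assert np.abs(m0.pixels - m1.pixels).max() < 1e-6


class TestSelectInterscan:
    def _reconstruct_at(self, j, vel, noise, base_dt=0.010, n_rep=40, seed=4):
        inten = np.ones((6, 16, 8))
        acq = octsim.AcquisitionParams(base_dt, n_rep)
        vol = octsim.simulate_bm_volume(inten, vel, acq,
                                        phase_noise_sigma=noise, seed=seed)
        av = octa.reconstruct_volume(vol, j, 0.2)
        return octa.denoise_and_project(av, 0, directional=False,
                                        normalize=False), av

    def test_slow_vessel_contrast_peaks_at_intermediate_dt(self):
        # 10 µm/s vessel: its (aliased) phase signature sits below the phase
        # noise at 30 ms, well above it at 160 ms
        v = 10.0
        noise = 0.12
        sig = {dt: abs(octsim.wrap_phase(octsim.doppler_phase_rad(v, dt)))
               for dt in (0.030, 0.160, 0.330)}
        assert sig[0.030] < noise < sig[0.160]
        vel = np.zeros((6, 16, 8))
        vel[2:4, 4:8] = v
        vmask = np.zeros((8, 16), dtype=bool)
        vmask[:, 4:8] = True
        bmask = ~vmask
        maps = {}
        for j in (3, 16, 33):  # dt_eff = 30, 160, 330 ms
            m, _ = self._reconstruct_at(j, vel, noise)
            maps[j] = m
        df = octa.select_interscan(maps, vmask, bmask, dt_s=0.010)
        ratios = dict(zip(df.pair_separation, df.contrast_ratio))
        assert ratios[16] > ratios[3]
        assert ratios[16] > ratios[33]

    def test_noise_free_ratio_monotone_until_wrapping(self):
        # a truly slow scatterer (0.05 µm/s): phase stays below pi for every
        # tested separation, so vessel contrast grows monotonically
        vel = np.zeros((6, 16, 8))
        vel[2:4, 4:8] = 0.05
        assert abs(octsim.doppler_phase_rad(0.05, 0.010 * 16)) < np.pi
        vmask = np.zeros((8, 16), dtype=bool)
        vmask[:, 4:8] = True
        means = []
        for j in (1, 4, 16):
            m, _ = self._reconstruct_at(j, vel, noise=0.0)
            means.append(m.pixels[vmask.nonzero()].mean())
        # below the wrap the vessel contrast grows linearly with dt_eff
        assert means[0] < means[1] < means[2]

    def test_fewer_than_two_settings_rejected(self):
        m, _ = self._reconstruct_at(1, np.zeros((6, 16, 8)), 0.0)
        with pytest.raises(ValueError):
            octa.select_interscan({1: m}, np.ones((8, 16), bool),
                                  np.ones((8, 16), bool))


def test_doppler_linearity_below_wrap():
    """Mean |Δφ| is linear in v·dt_eff with slope 4πn/λ within 2 %."""
    slope_expect = 4 * np.pi * 1.33 / 800e-9
    for v, dt in [(10.0, 0.001), (40.0, 0.001), (20.0, 0.002)]:
        s = make_series(v=v, dt=dt)
        meas = octa.aggregate_contrast(octa.phase_difference(s, 1)).mean()
        assert meas == pytest.approx(slope_expect * v * 1e-6 * dt, rel=0.02)
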