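"""Per-pixel Fourier analysis: DFT, closed-form inversion, quality metrics."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from ffpshg.core import (
    MAP_KEYS,
    SNR_CAP_DB,
    average_endpoint_frames,
    compute_err,
    compute_r2,
    compute_snr,
    fit_stack,
    invert_spectrum,
    pixel_dft,
)
from ffpshg.model import (
    DEFAULT_GRID,
    PROCESSING_GRID,
    CollagenParams,
    generate_stack,
    shg_intensity,
)
from conftest import region_grid_spec

ANGLES9 = PROCESSING_GRID.as_array()
ANGLES10 = DEFAULT_GRID.as_array()


def model_series(params: CollagenParams, angles=ANGLES9) -> np.ndarray:
    return np.asarray(shg_intensity(params, angles))


def nls_fit(series9: np.ndarray) -> CollagenParams:
    """Independent oracle: multi-start nonlinear least squares on the model."""

    def resid(p):
        i0, b, c, phi = p
        return model_series(CollagenParams(max(i0, 1e-12), b, c, phi)) - series9

    best, best_cost = None, np.inf
    for phi0 in range(0, 180, 15):
        sol = least_squares(
            resid,
            x0=[max(series9.max(), 1e-6), 1.0, 2.0, float(phi0)],
            bounds=([1e-9, 0, 0, -360], [np.inf, 20, 20, 720]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if sol.cost < best_cost:
            best, best_cost = sol.x, sol.cost
    i0, b, c, phi = best
    if b > c:  # canonical branch: the model cannot tell (b,c,phi) from (c,b,phi+90)
        b, c, phi = c, b, phi + 90
    return CollagenParams(i0, b, c, phi % 180)


class TestEndpointAveraging:
    def test_mean_of_endpoints(self):
        stack = np.zeros((10, 2, 2))
        stack[0] = 100.0
        stack[9] = 50.0
        stack[3] = 7.0
        out = average_endpoint_frames(stack)
        assert out.shape[0] == 9
        assert np.all(out[0] == 75.0)
        assert np.all(out[3] == 7.0)

    def test_idempotent_when_endpoints_equal(self):
        stack = np.random.default_rng(0).random((10, 3, 3))
        stack[9] = stack[0]
        out = average_endpoint_frames(stack)
        assert np.array_equal(out[0], stack[0])

    def test_rejects_wrong_frame_count(self):
        with pytest.raises(ValueError, match="10"):
            average_endpoint_frames(np.zeros((9, 2, 2)))


class TestPixelDft:
    def test_constant_series_is_dc_only(self):
        spec = pixel_dft(np.full(9, 3.25))
        assert spec.chat[0] == pytest.approx(3.25, abs=1e-12)
        assert np.allclose(spec.chat[1:], 0.0, atol=1e-12)

    def test_model_harmonics_land_in_bins_1_and_2(self):
        # series from the harmonic form with (c0,c1,c2)=(2.875,1.5,-0.375), phi=0
        d = np.deg2rad(-ANGLES9)
        series = 2.875 + 1.5 * np.cos(2 * d) - 0.375 * np.cos(4 * d)
        spec = pixel_dft(series)
        assert spec.chat[0] == pytest.approx(2.875, abs=1e-9)
        assert spec.chat[1] == pytest.approx(1.5, abs=1e-9)
        assert spec.chat[2] == pytest.approx(0.375, abs=1e-9)
        # the sign flip of the cos4 term is carried by the phase of G2
        assert abs(spec.phase2) == pytest.approx(np.pi, abs=1e-9)
        assert np.allclose(spec.chat[3:], 0.0, atol=1e-9)

    def test_parseval_identity(self, rng):
        series = rng.normal(5, 2, size=(100, 9))
        spec = pixel_dft(series)
        lhs = np.sum((series - series.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
        rhs = np.sum(np.abs(spec.g[..., 1:]) ** 2, axis=-1) / 9.0
        assert np.allclose(lhs, rhs, rtol=1e-9)

    def test_conjugate_symmetry(self, rng):
        spec = pixel_dft(rng.random(9))
        for k in range(1, 5):
            assert abs(spec.g[9 - k]) == pytest.approx(abs(spec.g[k]), rel=1e-12)

    def test_nonfinite_pixel_flagged(self):
        series = np.ones(9)
        series[4] = np.nan
        fit = invert_spectrum(pixel_dft(series))
        assert np.isnan(fit.chi3315)


class TestInvertSpectrum:
    def test_recovers_known_pixel(self):
        series = model_series(CollagenParams(1.0, 1.0, 2.0, 30.0))
        fit = invert_spectrum(pixel_dft(series))
        assert fit.i0 == pytest.approx(1.0, abs=1e-9)
        assert fit.chi3115 == pytest.approx(1.0, abs=1e-9)
        assert fit.chi3315 == pytest.approx(2.0, abs=1e-9)
        assert fit.chi3331 == pytest.approx(2.0, abs=1e-9)
        assert fit.phi == pytest.approx(30.0, abs=1e-9)
        assert fit.theta_e == pytest.approx(45.0, abs=1e-9)

    def test_quadratic_root_rejection(self):
        """(M0,M1,M2)=(2.875,1.5,-0.375) has roots {1,3}; root 3 gives b<0."""
        m0, m1, m2 = 2.875, 1.5, -0.375
        roots = np.roots([1.0, 3 * m2 - m0, m1**2 / 4 - 2 * m0 * m2 + 2 * m2**2])
        assert sorted(roots) == pytest.approx([1.0, 3.0])
        # with I0=3: u^2=8(m2+1.5)/3=3, v^2=4(m0-m2-3)/3=1/3 -> b=(v-u)/2<0
        u, v = np.sqrt(3), np.sqrt(1 / 3)
        assert (v - u) / 2 == pytest.approx(-0.577, abs=1e-3)
        series = model_series(CollagenParams(1.0, 1.0, 2.0, 0.0))
        fit = invert_spectrum(pixel_dft(series))
        assert fit.i0 == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_gives_nan_fit(self):
        fit = invert_spectrum(pixel_dft(np.full(9, 7.0)))
        for v in (fit.i0, fit.chi3115, fit.chi3315, fit.chi3331, fit.phi, fit.theta_e):
            assert np.isnan(v)

    def test_equal_ratios_recovered_mod_90(self):
        series = model_series(CollagenParams(2.0, 1.5, 1.5, 70.0))
        fit = invert_spectrum(pixel_dft(series))
        assert fit.chi3115 == pytest.approx(1.5, abs=1e-9)
        assert fit.chi3315 == pytest.approx(1.5, abs=1e-9)
        assert float(fit.phi) % 90 == pytest.approx(70.0 % 90, abs=1e-6)

    def test_matches_least_squares_oracle(self, rng):
        """Closed-form inversion equals multi-start NLS on clean pixels."""
        for _ in range(100):
            true = CollagenParams(
                i0=float(rng.uniform(0.5, 5)),
                b=float(rng.uniform(0.5, 1.5)),
                c=float(rng.uniform(1.0, 3.0)),
                phi=float(rng.uniform(0, 180)),
            )
            if true.c <= true.b + 0.05:  # stay off the degenerate b=c seam
                continue
            series = model_series(true)
            fit = invert_spectrum(pixel_dft(series))
            oracle = nls_fit(series)
            assert fit.i0 == pytest.approx(oracle.i0, abs=1e-6)
            assert fit.chi3115 == pytest.approx(oracle.b, abs=1e-6)
            assert fit.chi3315 == pytest.approx(oracle.c, abs=1e-6)
            dphi = abs(float(fit.phi) - oracle.phi) % 180
            assert min(dphi, 180 - dphi) < 1e-6


class TestQualityMetrics:
    def test_r2_exact_for_model_data(self):
        params = CollagenParams(1.2, 0.9, 2.1, 55.0)
        series10 = model_series(params, ANGLES10)
        fit = invert_spectrum(pixel_dft(average_endpoint_frames(series10.reshape(10, 1, 1))
                                        .reshape(9)))
        assert compute_r2(series10, fit) == pytest.approx(1.0, abs=1e-9)

    def test_r2_matches_direct_sums_under_perturbation(self):
        """With a fixed residual pattern, R2 equals 1 - SSR/SST by direct sums."""
        params = CollagenParams(1.0, 1.0, 2.0, 30.0)
        y = model_series(params, ANGLES10)
        resid = 0.5 * (y - y.mean())  # scales with the signal, keeps SST > 0
        x = y + resid
        fit = invert_spectrum(pixel_dft(average_endpoint_frames(y.reshape(10, 1, 1)).reshape(9)))
        ssr = np.sum((x - y) ** 2)
        sst = np.sum((x - x.mean()) ** 2)
        assert ssr / sst == pytest.approx(0.25 / 2.25, abs=1e-12)
        assert compute_r2(x, fit) == pytest.approx(1 - ssr / sst, abs=1e-9)

    def test_r2_nan_for_flat_series(self):
        series10 = np.full(10, 5.0)
        fit = invert_spectrum(pixel_dft(series10[:9]))
        assert np.isnan(compute_r2(series10, fit))

    def test_err_zero_for_clean_model(self):
        series = model_series(CollagenParams(1.0, 1.0, 2.0, 30.0))
        assert compute_err(pixel_dft(series)) < 1e-9

    def test_err_one_for_balanced_spectrum(self):
        # chat3 = chat4 = mean(chat0, chat1, chat2) = 1 gives ERR exactly 1
        n = np.arange(9)
        series = (3.0 + 1.0 * np.cos(2 * np.pi * 3 * n / 9)
                  + 1.0 * np.cos(2 * np.pi * 4 * n / 9))
        spec = pixel_dft(series)
        assert spec.chat[0] == pytest.approx(3.0, abs=1e-9)
        assert spec.chat[3] == pytest.approx(1.0, abs=1e-9)
        assert spec.chat[4] == pytest.approx(1.0, abs=1e-9)
        assert compute_err(spec) == pytest.approx(1.0, abs=1e-9)

    def test_snr_cap_for_clean_model(self):
        series = model_series(CollagenParams(1.0, 1.0, 2.0, 30.0))
        assert compute_snr(pixel_dft(series)) == SNR_CAP_DB

    def test_snr_log_identity(self):
        n = np.arange(9)
        # equal amplitude in bins 1..4: conjugate symmetry doubles the noise sum
        series = sum(np.cos(2 * np.pi * k * n / 9) for k in range(1, 5))
        snr = compute_snr(pixel_dft(np.asarray(series)))
        assert snr == pytest.approx(10 * np.log10(2 / 4), abs=1e-9)

    def test_snr_nan_for_flat(self):
        assert np.isnan(compute_snr(pixel_dft(np.full(9, 2.0))))


class TestFitStack:
    def test_recovers_ground_truth_maps(self):
        combos = [(b, c, phi) for b in (0.6, 1.0) for c in (1.6, 2.4) for phi in (20, 110)]
        spec = region_grid_spec(combos, tile=4, width_tiles=4)
        stack = generate_stack(spec)
        maps = fit_stack(stack)
        gt = spec.ground_truth()
        assert set(maps.maps) == set(MAP_KEYS)
        on = np.isfinite(gt["FI"])
        for key in ("CHI3115", "CHI3315", "CHI3331", "THETA"):
            assert np.nanmax(np.abs(maps[key][on] - gt[key][on])) < 1e-6
        dphi = np.abs(maps["FI"][on] - gt["FI"][on]) % 180
        assert np.max(np.minimum(dphi, 180 - dphi)) < 1e-6

    def test_background_only_stack(self):
        stack = np.full((10, 4, 4), 3.0)
        maps = fit_stack(stack)
        for key in ("CHI3115", "CHI3315", "CHI3331", "FI", "THETA", "R2", "SNR"):
            assert np.all(np.isnan(maps[key]))
        assert np.allclose(maps["ERR"], 0.0)  # flat series: all AC bins empty

    def test_scale_invariance(self):
        combos = [(1.0, 2.0, 30.0), (0.8, 1.7, 140.0)]
        spec = region_grid_spec(combos, tile=4, width_tiles=2)
        stack = generate_stack(spec)
        m1, m2 = fit_stack(stack), fit_stack(3.7 * stack)
        for key in ("CHI3115", "CHI3315", "CHI3331", "FI", "THETA", "R2", "ERR", "SNR"):
            a, b = m1[key], m2[key]
            both = np.isfinite(a) & np.isfinite(b)
            assert np.array_equal(np.isfinite(a), np.isfinite(b))
            assert np.allclose(a[both], b[both], atol=1e-6)

    def test_rotation_equivariance(self):
        delta = 25.0
        base = [(1.0, 2.0, 30.0)]
        shifted = [(1.0, 2.0, 30.0 + delta)]
        m1 = fit_stack(generate_stack(region_grid_spec(base, tile=4, width_tiles=1)))
        m2 = fit_stack(generate_stack(region_grid_spec(shifted, tile=4, width_tiles=1)))
        dphi = (m2["FI"] - m1["FI"]) % 180
        assert np.allclose(dphi, delta, atol=1e-9)
        for key in ("CHI3115", "CHI3315", "CHI3331", "THETA"):
            assert np.allclose(m1[key], m2[key], atol=1e-9)

    def test_noise_degrades_r2_and_snr(self):
        combos = [(1.0, 2.0, 30.0), (0.8, 1.7, 140.0)]
        mean_r2, mean_snr = [], []
        for sigma in (0, 2, 8, 32):
            spec = region_grid_spec(
                combos, tile=8, width_tiles=2, i0=100.0 / 4.0,
                noise_model="gaussian" if sigma else "none",
                noise_sigma=float(sigma), seed=5,
            )
            maps = fit_stack(generate_stack(spec))
            mean_r2.append(np.nanmean(maps["R2"]))
            mean_snr.append(np.nanmean(maps["SNR"]))
        assert np.all(np.diff(mean_r2) < 0)
        assert np.all(np.diff(mean_snr) < 0)

    def test_chi3331_consistency(self):
        combos = [(0.7, 2.1, 45.0), (1.2, 1.9, 160.0)]
        maps = fit_stack(generate_stack(region_grid_spec(combos, tile=4, width_tiles=2)))
        fin = np.isfinite(maps["CHI3331"])
        assert np.allclose(
            maps["CHI3331"][fin], maps["CHI3315"][fin] / maps["CHI3115"][fin], rtol=1e-6
        )

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            fit_stack(np.zeros((9, 4, 4)))
        with pytest.raises(ValueError):
            fit_stack(np.zeros((10, 4)))
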