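"""Preprocessing: each step against an independent oracle, plus pipeline
composition and ordering properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanembryo.datatypes import RamanSpectrum
from ramanembryo.preprocess import (MAD_SCALE, PreprocessConfig, area_normalize,
                                    asls_baseline, despike, preprocess_pipeline,
                                    qc_filter, sg_smooth, spectrum_snr,
                                    truncate_resample)
from ramanembryo.synth import BaselineConfig, GeneratorConfig, default_peak_templates, generate_dataset

from conftest import small_generator_config


def make_spectrum(y, start=300.0, step=1.0):
    y = np.asarray(y, dtype=float)
    return RamanSpectrum(start + step * np.arange(len(y)), y)


# ------------------------------------------------------------------ despike

class TestDespike:
    def test_single_spike_replaced_others_untouched(self):
        y = np.full(200, 10.0)
        y[77] = 10_000.0
        out = despike(make_spectrum(y), filter_size=4, dynamic_factor=6)
        assert out.intensities[77] == 10.0
        mask = np.ones(200, bool)
        mask[77] = False
        assert np.array_equal(out.intensities[mask], y[mask])

    def test_smooth_peak_untouched_by_bruteforce_threshold(self, rng):
        """Oracle: re-derive the spike decision per point with explicit
        python loops; a clean Gaussian peak must trip it nowhere."""
        # realistic scale: peak-to-noise ~100 (a 9-point median window cannot
        # tell a sharp apex from a spike at arbitrarily high SNR)
        grid = np.arange(300.0, 800.0)
        y = 5 * np.exp(-0.5 * ((grid - 550) / 8) ** 2) + 0.05 * rng.standard_normal(len(grid))
        fs, df = 4, 6.0
        med = np.array([np.median(y[max(0, i - fs):i + fs + 1]) for i in range(len(y))])
        dev = np.abs(y - med)
        local = MAD_SCALE * np.array(
            [np.median(dev[max(0, i - fs):i + fs + 1]) for i in range(len(y))])
        scale = np.maximum(local, MAD_SCALE * np.median(dev))
        assert not np.any(dev > df * scale)  # oracle agrees nothing is a spike
        out = despike(RamanSpectrum(grid, y), fs, df)
        assert np.array_equal(out.intensities, y)

    def test_injected_spikes_removed_vs_spikefree_truth(self):
        """Generated data with spikes, despiked, lands within the noise
        floor of the same seed's spike-free realization."""
        # 1 cm^-1 sampling: on coarser grids the narrow peaks themselves
        # become spike-like for a +/-4-point window
        t = default_peak_templates()
        cfg_s = small_generator_config(seed=21, spike_rate=2.0,
                                       grid=(300.0, 2800.0, 1.0))
        cfg_c = small_generator_config(seed=21, spike_rate=0.0,
                                       grid=(300.0, 2800.0, 1.0))
        spiked = generate_dataset(cfg_s, t)[0].spectra
        clean = generate_dataset(cfg_c, t)[0].spectra
        for ss, sc in zip(spiked, clean):
            if np.array_equal(ss.intensities, sc.intensities):
                continue
            out = despike(ss, 4, 6.0)
            rms = np.sqrt(np.mean((out.intensities - sc.intensities) ** 2))
            assert rms < cfg_s.noise_sd

    def test_idempotent(self):
        t = default_peak_templates()
        ds = generate_dataset(small_generator_config(
            seed=9, spike_rate=1.0, grid=(300.0, 2800.0, 1.0)), t)
        for s in ds[0].spectra[:5]:
            once = despike(s, 4, 6.0)
            twice = despike(once, 4, 6.0)
            assert np.array_equal(once.intensities, twice.intensities)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            despike(make_spectrum(np.ones(5)), filter_size=4)


# ------------------------------------------------------- truncate/resample

class TestTruncateResample:
    def test_default_grid_has_3101_points(self):
        s = make_spectrum(np.ones(3201), start=250.0)
        out = truncate_resample(s, (300.0, 3400.0), 1.0)
        assert len(out) == 3101
        assert out.wavenumbers[0] == 300.0 and out.wavenumbers[-1] == 3400.0

    def test_identity_on_target_grid(self, rng):
        y = rng.random(3101)
        s = make_spectrum(y, start=300.0)
        out = truncate_resample(s, (300.0, 3400.0), 1.0)
        assert np.allclose(out.intensities, y)

    def test_linear_ramp_exact_on_coarse_input(self):
        wn = np.arange(300.0, 3402.0, 2.0)
        s = RamanSpectrum(wn, 0.5 * wn + 7.0)
        out = truncate_resample(s, (300.0, 3400.0), 1.0)
        assert np.allclose(out.intensities, 0.5 * out.wavenumbers + 7.0)

    def test_uncovered_end_reported(self):
        s = make_spectrum(np.ones(1000), start=500.0)
        with pytest.raises(ValueError, match="low end"):
            truncate_resample(s, (300.0, 1000.0), 1.0)
        with pytest.raises(ValueError, match="high end"):
            truncate_resample(s, (600.0, 3400.0), 1.0)


# ------------------------------------------------------------ AsLS baseline

class TestAsls:
    def test_line_input_fully_absorbed(self):
        wn = np.arange(300.0, 1300.0)
        y = 0.01 * wn + 3.0
        base, corr = asls_baseline(RamanSpectrum(wn, y), lam=1e5, p=0.01)
        assert np.max(np.abs(corr.intensities)) < 1e-6 * np.max(np.abs(y))

    def test_recovers_known_line_under_gaussian_peak(self):
        wn = np.arange(300.0, 1300.0)
        truth = 0.005 * wn + 2.0
        y = truth + 4.0 * np.exp(-0.5 * ((wn - 800) / 15) ** 2)
        base, _ = asls_baseline(RamanSpectrum(wn, y), lam=1e5, p=0.01)
        off_peak = np.abs(wn - 800) > 100
        rel = np.abs(base[off_peak] - truth[off_peak]) / truth[off_peak]
        assert np.max(rel) < 0.02

    def test_p_half_equals_fixed_weight_dense_oracle(self, rng):
        """At p=0.5 the weights are constant, so one penalized weighted
        least-squares solve (dense, built independently) is the answer."""
        n = 300
        wn = np.arange(300.0, 300.0 + n)
        y = rng.standard_normal(n)
        lam = 1e4
        base, _ = asls_baseline(RamanSpectrum(wn, y), lam=lam, p=0.5, iters=10)
        D = np.diff(np.eye(n), 2, axis=0)
        A = 0.5 * np.eye(n) + lam * D.T @ D
        oracle = np.linalg.solve(A, 0.5 * y)
        assert np.allclose(base, oracle, atol=1e-8)

    def test_invalid_parameters(self):
        s = make_spectrum(np.ones(100))
        with pytest.raises(ValueError):
            asls_baseline(s, lam=-1)
        with pytest.raises(ValueError):
            asls_baseline(s, p=1.5)


# ---------------------------------------------------------------- smoothing

class TestSavitzkyGolay:
    def test_exact_on_cubic(self):
        wn = np.arange(300.0, 800.0)
        x = (wn - 550) / 100
        y = 1 + 2 * x - 0.5 * x ** 2 + 0.1 * x ** 3
        out = sg_smooth(RamanSpectrum(wn, y), window=11, order=3)
        assert np.allclose(out.intensities, y, atol=1e-10)

    def test_reduces_white_noise_variance(self, rng):
        y = rng.standard_normal(2000)
        out = sg_smooth(make_spectrum(y), 11, 3)
        assert np.var(out.intensities) < np.var(y)

    def test_impulse_response_is_kernel(self):
        from scipy.signal import savgol_coeffs
        y = np.zeros(101)
        y[50] = 1.0
        out = sg_smooth(make_spectrum(y), 11, 3)
        kernel = savgol_coeffs(11, 3)
        assert np.allclose(out.intensities[45:56], kernel[::-1])

    def test_even_window_suggests_odd(self):
        with pytest.raises(ValueError, match="11"):
            sg_smooth(make_spectrum(np.ones(50)), window=10, order=3)


# ------------------------------------------------------------ normalization

class TestAreaNormalize:
    def test_worked_example(self):
        out = area_normalize(make_spectrum([2.0, 2.0, 4.0]), 100.0)
        assert np.allclose(out.intensities, [25.0, 25.0, 50.0])

    def test_already_normalized_unchanged(self):
        y = np.array([30.0, 30.0, 40.0])
        out = area_normalize(make_spectrum(y), 100.0)
        assert np.allclose(out.intensities, y)

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            area_normalize(make_spectrum([0.0, 0.0, 0.0]), 100.0)

    @given(st.lists(st.floats(0.01, 1e6), min_size=3, max_size=50),
           st.floats(0.1, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariant_and_idempotent(self, values, scale):
        s = make_spectrum(values)
        once = area_normalize(s, 100.0)
        assert abs(once.intensities.sum() - 100.0) < 1e-9
        scaled = area_normalize(make_spectrum(np.asarray(values) * scale), 100.0)
        assert np.allclose(once.intensities, scaled.intensities, rtol=1e-9)
        assert np.allclose(area_normalize(once, 100.0).intensities,
                           once.intensities, rtol=1e-12)


# --------------------------------------------------------------------- QC

class TestQc:
    def test_pure_noise_excluded_at_snr_3(self, rng):
        wn = np.arange(300.0, 2801.0)
        noise = RamanSpectrum(wn, 1.0 + 0.05 * rng.standard_normal(len(wn)))
        kept, excluded = qc_filter([noise], snr_min=3.0)
        assert kept == [] and len(excluded) == 1
        assert "low_snr" in excluded[0][1]

    def test_clean_generated_spectrum_kept(self):
        ds = generate_dataset(small_generator_config(seed=2, spike_rate=0.0),
                              default_peak_templates())
        s = ds[0].spectra[0]
        cfg = PreprocessConfig(range=(300, 2800), step=4.0)
        assert spectrum_snr(s, cfg) > 3.0
        kept, excluded = qc_filter([s], snr_min=3.0, config=cfg)
        assert len(kept) == 1 and excluded == []

    def test_zero_threshold_keeps_everything(self, rng):
        wn = np.arange(300.0, 2801.0)
        spectra = [RamanSpectrum(wn, 1 + 0.05 * rng.standard_normal(len(wn)))
                   for _ in range(3)]
        kept, excluded = qc_filter(spectra, snr_min=0.0)
        assert len(kept) == 3 and excluded == []

    def test_missing_silent_region_excluded_with_reason(self):
        s = make_spectrum(np.ones(500), start=300.0)  # ends at 799
        kept, excluded = qc_filter([s], snr_min=3.0)
        assert kept == []
        assert "uncovered_region" in excluded[0][1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qc_filter([], 3.0)


# ---------------------------------------------------------------- pipeline

class TestPipeline:
    def test_composition_contracts(self, ml_data):
        """Every preprocessed spectrum sits on the coarse grid with total
        intensity exactly 100 (composition of the per-step contracts)."""
        n_expected = int((2800 - 300) / 4.0) + 1
        for rec in ml_data["samples"]:
            for s in rec.spectra:
                assert len(s) == n_expected
                assert abs(s.intensities.sum() - 100.0) < 1e-9

    def test_empty_input(self):
        out, report = preprocess_pipeline([], PreprocessConfig())
        assert out == [] and report["output"] == 0

    def test_unreachable_snr_excludes_all(self):
        ds = generate_dataset(small_generator_config(seed=4),
                              default_peak_templates())
        cfg = PreprocessConfig(range=(300, 2800), step=4.0, snr_min=1e9)
        out, report = preprocess_pipeline(ds[0].spectra, cfg)
        assert out == []
        assert len(report["qc_excluded"]) == len(ds[0].spectra)

    def test_normalize_before_baseline_changes_result(self):
        """Regression guard on step order: normalizing before baseline
        removal is not equivalent to the specified order."""
        ds = generate_dataset(small_generator_config(seed=6, spike_rate=0.0),
                              default_peak_templates())
        s = ds[0].spectra[0]
        cfg = PreprocessConfig(range=(300, 2800), step=4.0)
        correct, _ = preprocess_pipeline([s], cfg)
        # permuted order: normalize the raw spectrum first
        permuted = area_normalize(s, cfg.norm_total)
        permuted = despike(permuted, cfg.spike_filter_size, cfg.spike_dynamic_factor)
        permuted = truncate_resample(permuted, cfg.range, cfg.step)
        _, permuted = asls_baseline(permuted, cfg.asls_lambda, cfg.asls_p,
                                    cfg.asls_iters)
        permuted = sg_smooth(permuted, cfg.sg_window, cfg.sg_order)
        assert not np.allclose(correct[0].intensities, permuted.intensities)

    def test_peak_positions_survive_pipeline(self):
        """On spike- and baseline-free input the pipeline moves no peak
        argmax by more than one grid point."""
        templates = default_peak_templates()
        cfg = GeneratorConfig(
            group_sizes=(2, 2, 2), spectra_per_sample=(2, 2), seed=8,
            baseline=BaselineConfig(poly=(0, 0, 0), hump_amplitude=0.0),
            spike_rate=0.0, noise_sd=0.005)
        ds = generate_dataset(cfg, templates)
        out, _ = preprocess_pipeline(ds[0].spectra, PreprocessConfig())
        for s in out:
            for t in templates:
                w = np.abs(s.wavenumbers - t.position) <= 6
                local = s.wavenumbers[w][np.argmax(s.intensities[w])]
                assert abs(local - t.position) <= 1.0
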