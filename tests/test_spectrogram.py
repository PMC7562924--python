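"""Spectrogram builder: PSD estimation, baseline, D(omega,t), DQ, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biodyn as bd
from biodyn.spectrogram import FluctuationSpectrumSeries, cohort_activity_threshold


def _series(grid, spectra):
    return FluctuationSpectrumSeries(grid=grid, spectra=spectra)


class TestPowerSpectrum:
    def test_sinusoid_mass_in_correct_bin(self, grid):
        fs, n = 25.0, 4096
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        psd = bd.power_spectrum(x, fs, grid)
        edges = np.sqrt(grid.frequencies[:-1] * grid.frequencies[1:])
        widths = np.diff(np.concatenate([[grid.frequencies[0] ** 2 / edges[0]],
                                         edges,
                                         [grid.frequencies[-1] ** 2 / edges[-1]]]))
        power = psd * widths
        peak = int(np.argmax(power))
        lo = edges[peak - 1] if peak > 0 else 0.0
        hi = edges[peak] if peak < edges.size else np.inf
        assert lo <= 1.0 <= hi
        assert power[peak] / power.sum() > 0.9

    def test_white_noise_parseval(self, grid, rng):
        x = rng.normal(size=2**15)
        v = x.var()
        psd = bd.power_spectrum(x, 25.0, grid)
        edges = np.sqrt(grid.frequencies[:-1] * grid.frequencies[1:])
        widths = np.diff(np.concatenate([[0.0], edges, [12.5]]))
        total = float(np.sum(psd * widths))
        assert total == pytest.approx(v, rel=0.1)

    def test_quadratic_scaling(self, grid, rng):
        x = rng.normal(size=4096)
        x -= x.mean()
        p1 = bd.power_spectrum(x, 25.0, grid)
        p3 = bd.power_spectrum(3.0 * x, 25.0, grid)
        assert np.allclose(p3, 9.0 * p1, rtol=1e-10)

    def test_too_short_series_rejected(self, grid):
        with pytest.raises(ValueError):
            bd.power_spectrum(np.array([1.0]), 25.0, grid)


class TestBaselineAverage:
    def test_identical_loops_idempotent(self, noiseless_params, grid):
        s = bd.baseline_doppler_spectrum(noiseless_params, grid)
        series = _series(grid, np.tile(s, (grid.n_loops, 1)))
        assert np.allclose(bd.baseline_average(series), s)

    def test_geometric_mean_identity(self, noiseless_params, grid):
        s = bd.baseline_doppler_spectrum(noiseless_params, grid)
        spectra = np.tile(s, (grid.n_loops, 1))
        spectra[0] *= 100.0
        spectra[2] *= 100.0  # two loops at 100 S, two at S -> geometric mean 10 S
        series = _series(grid, spectra)
        assert np.allclose(bd.baseline_average(series), 10.0 * s, rtol=1e-12)

    def test_requires_four_predose_loops(self, noiseless_params):
        freqs = np.geomspace(0.01, 12.5, 20)
        times = np.arange(6) * 82.0 / 60.0
        grid3 = bd.TimeFrequencyGrid(frequencies=freqs, loop_times=times, dose_loop=3)
        series = _series(grid3, np.ones((6, 20)))
        with pytest.raises(ValueError):
            bd.baseline_average(series)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_log_average_equals_direct_geometric_mean(self, seed):
        grid = bd.TimeFrequencyGrid.default(n_frequencies=8)
        r = np.random.default_rng(seed)
        spectra = 10.0 ** r.uniform(-2, 3, size=(grid.n_loops, 8))
        series = _series(grid, spectra)
        pre = spectra[grid.dose_loop - 4: grid.dose_loop]
        direct = np.prod(pre, axis=0) ** 0.25
        assert np.allclose(bd.baseline_average(series), direct, rtol=1e-10)


class TestDrugResponseSpectrogram:
    def test_identity_case_zero(self, noiseless_params, grid):
        s = bd.baseline_doppler_spectrum(noiseless_params, grid)
        series = _series(grid, np.tile(s, (grid.n_loops, 1)))
        spgm = bd.drug_response_spectrogram(series)
        assert np.allclose(spgm.D, 0.0)

    def test_log10_convention(self, noiseless_params, grid):
        s = bd.baseline_doppler_spectrum(noiseless_params, grid)
        spectra = np.tile(s, (grid.n_loops, 1))
        spectra[grid.dose_loop:] *= 10.0
        spgm = bd.drug_response_spectrogram(_series(grid, spectra))
        assert np.allclose(spgm.D, 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 1e6))
    def test_gauge_invariance(self, scale):
        """D is unchanged when all of a well's spectra scale by c > 0."""
        grid = bd.TimeFrequencyGrid.default(n_frequencies=10)
        r = np.random.default_rng(0)
        spectra = 10.0 ** r.uniform(-1, 2, size=(grid.n_loops, 10))
        d1 = bd.drug_response_spectrogram(_series(grid, spectra)).D
        d2 = bd.drug_response_spectrogram(_series(grid, scale * spectra)).D
        assert np.allclose(d1, d2, atol=1e-9)


class TestDataQuality:
    def _clean_well(self, noiseless_params, grid):
        return bd.simulate_well(noiseless_params, grid, "sensitive", "control",
                                np.random.default_rng(0), inject_violations=False)

    def test_no_violations_unity(self, noiseless_params, grid):
        well = self._clean_well(noiseless_params, grid)
        assert bd.assess_data_quality(well, grid) == 1.0

    def test_brightness_jump_halves(self, noiseless_params, grid):
        well = self._clean_well(noiseless_params, grid)
        well.brightness[6:] *= 2.0
        assert bd.assess_data_quality(well, grid) == 0.5

    def test_two_violations_quarter(self, noiseless_params, grid):
        well = self._clean_well(noiseless_params, grid)
        well.brightness[6:] *= 2.0
        well.violations = ["debris"]
        assert bd.assess_data_quality(well, grid) == 0.25

    def test_three_violations_eighth(self, noiseless_params, grid):
        well = self._clean_well(noiseless_params, grid)
        well.violations = ["debris", "stage_drift", "meniscus"]
        assert bd.assess_data_quality(well, grid) == 0.125

    def test_low_activity_detected(self, noiseless_params, grid):
        active = [self._clean_well(noiseless_params, grid) for _ in range(5)]
        quiet = bd.simulate_well(
            bd.PhenotypeParams(amplitude=0.05, sigma_log=0, patient_sigma=0,
                               violation_prob=0),
            grid, "sensitive", "control", np.random.default_rng(1),
            inject_violations=False)
        thr = bd.DQThresholds(
            min_band_power=cohort_activity_threshold(active, grid))
        assert bd.assess_data_quality(quiet, grid, thr) == 0.5
        assert bd.assess_data_quality(active[0], grid, thr) == 1.0


class TestWeightedAverage:
    def _spgms(self, grid, values, treatment="carboplatin"):
        return [bd.DrugResponseSpectrogram(
            grid=grid, D=np.full((grid.n_post_loops, grid.n_frequencies), v),
            treatment=treatment) for v in values]

    def test_equal_dq_is_arithmetic_mean(self, grid):
        spgms = self._spgms(grid, [1.0, 2.0, 3.0])
        avg = bd.weighted_average_spectrograms(spgms, [0.5, 0.5, 0.5])
        assert np.allclose(avg.D, 2.0)
        assert avg.dq == pytest.approx(0.5)

    def test_vanishing_weight_limit(self, grid):
        spgms = self._spgms(grid, [1.0, 100.0])
        avg = bd.weighted_average_spectrograms(spgms, [1.0, 1e-12])
        assert np.allclose(avg.D, 1.0, atol=1e-9)

    def test_single_spectrogram_unchanged(self, grid):
        spgm = self._spgms(grid, [7.0])[0]
        avg = bd.weighted_average_spectrograms([spgm], [0.25])
        assert np.array_equal(avg.D, spgm.D)

    def test_all_zero_dq_rejected(self, grid):
        with pytest.raises(ValueError):
            bd.weighted_average_spectrograms(self._spgms(grid, [1.0]), [0.0])

    def test_mixed_treatments_rejected(self, grid):
        spgms = (self._spgms(grid, [1.0], "carboplatin")
                 + self._spgms(grid, [2.0], "paclitaxel"))
        with pytest.raises(ValueError):
            bd.weighted_average_spectrograms(spgms, [1.0, 1.0])


class TestSubtractControl:
    def test_self_subtraction_zero(self, grid, rng):
        D = rng.normal(size=(grid.n_post_loops, grid.n_frequencies))
        spgm = bd.DrugResponseSpectrogram(grid=grid, D=D, treatment="carboplatin")
        ctrl = bd.DrugResponseSpectrogram(grid=grid, D=D.copy(), treatment="control")
        assert np.allclose(bd.subtract_control(spgm, ctrl).D, 0.0)

    def test_subtract_then_add_back(self, grid, rng):
        D = rng.normal(size=(grid.n_post_loops, grid.n_frequencies))
        C = rng.normal(size=D.shape)
        spgm = bd.DrugResponseSpectrogram(grid=grid, D=D, treatment="paclitaxel")
        ctrl = bd.DrugResponseSpectrogram(grid=grid, D=C, treatment="control")
        sub = bd.subtract_control(spgm, ctrl)
        assert np.allclose(sub.D + C, D)
        assert sub.treatment == "paclitaxel"

    def test_missing_control_policy(self, grid, rng):
        D = rng.normal(size=(grid.n_post_loops, grid.n_frequencies))
        spgm = bd.DrugResponseSpectrogram(grid=grid, D=D, treatment="combination")
        with pytest.raises(ValueError):
            bd.subtract_control(spgm, None)
        with pytest.warns(UserWarning):
            out = bd.subtract_control(spgm, None, missing="pass")
        assert out is spgm
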