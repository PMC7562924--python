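"""Filter masks, projections, preconditions, feature assembly, Doppler."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biodyn as bd
from biodyn.biomarkers import PRECONDITION_NAMES


class TestGlobalMasks:
    def test_count_is_nine(self, grid):
        assert len(bd.build_global_masks(grid)) == 9

    def test_order_zero_mask_constant(self, grid):
        mask = bd.build_global_masks(grid)[0]
        assert mask.time_order == 0 and mask.freq_order == 0
        assert np.allclose(mask.weights, mask.weights.flat[0])

    def test_gram_matrix_identity(self, grid):
        masks = bd.build_global_masks(grid)
        G = np.array([[np.sum(a.weights * b.weights) for b in masks] for a in masks])
        assert np.abs(G - np.eye(9)).max() < 1e-6

    def test_degenerate_grid_rejected(self):
        freqs = np.geomspace(0.01, 12.5, 2)
        times = np.arange(13) * 82 / 60
        narrow = bd.TimeFrequencyGrid(frequencies=freqs, loop_times=times)
        with pytest.raises(ValueError):
            bd.build_global_masks(narrow)


class TestLocalMasks:
    def test_count_is_nine(self, grid):
        assert len(bd.build_local_masks(grid)) == 9

    def test_cross_band_orthogonality(self, grid):
        masks = bd.build_local_masks(grid)
        for a in masks:
            for b in masks:
                if a.band != b.band:
                    assert np.sum(a.weights * b.weights) == 0.0

    def test_order_one_time_mask_zero_column_sum(self, grid):
        mask = next(m for m in bd.build_local_masks(grid)
                    if m.band == "mid" and m.time_order == 1)
        col_sums = mask.weights.sum(axis=0)
        assert np.allclose(col_sums, 0.0, atol=1e-12)

    def test_overlapping_bands_rejected(self, grid):
        with pytest.raises(ValueError):
            bd.build_local_masks(grid, band_edges=(0.01, 1.0, 0.1, 10.0))


class TestProjection:
    def test_zero_spectrogram_zero_features(self, grid):
        masks = bd.spectrogram_masks(grid)
        D = np.zeros((grid.n_post_loops, grid.n_frequencies))
        assert np.allclose(bd.project(D, masks), 0.0)

    def test_constant_spectrogram_only_order_zero(self, grid):
        masks = bd.spectrogram_masks(grid)
        D = np.full((grid.n_post_loops, grid.n_frequencies), 3.0)
        feats = bd.project(D, masks)
        for mask, value in zip(masks, feats):
            order = mask.time_order + (mask.freq_order or 0)
            if order == 0:
                assert abs(value) > 1.0  # constant captured by order-0 masks
            else:
                assert abs(value) < 1e-9

    def test_time_ramp_against_bruteforce_sum(self, grid):
        """Linear-in-time ramp: global (t1, f0) feature equals the explicit
        double sum of mask x spectrogram."""
        masks = bd.build_global_masks(grid)
        t = np.linspace(-1, 1, grid.n_post_loops)
        D = 2.5 * np.tile(t[:, None], (1, grid.n_frequencies))
        feats = bd.project(D, masks)
        m10 = next(i for i, m in enumerate(masks)
                   if m.time_order == 1 and m.freq_order == 0)
        brute = sum(masks[m10].weights[i, j] * D[i, j]
                    for i in range(grid.n_post_loops)
                    for j in range(grid.n_frequencies))
        assert feats[m10] == pytest.approx(brute, rel=1e-12)
        assert abs(feats[m10]) > 0.1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5), st.integers(0, 2**31 - 1))
    def test_linearity(self, a, b, seed):
        grid = bd.TimeFrequencyGrid.default(n_frequencies=12)
        masks = bd.spectrogram_masks(grid)
        r = np.random.default_rng(seed)
        D1 = r.normal(size=(grid.n_post_loops, 12))
        D2 = r.normal(size=(grid.n_post_loops, 12))
        lhs = bd.project(a * D1 + b * D2, masks)
        rhs = a * bd.project(D1, masks) + b * bd.project(D2, masks)
        assert np.allclose(lhs, rhs, atol=1e-8)


class TestPreconditions:
    def test_noiseless_recovery_within_5pct(self, grid):
        p = bd.PhenotypeParams(amplitude=100.0, knee_hz=0.3, rolloff=1.6,
                               nyquist_floor=1.0, sigma_log=0, patient_sigma=0)
        pre = bd.fit_preconditions(bd.baseline_doppler_spectrum(p, grid), grid)
        assert pre.knee == pytest.approx(0.3, rel=0.05)
        assert pre.s == pytest.approx(1.6, rel=0.05)
        assert pre.knee_converged and pre.s_converged

    def test_half_width_equals_knee_on_model(self, grid):
        p = bd.PhenotypeParams(sigma_log=0, patient_sigma=0)
        pre = bd.fit_preconditions(bd.baseline_doppler_spectrum(p, grid), grid)
        assert pre.hw == pytest.approx(p.knee_hz, rel=0.02)

    def test_dynamic_range_log10(self, grid):
        p = bd.PhenotypeParams(amplitude=99.0, nyquist_floor=1.0,
                               sigma_log=0, patient_sigma=0)
        pre = bd.fit_preconditions(bd.baseline_doppler_spectrum(p, grid), grid)
        assert pre.dr == pytest.approx(2.0, abs=0.02)

    def test_recovery_median_error_below_1pct(self, grid):
        """Over 100 noiseless random parameter draws the median relative
        error of KNEE and S stays below 1%."""
        r = np.random.default_rng(2024)
        errs_k, errs_s = [], []
        for _ in range(100):
            p = bd.PhenotypeParams(
                amplitude=10 ** r.uniform(1, 3),
                knee_hz=10 ** r.uniform(math.log10(0.05), math.log10(2.0)),
                rolloff=r.uniform(0.8, 3.0),
                nyquist_floor=10 ** r.uniform(-0.5, 0.5),
                sigma_log=0, patient_sigma=0)
            pre = bd.fit_preconditions(bd.baseline_doppler_spectrum(p, grid), grid)
            errs_k.append(abs(pre.knee - p.knee_hz) / p.knee_hz)
            errs_s.append(abs(pre.s - p.rolloff) / p.rolloff)
        assert np.median(errs_k) < 0.01
        assert np.median(errs_s) < 0.01


class TestPreconditionDeltas:
    def _pre(self, **kw):
        base = dict(nsd=0.45, bsb=2000.0, ncnt=1200, dr=2.0, ny=1.0,
                    knee=0.3, hw=0.3, s=1.6, sf=-1.5)
        base.update(kw)
        return bd.PreconditionSet(**base)

    def test_identity_all_zero(self):
        deltas, imputed = bd.precondition_deltas(self._pre(), self._pre())
        assert np.allclose(deltas, 0.0)
        assert imputed == []

    def test_knee_halving_log_ratio(self):
        deltas, _ = bd.precondition_deltas(self._pre(), self._pre(knee=0.15))
        i = PRECONDITION_NAMES.index("KNEE")
        assert deltas[i] == pytest.approx(math.log10(0.5), abs=1e-12)

    def test_slope_arithmetic_difference(self):
        deltas, _ = bd.precondition_deltas(self._pre(s=1.6), self._pre(s=2.1))
        i = PRECONDITION_NAMES.index("S")
        assert deltas[i] == pytest.approx(0.5)

    def test_unfit_knee_imputed_zero_with_flag(self):
        deltas, imputed = bd.precondition_deltas(
            self._pre(knee=math.nan), self._pre())
        i = PRECONDITION_NAMES.index("KNEE")
        assert deltas[i] == 0.0
        assert "KNEE" in imputed


class TestAssembleFeatureVector:
    def test_three_blocks_make_81(self):
        blocks = {t: np.arange(27, dtype=float)
                  for t in ("carboplatin", "paclitaxel", "combination")}
        fv = bd.assemble_feature_vector(blocks, "pt00", -1)
        assert fv.n_features == 81
        assert len(bd.feature_names()) == 81

    def test_block_order_fixed_regardless_of_dict_order(self):
        blocks = {"combination": np.full(27, 3.0),
                  "carboplatin": np.full(27, 1.0),
                  "paclitaxel": np.full(27, 2.0)}
        fv = bd.assemble_feature_vector(blocks, "pt00", 1)
        assert np.allclose(fv.values[:27], 1.0)
        assert np.allclose(fv.values[27:54], 2.0)
        assert np.allclose(fv.values[54:], 3.0)

    def test_missing_or_mislabeled_block_rejected(self):
        blocks = {t: np.zeros(27) for t in ("carboplatin", "paclitaxel")}
        with pytest.raises(ValueError):
            bd.assemble_feature_vector(blocks, "pt00", 1)
        blocks["taxol"] = np.zeros(27)
        with pytest.raises(ValueError):
            bd.assemble_feature_vector(blocks, "pt00", 1)


class TestDoppler:
    def test_one_micron_per_second_is_3hz(self):
        f = bd.doppler_shift(1e-6)
        assert round(f, 0) == 3.0
        assert f == pytest.approx(2 * 1.33 * 1e-6 / 840e-9, rel=1e-12)

    def test_zero_speed_zero_shift(self):
        assert bd.doppler_shift(0.0) == 0.0

    def test_nyquist_speed_rounds_to_4um_s(self):
        v = bd.doppler_speed(12.5)
        assert round(v * 1e6) == 4.0

    def test_roundtrip_identity(self):
        for v in (1e-9, 3.1e-7, 1e-6, 4.2e-6):
            assert bd.doppler_speed(bd.doppler_shift(v)) == pytest.approx(v, rel=1e-14)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            bd.doppler_shift(-1e-6)
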