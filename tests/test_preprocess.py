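"""Preprocessing chain: Savitzky-Golay, airPLS baseline removal, min-max scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramandx import (
    PreprocessConfig,
    airpls,
    generate_dataset,
    make_axis,
    minmax_scale,
    preprocess_set,
    savitzky_golay,
)
from ramandx.errors import ConfigError, DataError, NumericalError
from ramandx.synth import baseline_curve, lorentzian
from ramandx.types import SpectrumSet

from conftest import small_generator_config


class TestSavitzkyGolay:
    @pytest.mark.parametrize("degree", [0, 1, 2, 3])
    def test_exact_on_polynomials_up_to_fit_order(self, degree):
        x = np.linspace(0, 1, 200)
        y = np.polynomial.polynomial.polyval(x, np.arange(1.0, degree + 2))
        out = savitzky_golay(y, window=11, order=3)
        assert np.allclose(out[5:-5], y[5:-5], atol=1e-9)

    def test_constant_preserved(self):
        assert np.allclose(savitzky_golay(np.full(50, 3.7), 11, 3), 3.7)

    def test_white_noise_variance_reduced(self):
        """Monte-Carlo: smoothing must shrink white-noise variance in every draw."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = rng.normal(size=300)
            assert savitzky_golay(y, 11, 3).var() < y.var()

    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        y1, y2 = rng.normal(size=(2, 64))
        lhs = savitzky_golay(a * y1 + b * y2, 11, 3)
        rhs = a * savitzky_golay(y1, 11, 3) + b * savitzky_golay(y2, 11, 3)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_invalid_parameters_rejected(self):
        y = np.zeros(50)
        with pytest.raises(ConfigError):
            savitzky_golay(y, window=10, order=3)
        with pytest.raises(ConfigError):
            savitzky_golay(y, window=11, order=11)
        with pytest.raises(DataError):
            savitzky_golay(np.zeros(5), window=11, order=3)


class TestAirPLS:
    def test_straight_line_is_its_own_baseline(self):
        line = np.linspace(1.0, 4.0, 500)
        res = airpls(line)
        assert np.abs(res.corrected).max() < 1e-6 * np.abs(line).max()

    def test_all_zero_input_converges_immediately(self):
        res = airpls(np.zeros(100))
        assert res.converged and res.n_iterations == 1
        assert np.allclose(res.baseline, 0.0)

    def test_recovers_known_cubic_baseline_under_peaks(self):
        """Known-truth oracle: cubic background + 3 Lorentzians, peak height
        5x the baseline range; recovered baseline RMSE < 5% of that range and
        peak apices in the corrected signal unmoved."""
        axis = make_axis(400, 4000, 1698)
        base = baseline_curve(axis, (0.5, 1.0, -0.8, 0.4))
        span = base.max() - base.min()
        centers = (1154.0, 1514.0, 2662.0)
        y = base.copy()
        for c in centers:
            y += 5.0 * span * lorentzian(axis, c, 16.0)
        res = airpls(y)
        rmse = np.sqrt(np.mean((res.baseline - base) ** 2))
        assert rmse < 0.05 * span
        for c in centers:
            true_bin = int(np.abs(axis - c).argmin())
            window = res.corrected[true_bin - 10 : true_bin + 11]
            assert abs(int(window.argmax()) - 10) <= 1

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=300).cumsum()
        res = airpls(y)
        assert np.allclose(res.baseline + res.corrected, y, rtol=1e-9, atol=1e-9)

    def test_constant_shift_moves_baseline_by_constant(self):
        """Each weighted Whittaker solve is shift-equivariant (constants lie in
        the penalty's null space).  The stop rule normalises by ||y||_1, which
        a shift changes, so the comparison pins the iteration count."""
        axis = make_axis(400, 4000, 800)
        y = baseline_curve(axis, (0.5, 1.0, -0.8, 0.4)) + 2.0 * lorentzian(axis, 1154, 16)
        res0 = airpls(y, ratio=1e-12, maxiter=6)
        res1 = airpls(y + 7.0, ratio=1e-12, maxiter=6)
        assert res0.n_iterations == res1.n_iterations == 6
        scale = np.abs(res0.baseline).max()
        assert np.allclose(res1.baseline, res0.baseline + 7.0, atol=1e-6 * scale)

    def test_iteration_cap_respected(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200).cumsum()
        res = airpls(y, maxiter=2)
        assert res.n_iterations <= 2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(NumericalError):
            airpls(np.array([1.0, np.nan, 2.0, 3.0, 4.0]))
        with pytest.raises(DataError):
            airpls(np.zeros(3))
        with pytest.raises(ConfigError):
            airpls(np.zeros(100), lam=0.0)


class TestMinMaxScale:
    def test_simple_example(self):
        assert np.allclose(minmax_scale(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0])

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_bounds_exact_and_idempotent(self, seed):
        y = np.random.default_rng(seed).normal(size=64)
        out = minmax_scale(y)
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.allclose(minmax_scale(out), out)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DataError):
            minmax_scale(np.full(30, 1.5))


class TestPreprocessSet:
    def test_single_peak_set_scaled_with_apex_preserved(self, axis256):
        from ramandx import PeakSpec, render_clean_spectrum

        peak = PeakSpec(1154.0, 16.0, 1.0)
        spectra = [render_clean_spectrum(axis256, [peak], [0.5]) for _ in range(3)]
        sset = SpectrumSet.from_spectra(spectra)
        out = preprocess_set(sset, PreprocessConfig())
        apex = int(np.abs(axis256 - 1154.0).argmin())
        for row in out.intensities:
            assert row.min() == 0.0 and row.max() == 1.0
            assert abs(int(row.argmax()) - apex) <= 1

    def test_stage_order_is_smooth_then_baseline_then_scale(self):
        """Permuting the stage order changes the output (order regression)."""
        cfg = small_generator_config(noise_sd=0.05)
        data = generate_dataset(cfg)
        pp = PreprocessConfig()
        spec_order = preprocess_set(data, pp).intensities[0]
        y = data.intensities[0]
        permuted = minmax_scale(
            savitzky_golay(airpls(y, pp.airpls_lambda).corrected, pp.sg_window, pp.sg_order)
        )
        assert not np.allclose(spec_order, permuted)

    def test_labels_and_ids_pass_through(self, small_config):
        data = generate_dataset(small_config)
        out = preprocess_set(data)
        assert list(out.labels) == list(data.labels)
        assert out.sample_ids == data.sample_ids

    def test_empty_set_passes_through(self, axis256):
        empty = SpectrumSet(
            axis=axis256,
            intensities=np.empty((0, axis256.size)),
            labels=np.array([], dtype=object),
        )
        assert len(preprocess_set(empty)) == 0

    def test_errors_annotated_with_sample_id(self, axis256):
        flat = SpectrumSet(
            axis=axis256,
            intensities=np.zeros((1, axis256.size)),
            labels=np.array(["HC"], dtype=object),
            sample_ids=["bad-001"],
        )
        with pytest.raises(DataError, match="bad-001"):
            preprocess_set(flat)
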