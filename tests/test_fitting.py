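"""Voxel-wise fit correctness: round trips, collapse, FA, volume fitting."""

import math

import numpy as np
import pytest

from placenta_dwr.fitting import (
    FitConfig,
    fit_ivim,
    fit_monoexp,
    fit_tensor_fa,
    fit_volume,
    rician_expectation,
)
from placenta_dwr.models import (
    DiffusionTensor,
    IvimParams,
    MonoExpParams,
    signal_ivim,
    signal_monoexp,
    signal_tensor,
)
from placenta_dwr.protocol import AcquisitionScheme, Measurement
from placenta_dwr.synthetic import add_noise, make_phantom, synthesise_volume


class TestMonoExpFit:
    def test_noiseless_round_trip(self, protocol_scheme):
        truth = MonoExpParams(100.0, 50.0, 2e-3)
        res = fit_monoexp(signal_monoexp(truth, protocol_scheme), protocol_scheme)
        assert res.converged
        assert res.params.s0 == pytest.approx(truth.s0, rel=1e-6)
        assert res.params.t2_star == pytest.approx(truth.t2_star, rel=1e-6)
        assert res.params.adc == pytest.approx(truth.adc, rel=1e-6)

    def test_b_constant_signal_gives_zero_adc(self, protocol_scheme):
        truth = MonoExpParams(80.0, 45.0, 0.0)
        res = fit_monoexp(signal_monoexp(truth, protocol_scheme), protocol_scheme)
        assert res.params.adc == pytest.approx(0.0, abs=1e-8)

    def test_nonpositive_signal_flagged_not_raised(self, protocol_scheme):
        res = fit_monoexp(np.zeros(len(protocol_scheme)), protocol_scheme)
        assert not res.converged and res.params is None

    def test_too_few_echo_times_rejected(self):
        s = AcquisitionScheme(tuple(
            Measurement(b, (1.0, 0.0, 0.0), 78.0) for b in (5.0, 100.0, 800.0)
        ))
        with pytest.raises(ValueError, match="distinct"):
            fit_monoexp(np.ones(3), s)

    def test_gaussian_noise_median_bias_small(self, protocol_scheme):
        truth = MonoExpParams(100.0, 50.0, 2e-3)
        clean = signal_monoexp(truth, protocol_scheme)
        rng = np.random.default_rng(11)
        est = []
        for _ in range(200):
            res = fit_monoexp(add_noise(clean, 1.0, "gaussian", rng), protocol_scheme)
            est.append(res.params.t2_star)
        bias = np.median(est) / truth.t2_star - 1
        assert abs(bias) < 0.03


class TestRicianExpectation:
    def test_limits(self):
        sigma = 3.0
        assert rician_expectation(0.0, sigma) == pytest.approx(sigma * math.sqrt(math.pi / 2))
        assert rician_expectation(300.0, sigma) == pytest.approx(
            math.sqrt(300.0**2 + sigma**2), rel=1e-4
        )

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        sigma = 3.0
        for s in (0.0, 1.5, 3.0, 9.0, 30.0):
            draws = np.sqrt(
                (s + rng.normal(0, sigma, 300_000)) ** 2 + rng.normal(0, sigma, 300_000) ** 2
            )
            assert rician_expectation(s, sigma) == pytest.approx(draws.mean(), rel=5e-3)


class TestIvimFit:
    TRUTH = IvimParams(100.0, 0.3, 80.0, 40.0, 0.05, 2e-3)

    def test_noiseless_round_trip_full(self, protocol_scheme):
        res = fit_ivim(signal_ivim(self.TRUTH, protocol_scheme), protocol_scheme, "full")
        assert res.converged
        for name in ("s0", "f", "t2_star_fast", "t2_star_slow", "d_star", "adc"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(self.TRUTH, name), rel=1e-2
            ), name

    def test_segmented_close_to_truth(self, protocol_scheme):
        res = fit_ivim(signal_ivim(self.TRUTH, protocol_scheme), protocol_scheme, "segmented")
        for name in ("f", "t2_star_fast", "t2_star_slow", "adc"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(self.TRUTH, name), rel=0.05
            ), name

    def test_f0_truth_recovers_slow_compartment(self, protocol_scheme):
        truth = IvimParams(100.0, 0.0, 80.0, 40.0, 0.05, 2e-3)
        sig = signal_ivim(truth, protocol_scheme)
        res = fit_ivim(sig, protocol_scheme, "full")
        assert res.params.f < 0.02
        mono = fit_monoexp(sig, protocol_scheme)
        assert res.params.adc == pytest.approx(mono.params.adc, rel=0.02)
        assert res.params.t2_star_slow == pytest.approx(truth.t2_star_slow, rel=0.02)

    def test_swapped_truth_labels_give_same_canonical_fit(self, protocol_scheme):
        swapped = IvimParams(100.0, 0.7, 40.0, 80.0, 2e-3, 0.05)
        sig = signal_ivim(swapped, protocol_scheme)
        res = fit_ivim(sig, protocol_scheme, "full")
        assert res.params.d_star > res.params.adc
        assert res.params.f == pytest.approx(0.3, abs=0.01)
        assert res.params.t2_star_fast == pytest.approx(80.0, rel=0.02)

    def test_unknown_strategy_rejected(self, protocol_scheme):
        with pytest.raises(ValueError, match="strategy"):
            fit_ivim(np.ones(len(protocol_scheme)), protocol_scheme, "bayesian")

    def test_rician_correction_removes_floor_bias(self, protocol_scheme):
        clean = signal_ivim(self.TRUTH, protocol_scheme)
        rng = np.random.default_rng(5)
        sigma = 100.0 / 30.0
        naive, corrected = [], []
        for _ in range(60):
            noisy = add_noise(clean, sigma, "rician", rng)
            naive.append(fit_ivim(noisy, protocol_scheme, "segmented").params.t2_star_fast)
            corrected.append(
                fit_ivim(noisy, protocol_scheme, "segmented", FitConfig(sigma=sigma)).params.t2_star_fast
            )
        bias_naive = abs(np.median(naive) / self.TRUTH.t2_star_fast - 1)
        bias_corr = abs(np.median(corrected) / self.TRUTH.t2_star_fast - 1)
        assert bias_corr < 0.05
        assert bias_corr < bias_naive


class TestTensorFaFit:
    def _first_te(self, scheme):
        return scheme.at_first_te()

    def test_isotropic_truth_gives_zero_fa(self, protocol_scheme):
        s = self._first_te(protocol_scheme)
        t = DiffusionTensor.from_matrix(1.8e-3 * np.eye(3), s0=120.0)
        res = fit_tensor_fa(signal_tensor(t, s), s)
        assert res.fa == pytest.approx(0.0, abs=1e-6)

    def test_prolate_tensor_fa_closed_form(self, protocol_scheme):
        s = self._first_te(protocol_scheme)
        t = DiffusionTensor.from_matrix(np.diag([2e-3, 1e-3, 1e-3]), s0=90.0)
        res = fit_tensor_fa(signal_tensor(t, s), s)
        assert res.fa == pytest.approx(1 / math.sqrt(6), abs=1e-6)
        lam = np.sort(res.params.eigenvalues())
        np.testing.assert_allclose(lam, [1e-3, 1e-3, 2e-3], rtol=1e-6)

    def test_rank_one_tensor_fa_approaches_one(self, protocol_scheme):
        s = self._first_te(protocol_scheme)
        t = DiffusionTensor.from_matrix(np.diag([2.5e-3, 1e-9, 1e-9]), s0=90.0)
        res = fit_tensor_fa(signal_tensor(t, s), s)
        assert res.fa == pytest.approx(1.0, abs=1e-3)

    def test_rank_deficient_directions_rejected(self):
        rows = [Measurement(0.0, (0.0, 0.0, 0.0), 78.0)] + [
            Measurement(800.0, (1.0, 0.0, 0.0), 78.0) for _ in range(8)
        ]
        s = AcquisitionScheme(tuple(rows))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_tensor_fa(np.ones(len(s)), s)

    def test_fitted_fa_always_in_unit_interval(self, protocol_scheme, rng):
        s = self._first_te(protocol_scheme)
        t = DiffusionTensor.from_matrix(np.diag([2e-3, 1.2e-3, 0.4e-3]), s0=100.0)
        clean = signal_tensor(t, s)
        for _ in range(25):
            res = fit_tensor_fa(add_noise(clean, 4.0, "rician", rng), s)
            assert 0.0 <= res.fa <= 1.0


@pytest.fixture(scope="module")
def phantom_and_data(protocol_scheme):
    ph = make_phantom(28.0, "control", (6, 6, 5), seed=4)
    data = synthesise_volume(ph, protocol_scheme, snr=None)
    return ph, data


class TestFitVolume:
    def test_noiseless_volume_recovery(self, protocol_scheme, phantom_and_data):
        ph, data = phantom_and_data
        maps = fit_volume(data, ph.mask, protocol_scheme, "t2adc")
        assert maps.summary["n_non_converged"] == 0
        # the mono-exponential T2* of two-compartment data is an effective
        # value sandwiched between the slow and fast compartment T2*
        est = maps.maps["t2_star"][ph.mask]
        t2s = ph.param_maps["t2_star_slow"][ph.mask]
        t2f = ph.param_maps["t2_star_fast"][ph.mask]
        assert np.all(est > t2s * 0.99)
        assert np.all(est < t2f)
        # perfusion contaminates the low-b decay, so the mono ADC sits a
        # little above the tissue diffusivity but stays the right scale
        adc = maps.maps["adc"][ph.mask]
        truth_adc = ph.param_maps["adc"][ph.mask]
        rel = np.median(adc / truth_adc - 1)
        assert 0.0 < rel < 0.3

    def test_maps_defined_exactly_on_mask(self, protocol_scheme, phantom_and_data):
        ph, data = phantom_and_data
        maps = fit_volume(data, ph.mask, protocol_scheme, "t2adc")
        assert np.all(np.isfinite(maps.maps["t2_star"][ph.mask]))
        assert np.all(np.isnan(maps.maps["t2_star"][~ph.mask]))

    def test_determinism_under_seed(self, protocol_scheme, phantom_and_data):
        ph, data = phantom_and_data
        cfg = FitConfig(strategy="segmented", seed=3)
        a = fit_volume(data, ph.mask, protocol_scheme, "t2ivim", cfg)
        b = fit_volume(data, ph.mask, protocol_scheme, "t2ivim", cfg)
        for key in a.maps:
            np.testing.assert_array_equal(a.maps[key], b.maps[key])

    def test_empty_mask_rejected(self, protocol_scheme, phantom_and_data):
        ph, data = phantom_and_data
        with pytest.raises(ValueError, match="empty"):
            fit_volume(data, np.zeros(ph.shape, bool), protocol_scheme, "t2adc")

    def test_shape_mismatch_rejected_before_fitting(self, protocol_scheme, phantom_and_data):
        ph, data = phantom_and_data
        with pytest.raises(ValueError, match="scheme length"):
            fit_volume(data[..., :100], ph.mask, protocol_scheme, "t2adc")
        with pytest.raises(ValueError, match="mask shape"):
            fit_volume(data, ph.mask[:-1], protocol_scheme, "t2adc")
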