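"""MVAR fitting, PDC/wPDC and band reduction against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiconnect.cohort import NetworkTemplate, simulate_subject
from epiconnect.connectivity import (
    BandSpec,
    ConnectivityTensor,
    MVARModel,
    band_reduce,
    fit_mvar,
    pdc_spectrum,
    select_order,
    sender_weights,
    subject_connectivity,
    weight_pdc,
)


def _simulate_raw(coeffs, noise_cov, n, seed, burn=200):
    """Plain MVAR simulation used as fitting ground truth."""
    p, R, _ = coeffs.shape
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(noise_cov)
    x = np.zeros((burn + n, R))
    innov = rng.standard_normal((burn + n, R)) @ chol.T
    for t in range(burn + n):
        acc = innov[t].copy()
        for r in range(min(p, t)):
            acc += coeffs[r] @ x[t - r - 1]
        x[t] = acc
    return x[burn:].T  # (R, n)


class TestFitMvar:
    def test_recovers_scalar_ar1(self):
        epoch = _simulate_raw(np.array([[[0.6]]]), np.eye(1), 10_000, seed=0)
        model = fit_mvar(epoch, order=1, fs=250.0)
        # cross-check against the direct lag-1 autocorrelation estimator
        x = epoch[0]
        direct = np.dot(x[1:], x[:-1]) / np.dot(x[:-1], x[:-1])
        assert model.coeffs[0, 0, 0] == pytest.approx(0.6, abs=0.02)
        assert model.coeffs[0, 0, 0] == pytest.approx(direct, abs=1e-9)

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(1)
        epoch = rng.standard_normal((2, 5_000))
        model = fit_mvar(epoch, order=1, fs=250.0)
        assert np.abs(model.coeffs).max() < 3 / np.sqrt(5_000)

    def test_recovers_three_node_order2_system(self, three_node_model):
        coeffs, noise_cov = three_node_model
        epoch = _simulate_raw(coeffs, noise_cov, 100_000, seed=2)
        model = fit_mvar(epoch, order=2, fs=250.0)
        assert np.abs(model.coeffs - coeffs).max() < 0.05

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_mvar(np.zeros((4, 20)), order=5, fs=250.0)

    def test_rank_deficient_rejected(self):
        # duplicated channel makes the lagged regressor matrix singular
        x = _simulate_raw(np.array([[[0.5]]]), np.eye(1), 500, seed=3)
        epoch = np.vstack([x, x])
        with pytest.raises(np.linalg.LinAlgError):
            fit_mvar(epoch, order=1, fs=250.0)


class TestSelectOrder:
    def test_bic_recovers_true_order(self):
        epoch = _simulate_raw(np.array([[[0.6]]]), np.eye(1), 5_000, seed=4)
        assert select_order(epoch, max_order=5, criterion="bic") == 1

    def test_single_candidate(self):
        rng = np.random.default_rng(5)
        epoch = rng.standard_normal((2, 200))
        assert select_order(epoch, max_order=1) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_aic_at_least_bic(self, seed, three_node_model):
        coeffs, noise_cov = three_node_model
        epoch = _simulate_raw(coeffs, noise_cov, 400, seed=seed)
        aic = select_order(epoch, max_order=6, criterion="aic")
        bic = select_order(epoch, max_order=6, criterion="bic")
        assert aic >= bic


class TestPdcSpectrum:
    def test_uncoupled_model_is_identity_pattern(self):
        model = MVARModel(order=1, coeffs=np.zeros((1, 3, 3)),
                          noise_cov=np.eye(3), fs=250.0)
        tensor = pdc_spectrum(model, np.arange(1.0, 30.0))
        eye = np.eye(3)[:, :, None] * np.ones((1, 1, 29))
        np.testing.assert_allclose(tensor.values, eye, atol=1e-12)

    def test_two_node_closed_form(self):
        # PDC(2<-1) at f = |a e^{-i t}| / sqrt(|1-0.5 e^{-i t}|^2 + |0.4 e^{-i t}|^2)
        model = MVARModel(
            order=1, coeffs=np.array([[[0.5, 0.0], [0.4, 0.5]]]),
            noise_cov=np.eye(2), fs=250.0,
        )
        f = 10.0
        tensor = pdc_spectrum(model, [f])
        theta = 2 * np.pi * f / 250.0
        z = np.exp(-1j * theta)
        expected = abs(0.4 * z) / np.sqrt(abs(1 - 0.5 * z) ** 2 + abs(0.4 * z) ** 2)
        assert tensor.values[1, 0, 0] == pytest.approx(expected, abs=1e-10)

    def test_frequency_outside_nyquist_rejected(self):
        model = MVARModel(order=1, coeffs=np.zeros((1, 2, 2)),
                          noise_cov=np.eye(2), fs=250.0)
        with pytest.raises(ValueError, match="fs/2"):
            pdc_spectrum(model, [200.0])

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 1_000))
    def test_column_normalization_identity(self, seed):
        """For every sender column and frequency, the squared PDC sums to 1."""
        rng = np.random.default_rng(seed)
        coeffs = 0.25 * rng.standard_normal((2, 4, 4))
        model = MVARModel(order=2, coeffs=coeffs, noise_cov=np.eye(4), fs=250.0)
        tensor = pdc_spectrum(model, np.arange(1.0, 31.0))
        sums = (tensor.values**2).sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestWeightPdc:
    def test_equal_power_weights_are_unity(self):
        model = MVARModel(order=1, coeffs=np.zeros((1, 2, 2)),
                          noise_cov=np.eye(2), fs=250.0)
        pdc = pdc_spectrum(model, [5.0, 10.0])
        rng = np.random.default_rng(0)
        base = rng.standard_normal(500)
        epoch = np.vstack([base, rng.permutation(base)])  # identical power
        wpdc = weight_pdc(pdc, epoch)
        np.testing.assert_allclose(wpdc.values, pdc.values, atol=1e-12)

    def test_amplitude_doubling_quadruples_relative_weight(self):
        rng = np.random.default_rng(6)
        epoch = rng.standard_normal((3, 1_000))
        w = sender_weights(epoch)
        scaled = epoch.copy()
        scaled[0] *= 2.0
        w2 = sender_weights(scaled)
        assert (w2[0] / w2[1]) == pytest.approx(4 * w[0] / w[1], rel=1e-9)

    def test_weights_in_unit_interval_with_max_one(self):
        rng = np.random.default_rng(7)
        w = sender_weights(rng.standard_normal((5, 300)) * [[1], [2], [3], [4], [5]])
        assert w.max() == pytest.approx(1.0)
        assert (w > 0).all()

    def test_zero_power_channel_rejected(self):
        epoch = np.zeros((2, 100))
        epoch[0] = 1.0 + np.sin(np.arange(100))
        with pytest.raises(ValueError, match="zero-power"):
            sender_weights(epoch)


class TestBands:
    def test_default_band_grid_membership(self):
        bands = BandSpec()
        members = bands.grid_members(np.arange(1.0, 31.0))
        freqs = np.arange(1.0, 31.0)
        assert freqs[members["theta"]].tolist() == [4, 5, 6, 7]
        assert freqs[members["alpha"]].tolist() == [8, 9, 10, 11]
        assert freqs[members["beta"]].tolist() == list(range(12, 30))

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BandSpec({"a": (4.0, 9.0), "b": (8.0, 12.0)})

    def test_empty_band_rejected(self):
        bands = BandSpec({"theta": (4.0, 8.0), "hi": (40.0, 50.0)})
        with pytest.raises(ValueError, match="captures no grid frequency"):
            bands.grid_members(np.arange(1.0, 31.0))

    def test_constant_spectrum_band_means_equal_constant(self):
        values = np.full((2, 2, 29), 0.37)
        tensor = ConnectivityTensor(values, "frequency_grid",
                                    np.arange(1.0, 30.0), ("a-L", "a-R"))
        reduced = band_reduce(tensor, BandSpec())
        np.testing.assert_allclose(reduced.values, 0.37)


class TestSubjectConnectivity:
    def test_single_epoch_equals_band_average(self, two_pair_template):
        subj = simulate_subject(two_pair_template, n_epochs=1, epoch_seconds=2.0,
                                subject_jitter_sd=0.0, obs_noise_sd=0.0, seed=8)
        freqs = np.arange(1.0, 31.0)
        tensor = subject_connectivity(subj, order=1, freqs=freqs)
        model = fit_mvar(subj.epochs[0], order=1, fs=subj.fs,
                         roi_names=subj.roi_names)
        expected = band_reduce(
            weight_pdc(pdc_spectrum(model, freqs), subj.epochs[0]), BandSpec()
        )
        np.testing.assert_allclose(tensor.values, expected.values)

    def test_fitted_pdc_matches_true_coefficients(self, three_node_model):
        """PDC from a long fit tracks the analytic PDC of the generator."""
        coeffs, noise_cov = three_node_model
        epoch = _simulate_raw(coeffs, noise_cov, 100_000, seed=9)
        freqs = np.arange(1.0, 31.0)
        fitted = pdc_spectrum(fit_mvar(epoch, order=2, fs=250.0), freqs)
        true_model = MVARModel(order=2, coeffs=coeffs, noise_cov=noise_cov, fs=250.0)
        oracle = pdc_spectrum(true_model, freqs)
        assert np.abs(fitted.values - oracle.values).max() < 0.02

    def test_long_format_roundtrip(self, tmp_path, two_pair_template):
        subj = simulate_subject(two_pair_template, n_epochs=2, seed=10)
        tensor = subject_connectivity(subj, order=1)
        frame = tensor.to_frame()
        assert len(frame) == 2 * 2 * 3
        assert set(frame["band_or_freq"]) == {"theta", "alpha", "beta"}
        tensor.to_csv(tmp_path / "conn.csv")
        from epiconnect.connectivity import ConnectivityTensor

        back = ConnectivityTensor.from_csv(tmp_path / "conn.csv")
        assert back.roi_names == tensor.roi_names
        np.testing.assert_allclose(back.values, tensor.values, rtol=1e-10)

    def test_npz_roundtrip_is_exact(self, tmp_path, two_pair_template):
        subj = simulate_subject(two_pair_template, n_epochs=1, seed=11)
        from epiconnect.connectivity import ConnectivityTensor

        for tensor in (
            subject_connectivity(subj, order=1),  # bands
            pdc_spectrum(fit_mvar(subj.epochs[0], 1, subj.fs, subj.roi_names),
                         np.arange(1.0, 31.0)),  # frequency grid
        ):
            tensor.to_npz(tmp_path / "t.npz")
            back = ConnectivityTensor.from_npz(tmp_path / "t.npz")
            assert back.axis_kind == tensor.axis_kind
            assert back.roi_names == tensor.roi_names
            np.testing.assert_array_equal(back.values, tensor.values)
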