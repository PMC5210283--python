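"""Band-pass filtering, CSP/CSSP spatial patterns, Fisher LDA."""

import numpy as np
import pytest
from scipy import signal

from lrlds import (
    EpochSet,
    EvalConfig,
    bandpass_filter,
    csp_features,
    csp_fit,
    cssp_augment,
    evaluate,
    holdout_split,
    lda_fit,
    lda_predict,
    simulate_epochs,
)
from lrlds.baselines import CSPFilters, lda_decision
from lrlds.synthetic import ClassSpec, SimConfig, simulate_spatial_epochs


def sinusoid_epochs(freq_hz, fs=100.0, tau=500, m=3, trials=2, amp=1.0):
    t = np.arange(tau) / fs
    wave = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(wave, (trials, m, 1))
    return EpochSet(data=data, labels=np.zeros(trials, dtype=int), fs=fs)


class TestBandpass:
    def test_passband_tone_survives(self):
        """20 Hz tone through 8-30 Hz: RMS within 5% of the analytic gain."""
        ep = sinusoid_epochs(20.0)
        out = bandpass_filter(ep, 8.0, 30.0, order=4)
        sos = signal.butter(4, [8, 30], btype="bandpass", fs=100, output="sos")
        _, h = signal.sosfreqz(sos, worN=[20.0], fs=100)
        expected_gain = np.abs(h[0]) ** 2  # forward-backward squares |H|
        # trim filtfilt edge transients before comparing energy
        rms_in = np.sqrt(np.mean(ep.data[0, 0, 100:-100] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, 0, 100:-100] ** 2))
        assert rms_out / rms_in == pytest.approx(expected_gain, rel=0.05)
        assert rms_out / rms_in == pytest.approx(1.0, rel=0.05)

    def test_dc_is_rejected(self):
        ep = EpochSet(np.ones((1, 2, 400)), np.zeros(1, int), fs=100.0)
        out = bandpass_filter(ep, 8.0, 30.0)
        assert np.sqrt(np.mean(out.data**2)) < 0.01

    def test_stopband_tone_attenuated_20db(self):
        """2 Hz tone: attenuation at least the designed response (>= 20 dB)."""
        ep = sinusoid_epochs(2.0, tau=2000)
        out = bandpass_filter(ep, 8.0, 30.0, order=4)
        sos = signal.butter(4, [8, 30], btype="bandpass", fs=100, output="sos")
        _, h = signal.sosfreqz(sos, worN=[2.0], fs=100)
        designed_db = -20 * np.log10(np.abs(h[0]) ** 2)
        rms_in = np.sqrt(np.mean(ep.data[0, 0, 500:-500] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, 0, 500:-500] ** 2))
        atten_db = -20 * np.log10(rms_out / rms_in)
        assert designed_db >= 20
        assert atten_db >= 20

    def test_band_outside_nyquist_rejected(self):
        ep = sinusoid_epochs(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(ep, 8.0, 60.0)

    def test_shape_preserved(self, small_epochs):
        out = bandpass_filter(small_epochs, 8.0, 30.0)
        assert out.data.shape == small_epochs.data.shape
        assert np.array_equal(out.labels, small_epochs.labels)


class TestCSP:
    def test_identical_class_covariances_give_half_eigenvalues(self):
        ep = simulate_spatial_epochs(30, cov_diags=((1.0,) * 6, (1.0,) * 6),
                                     seed=0)
        filters = csp_fit(ep, n_pairs=2)
        assert np.allclose(filters.eigenvalues, 0.5, atol=0.05)

    def test_identical_covariances_classify_at_chance(self):
        """Non-discriminable classes: mean accuracy within chance +/- 10%."""
        accs = []
        for seed in range(20):
            ep = simulate_spatial_epochs(
                20, cov_diags=((1.0,) * 6, (1.0,) * 6), seed=seed
            )
            res = evaluate(ep, "csp", holdout_split(ep.labels, 0.3, seed),
                           EvalConfig())
            accs.append(res.accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.10

    def test_diagonal_pencil_filters_align_with_planted_axes(self):
        """diag(4,1,..) vs diag(1,4,..): extreme filters hit axes 0 and 1."""
        ep = simulate_spatial_epochs(200, m=4, seed=1)
        filters = csp_fit(ep, n_pairs=1)
        top = filters.W[:, 0] / np.linalg.norm(filters.W[:, 0])
        bottom = filters.W[:, -1] / np.linalg.norm(filters.W[:, -1])
        assert abs(top[0]) > 0.99 or abs(top[1]) > 0.99
        assert abs(bottom[0]) > 0.99 or abs(bottom[1]) > 0.99
        assert abs(np.dot(top, bottom)) < 0.2

    def test_reported_eigenvalues_are_rayleigh_quotients(self):
        ep = simulate_spatial_epochs(25, seed=2)
        filters = csp_fit(ep, n_pairs=3)
        covs = []
        for c in (0, 1):
            trials = ep.data[ep.labels == c]
            covs.append(np.mean(
                [Y @ Y.T / np.trace(Y @ Y.T) for Y in trials], axis=0))
        S1, S2 = covs
        for w_vec, lam in zip(filters.W.T, filters.eigenvalues):
            rq = (w_vec @ S1 @ w_vec) / (w_vec @ (S1 + S2) @ w_vec)
            assert rq == pytest.approx(lam, abs=1e-8)

    def test_eigenvalue_pairing_sums_to_one(self):
        """Per filter, the class-1 and class-2 variance shares sum to 1,
        and under exact class-swap symmetry the sorted spectrum mirrors."""
        ep = simulate_spatial_epochs(25, seed=3)
        filters = csp_fit(ep, n_pairs=3)
        covs = []
        for c in (0, 1):
            trials = ep.data[ep.labels == c]
            covs.append(np.mean(
                [Y @ Y.T / np.trace(Y @ Y.T) for Y in trials], axis=0))
        S1, S2 = covs
        for w_vec in filters.W.T:
            share1 = (w_vec @ S1 @ w_vec) / (w_vec @ (S1 + S2) @ w_vec)
            share2 = (w_vec @ S2 @ w_vec) / (w_vec @ (S1 + S2) @ w_vec)
            assert share1 + share2 == pytest.approx(1.0, abs=1e-8)
        # class 2 = class 1 with two channels swapped: spectrum mirrors exactly
        swapped = ep.data[ep.labels == 0][:, [1, 0, 2, 3, 4, 5], :]
        sym = EpochSet(
            np.concatenate([ep.data[ep.labels == 0], swapped]),
            np.repeat([0, 1], (ep.labels == 0).sum()), ep.fs,
        )
        lam = csp_fit(sym, n_pairs=3).eigenvalues
        for i in range(3):
            assert lam[i] + lam[-(i + 1)] == pytest.approx(1.0, abs=1e-8)

    def test_more_than_two_classes_rejected(self, fourclass_epochs):
        with pytest.raises(ValueError, match="2 classes"):
            csp_fit(fourclass_epochs)

    def test_channel_rescaling_leaves_downstream_unchanged(self):
        """Rescaling one channel adapts the filters but not the predictions.

        Per-trial trace normalization makes the eigenvalues only
        approximately invariant; the end-to-end predictions are stable.
        """
        for seed in range(5):
            ep = simulate_spatial_epochs(20, seed=seed)
            scaled_data = ep.data * np.array([1, 1, 10, 1, 1, 1])[None, :, None]
            scaled = EpochSet(scaled_data, ep.labels, ep.fs)
            assert np.allclose(
                np.sort(csp_fit(ep, 2).eigenvalues),
                np.sort(csp_fit(scaled, 2).eigenvalues), atol=0.02,
            )
            split = holdout_split(ep.labels, 0.3, seed)
            cfg = EvalConfig(bandpass=False)
            r1 = evaluate(ep, "csp", split, cfg)
            r2 = evaluate(scaled, "csp", split, cfg)
            assert np.array_equal(r1.predicted, r2.predicted)


class TestCSPFeatures:
    def test_identity_filters_on_white_trials(self, rng):
        m = 5
        data = rng.standard_normal((20, m, 4000))
        ep = EpochSet(data, np.zeros(20, int), fs=100.0)
        identity = CSPFilters(W=np.eye(m), eigenvalues=np.full(m, 0.5),
                              n_pairs=m // 2)
        feats = csp_features(ep, identity)
        assert np.allclose(feats, np.log(1 / m), atol=0.05)

    def test_features_sum_exp_to_one(self, small_epochs):
        filters = csp_fit(small_epochs, 2)
        feats = csp_features(small_epochs, filters)
        assert np.allclose(np.exp(feats).sum(axis=1), 1.0, atol=1e-10)

    def test_amplitude_scaling_invariance(self, small_epochs):
        filters = csp_fit(small_epochs, 2)
        doubled = EpochSet(2.0 * small_epochs.data, small_epochs.labels,
                           small_epochs.fs)
        assert np.allclose(csp_features(small_epochs, filters),
                           csp_features(doubled, filters), atol=1e-10)

    def test_channel_mismatch_rejected(self, small_epochs):
        filters = CSPFilters(W=np.eye(5), eigenvalues=np.full(5, 0.5), n_pairs=2)
        with pytest.raises(ValueError, match="channel count"):
            csp_features(small_epochs, filters)


class TestCSSP:
    def test_shape_contract(self, small_epochs):
        tau = 7
        aug = cssp_augment(small_epochs, tau)
        assert aug.n_channels == 2 * small_epochs.n_channels
        assert aug.n_samples == small_epochs.n_samples - tau

    def test_delayed_copy_is_phase_shifted_sinusoid(self):
        fs, f, tau = 100.0, 10.0, 3
        ep = sinusoid_epochs(f, fs=fs, m=1)
        aug = cssp_augment(ep, tau)
        t = np.arange(ep.n_samples) / fs
        expected = np.sin(2 * np.pi * f * (t - tau / fs))[tau:]
        assert np.allclose(aug.data[0, 1], expected[: aug.n_samples], atol=1e-10)

    def test_out_of_range_delay_rejected(self, small_epochs):
        with pytest.raises(ValueError, match="tau"):
            cssp_augment(small_epochs, 0)
        with pytest.raises(ValueError, match="tau"):
            cssp_augment(small_epochs, small_epochs.n_samples)

    def test_beats_plain_csp_on_spectral_class_difference(self):
        """Classes differing only in rhythm frequency favor CSSP over CSP."""
        csp_accs, cssp_accs = [], []
        for seed in range(20):
            specs = [
                ClassSpec(radii=[0.9, 0.9], freqs_hz=[10.0, 10.0], label=0),
                ClassSpec(radii=[0.9, 0.9], freqs_hz=[14.0, 14.0], label=1),
            ]
            cfg = SimConfig(m=4, tau=200, class_specs=specs, obs_snr_db=5.0,
                            seed=seed)
            ep = simulate_epochs(cfg, 15)
            split = holdout_split(ep.labels, 1 / 3, seed)
            eval_cfg = EvalConfig(n_pairs=2)
            csp_accs.append(evaluate(ep, "csp", split, eval_cfg).accuracy)
            cssp_accs.append(evaluate(ep, "cssp", split, eval_cfg).accuracy)
        assert np.mean(cssp_accs) > np.mean(csp_accs)


class TestLDA:
    def test_separated_blobs_train_perfectly(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)) + [8, 8],
                       rng.standard_normal((30, 2)) - [8, 8]])
        y = np.repeat([0, 1], 30)
        clf = lda_fit(X, y)
        assert np.mean(lda_predict(clf, X) == y) == 1.0

    def test_weight_vector_is_fisher_direction(self, rng):
        """Weights parallel to pooled-covariance^-1 (mu1 - mu0)."""
        A_mix = rng.standard_normal((3, 3))
        X0 = rng.standard_normal((200, 3)) @ A_mix.T
        X1 = rng.standard_normal((200, 3)) @ A_mix.T + [1.0, 0.5, -0.5]
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 200)
        clf = lda_fit(X, y)
        mu0, mu1 = X0.mean(0), X1.mean(0)
        Xc = np.vstack([X0 - mu0, X1 - mu1])
        pooled = Xc.T @ Xc / (len(X) - 2)
        fisher = np.linalg.solve(pooled, mu1 - mu0)
        w = clf.coef
        cos = np.dot(w, fisher) / (np.linalg.norm(w) * np.linalg.norm(fisher))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_single_feature_reduces_to_midpoint_threshold(self, rng):
        x0 = rng.normal(0.0, 1.0, 300)
        x1 = rng.normal(4.0, 1.0, 300)
        X = np.concatenate([x0, x1])[:, None]
        y = np.repeat([0, 1], 300)
        clf = lda_fit(X, y)
        threshold = (x0.mean() + x1.mean()) / 2
        eps = 1e-3
        assert lda_predict(clf, [[threshold - eps]])[0] == 0
        assert lda_predict(clf, [[threshold + eps]])[0] == 1
        assert abs(lda_decision(clf, [[threshold]])[0]) < 1e-6

    def test_more_than_two_classes_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            lda_fit(rng.standard_normal((9, 2)), np.arange(9) % 3)


def test_end_to_end_csp_lda_sanity():
    """Planted spatial covariance difference: >= 90% mean accuracy."""
    accs = []
    for seed in range(10):
        ep = simulate_spatial_epochs(20, seed=seed)
        res = evaluate(ep, "csp", holdout_split(ep.labels, 0.3, seed),
                       EvalConfig())
        accs.append(res.accuracy)
    assert np.mean(accs) >= 0.90
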