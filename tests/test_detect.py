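"""Spectral SNR statistic, CCA, filter-bank CCA and classification."""

import numpy as np
import pytest

from ssveplab.detect import (FilterBankConfig, PowerSpectrum, ResolutionError,
                             build_reference, cca_correlate, classify_cca,
                             classify_psda, fbcca_classify, ssvep_snr,
                             welch_psd)


def _flat_spectrum(value=1.0, n_ch=1, fmax=60.0, df=0.25):
    freqs = np.arange(0.0, fmax + df, df)
    return PowerSpectrum(freqs=freqs,
                         power=np.full((n_ch, len(freqs)), value))


class TestWelchPsd:
    def test_peak_at_tone_frequency(self):
        fs = 500.0
        t = np.arange(int(5 * fs)) / fs
        ps = welch_psd(np.sin(2 * np.pi * 10.0 * t), fs)
        assert ps.freqs[np.argmax(ps.power[0])] == pytest.approx(10.0,
                                                                 abs=0.25)
        assert ps.bin_spacing <= 0.25

    def test_parseval_total_power(self, rng):
        fs = 500.0
        x = rng.standard_normal((3, int(5 * fs)))
        ps = welch_psd(x, fs)
        band_power = ps.power.sum(axis=1) * ps.bin_spacing
        assert np.allclose(band_power, x.var(axis=1), rtol=0.05)

    def test_short_window_rejected(self):
        with pytest.raises(ResolutionError):
            welch_psd(np.zeros((1, 100)), 500.0)


class TestSsvepSnr:
    def test_flat_spectrum_gives_two(self):
        assert ssvep_snr(_flat_spectrum(3.7), 10.0) == pytest.approx(2.0)

    def test_matches_hand_arithmetic(self):
        """Constructed-spectrum value equals the explicit neighbor-bin ratio."""
        rng = np.random.default_rng(8)
        spec = _flat_spectrum(1.0, n_ch=2)
        spec.power[:] = rng.uniform(0.5, 2.0, size=spec.power.shape)
        f = 8.0
        expected = np.zeros(2)
        for c in range(2):
            y = dict(zip(np.round(spec.freqs, 4), spec.power[c]))
            for f0 in (f, 2 * f):
                neighbors = sum(y[round(f0 + 0.25 * k, 4)]
                                + y[round(f0 - 0.25 * k, 4)]
                                for k in (1, 2, 3))
                expected[c] += 6.0 * y[f0] / neighbors
        got = ssvep_snr(spec, f, per_channel=True)
        assert np.allclose(got, expected, rtol=0.0, atol=1e-9)
        assert ssvep_snr(spec, f) == pytest.approx(expected.mean(), abs=1e-9)

    def test_zero_neighbors_capped(self):
        spec = _flat_spectrum(0.0)
        idx = int(round(10.0 / 0.25))
        spec.power[0, idx] = 1.0
        spec.power[0, 2 * idx] = 1.0
        assert ssvep_snr(spec, 10.0) == 2e12

    def test_edge_frequency_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            ssvep_snr(_flat_spectrum(), 29.9)


class TestReferenceTemplate:
    def test_shape_and_first_row(self):
        tpl = build_reference(10.0, 3, 2500, 500.0)
        assert tpl.matrix.shape == (6, 2500)
        t = np.arange(1, 2501) / 500.0
        assert np.allclose(tpl.matrix[0], np.sin(2 * np.pi * 10.0 * t))
        assert np.allclose(tpl.matrix[1], np.cos(2 * np.pi * 10.0 * t))

    def test_rows_orthogonal_over_integer_cycles(self):
        tpl = build_reference(10.0, 3, 2500, 500.0)
        gram = tpl.matrix @ tpl.matrix.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * 2500

    def test_single_harmonic(self):
        assert build_reference(10.0, 1, 100, 500.0).matrix.shape == (2, 100)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            build_reference(100.0, 3, 1000, 500.0)


def _normal_equation_rho(x, y):
    """Independent oracle: largest root of the CCA eigenproblem solved from
    covariance matrices (the textbook normal-equations route)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    cxx = xc @ xc.T
    cyy = yc @ yc.T
    cxy = xc @ yc.T
    m = np.linalg.solve(cxx, cxy) @ np.linalg.solve(cyy, cxy.T)
    eig = np.linalg.eigvals(m)
    return float(np.sqrt(np.max(eig.real)))


class TestCCA:
    def test_self_template_has_unit_correlation(self):
        tpl = build_reference(8.57, 3, 2500, 500.0)
        assert cca_correlate(tpl.matrix, tpl) == pytest.approx(1.0, abs=1e-9)

    def test_clean_sinusoid_matches_own_template(self):
        t = np.arange(1, 2501) / 500.0
        x = np.sin(2 * np.pi * 8.57 * t + 0.7)[None, :]
        tpl = build_reference(8.57, 3, 2500, 500.0)
        assert cca_correlate(x, tpl) > 0.99

    def test_agrees_with_normal_equations_oracle(self, rng):
        x = rng.standard_normal((6, 800))
        tpl = build_reference(9.0, 2, 800, 500.0)
        rho = cca_correlate(x, tpl)
        assert rho == pytest.approx(_normal_equation_rho(x, tpl.matrix),
                                    abs=1e-8)

    def test_invariant_to_per_channel_affine_rescaling(self, rng):
        x = rng.standard_normal((8, 1000))
        tpl = build_reference(7.5, 3, 1000, 500.0)
        scaled = x * rng.uniform(0.2, 5.0, size=(8, 1))
        scaled += rng.uniform(-10.0, 10.0, size=(8, 1))
        assert cca_correlate(scaled, tpl) == pytest.approx(
            cca_correlate(x, tpl), abs=1e-8)

    def test_white_noise_below_permutation_null(self, rng):
        """Noise correlation stays under the 99th percentile of a
        time-shuffled permutation null."""
        x = rng.standard_normal((8, 2500))
        tpl = build_reference(10.0, 3, 2500, 500.0)
        rho = cca_correlate(x, tpl)
        null = np.empty(200)
        for i in range(200):
            perm = np.array([rng.permutation(row) for row in x])
            null[i] = cca_correlate(perm, tpl)
        assert rho < np.quantile(null, 0.99)

    def test_rank_deficient_input_warns_and_bounds(self, rng, caplog):
        x = rng.standard_normal((1, 600))
        x = np.vstack([x, x])  # duplicated channel: rank 1
        tpl = build_reference(10.0, 3, 600, 500.0)
        with caplog.at_level("WARNING"):
            rho = cca_correlate(x, tpl)
        assert "rank-deficient" in caplog.text
        assert 0.0 <= rho <= 1.0

    def test_window_shorter_than_variates_rejected(self):
        tpl = build_reference(10.0, 3, 10, 500.0)
        with pytest.raises(ValueError, match="too short"):
            cca_correlate(np.zeros((8, 10)), tpl)


class TestClassification:
    def test_argmax_and_tie_break(self, default_segments):
        results = classify_cca(default_segments[:4], [6.67, 7.5, 8.57, 10.0],
                               2.0)
        for r in results:
            assert r.detected_frequency == max(r.scores, key=r.scores.get)
        # exact ties resolve toward the lowest candidate frequency
        from ssveplab.detect import _argmax_lowest_tie
        assert _argmax_lowest_tie({10.0: 0.9, 7.5: 0.9, 8.57: 0.3}) == 7.5

    def test_accuracy_monotone_in_window_length(self, candidate_frequencies):
        """Longer analysis windows never hurt: the accuracy curve over
        window length rises on a default-condition 100-trial session."""
        from ssveplab.preprocess import (filter_recording, restrict_channels,
                                         segment_trials)
        from ssveplab.simulate import (POSTERIOR_CHANNELS, SimulationConfig,
                                       generate_session)
        rec = generate_session(SimulationConfig(), 25, seed=1)
        segs = restrict_channels(segment_trials(filter_recording(rec), 5.0),
                                 POSTERIOR_CHANNELS)
        accs = []
        for w in (1.0, 2.0, 3.0, 4.0, 5.0):
            res = classify_cca(segs, candidate_frequencies, w)
            accs.append(np.mean([r.correct for r in res]))
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))

    def test_psda_detects_on_default_session(self, default_segments,
                                             candidate_frequencies):
        res = classify_psda(default_segments, candidate_frequencies, 5.0)
        assert np.mean([r.correct for r in res]) > 0.9


class TestFilterBank:
    def test_weight_formula(self):
        bank = FilterBankConfig()
        w = bank.weights()
        assert w[0] == pytest.approx(1.25)
        assert w[1] == pytest.approx(2 ** -1.25 + 0.25)
        assert len(w) == 5

    def test_subband_layout(self):
        edges = FilterBankConfig().subband_edges()
        assert edges[0] == (6.0, 40.0) and edges[4] == (30.0, 40.0)
        for (lo1, _), (lo2, _) in zip(edges, edges[1:]):
            assert lo2 > lo1

    def test_invalid_bank_rejected(self):
        with pytest.raises(ValueError):
            FilterBankConfig(n_subbands=8).subband_edges()
        with pytest.raises(ValueError):
            # Nyquist at 40 Hz cannot hold a 42 Hz filter edge
            FilterBankConfig().validate(80.0)

    def test_single_wide_subband_reduces_to_cca(self, default_segments,
                                                candidate_frequencies):
        """One subband covering the whole 4-40 Hz band ranks like plain CCA."""
        bank = FilterBankConfig(n_subbands=1, start_spacing_hz=4.0,
                                weight_a=0.0, weight_b=0.0)  # w(1) = 1
        segs = default_segments[:12]
        fb = fbcca_classify(segs, candidate_frequencies, 3.0, bank=bank)
        plain = classify_cca(segs, candidate_frequencies, 3.0)
        for a, b in zip(fb, plain):
            assert a.detected_frequency == b.detected_frequency
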