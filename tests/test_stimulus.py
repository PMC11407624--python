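"""Frame-pattern enumeration, square-wave spectra, geometry, stimulus SNR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssveplab.stimulus import (DUTY_BINS, FrequencyUnrealizableError,
                               NoPatternError, design_frame_pattern,
                               enumerate_duty_bins, frames_per_cycle,
                               icon_visual_angle, square_wave_spectrum,
                               stimulus_snr, visual_angle)

# The published duty-cycle table for the four flicker frequencies at 60 fps:
# frequency -> frames per cycle and the (on, off) -> rounded-percent entries
# that fall in the four bins.
DUTY_TABLE = {
    6.67: (9, {(2, 7): 22, (3, 6): 33, (5, 4): 56, (6, 3): 67}),
    7.5: (8, {(2, 6): 25, (3, 5): 38, (4, 4): 50, (5, 3): 63}),
    8.57: (7, {(1, 6): 14, (2, 5): 29, (4, 3): 57, (5, 2): 71}),
    10.0: (6, {(1, 5): 17, (2, 4): 33, (3, 3): 50, (4, 2): 67}),
}


class TestFramePatterns:
    @pytest.mark.parametrize("freq,expected", DUTY_TABLE.items())
    def test_duty_table_reproduced(self, freq, expected):
        """Every binned on/off split matches the published table exactly."""
        n_frames, entries = expected
        patterns = enumerate_duty_bins(freq, 60.0)
        assert patterns[0].frames_per_cycle == n_frames
        binned = {(p.on_frames, p.off_frames): p.duty_cycle_pct
                  for p in patterns if p.bin_label is not None}
        assert binned == entries

    @pytest.mark.parametrize("freq,on,off,pct", [
        (6.67, 5, 4, 56),   # nine-frame cycle cannot reach 50% exactly
        (10.0, 3, 3, 50),
        (15.0, 2, 2, 50),
    ])
    def test_reference_bin_patterns(self, freq, on, off, pct):
        p = design_frame_pattern(freq, 60.0, "45-57")
        assert (p.on_frames, p.off_frames, p.duty_cycle_pct) == (on, off, pct)
        assert p.bin_label == "45-57"

    def test_on_frames_lead_the_cycle(self):
        p = design_frame_pattern(6.67, 60.0, "45-57")
        assert p.frame_sequence.tolist() == [1, 1, 1, 1, 1, 0, 0, 0, 0]
        assert p.render(2).sum() == 2 * p.on_frames

    def test_unrealizable_frequency_rejected(self):
        with pytest.raises(FrequencyUnrealizableError):
            frames_per_cycle(11.0, 60.0)

    def test_nominal_frequencies_accepted(self):
        # 60/9 = 6.667 Hz is printed as 6.67 Hz; both must map to 9 frames
        assert frames_per_cycle(6.67, 60.0) == 9
        assert frames_per_cycle(60.0 / 9.0, 60.0) == 9

    def test_empty_bin_raises(self):
        # a 2-frame cycle only realizes 50%, so the lowest bin is empty
        with pytest.raises(NoPatternError):
            design_frame_pattern(30.0, 60.0, "14-25")

    def test_single_frame_cycle_has_no_split(self):
        with pytest.raises(NoPatternError):
            enumerate_duty_bins(60.0, 60.0)

    def test_unbinned_splits_reported(self):
        labels = {(p.on_frames, p.off_frames): p.bin_label
                  for p in enumerate_duty_bins(8.57, 60.0)}
        assert labels[(3, 4)] is None and labels[(6, 1)] is None

    @given(n=st.integers(2, 24), on=st.integers(1, 23))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_enumeration_invariants(self, n, on):
        """Splits partition the cycle and round half-up into closed bins."""
        if on >= n:
            return
        fps = 120.0
        patterns = enumerate_duty_bins(fps / n, fps)
        assert len(patterns) == n - 1
        p = patterns[on - 1]
        assert p.on_frames + p.off_frames == p.frames_per_cycle == n
        assert p.duty_cycle_pct == math.floor(100.0 * on / n + 0.5)
        assert p.frame_sequence.sum() == p.on_frames
        if p.bin_label is not None:
            lo, hi = DUTY_BINS[p.bin_label]
            assert lo <= p.duty_cycle_pct <= hi


class TestSquareWaveSpectrum:
    @pytest.mark.parametrize("duty", [round(0.1 * k, 1) for k in range(1, 10)])
    def test_matches_dense_fft_oracle(self, duty):
        """Fourier amplitudes agree with the FFT of the sampled waveform.

        The oracle samples one period on a grid where the duty cycle is an
        exact sample count, dense enough that discretization error is far
        below the comparison tolerance.
        """
        n = 10 * 65536
        spec = square_wave_spectrum(duty, 12)
        wave = (np.arange(n) < duty * n).astype(float)
        fft_amp = 2.0 * np.abs(np.fft.rfft(wave)[1:13]) / n
        assert np.allclose(spec.harmonic_amplitudes, fft_amp,
                           rtol=1e-6, atol=1e-9)
        assert spec.dc_term == pytest.approx(np.mean(wave), rel=1e-9)

    def test_even_harmonics_vanish_at_half_duty(self):
        spec = square_wave_spectrum(0.5, 10)
        assert np.all(np.abs(spec.harmonic_amplitudes[1::2]) < 1e-12)
        # odd harmonics follow 2/(n pi)
        odd = np.arange(1, 10, 2)
        assert np.allclose(spec.harmonic_amplitudes[0::2], 2.0 / (odd * np.pi))
        assert spec.offset == pytest.approx(0.0)

    def test_full_duty_is_constant(self):
        spec = square_wave_spectrum(1.0, 8)
        assert np.all(np.abs(spec.harmonic_amplitudes) < 1e-12)
        assert spec.dc_term == pytest.approx(1.0)

    def test_quarter_duty_kills_fourth_harmonic(self):
        spec = square_wave_spectrum(0.25, 8)
        assert abs(spec.amplitude(4)) < 1e-12
        assert abs(spec.amplitude(8)) < 1e-12

    @pytest.mark.parametrize("duty", [0.0, -0.1, 1.2])
    def test_domain_errors(self, duty):
        with pytest.raises(ValueError):
            square_wave_spectrum(duty)


class TestVisualAngle:
    @pytest.mark.parametrize("area,expected", [
        (5.06, 1.35), (20.25, 2.69), (36.0, 3.6), (81.0, 5.38),
    ])
    def test_icon_sizes_at_95cm(self, area, expected):
        """The four icon areas subtend the published angles at 95 cm."""
        assert icon_visual_angle(area, 95.0) == pytest.approx(expected,
                                                              abs=0.04)

    def test_trivial_angles(self):
        assert visual_angle(0.0, 95.0) == 0.0
        assert visual_angle(95.0, 95.0) == pytest.approx(45.0)

    @given(st.floats(0.1, 500.0), st.floats(0.1, 500.0),
           st.floats(10.0, 300.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_size_inverse_in_distance(self, a, b, d):
        lo, hi = sorted((a, b))
        assert visual_angle(lo, d) <= visual_angle(hi, d)
        assert visual_angle(hi, d) >= visual_angle(hi, d + 10.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            visual_angle(10.0, 0.0)
        with pytest.raises(ValueError):
            visual_angle(-1.0, 95.0)


class TestStimulusSNR:
    FS = 500.0
    F = 60.0 / 9.0  # frame-realized 6.67 Hz

    def _trace(self, seed, target_db, duration_s=40.0, harmonic_db=None):
        """Tone + white noise with a known bin-power ratio on the SNR grid."""
        rng = np.random.default_rng(seed)
        t = np.arange(int(self.FS * duration_s)) / self.FS
        df = self.F / round(4.0 * self.F)
        noise_psd = 2.0 / self.FS  # one-sided density of unit white noise
        amp = math.sqrt(2.0 * 10 ** (target_db / 10.0) * noise_psd * df)
        x = amp * np.sin(2 * np.pi * self.F * t) + rng.standard_normal(len(t))
        if harmonic_db is not None:
            amp2 = math.sqrt(2.0 * 10 ** (harmonic_db / 10.0) * noise_psd * df)
            x += amp2 * np.sin(2 * np.pi * 2 * self.F * t)
        return x

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_injected_ratio(self, seed):
        """A 30 dB injected tone/noise bin ratio is read back within 2 dB."""
        rep = stimulus_snr(self._trace(seed, 30.0), self.FS, self.F)
        assert rep.fundamental_snr_db == pytest.approx(30.0, abs=2.0)
        assert rep.classification == "low"

    def test_high_snr_stimulus_classified_high(self):
        rep = stimulus_snr(self._trace(3, 70.0, harmonic_db=55.0),
                           self.FS, self.F)
        assert rep.fundamental_snr_db == pytest.approx(70.0, abs=2.0)
        assert rep.second_harmonic_snr_db == pytest.approx(55.0, abs=2.0)
        assert rep.classification == "high"

    def test_equal_tone_and_noise_power_reads_three_db(self):
        # the target bin carries tone plus its own noise floor, so an
        # injected 0 dB tone/noise ratio reads 10 log10(2) ~ 3 dB
        rep = stimulus_snr(self._trace(7, 0.0), self.FS, self.F)
        assert rep.fundamental_snr_db == pytest.approx(3.0, abs=2.0)

    def test_noiseless_tone_hits_documented_ceiling(self):
        t = np.arange(int(self.FS * 20)) / self.FS
        rep = stimulus_snr(np.sin(2 * np.pi * self.F * t), self.FS, self.F)
        assert rep.fundamental_snr_db == 120.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="0.25 Hz"):
            stimulus_snr(np.zeros(int(2 * self.FS)), self.FS, self.F)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="harmonic"):
            stimulus_snr(np.zeros(10000), 25.0, self.F)
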