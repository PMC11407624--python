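"""SSVEP frequency detection: PSDA, CCA and filter-bank CCA.

PSDA scores a trial by a narrow-band spectral SNR: with a Welch power
spectrum y on a 0.25 Hz grid,

    SNR(f) = 6 y(f) / sum_{k=1..3} [y(f + 0.25k) + y(f - 0.25k)]
           + 6 y(2f) / sum_{k=1..3} [y(2f + 0.25k) + y(2f - 0.25k)],

i.e. the power at the fundamental and 2nd harmonic each relative to the mean
of their six nearest neighbor bins.  CCA scores a trial by the largest
canonical correlation between the multi-channel EEG window and a reference
template of sines/cosines at the candidate frequency and its harmonics;
FBCCA repeats the CCA per filter-bank subband and combines the squared
correlations with decaying weights.  In every method the candidate with the
highest score is the detected frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal as sps

if TYPE_CHECKING:  # segments are duck-typed: .stimulation/.trial_id/.true_frequency
    from .preprocess import TrialSegment

__all__ = [
    "PowerSpectrum",
    "ReferenceTemplate",
    "DetectionResult",
    "FilterBankConfig",
    "ResolutionError",
    "welch_psd",
    "ssvep_snr",
    "build_reference",
    "cca_correlate",
    "classify_psda",
    "classify_cca",
    "fbcca_classify",
]

logger = logging.getLogger(__name__)

#: Ratio ceiling reported by ssvep_snr when every neighbor bin is zero.
SNR_RATIO_CEILING = 1e12


class ResolutionError(ValueError):
    """The window is too short for the required spectral resolution."""


@dataclass(frozen=True)
class PowerSpectrum:
    """Per-channel Welch power spectral density on a uniform frequency grid."""

    freqs: np.ndarray          # (n_bins,)
    power: np.ndarray          # (n_channels, n_bins)

    @property
    def bin_spacing(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(window: np.ndarray, sampling_rate: float,
              resolution: float = 0.25,
              segment_length_s: float = 4.0) -> PowerSpectrum:
    """Welch PSD with Hann segments, 50% overlap, on a ``resolution`` grid.

    Segments are ``segment_length_s`` long (truncated to the window when it
    is shorter) and zero-padded so the grid spacing is at most
    ``resolution``.  The neighbor-bin SNR statistic needs its six noise
    bins at +-0.25..0.75 Hz to sit outside the segment mainlobe, which the
    4 s default provides; 1 s segments (coarser but lower-variance) remain
    available for broadband spectral estimates.
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    if x.shape[1] < int(round(sampling_rate)):
        raise ResolutionError("window must be at least 1 s long")
    nper = min(int(round(segment_length_s * sampling_rate)), x.shape[1])
    nfft = max(int(math.ceil(sampling_rate / resolution)), nper)
    freqs, power = sps.welch(x, fs=sampling_rate, window="hann",
                             nperseg=nper, noverlap=nper // 2, nfft=nfft,
                             detrend="constant", axis=-1)
    return PowerSpectrum(freqs=freqs, power=power)


def _neighbor_ratio(power: np.ndarray, freqs: np.ndarray, f: float,
                    step: float = 0.25) -> np.ndarray:
    """Per-channel 6 y(f) / sum of the six +-0.25k Hz neighbors.

    ``f`` is mapped to the nearest grid bin (the nominal frame-realized
    frequencies, e.g. 6.67 Hz, need not be exact multiples of 0.25 Hz).
    """
    df = freqs[1] - freqs[0]
    i = int(round(f / df))
    k = int(round(step / df))
    if k < 1:
        raise ValueError(f"spectral grid spacing {df} Hz coarser than {step} Hz")
    if i - 3 * k < 0 or i + 3 * k >= len(freqs):
        raise ValueError(f"{f} Hz too close to the spectrum edge")
    idx = [i - 3 * k, i - 2 * k, i - k, i + k, i + 2 * k, i + 3 * k]
    num = 6.0 * power[:, i]
    den = power[:, idx].sum(axis=1)
    out = np.full_like(num, SNR_RATIO_CEILING)
    ok = den > 0
    out[ok] = np.minimum(num[ok] / den[ok], SNR_RATIO_CEILING)
    out[~ok & (num <= 0)] = 0.0
    return out


def ssvep_snr(spectrum: PowerSpectrum, target_frequency: float,
              per_channel: bool = False) -> np.ndarray | float:
    """Narrow-band SSVEP SNR at the fundamental plus the 2nd harmonic.

    Returns the channel mean by default, or the per-channel vector.  On a
    perfectly flat spectrum both terms equal 1 and the value is 2.
    """
    snr = (_neighbor_ratio(spectrum.power, spectrum.freqs, target_frequency)
           + _neighbor_ratio(spectrum.power, spectrum.freqs,
                             2.0 * target_frequency))
    return snr if per_channel else float(snr.mean())


def ssvep_snr_db(spectrum: PowerSpectrum, target_frequency: float) -> float:
    """Channel-mean SSVEP SNR expressed in dB."""
    return 10.0 * math.log10(max(ssvep_snr(spectrum, target_frequency), 1e-300))


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceTemplate:
    """Sin/cos reference set for one candidate frequency.

    Rows are sin(2 pi n f t), cos(2 pi n f t) for n = 1..n_harmonics with
    t = 1/fs, 2/fs, ..., N/fs.
    """

    frequency: float
    n_harmonics: int
    n_samples: int
    sampling_rate: float
    matrix: np.ndarray = field(repr=False)   # (2 n_harmonics, n_samples)


def build_reference(frequency: float, n_harmonics: int, n_samples: int,
                    sampling_rate: float) -> ReferenceTemplate:
    """Reference template at ``frequency`` and its harmonics (default use: 3)."""
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    if n_harmonics * frequency >= sampling_rate / 2.0:
        raise ValueError(
            f"harmonic {n_harmonics}x{frequency} Hz at or above Nyquist")
    t = np.arange(1, n_samples + 1) / sampling_rate
    rows = []
    for n in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * n * frequency * t
        rows.append(np.sin(w))
        rows.append(np.cos(w))
    return ReferenceTemplate(frequency=float(frequency),
                             n_harmonics=n_harmonics, n_samples=n_samples,
                             sampling_rate=float(sampling_rate),
                             matrix=np.vstack(rows))


def _orth_basis(a: np.ndarray) -> tuple[np.ndarray, bool]:
    """Orthonormal column basis of ``a`` via SVD with a rank tolerance."""
    u, s, _ = np.linalg.svd(a, full_matrices=False)
    tol = max(a.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    return u[:, :rank], rank < min(a.shape)


def cca_correlate(eeg_window: np.ndarray, template: ReferenceTemplate) -> float:
    """Largest canonical correlation between an EEG window and a template.

    Both variable sets are mean-centered; the correlation is the leading
    singular value of the product of their orthonormal bases, so it lies in
    [0, 1] by construction.  Rank-deficient inputs are handled by dropping
    null directions (logged).
    """
    x = np.asarray(eeg_window, dtype=float)
    y = template.matrix
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1]
    if y.shape[1] != n:
        raise ValueError("EEG window and template lengths differ")
    if n <= x.shape[0] + y.shape[0]:
        raise ValueError("window too short for the number of variates")
    xc = (x - x.mean(axis=1, keepdims=True)).T     # n x ch
    yc = (y - y.mean(axis=1, keepdims=True)).T     # n x 2Nh
    qx, x_def = _orth_basis(xc)
    qy, y_def = _orth_basis(yc)
    if x_def or y_def:
        logger.warning("rank-deficient CCA input; solving on the reduced space")
    if qx.shape[1] == 0 or qy.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionResult:
    """Per-trial candidate scores and the winning frequency."""

    trial_id: int
    true_frequency: float
    scores: dict[float, float]
    detected_frequency: float
    method: str
    window_length_s: float

    @property
    def correct(self) -> bool:
        return self.detected_frequency == self.true_frequency


def _argmax_lowest_tie(scores: dict[float, float]) -> float:
    """Winning candidate; exact ties resolve to the lowest frequency."""
    best = max(scores.values())
    return min(f for f, s in scores.items() if s == best)


def _stim_window(segment: TrialSegment, window_length_s: float,
                 sampling_rate: float) -> np.ndarray:
    n = int(round(window_length_s * sampling_rate))
    if n > segment.stimulation.shape[1]:
        raise ValueError(
            f"trial {segment.trial_id}: window {window_length_s} s exceeds "
            "the stimulation span")
    return segment.stimulation[:, :n]


def classify_psda(segments: list[TrialSegment],
                  candidate_frequencies: list[float],
                  window_length_s: float,
                  sampling_rate: float | None = None) -> list[DetectionResult]:
    """Detect by the largest channel-mean SSVEP SNR among the candidates."""
    if sampling_rate is None:
        sampling_rate = segments[0].sampling_rate
    results = []
    for seg in segments:
        spectrum = welch_psd(_stim_window(seg, window_length_s, sampling_rate),
                             sampling_rate)
        scores = {f: ssvep_snr(spectrum, f) for f in candidate_frequencies}
        results.append(DetectionResult(
            trial_id=seg.trial_id, true_frequency=seg.true_frequency,
            scores=scores, detected_frequency=_argmax_lowest_tie(scores),
            method="psda", window_length_s=window_length_s))
    return results


def classify_cca(segments: list[TrialSegment],
                 candidate_frequencies: list[float],
                 window_length_s: float,
                 sampling_rate: float | None = None,
                 n_harmonics: int = 3) -> list[DetectionResult]:
    """Detect by the largest canonical correlation among the candidates."""
    if sampling_rate is None:
        sampling_rate = segments[0].sampling_rate
    n = int(round(window_length_s * sampling_rate))
    templates = {f: build_reference(f, n_harmonics, n, sampling_rate)
                 for f in candidate_frequencies}
    results = []
    for seg in segments:
        window = _stim_window(seg, window_length_s, sampling_rate)
        scores = {f: cca_correlate(window, tpl)
                  for f, tpl in templates.items()}
        results.append(DetectionResult(
            trial_id=seg.trial_id, true_frequency=seg.true_frequency,
            scores=scores, detected_frequency=_argmax_lowest_tie(scores),
            method="cca", window_length_s=window_length_s))
    return results


@dataclass(frozen=True)
class FilterBankConfig:
    """Subband layout and weights for filter-bank CCA.

    Subband n spans [n * start_spacing_hz, upper_edge_hz]; the realized
    band-pass adds ``transition_hz`` on both sides.  Weights follow
    w(n) = n^-a + b.
    """

    n_subbands: int = 5
    start_spacing_hz: float = 6.0
    upper_edge_hz: float = 40.0
    transition_hz: float = 2.0
    weight_a: float = 1.25
    weight_b: float = 0.25
    ripple_db: float = 0.5
    order: int = 4

    def subband_edges(self) -> list[tuple[float, float]]:
        edges = []
        for n in range(1, self.n_subbands + 1):
            lo = n * self.start_spacing_hz
            if lo >= self.upper_edge_hz:
                raise ValueError(
                    f"subband {n} start {lo} Hz reaches the upper edge")
            edges.append((lo, self.upper_edge_hz))
        return edges

    def weights(self) -> np.ndarray:
        n = np.arange(1, self.n_subbands + 1, dtype=float)
        return n ** (-self.weight_a) + self.weight_b

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        for lo, hi in self.subband_edges():
            if hi + self.transition_hz >= nyq or lo <= 0:
                raise ValueError("filter bank exceeds the valid band")


def _subband_filter(lo: float, hi: float, bank: FilterBankConfig,
                    sampling_rate: float) -> np.ndarray:
    pass_lo = max(lo - bank.transition_hz, 0.5)
    pass_hi = min(hi + bank.transition_hz, 0.99 * sampling_rate / 2.0)
    return sps.cheby1(bank.order, bank.ripple_db, [pass_lo, pass_hi],
                      btype="bandpass", fs=sampling_rate, output="sos")


def fbcca_classify(segments: list[TrialSegment],
                   candidate_frequencies: list[float],
                   window_length_s: float,
                   sampling_rate: float | None = None,
                   bank: FilterBankConfig | None = None,
                   n_harmonics: int = 3) -> list[DetectionResult]:
    """Filter-bank CCA: weighted sum of squared subband correlations.

    Each subband is extracted with a zero-phase Chebyshev type-I band-pass
    (2 Hz transition margin on both sides) and scored with plain CCA; the
    combined score for candidate i is sum_n w(n) rho_{n,i}^2.
    """
    if sampling_rate is None:
        sampling_rate = segments[0].sampling_rate
    bank = bank or FilterBankConfig()
    bank.validate(sampling_rate)
    weights = bank.weights()
    sos_list = [_subband_filter(lo, hi, bank, sampling_rate)
                for lo, hi in bank.subband_edges()]
    n = int(round(window_length_s * sampling_rate))
    templates = {f: build_reference(f, n_harmonics, n, sampling_rate)
                 for f in candidate_frequencies}
    results = []
    for seg in segments:
        window = _stim_window(seg, window_length_s, sampling_rate)
        subbands = [sps.sosfiltfilt(sos, window, axis=-1) for sos in sos_list]
        scores = {}
        for f, tpl in templates.items():
            rho2 = np.array([cca_correlate(sb, tpl) ** 2 for sb in subbands])
            scores[f] = float(np.dot(weights, rho2))
        results.append(DetectionResult(
            trial_id=seg.trial_id, true_frequency=seg.true_frequency,
            scores=scores, detected_frequency=_argmax_lowest_tie(scores),
            method="fbcca", window_length_s=window_length_s))
    return results
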