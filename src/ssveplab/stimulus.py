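"""Frame-based flicker stimulus design.

A display running at a fixed picture frame rate (PFR) can only realize flicker
frequencies whose period is a whole number of frames, and only duty cycles that
are whole-frame ON/OFF splits of that period.  This module enumerates those
realizable patterns, groups their duty cycles into the four bins used for the
stimulus-property comparisons ([14-25], [28-38], [45-57], [62-72] percent),
computes the Fourier amplitude spectrum of the resulting rectangular wave,
converts icon sizes and offsets into visual angles, and measures the spectral
SNR of a rendered stimulus from a photodiode luminance trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "DUTY_BINS",
    "FlickerPattern",
    "SquareWaveSpectrum",
    "StimulusLayout",
    "StimulusSNRReport",
    "FrequencyUnrealizableError",
    "NoPatternError",
    "frames_per_cycle",
    "design_frame_pattern",
    "enumerate_duty_bins",
    "square_wave_spectrum",
    "visual_angle",
    "icon_visual_angle",
    "stimulus_snr",
]

#: Duty-cycle bins (closed intervals on the rounded integer percentage).
DUTY_BINS: dict[str, tuple[int, int]] = {
    "14-25": (14, 25),
    "28-38": (28, 38),
    "45-57": (45, 57),
    "62-72": (62, 72),
}

#: dB ceiling reported when the noise floor of a luminance trace is zero.
SNR_DB_CEILING = 120.0


class FrequencyUnrealizableError(ValueError):
    """The target frequency has no whole-frame period at the given frame rate."""


class NoPatternError(ValueError):
    """No ON/OFF frame split satisfies the request."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _bin_for(duty_pct: int) -> str | None:
    for label, (lo, hi) in DUTY_BINS.items():
        if lo <= duty_pct <= hi:
            return label
    return None


@dataclass(frozen=True)
class FlickerPattern:
    """One frame-exact realization of a flicker frequency.

    ON frames lead the cycle; the pattern repeats every ``frames_per_cycle``
    frames, i.e. every ``frames_per_cycle / frame_rate`` seconds.
    """

    target_frequency: float
    frame_rate: float
    frames_per_cycle: int
    on_frames: int
    off_frames: int
    duty_cycle_pct: int
    bin_label: str | None
    frame_sequence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.on_frames + self.off_frames != self.frames_per_cycle:
            raise ValueError("on_frames + off_frames must equal frames_per_cycle")
        if not 1 <= self.on_frames <= self.frames_per_cycle - 1:
            raise ValueError("on_frames must be in [1, frames_per_cycle - 1]")
        if int(self.frame_sequence.sum()) != self.on_frames:
            raise ValueError("frame_sequence must sum to on_frames")

    @property
    def duty_cycle(self) -> float:
        """Exact (unrounded) duty cycle as a fraction."""
        return self.on_frames / self.frames_per_cycle

    def render(self, n_cycles: int = 1) -> np.ndarray:
        """Binary per-frame sequence over ``n_cycles`` repetitions."""
        return np.tile(self.frame_sequence, n_cycles)


def frames_per_cycle(target_frequency: float, frame_rate: float,
                     rel_tol: float = 0.01) -> int:
    """Whole-frame period of ``target_frequency`` at ``frame_rate``.

    Nominal frequencies are accepted: 6.67 Hz at 60 fps maps to 9 frames
    (60/9 = 6.667 Hz) within ``rel_tol`` relative error.
    """
    if target_frequency <= 0 or frame_rate <= 0:
        raise FrequencyUnrealizableError("frequency and frame rate must be positive")
    n = _round_half_up(frame_rate / target_frequency)
    if n < 1:
        raise FrequencyUnrealizableError(
            f"{target_frequency} Hz exceeds the frame rate {frame_rate} fps")
    realized = frame_rate / n
    if abs(realized - target_frequency) / target_frequency > rel_tol:
        raise FrequencyUnrealizableError(
            f"{target_frequency} Hz is not realizable at {frame_rate} fps "
            f"(nearest whole-frame frequency is {realized:.3f} Hz)")
    return n


def _make_pattern(target_frequency: float, frame_rate: float,
                  n: int, on: int) -> FlickerPattern:
    seq = np.zeros(n, dtype=np.int8)
    seq[:on] = 1  # ON block leads the cycle
    pct = _round_half_up(100.0 * on / n)
    return FlickerPattern(
        target_frequency=target_frequency,
        frame_rate=frame_rate,
        frames_per_cycle=n,
        on_frames=on,
        off_frames=n - on,
        duty_cycle_pct=pct,
        bin_label=_bin_for(pct),
        frame_sequence=seq,
    )


def enumerate_duty_bins(target_frequency: float,
                        frame_rate: float) -> list[FlickerPattern]:
    """All ON/OFF splits of one flicker cycle, with duty-cycle bin labels.

    Splits whose rounded duty percentage falls outside every bin carry
    ``bin_label=None`` (reported as unbinned).
    """
    n = frames_per_cycle(target_frequency, frame_rate)
    if n < 2:
        raise NoPatternError(
            f"a {n}-frame cycle admits no ON/OFF split")
    return [_make_pattern(target_frequency, frame_rate, n, on)
            for on in range(1, n)]


def design_frame_pattern(target_frequency: float, frame_rate: float,
                         requested_bin: str) -> FlickerPattern:
    """The achievable pattern whose rounded duty cycle lies in ``requested_bin``.

    ``requested_bin`` is a bin label ("45-57") or a (lo, hi) percentage pair.
    If several splits fall in the bin, the one closest to the bin midpoint is
    returned (ties toward the lower duty cycle); for the four canonical bins
    at the frequencies of interest the pattern is unique.
    """
    if isinstance(requested_bin, str):
        key = requested_bin.replace("%", "").replace("[", "").replace("]", "")
        key = key.replace("–", "-").strip()
        if key not in DUTY_BINS:
            raise NoPatternError(f"unknown duty-cycle bin {requested_bin!r}")
        lo, hi = DUTY_BINS[key]
    else:
        lo, hi = requested_bin
    candidates = [p for p in enumerate_duty_bins(target_frequency, frame_rate)
                  if lo <= p.duty_cycle_pct <= hi]
    if not candidates:
        raise NoPatternError(
            f"no ON/OFF split of {target_frequency} Hz at {frame_rate} fps "
            f"has a duty cycle in [{lo}-{hi}%]")
    mid = (lo + hi) / 2.0
    return min(candidates, key=lambda p: (abs(p.duty_cycle_pct - mid),
                                          p.duty_cycle_pct))


# ---------------------------------------------------------------------------
# Rectangular-wave Fourier spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SquareWaveSpectrum:
    """Fourier amplitudes of a unit rectangular wave with a given duty cycle.

    For a 0/1 pulse train with duty cycle ``d`` (period ``2L``, ON time
    ``L + offset``), the DC level is ``a0/2 = d`` and harmonic ``n`` has
    amplitude ``|c_n| = (2 / n pi) |sin(n pi d)|``.  At d = 0.5 the even
    harmonics vanish; at d = 1 the wave is constant and every harmonic is 0.
    """

    duty_cycle: float
    dc_term: float
    harmonic_amplitudes: np.ndarray = field(repr=False)
    half_period: float = 0.5
    offset: float = 0.0

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonic_amplitudes)

    def amplitude(self, n: int) -> float:
        """Amplitude of harmonic ``n`` (1-based)."""
        return float(self.harmonic_amplitudes[n - 1])


def square_wave_spectrum(duty_cycle: float, n_harmonics: int = 10,
                         half_period: float = 0.5) -> SquareWaveSpectrum:
    """Fourier amplitude spectrum of a 0/1 rectangular wave.

    Parameters
    ----------
    duty_cycle : fraction in (0, 1].
    n_harmonics : number of harmonics (1..n) to evaluate.
    half_period : L; the waveform period is 2L (amplitudes are independent
        of L, which only fixes the frequency axis).
    """
    if not 0.0 < duty_cycle <= 1.0:
        raise ValueError(f"duty cycle must be in (0, 1], got {duty_cycle}")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    n = np.arange(1, n_harmonics + 1)
    amps = (2.0 / (n * np.pi)) * np.abs(np.sin(n * np.pi * duty_cycle))
    # ON time = L + offset, so offset = (2 d - 1) L; offset 0 <=> 50% duty.
    offset = (2.0 * duty_cycle - 1.0) * half_period
    return SquareWaveSpectrum(
        duty_cycle=float(duty_cycle),
        dc_term=float(duty_cycle),
        harmonic_amplitudes=amps,
        half_period=float(half_period),
        offset=float(offset),
    )


# ---------------------------------------------------------------------------
# Viewing geometry
# ---------------------------------------------------------------------------

def visual_angle(size_or_offset: float, viewer_distance: float) -> float:
    """Angle in degrees subtended by ``size_or_offset`` at ``viewer_distance``.

    Both lengths share a unit (cm here).  Used for the eccentricity of an
    icon center offset d2 viewed from distance d1, and for the full-side
    angle of a square icon.
    """
    if viewer_distance <= 0:
        raise ValueError("viewer distance must be positive")
    if size_or_offset < 0:
        raise ValueError("size/offset must be non-negative")
    return math.degrees(math.atan(size_or_offset / viewer_distance))


def icon_visual_angle(area_cm2: float, viewer_distance_cm: float) -> float:
    """Subtended angle of a square icon given its area in cm^2."""
    if area_cm2 < 0:
        raise ValueError("icon area must be non-negative")
    return visual_angle(math.sqrt(area_cm2), viewer_distance_cm)


@dataclass(frozen=True)
class IconPlacement:
    label: str
    offset_cm: float          # d2: center offset from the fixation point
    area_cm2: float


@dataclass(frozen=True)
class StimulusLayout:
    """Geometry of an icon array viewed from distance d1.

    Eccentricity of each icon is atan(d2/d1) and its subtended angle is
    atan(side/d1) with side = sqrt(area); both grow with the length and
    shrink with the distance.
    """

    viewer_distance_cm: float                      # d1
    icons: tuple[IconPlacement, ...]
    array_configuration: str = "1x4"               # "1x4" or "2x2"
    location: str = "center"                       # "center" or "bottom"

    def __post_init__(self) -> None:
        if self.viewer_distance_cm <= 0:
            raise ValueError("viewer distance must be positive")

    def eccentricities_deg(self) -> dict[str, float]:
        return {i.label: visual_angle(i.offset_cm, self.viewer_distance_cm)
                for i in self.icons}

    def icon_angles_deg(self) -> dict[str, float]:
        return {i.label: icon_visual_angle(i.area_cm2, self.viewer_distance_cm)
                for i in self.icons}


# ---------------------------------------------------------------------------
# Stimulus SNR from a luminance trace
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSNRReport:
    """Spectral SNR of a rendered flicker stimulus.

    ``snr_db = 10 log10(P_signal / P_noise)`` where the signal power is the
    PSD at the target (or 2nd-harmonic) bin and the noise power is the mean
    of the six neighboring bins at +-0.25, +-0.5 and +-0.75 Hz.
    """

    target_frequency: float
    fundamental_snr_db: float
    second_harmonic_snr_db: float
    classification: str  # "low" or "high"


def _band_snr_db(psd: np.ndarray, center_bin: int) -> float:
    """10 log10 of the center-bin power over the mean of its six neighbors."""
    i = center_bin
    if i - 3 < 0 or i + 3 >= len(psd):
        raise ValueError("target too close to the spectrum edge")
    neighbors = psd[[i - 3, i - 2, i - 1, i + 1, i + 2, i + 3]]
    p_noise = float(np.mean(neighbors))
    p_signal = float(psd[i])
    if p_noise <= 0.0:
        return SNR_DB_CEILING
    return min(10.0 * math.log10(max(p_signal, 1e-300) / p_noise),
               SNR_DB_CEILING)


def stimulus_snr(luminance_trace: np.ndarray, sampling_rate: float,
                 target_frequency: float,
                 high_snr_threshold_db: float = 50.0) -> StimulusSNRReport:
    """Measure the SNR of a stimulus luminance trace at f and 2f.

    Power is estimated by Welch's method with 50%-overlapping rectangular
    segments whose length is the whole number of stimulus periods nearest
    4 s, so the target frequency (and its 2nd harmonic) fall exactly on a
    spectral bin of spacing ~0.25 Hz and do not leak into the six
    neighboring noise bins.  Requires a sampling rate above twice the 2nd
    harmonic and at least one full segment (~4 s) of samples; frequencies
    not commensurate with the segment length are measured with residual
    scalloping leakage.
    """
    x = np.asarray(luminance_trace, dtype=float).ravel()
    if sampling_rate <= 4.0 * target_frequency:
        raise ValueError("sampling rate must exceed twice the 2nd harmonic")
    n_cycles = max(int(round(4.0 * target_frequency)), 4)
    nper = int(round(n_cycles / target_frequency * sampling_rate))
    if x.size < nper:
        raise ValueError(
            f"trace shorter than {nper / sampling_rate:.2f} s: cannot "
            "resolve the 0.25 Hz neighbor bins")
    freqs, psd = sps.welch(x, fs=sampling_rate, window="boxcar",
                           nperseg=nper, noverlap=nper // 2,
                           detrend="constant")
    df = freqs[1] - freqs[0]
    fund = _band_snr_db(psd, int(round(target_frequency / df)))
    harm = _band_snr_db(psd, int(round(2.0 * target_frequency / df)))
    cls = "high" if fund >= high_snr_threshold_db else "low"
    return StimulusSNRReport(
        target_frequency=float(target_frequency),
        fundamental_snr_db=fund,
        second_harmonic_snr_db=harm,
        classification=cls,
    )
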