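"""Synthetic multi-channel SSVEP EEG sessions.

Emulates the recording setup the detection pipeline assumes: a 16-channel
10-20 montage sampled at 500 Hz, trials consisting of a pre-stimulus idle
span, a 2 s cue, a 1 s fade, and 5 s of flicker during which a steady-state
response appears at the target frequency and its 2nd/3rd harmonics,
concentrated over occipital/parieto-occipital electrodes.  Background
activity is 1/f^gamma colored noise plus a narrow-band ~10 Hz alpha
intrusion and 60 Hz line interference.

Every random process is drawn from an independent, seeded stream keyed by
(master seed, trial index, process id).  Changing the stimulus-SNR or
attention condition therefore perturbs only the condition-specific
components: a low-SNR regeneration of a session is sample-exact paired with
its high-SNR counterpart everywhere except the stimulus-related additions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNELS_1020",
    "POSTERIOR_CHANNELS",
    "SimulationConfig",
    "Event",
    "EEGRecording",
    "generate_trial",
    "generate_session",
    "inject_condition",
]

#: The 16-electrode montage of the g.Nautilus cap used for this paradigm.
CHANNELS_1020 = ("Fz", "Cz", "CPz", "P1", "Pz", "P2", "PO3", "POz", "PO4",
                 "PO7", "PO8", "O1", "Oz", "O2", "TP9", "TP10")

#: The eight channels over visual cortex where SSVEP energy concentrates.
POSTERIOR_CHANNELS = ("PO3", "POz", "PO4", "PO7", "PO8", "O1", "Oz", "O2")

#: Default per-channel SSVEP gain: strong occipital/parieto-occipital,
#: moderate parietal, weak frontal/central/temporal.
DEFAULT_GAIN_MAP = {
    **{ch: 1.0 for ch in POSTERIOR_CHANNELS},
    "P1": 0.35, "Pz": 0.35, "P2": 0.35, "CPz": 0.35,
    "Fz": 0.1, "Cz": 0.1, "TP9": 0.1, "TP10": 0.1,
}

# Stream ids for the per-trial random substreams.
_BG, _ALPHA, _LINE, _SSVEP, _COND, _LAPSE = range(6)


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic SSVEP session.

    Amplitudes are in microvolts.  ``ssvep_amplitude`` is the fundamental
    amplitude on a gain-1.0 (occipital) channel; harmonics decay as
    ``harmonic_decay``.  ``background_scale`` is the RMS of the 1/f^gamma
    background per channel, ``alpha_amplitude`` the RMS of the ~10 Hz
    intrusion on a gain-1.0 channel, ``line_amplitude`` the 60 Hz sinusoid
    amplitude (all channels equally).
    """

    n_channels: int = 16
    sampling_rate: float = 500.0
    channel_labels: tuple[str, ...] = CHANNELS_1020
    target_frequencies: tuple[float, ...] = (6.67, 7.5, 8.57, 10.0)
    idle_s: float = 3.0
    cue_s: float = 2.0
    fade_s: float = 1.0
    flicker_s: float = 5.0
    ssvep_amplitude: float = 3.0
    harmonic_decay: tuple[float, float, float] = (1.0, 0.5, 0.25)
    channel_gain_map: dict = field(default_factory=lambda: dict(DEFAULT_GAIN_MAP))
    background_exponent: float = 1.5
    background_scale: float = 10.0
    alpha_amplitude: float = 4.0
    alpha_center_hz: float = 10.0
    alpha_bandwidth_hz: float = 1.0
    line_amplitude: float = 2.0
    line_frequency: float = 60.0
    stimulus_snr_condition: str = "high"
    competitor_amplitude: float = 2.0     # 10 Hz ambient component (low SNR)
    fundamental_retention: float = 0.5    # rendering-leak factor (low SNR)
    attention_lapse_prob: float = 0.0
    inattentive_factor: float = 0.2
    max_channel_lag_s: float = 0.010

    def __post_init__(self) -> None:
        if len(self.channel_labels) != self.n_channels:
            raise ConfigurationError("channel_labels length must equal n_channels")
        if self.stimulus_snr_condition not in ("high", "low"):
            raise ConfigurationError(
                f"unknown stimulus SNR condition {self.stimulus_snr_condition!r}")
        nyq = self.sampling_rate / 2.0
        n_h = len(self.harmonic_decay)
        for f in self.target_frequencies:
            if n_h * f >= nyq:
                raise ConfigurationError(
                    f"harmonic {n_h}x{f} Hz at or above Nyquist ({nyq} Hz)")
        if not 0.0 <= self.attention_lapse_prob <= 1.0:
            raise ConfigurationError("attention_lapse_prob must be in [0, 1]")

    @property
    def trial_duration_s(self) -> float:
        return self.idle_s + self.cue_s + self.fade_s + self.flicker_s

    @property
    def onset_offset_s(self) -> float:
        """Stimulation onset relative to the start of a trial."""
        return self.idle_s + self.cue_s + self.fade_s

    def gains(self) -> np.ndarray:
        return np.array([self.channel_gain_map.get(ch, 0.0)
                         for ch in self.channel_labels])

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_labels"] = list(self.channel_labels)
        d["target_frequencies"] = list(self.target_frequencies)
        d["harmonic_decay"] = list(self.harmonic_decay)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("channel_labels", "target_frequencies", "harmonic_decay"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class Event:
    onset_sample: int
    trial_id: int
    frequency: float
    inattentive: bool = False
    stimulus_snr: str = "high"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EEGRecording:
    """Multi-channel EEG in microvolts with stimulation event markers."""

    data: np.ndarray                   # channels x samples
    sampling_rate: float
    channel_labels: tuple[str, ...]
    events: list[Event]
    source_config: SimulationConfig | None = None
    seed: int | None = None
    n_trials_per_frequency: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data row count must match channel_labels")
        ids = [e.trial_id for e in self.events]
        if len(ids) != len(set(ids)):
            raise ValueError("event trial ids must be unique")
        flicker_s = (self.source_config.flicker_s
                     if self.source_config is not None else 5.0)
        stim = int(round(flicker_s * self.sampling_rate))
        for e in self.events:
            if e.onset_sample < 0 or e.onset_sample + stim > self.n_samples:
                raise ValueError(
                    f"trial {e.trial_id}: stimulation window exceeds the data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self, data: np.ndarray | None = None) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy() if data is None else data,
            sampling_rate=self.sampling_rate,
            channel_labels=self.channel_labels,
            events=list(self.events),
            source_config=self.source_config,
            seed=self.seed,
            n_trials_per_frequency=self.n_trials_per_frequency,
        )


# ---------------------------------------------------------------------------
# Noise and signal processes
# ---------------------------------------------------------------------------

def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   exponent: float, rms: float, f_floor: float = 1.0) -> np.ndarray:
    """1/f^exponent (power) noise, flattened below ``f_floor`` Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    hi = freqs >= f_floor
    shape[hi] = freqs[hi] ** (-exponent / 2.0)
    shape[~hi] = f_floor ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return x * (rms / s) if s > 0 else x


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      center: float, bandwidth: float, rms: float) -> np.ndarray:
    """Stochastic oscillation: white noise shaped by a Gaussian spectral bump."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = bandwidth / 2.0
    shape = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return x * (rms / s) if s > 0 else x


def _trial_rng(seed: int, trial_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, trial_index, stream])


def _render_trial(config: SimulationConfig, target_frequency: float,
                  seed: int, trial_index: int) -> tuple[np.ndarray, bool]:
    """One trial's channels x samples array and its inattentive flag."""
    fs = config.sampling_rate
    n = int(round(config.trial_duration_s * fs))
    n_ch = config.n_channels
    onset = int(round(config.onset_offset_s * fs))
    n_stim = int(round(config.flicker_s * fs))
    gains = config.gains()

    data = np.empty((n_ch, n))
    bg_rng = _trial_rng(seed, trial_index, _BG)
    alpha_rng = _trial_rng(seed, trial_index, _ALPHA)
    for c in range(n_ch):
        data[c] = _colored_noise(bg_rng, n, fs, config.background_exponent,
                                 config.background_scale)
        if config.alpha_amplitude > 0:
            data[c] += gains[c] * _narrowband_noise(
                alpha_rng, n, fs, config.alpha_center_hz,
                config.alpha_bandwidth_hz, config.alpha_amplitude)

    if config.line_amplitude > 0:
        line_rng = _trial_rng(seed, trial_index, _LINE)
        t = np.arange(n) / fs
        phase = line_rng.uniform(0, 2 * np.pi)
        data += config.line_amplitude * np.sin(
            2 * np.pi * config.line_frequency * t + phase)

    lapse_rng = _trial_rng(seed, trial_index, _LAPSE)
    inattentive = bool(lapse_rng.random() < config.attention_lapse_prob)
    att = config.inattentive_factor if inattentive else 1.0

    # Steady-state response during the flicker span only.
    ssvep_rng = _trial_rng(seed, trial_index, _SSVEP)
    t_stim = np.arange(n_stim) / fs
    lags = ssvep_rng.uniform(0.0, config.max_channel_lag_s, size=n_ch)
    phases = ssvep_rng.uniform(0, 2 * np.pi, size=len(config.harmonic_decay))

    low = config.stimulus_snr_condition == "low"
    cond_rng = _trial_rng(seed, trial_index, _COND)
    if low:
        r = config.fundamental_retention
        delta = cond_rng.uniform(0.15, 0.35)           # sideband jitter (Hz)
        side_amp_frac = np.sqrt(max(1.0 - r * r, 0.0) / 2.0)
        side_phases = cond_rng.uniform(0, 2 * np.pi, size=2)
        comp_phase = cond_rng.uniform(0, 2 * np.pi)

    amp0 = config.ssvep_amplitude * att
    if amp0 > 0:
        stim = np.zeros((n_ch, n_stim))
        for h, decay in enumerate(config.harmonic_decay, start=1):
            a = amp0 * decay
            # a weaker stimulus drives a weaker evoked response at every
            # harmonic; the leaked stimulus energy reappears as an
            # incoherent sideband pair around the fundamental
            a_fund = a * config.fundamental_retention if low else a
            for c in range(n_ch):
                if gains[c] == 0.0:
                    continue
                tt = t_stim - lags[c]
                stim[c] += gains[c] * a_fund * np.sin(
                    2 * np.pi * h * target_frequency * tt + phases[h - 1])
                if h == 1 and low:
                    # energy leaked into a jittered sideband pair
                    for s_i, sgn in enumerate((-1.0, 1.0)):
                        f_side = target_frequency + sgn * delta
                        stim[c] += gains[c] * a * side_amp_frac * np.sin(
                            2 * np.pi * f_side * tt + side_phases[s_i])
        data[:, onset:onset + n_stim] += stim
    if low and config.competitor_amplitude > 0:
        # persistent ~10 Hz ambient component during stimulation
        comp = config.competitor_amplitude * np.sin(
            2 * np.pi * 10.0 * t_stim + comp_phase)
        data[:, onset:onset + n_stim] += gains[:, None] * comp[None, :]

    return data, inattentive


def generate_trial(config: SimulationConfig, target_frequency: float,
                   seed: int) -> EEGRecording:
    """A single-trial recording with one stimulation event.

    The idle/cue/fade span carries background processes only; the flicker
    span adds sinusoids at f, 2f, 3f with per-channel gains, random phase
    and small per-channel lags.
    """
    if target_frequency not in config.target_frequencies:
        raise ConfigurationError(
            f"{target_frequency} Hz not in the configured target list")
    data, inatt = _render_trial(config, target_frequency, seed, trial_index=0)
    onset = int(round(config.onset_offset_s * config.sampling_rate))
    events = [Event(onset_sample=onset, trial_id=0, frequency=target_frequency,
                    inattentive=inatt,
                    stimulus_snr=config.stimulus_snr_condition)]
    return EEGRecording(data=data, sampling_rate=config.sampling_rate,
                        channel_labels=config.channel_labels, events=events,
                        source_config=config, seed=seed,
                        n_trials_per_frequency=1)


def generate_session(config: SimulationConfig, n_trials_per_frequency: int,
                     seed: int) -> EEGRecording:
    """A full session: blocks of all targets in seeded random order.

    Each block presents every target frequency once (shuffled), mirroring a
    set of cued trials; ``n_trials_per_frequency`` blocks are concatenated
    with each trial carrying its own pre-onset idle span.
    """
    if n_trials_per_frequency < 1:
        raise ConfigurationError("need at least one trial per frequency")
    order_rng = np.random.default_rng([seed, 987654321])
    freqs = list(config.target_frequencies)
    sequence: list[float] = []
    for _ in range(n_trials_per_frequency):
        block = list(freqs)
        order_rng.shuffle(block)
        sequence.extend(block)

    fs = config.sampling_rate
    n_trial = int(round(config.trial_duration_s * fs))
    onset_in_trial = int(round(config.onset_offset_s * fs))
    data = np.empty((config.n_channels, n_trial * len(sequence)))
    events: list[Event] = []
    for i, f in enumerate(sequence):
        trial, inatt = _render_trial(config, f, seed, trial_index=i)
        data[:, i * n_trial:(i + 1) * n_trial] = trial
        events.append(Event(onset_sample=i * n_trial + onset_in_trial,
                            trial_id=i, frequency=f, inattentive=inatt,
                            stimulus_snr=config.stimulus_snr_condition))
    return EEGRecording(data=data, sampling_rate=fs,
                        channel_labels=config.channel_labels, events=events,
                        source_config=config, seed=seed,
                        n_trials_per_frequency=n_trials_per_frequency)


def inject_condition(recording: EEGRecording, condition: str,
                     inattentive_fraction: float | None = None,
                     inattentive_factor: float | None = None) -> EEGRecording:
    """Re-realize a simulated recording under a different condition.

    ``condition`` is ``"low_snr"``, ``"high_snr"`` or ``"inattentive"``.
    The session is regenerated from its stored configuration and seed with
    only the condition-specific random streams altered, so the result is
    exactly paired with the original (identical background, alpha and line
    noise).  Requires a recording produced by this module.
    """
    if recording.source_config is None or recording.seed is None:
        raise ValueError("recording carries no simulation provenance; "
                         "conditions can only be injected into simulated data")
    cfg = recording.source_config
    if condition == "low_snr":
        cfg = cfg.replace(stimulus_snr_condition="low")
    elif condition == "high_snr":
        cfg = cfg.replace(stimulus_snr_condition="high")
    elif condition == "inattentive":
        changes: dict = {}
        if inattentive_fraction is not None:
            changes["attention_lapse_prob"] = inattentive_fraction
        if inattentive_factor is not None:
            changes["inattentive_factor"] = inattentive_factor
        cfg = cfg.replace(**changes)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    n = recording.n_trials_per_frequency or 1
    if len(recording.events) == n * len(cfg.target_frequencies):
        return generate_session(cfg, n, recording.seed)
    return generate_trial(cfg, recording.events[0].frequency, recording.seed)
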