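"""Filtering, trial segmentation and SNR-based channel selection.

Recordings are notch-filtered at the powerline frequency and band-passed to
4-40 Hz (both zero-phase), each trial is split into a 3 s pre-onset idle
window and a stimulation window, and channels are ranked by how much their
narrow-band SSVEP SNR rises from idle to stimulation, with a paired t-test
guarding against selecting channels whose rise is noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .simulate import EEGRecording

__all__ = [
    "TrialSegment",
    "ChannelSelection",
    "SegmentationError",
    "filter_recording",
    "segment_trials",
    "select_channels",
]

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    """A trial lacks the data needed for its idle or stimulation window."""


@dataclass(frozen=True)
class TrialSegment:
    """Paired idle and stimulation windows for one trial."""

    trial_id: int
    true_frequency: float
    idle: np.ndarray          # channels x samples, 3 s ending at onset
    stimulation: np.ndarray   # channels x samples from onset
    channel_labels: tuple[str, ...]
    sampling_rate: float = 500.0
    inattentive: bool = False
    stimulus_snr: str = "high"

    def __post_init__(self) -> None:
        if self.idle.shape[0] != self.stimulation.shape[0]:
            raise ValueError("idle and stimulation must share channels")


def filter_recording(recording: EEGRecording,
                     band: tuple[float, float] = (4.0, 40.0),
                     notch_hz: float = 60.0,
                     notch_q: float = 30.0,
                     order: int = 4) -> EEGRecording:
    """Zero-phase 60 Hz notch plus 4-40 Hz band-pass, per channel.

    Both filters are applied forward-backward (no phase distortion, which
    the CCA templates rely on); the output has the same length as the
    input.  Requires a sampling rate comfortably above the notch frequency.
    """
    fs = recording.sampling_rate
    if fs <= 2.0 * notch_hz or fs <= 3.0 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {band[1]} Hz band and "
            f"{notch_hz} Hz notch")
    b_notch, a_notch = sps.iirnotch(notch_hz, notch_q, fs=fs)
    sos_band = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    data = sps.filtfilt(b_notch, a_notch, recording.data, axis=-1)
    data = sps.sosfiltfilt(sos_band, data, axis=-1)
    return recording.copy(data=data)


def segment_trials(recording: EEGRecording,
                   stimulation_length_s: float = 5.0,
                   idle_length_s: float = 3.0,
                   on_error: str = "skip") -> list[TrialSegment]:
    """One idle/stimulation segment pair per event.

    Idle is the ``idle_length_s`` span ending at the onset sample
    (exclusive); stimulation starts at the onset.  Trials with
    insufficient surrounding data are skipped with a warning (default) or
    raise a :class:`SegmentationError` naming the trial (``on_error="raise"``).
    """
    fs = recording.sampling_rate
    n_idle = int(round(idle_length_s * fs))
    n_stim = int(round(stimulation_length_s * fs))
    segments: list[TrialSegment] = []
    for event in recording.events:
        onset = event.onset_sample
        if onset - n_idle < 0 or onset + n_stim > recording.n_samples:
            msg = (f"trial {event.trial_id}: needs samples "
                   f"[{onset - n_idle}, {onset + n_stim}) outside the data")
            if on_error == "raise":
                raise SegmentationError(msg)
            logger.warning("skipping %s", msg)
            continue
        segments.append(TrialSegment(
            trial_id=event.trial_id,
            true_frequency=event.frequency,
            idle=recording.data[:, onset - n_idle:onset],
            stimulation=recording.data[:, onset:onset + n_stim],
            channel_labels=recording.channel_labels,
            sampling_rate=fs,
            inattentive=event.inattentive,
            stimulus_snr=event.stimulus_snr,
        ))
    return segments


@dataclass(frozen=True)
class ChannelSelection:
    """Outcome of SNR-based channel screening."""

    channel_labels: tuple[str, ...]
    idle_snr: np.ndarray           # per-channel mean over trials
    stimulation_snr: np.ndarray
    p_values: np.ndarray           # paired t-test idle vs stimulation
    selected: tuple[str, ...]      # significant channels, top-k by SNR rise

    @property
    def snr_increase(self) -> np.ndarray:
        return self.stimulation_snr - self.idle_snr


def select_channels(segments: list[TrialSegment], alpha: float = 0.01,
                    top_k: int = 8) -> ChannelSelection:
    """Channels whose SSVEP SNR rises significantly from idle to stimulation.

    Per channel and trial the narrow-band SNR is computed at the trial's
    own target frequency for both windows; trial-paired t-tests identify
    channels with a genuine rise (p < alpha and positive mean increase),
    and the ``top_k`` of those with the largest mean rise are selected.
    The result is invariant to the ordering of channels in the recording.
    """
    from .detect import ssvep_snr, welch_psd

    if len(segments) < 2:
        raise ValueError("channel statistics need at least 2 trials")
    if len(segments) < 5:
        logger.warning("fewer than 5 trials: channel selection is unstable")
    n_ch = segments[0].idle.shape[0]
    labels = segments[0].channel_labels
    idle_snr = np.empty((len(segments), n_ch))
    stim_snr = np.empty((len(segments), n_ch))
    for i, seg in enumerate(segments):
        if seg.channel_labels != labels:
            raise ValueError("segments disagree on channel labels")
        fs = seg.sampling_rate
        # equal segment lengths for both windows keep the no-signal case
        # exchangeable between idle and stimulation
        seg_len = seg.idle.shape[1] / fs
        idle_snr[i] = ssvep_snr(
            welch_psd(seg.idle, fs, segment_length_s=seg_len),
            seg.true_frequency, per_channel=True)
        stim_snr[i] = ssvep_snr(
            welch_psd(seg.stimulation, fs, segment_length_s=seg_len),
            seg.true_frequency, per_channel=True)
    mean_idle = idle_snr.mean(axis=0)
    mean_stim = stim_snr.mean(axis=0)
    p = np.ones(n_ch)
    for c in range(n_ch):
        diff = stim_snr[:, c] - idle_snr[:, c]
        if np.allclose(diff.std(), 0.0):
            p[c] = 1.0
            continue
        p[c] = stats.ttest_rel(stim_snr[:, c], idle_snr[:, c]).pvalue
    increase = mean_stim - mean_idle
    significant = [c for c in range(n_ch) if p[c] < alpha and increase[c] > 0]
    ranked = sorted(significant, key=lambda c: (-increase[c], labels[c]))
    selected = tuple(labels[c] for c in ranked[:top_k])
    return ChannelSelection(channel_labels=labels, idle_snr=mean_idle,
                            stimulation_snr=mean_stim, p_values=p,
                            selected=selected)


def restrict_channels(segments: list[TrialSegment],
                      channels: tuple[str, ...] | list[str]) -> list[TrialSegment]:
    """Segments reduced to the given channel subset (selection order kept)."""
    out = []
    for seg in segments:
        idx = [seg.channel_labels.index(ch) for ch in channels]
        out.append(TrialSegment(
            trial_id=seg.trial_id, true_frequency=seg.true_frequency,
            idle=seg.idle[idx], stimulation=seg.stimulation[idx],
            channel_labels=tuple(channels), sampling_rate=seg.sampling_rate,
            inattentive=seg.inattentive, stimulus_snr=seg.stimulus_snr))
    return out
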