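"""Configuration, recording I/O and the end-to-end analysis pipeline.

The pipeline runs simulate (or ingest) -> filter -> segment -> select
channels -> detect (PSDA + CCA + FBCCA) -> evaluate, and writes per-trial
results, per-window summaries, confusion matrices and a JSON run manifest
(seed, package versions, config hash) to an output directory.

Recording containers
--------------------
``csv``    directory (or basename) with ``data.csv`` (samples x channels,
           header = channel labels), ``events.csv`` and ``meta.json``.
``hdf5``   single HDF5 file with the same content.
``edf``    European Data Format, read through MNE; stimulation events are
           taken from annotations named ``ssvep/<frequency>``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import FilterBankConfig, classify_cca, classify_psda, fbcca_classify
from .evaluate import DEFAULT_WINDOW_GRID, EvaluationSummary, accuracy_over_time
from .preprocess import (filter_recording, restrict_channels, segment_trials,
                         select_channels)
from .simulate import EEGRecording, Event, SimulationConfig, generate_session

__all__ = [
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_EVENT_COLUMNS = ["onset_sample", "trial_id", "frequency", "inattentive",
                  "stimulus_snr"]


class FormatError(ValueError):
    """A recording file is missing required fields."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs, serializable to YAML/JSON."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_trials_per_frequency: int = 10
    seed: int = 0
    input_path: str | None = None        # ingest instead of simulate
    input_format: str | None = None
    methods: tuple[str, ...] = ("psda", "cca", "fbcca")
    window_grid_s: tuple[float, ...] = DEFAULT_WINDOW_GRID
    stimulation_length_s: float = 5.0
    idle_length_s: float = 3.0
    channel_alpha: float = 0.01
    channel_top_k: int = 8
    n_harmonics: int = 3
    filter_band: tuple[float, float] = (4.0, 40.0)
    notch_hz: float = 60.0
    filter_bank: FilterBankConfig = field(default_factory=FilterBankConfig)
    run_channel_selection: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["methods"] = list(self.methods)
        d["window_grid_s"] = [float(w) for w in self.window_grid_s]
        d["filter_band"] = list(self.filter_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "filter_bank" in d and isinstance(d["filter_bank"], dict):
            d["filter_bank"] = FilterBankConfig(**d["filter_bank"])
        for key in ("methods", "window_grid_s", "filter_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Short stable digest of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _events_frame(recording: EEGRecording) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in recording.events],
                        columns=_EVENT_COLUMNS)


def _events_from_frame(df: pd.DataFrame) -> list[Event]:
    missing = [c for c in ("onset_sample", "trial_id", "frequency")
               if c not in df.columns]
    if missing:
        raise FormatError(f"event table lacks required columns: {missing}")
    events = []
    for row in df.itertuples(index=False):
        events.append(Event(
            onset_sample=int(row.onset_sample),
            trial_id=int(row.trial_id),
            frequency=float(row.frequency),
            inattentive=bool(getattr(row, "inattentive", False)),
            stimulus_snr=str(getattr(row, "stimulus_snr", "high"))))
    return events


def write_recording(recording: EEGRecording, path: str | Path,
                    fmt: str = "csv") -> Path:
    """Persist a recording as a csv directory or an HDF5 container."""
    path = Path(path)
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(recording.data.T,
                     columns=list(recording.channel_labels)).to_csv(
            path / "data.csv", index=False)
        _events_frame(recording).to_csv(path / "events.csv", index=False)
        meta = {"sampling_rate": recording.sampling_rate,
                "channel_labels": list(recording.channel_labels)}
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
        return path
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=recording.data)
            fh.attrs["sampling_rate"] = recording.sampling_rate
            fh.attrs["channel_labels"] = [str(c) for c in
                                          recording.channel_labels]
            ev = _events_frame(recording)
            grp = fh.create_group("events")
            for col in _EVENT_COLUMNS:
                vals = ev[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)
        return path
    raise FormatError(f"unknown recording format {fmt!r}")


def _read_csv_recording(path: Path) -> EEGRecording:
    data_path, events_path, meta_path = (path / "data.csv",
                                         path / "events.csv",
                                         path / "meta.json")
    if not data_path.exists():
        raise FormatError(f"missing data matrix: {data_path}")
    if not events_path.exists():
        raise FormatError(f"missing event table: {events_path}")
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("sampling_rate", "channel_labels"):
        if key not in meta:
            raise FormatError(f"metadata lacks required field {key!r}")
    df = pd.read_csv(data_path)
    labels = tuple(meta["channel_labels"])
    if tuple(df.columns) != labels:
        raise FormatError("data column headers do not match channel_labels")
    events = _events_from_frame(pd.read_csv(events_path))
    return EEGRecording(data=df.to_numpy().T,
                        sampling_rate=float(meta["sampling_rate"]),
                        channel_labels=labels, events=events)


def _read_hdf5_recording(path: Path) -> EEGRecording:
    import h5py
    with h5py.File(path, "r") as fh:
        if "data" not in fh:
            raise FormatError("HDF5 container lacks a 'data' dataset")
        if "events" not in fh:
            raise FormatError("HDF5 container lacks an 'events' group")
        data = fh["data"][()]
        fs = float(fh.attrs["sampling_rate"])
        labels = tuple(str(c) for c in np.asarray(fh.attrs["channel_labels"],
                                                  dtype=str))
        ev = {col: fh["events"][col][()] for col in fh["events"]}
    df = pd.DataFrame(ev)
    if "stimulus_snr" in df and df["stimulus_snr"].dtype == object:
        df["stimulus_snr"] = df["stimulus_snr"].str.decode("utf-8",
                                                           errors="ignore")
    return EEGRecording(data=data, sampling_rate=fs, channel_labels=labels,
                        events=_events_from_frame(df))


def _read_edf_recording(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise FormatError("EDF support requires the optional mne package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    labels = tuple(raw.ch_names)
    events = []
    for i, ann in enumerate(raw.annotations):
        desc = str(ann["description"])
        if not desc.startswith("ssvep/"):
            continue
        events.append(Event(onset_sample=int(round(ann["onset"] * fs)),
                            trial_id=i, frequency=float(desc.split("/", 1)[1])))
    if not events:
        raise FormatError(
            "EDF file carries no 'ssvep/<frequency>' annotations")
    return EEGRecording(data=data, sampling_rate=fs, channel_labels=labels,
                        events=events)


def read_recording(path: str | Path, fmt: str | None = None) -> EEGRecording:
    """Load a recording, inferring the container from the path if needed."""
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "csv"
        elif path.suffix in (".h5", ".hdf5"):
            fmt = "hdf5"
        elif path.suffix.lower() == ".edf":
            fmt = "edf"
        else:
            raise FormatError(f"cannot infer format of {path}")
    if fmt == "csv":
        return _read_csv_recording(path)
    if fmt == "hdf5":
        return _read_hdf5_recording(path)
    if fmt == "edf":
        return _read_edf_recording(path)
    raise FormatError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_CLASSIFIERS = {
    "psda": classify_psda,
    "cca": classify_cca,
    "fbcca": fbcca_classify,
}


def _detect_all(segments, candidates, config: PipelineConfig
                ) -> dict[str, dict[float, list]]:
    out: dict[str, dict[float, list]] = {}
    for method in config.methods:
        if method not in _CLASSIFIERS:
            raise ValueError(f"unknown detection method {method!r}")
        by_window = {}
        for w in config.window_grid_s:
            if method == "fbcca":
                by_window[w] = fbcca_classify(
                    segments, candidates, w, bank=config.filter_bank,
                    n_harmonics=config.n_harmonics)
            elif method == "cca":
                by_window[w] = classify_cca(
                    segments, candidates, w, n_harmonics=config.n_harmonics)
            else:
                by_window[w] = classify_psda(segments, candidates, w)
        out[method] = by_window
    return out


def _trial_table(detections: dict[str, dict[float, list]],
                 window_s: float) -> pd.DataFrame:
    rows: dict[int, dict] = {}
    for method, by_window in detections.items():
        for r in by_window[window_s]:
            row = rows.setdefault(r.trial_id, {
                "trial_id": r.trial_id, "true_frequency": r.true_frequency})
            row[f"detected_{method}"] = r.detected_frequency
            for f, s in r.scores.items():
                row[f"{method}_score_{f}"] = s
    return pd.DataFrame(sorted(rows.values(), key=lambda d: d["trial_id"]))


def run_pipeline(config: PipelineConfig,
                 output_dir: str | Path | None = None
                 ) -> dict[str, EvaluationSummary]:
    """Execute the full analysis and (optionally) write its artifacts.

    Returns one evaluation summary per detection method.  Stage failures
    are re-raised annotated with the stage name.
    """
    stage = "ingest"
    try:
        if config.input_path is not None:
            recording = read_recording(config.input_path, config.input_format)
        else:
            recording = generate_session(config.simulation,
                                         config.n_trials_per_frequency,
                                         config.seed)
        stage = "filter"
        filtered = filter_recording(recording, band=config.filter_band,
                                    notch_hz=config.notch_hz)
        stage = "segment"
        segments = segment_trials(filtered, config.stimulation_length_s,
                                  config.idle_length_s)
        if not segments:
            raise ValueError("no usable trials after segmentation")
        stage = "channel selection"
        selection = None
        if config.run_channel_selection:
            selection = select_channels(segments, alpha=config.channel_alpha,
                                        top_k=config.channel_top_k)
            if selection.selected:
                segments = restrict_channels(segments, selection.selected)
            else:
                logger.warning("no channel passed selection; keeping all")
        stage = "detection"
        candidates = sorted({s.true_frequency for s in segments})
        detections = _detect_all(segments, candidates, config)
        stage = "evaluation"
        condition = config.simulation.stimulus_snr_condition
        summaries = {m: accuracy_over_time(by_w, condition=condition, method=m)
                     for m, by_w in detections.items()}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg_hash = config.hash()
        longest = max(config.window_grid_s)
        trials = _trial_table(detections, longest)
        trials.insert(0, "config_hash", cfg_hash)
        trials.to_csv(out / "trials.csv", index=False)
        frames = []
        for m, summ in summaries.items():
            df = summ.to_frame()
            df.insert(0, "method", m)
            frames.append(df)
            summ.confusion.to_csv(out / f"confusion_{m}.csv")
        summary = pd.concat(frames, ignore_index=True)
        summary.insert(0, "config_hash", cfg_hash)
        summary.to_csv(out / "summary.csv", index=False)
        manifest = {
            "config_hash": cfg_hash,
            "config": config.to_dict(),
            "seed": config.seed,
            "ssveplab_version": __version__,
            "numpy_version": np.__version__,
            "selected_channels": list(selection.selected) if selection else None,
            "n_trials": len(segments),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        config.to_yaml(out / "config.yaml")
    return summaries
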