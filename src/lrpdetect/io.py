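"""Reading and writing study artifacts.

EEG goes to mne's FIF container (with events as annotations); event
tables, ground truth, motion traces, onset annotations and reports are
plain tab-separated tables, and every written dataset carries a JSON
manifest recording the generating configuration and seed so it can be
regenerated bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig
from .synthetic import EventTable, MotionTrace, Recording, SubjectTaskData


def to_mne_raw(recording: Recording):
    """Convert a :class:`Recording` to an :class:`mne.io.RawArray`.

    Channel data are scaled from microvolts to volts; events become
    annotations named by their kind and side.
    """
    import mne

    info = mne.create_info(list(recording.channel_names),
                           sfreq=recording.rate, ch_types="eeg")
    raw = mne.io.RawArray(recording.samples.astype(np.float64) * 1e-6,
                          info, verbose="error")
    ev = recording.events.frame
    raw.set_annotations(mne.Annotations(
        onset=ev["time"].to_numpy(),
        duration=np.zeros(len(ev)),
        description=[f"{k}/{s}" for k, s in zip(ev["kind"], ev["side"])]))
    return raw


def motion_frame(traces) -> pd.DataFrame:
    """All motion traces of a cell as one long table."""
    parts = []
    for m in traces:
        df = pd.DataFrame(m.positions, columns=["x", "y", "z"])
        df.insert(0, "time", m.times())
        df["hand"] = m.hand
        df["set_index"] = m.set_index
        df["trial_index"] = m.trial_index
        df["switch_release"] = m.switch_release
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(frame: pd.DataFrame, rate: float) -> list:
    """Rebuild :class:`MotionTrace` objects from a long motion table."""
    traces = []
    keys = ["hand", "set_index", "trial_index"]
    for (hand, s, k), df in frame.groupby(keys, sort=True):
        df = df.sort_values("time")
        traces.append(MotionTrace(
            positions=df[["x", "y", "z"]].to_numpy(),
            rate=rate, t_start=float(df["time"].iloc[0]),
            switch_release=float(df["switch_release"].iloc[0]),
            hand=hand, set_index=int(s), trial_index=int(k)))
    return traces


def save_subject_task(data: SubjectTaskData, out_dir, config: StudyConfig,
                      write_eeg: bool = True) -> Path:
    """Write one subject-task cell to ``out_dir``.

    Produces ``events.tsv``, ``trials.tsv`` (ground truth), ``motion.tsv``,
    ``manifest.json`` and, unless disabled, ``eeg_raw.fif``.
    """
    out = Path(out_dir) / f"sub-{data.subject:02d}_task-{data.task}"
    out.mkdir(parents=True, exist_ok=True)
    data.recording.events.frame.to_csv(out / "events.tsv", sep="\t",
                                       index=False)
    data.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    motion_frame(data.motion).to_csv(out / "motion.tsv", sep="\t",
                                     index=False, float_format="%.4f")
    manifest = dict(subject=data.subject, task=data.task,
                    config=config.to_dict(),
                    channel_names=list(data.recording.channel_names),
                    eeg_rate=data.recording.rate)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if write_eeg:
        to_mne_raw(data.recording).save(out / "eeg_raw.fif",
                                        overwrite=True, verbose="error")
    return out


def load_subject_task(cell_dir) -> SubjectTaskData:
    """Read a cell written by :func:`save_subject_task` (EEG required)."""
    import mne

    cell = Path(cell_dir)
    manifest = json.loads((cell / "manifest.json").read_text())
    raw = mne.io.read_raw_fif(cell / "eeg_raw.fif", preload=True,
                              verbose="error")
    events = EventTable(pd.read_csv(cell / "events.tsv", sep="\t"))
    recording = Recording(
        channel_names=tuple(manifest["channel_names"]),
        rate=manifest["eeg_rate"],
        samples=(raw.get_data() * 1e6).astype(np.float32),
        events=events)
    trials = pd.read_csv(cell / "trials.tsv", sep="\t")
    motion = frame_to_traces(pd.read_csv(cell / "motion.tsv", sep="\t"),
                             rate=manifest["config"]["motion_rate"])
    return SubjectTaskData(subject=manifest["subject"],
                           task=manifest["task"], recording=recording,
                           motion=motion, trials=trials)
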