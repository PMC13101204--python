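"""In-memory containers for continuous EEG and epoched trials.

Units are microvolts throughout; time is expressed in seconds relative to
stimulus onset for epoched data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Extended 10/20 montage of the 32-channel recording system the study
#: conditions assume (reference CPz and ground AFz are not data channels).
MONTAGE_32 = [
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4",
    "T8", "CP5", "CP1", "CP2", "CP6", "P3", "Pz", "P4",
    "P7", "M1", "POz", "M2", "P8", "O1", "Oz", "O2",
]

EVENT_COLUMNS = ["run", "trial", "paradigm", "feedback", "label", "onset_sample"]


@dataclass
class EEGRecording:
    """Continuous multichannel EEG (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Epoched trials (trials x channels x samples) with per-trial tags.

    ``window`` is (t_start, t_end) in seconds relative to stimulus onset;
    sample k of an epoch corresponds to time t_start + k / fs, so windows
    are half-open [t_start, t_end).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    window: tuple[float, float]
    channel_names: list[str]
    run: np.ndarray = field(default=None)
    paradigm: np.ndarray = field(default=None)
    feedback: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        n = self.data.shape[0]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per trial")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match data channels")
        if self.run is None:
            self.run = np.zeros(n, dtype=int)
        if self.paradigm is None:
            self.paradigm = np.array([""] * n, dtype=object)
        if self.feedback is None:
            self.feedback = np.array([""] * n, dtype=object)
        self.run = np.asarray(self.run)
        self.paradigm = np.asarray(self.paradigm, dtype=object)
        self.feedback = np.asarray(self.feedback, dtype=object)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch set") from None

    def pick_channels(self, names: list[str]) -> "EpochSet":
        idx = [self.channel_index(n) for n in names]
        return EpochSet(
            data=self.data[:, idx, :].copy(),
            labels=self.labels.copy(),
            fs=self.fs,
            window=self.window,
            channel_names=list(names),
            run=self.run.copy(),
            paradigm=self.paradigm.copy(),
            feedback=self.feedback.copy(),
        )

    def crop(self, t_start: float, t_end: float) -> "EpochSet":
        """Restrict to the half-open time interval [t_start, t_end)."""
        i0 = int(round((t_start - self.window[0]) * self.fs))
        i1 = int(round((t_end - self.window[0]) * self.fs))
        if i0 < 0 or i1 > self.n_samples or i0 >= i1:
            raise ValueError("crop interval outside the epoch window")
        return EpochSet(
            data=self.data[:, :, i0:i1].copy(),
            labels=self.labels.copy(),
            fs=self.fs,
            window=(t_start, t_end),
            channel_names=list(self.channel_names),
            run=self.run.copy(),
            paradigm=self.paradigm.copy(),
            feedback=self.feedback.copy(),
        )

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return EpochSet(
            data=self.data[idx].copy(),
            labels=self.labels[idx].copy(),
            fs=self.fs,
            window=self.window,
            channel_names=list(self.channel_names),
            run=self.run[idx].copy(),
            paradigm=self.paradigm[idx].copy(),
            feedback=self.feedback[idx].copy(),
        )

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.channel_names != first.channel_names:
                raise ValueError("channel sets differ")
            if p.fs != first.fs or p.window != first.window:
                raise ValueError("sampling or window differ")
        return EpochSet(
            data=np.concatenate([p.data for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            fs=first.fs,
            window=first.window,
            channel_names=list(first.channel_names),
            run=np.concatenate([p.run for p in parts]),
            paradigm=np.concatenate([p.paradigm for p in parts]),
            feedback=np.concatenate([p.feedback for p in parts]),
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": self.run,
                "trial": np.arange(self.n_trials),
                "paradigm": self.paradigm,
                "feedback": self.feedback,
                "label": self.labels,
                "onset_sample": np.zeros(self.n_trials, dtype=int),
            }
        )

    # -- serialization: binary array + JSON sidecar + TSV events ------------

    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "epochs.npy", self.data)
        meta = {
            "fs": self.fs,
            "window": list(self.window),
            "channel_names": list(self.channel_names),
        }
        (d / "epochs.json").write_text(json.dumps(meta, indent=2))
        self.events_frame().to_csv(d / "events.tsv", sep="\t", index=False)
        return d

    @staticmethod
    def load(directory: str | Path) -> "EpochSet":
        d = Path(directory)
        data = np.load(d / "epochs.npy")
        meta = json.loads((d / "epochs.json").read_text())
        ev = pd.read_csv(d / "events.tsv", sep="\t")
        return EpochSet(
            data=data,
            labels=ev["label"].to_numpy(),
            fs=float(meta["fs"]),
            window=tuple(meta["window"]),
            channel_names=list(meta["channel_names"]),
            run=ev["run"].to_numpy(),
            paradigm=ev["paradigm"].to_numpy(dtype=object),
            feedback=ev["feedback"].to_numpy(dtype=object),
        )
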