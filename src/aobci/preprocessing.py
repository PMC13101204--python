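"""Preprocessing chain: FIR bandpass, epoching with baseline correction,
amplitude-based trial rejection, and the C3/C4 surface Laplacian.

The surface Laplacian references a target electrode against the mean of its
six nearest neighbours, L_i = V_i - (1/N) * sum_{j in Omega_i} V_j, which
acts as a spatial high-pass and cancels signals common to the neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EEGRecording, EpochSet

logger = logging.getLogger(__name__)


def bandpass_fir(
    rec: EEGRecording,
    low: float = 3.0,
    high: float = 40.0,
    transition: float = 2.0,
) -> EEGRecording:
    """Zero-phase FIR bandpass (windowed-sinc, Hamming window).

    The number of taps is chosen from the Hamming-window transition-width
    rule (about 3.3 / normalized transition width); the filter is applied
    forward-backward, so the effective magnitude response is squared and
    phase is exactly zero.
    """
    if not 0 < low < high < rec.fs / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    numtaps = int(np.ceil(3.3 * rec.fs / transition))
    numtaps += 1 - numtaps % 2  # odd for a type-I linear-phase filter
    taps = signal.firwin(
        numtaps, [low, high], pass_zero=False, window="hamming", fs=rec.fs
    )
    if rec.n_samples <= 3 * numtaps:
        raise ValueError("recording too short for the designed filter")
    data = signal.filtfilt(taps, [1.0], rec.data, axis=-1)
    return EEGRecording(data=data, fs=rec.fs, channel_names=list(rec.channel_names))


def epoch_and_baseline(
    rec: EEGRecording,
    events: pd.DataFrame,
    window: tuple[float, float] = (-0.8, 4.0),
    baseline: tuple[float, float] = (-0.8, 0.0),
) -> EpochSet:
    """Cut epochs around event onsets and subtract the per-channel baseline
    mean.

    Sample indices are 0-based; the onset sample is the first sample of the
    stimulus segment and windows are half-open [start, end). At 500 Hz the
    default window yields 2400 samples per epoch, of which the 0-3 s
    stimulus segment holds 1500.
    """
    fs = rec.fs
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    b0 = int(round((baseline[0] - window[0]) * fs))
    b1 = int(round((baseline[1] - window[0]) * fs))
    if not (0 <= b0 < b1 <= i1 - i0):
        raise ValueError("baseline interval must lie inside the window")
    onsets = events["onset_sample"].to_numpy()
    trials = []
    for onset in onsets:
        start, stop = onset + i0, onset + i1
        if start < 0 or stop > rec.n_samples:
            raise ValueError(f"event at sample {onset} falls outside the recording")
        ep = rec.data[:, start:stop].copy()
        ep -= ep[:, b0:b1].mean(axis=1, keepdims=True)
        trials.append(ep)
    return EpochSet(
        data=np.stack(trials),
        labels=events["label"].to_numpy(),
        fs=fs,
        window=window,
        channel_names=list(rec.channel_names),
        run=events["run"].to_numpy(),
        paradigm=events["paradigm"].to_numpy(dtype=object),
        feedback=events["feedback"].to_numpy(dtype=object),
    )


def reject_amplitude(
    epochs: EpochSet, threshold: float = 200.0
) -> tuple[EpochSet, np.ndarray, float]:
    """Reject trials whose absolute amplitude strictly exceeds ``threshold``
    uV on any channel.

    Returns (kept epochs, boolean rejection mask, rejection rate). A sample
    exactly at the threshold is kept.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rejected = np.abs(epochs.data).max(axis=(1, 2)) > threshold
    kept = epochs.subset(~rejected)
    rate = float(rejected.mean()) if epochs.n_trials else 0.0
    if rejected.any():
        logger.info("rejected %d/%d trials (%.1f%%) above %.0f uV",
                    rejected.sum(), epochs.n_trials, 100 * rate, threshold)
    return kept, rejected, rate


@dataclass(frozen=True)
class LaplacianMap:
    """Target electrode and its neighbourhood Omega_i."""

    target: str
    neighbors: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.neighbors)


#: Six-neighbour Laplacian maps for the sensorimotor electrodes.
DEFAULT_LAPLACIAN_MAPS = [
    LaplacianMap("C3", ("FC5", "FC1", "T7", "CP5", "CP1", "Cz")),
    LaplacianMap("C4", ("FC6", "FC2", "T8", "CP6", "CP2", "Cz")),
]


def laplacian(
    epochs: EpochSet, maps: list[LaplacianMap] | None = None
) -> EpochSet:
    """Surface Laplacian per map; output restricted to the mapped electrodes.

    L_i(t) = V_i(t) - mean over neighbours of V_j(t). Linear in the input
    and exactly zero for spatially uniform potentials.
    """
    if maps is None:
        maps = DEFAULT_LAPLACIAN_MAPS
    out = np.empty((epochs.n_trials, len(maps), epochs.n_samples))
    for k, m in enumerate(maps):
        ti = epochs.channel_index(m.target)
        ni = [epochs.channel_index(nb) for nb in m.neighbors]
        out[:, k, :] = epochs.data[:, ti, :] - epochs.data[:, ni, :].mean(axis=1)
    return EpochSet(
        data=out,
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        window=epochs.window,
        channel_names=[m.target for m in maps],
        run=epochs.run.copy(),
        paradigm=epochs.paradigm.copy(),
        feedback=epochs.feedback.copy(),
    )


def ica_artifact_hook(epochs: EpochSet) -> EpochSet:
    """Placeholder for component-based ocular/muscular artifact removal.

    Synthetic sessions contain no such components, so this hook passes the
    data through unchanged and logs that it did.
    """
    logger.warning("ICA artifact removal hook is a no-op; data passed through")
    return epochs
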