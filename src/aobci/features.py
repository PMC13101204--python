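"""Occipital and sensorimotor EEG descriptors.

* single-sided amplitude spectra of the stimulus segment (SSMVEP peaks),
* event-related spectral perturbation (ERSP) maps in dB relative to the
  pre-stimulus baseline,
* band-averaged event-related desynchronization (ERD) values,
* the laterality index LI = (ERD_C3 - ERD_C4) / (ERD_C3 + ERD_C4).

Frequency-band conventions: alpha 8-12 Hz, beta 13-30 Hz, broad 5-30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochSet

BANDS = {"alpha": (8.0, 12.0), "beta": (13.0, 30.0), "broad": (5.0, 30.0)}


@dataclass
class AmplitudeSpectrum:
    freqs: np.ndarray
    amps: np.ndarray
    channel: str

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def amplitude_at(self, freq: float) -> float:
        """Amplitude at the bin nearest ``freq``."""
        return float(self.amps[int(np.argmin(np.abs(self.freqs - freq)))])

    def peak_frequency(self, fmin: float = 1.0, fmax: float | None = None) -> float:
        sel = self.freqs >= fmin
        if fmax is not None:
            sel &= self.freqs <= fmax
        idx = np.flatnonzero(sel)
        return float(self.freqs[idx[np.argmax(self.amps[idx])]])


def amplitude_spectrum(
    epochs: EpochSet,
    channel: str,
    segment: tuple[float, float] = (0.0, 3.0),
    average: bool = True,
) -> AmplitudeSpectrum:
    """Single-sided amplitude spectrum of the stimulus segment.

    Normalized so a unit sinusoid at a bin frequency yields amplitude 1.
    With ``average`` the evoked (trial-averaged) waveform is transformed,
    which emphasizes phase-locked steady-state components; otherwise
    per-trial amplitude spectra are averaged.
    """
    t0, t1 = epochs.window
    if segment[0] < t0 - 1e-9 or segment[1] > t1 + 1e-9:
        raise ValueError("segment outside the epoch window")
    sub = epochs.crop(*segment)
    x = sub.data[:, sub.channel_index(channel), :]
    n = x.shape[-1]

    def one_sided(y: np.ndarray) -> np.ndarray:
        a = np.abs(np.fft.rfft(y, axis=-1)) / n
        a[..., 1:] *= 2.0
        if n % 2 == 0:
            a[..., -1] /= 2.0
        return a

    amps = one_sided(x.mean(axis=0)) if average else one_sided(x).mean(axis=0)
    freqs = np.fft.rfftfreq(n, 1.0 / epochs.fs)
    return AmplitudeSpectrum(freqs=freqs, amps=amps, channel=channel)


@dataclass
class TFMap:
    """Time-frequency power map in dB relative to the baseline mean."""

    times: np.ndarray
    freqs: np.ndarray
    power_db: np.ndarray  # (freq, time)
    channel: str


def ersp(
    epochs: EpochSet,
    channel: str,
    freq_range: tuple[float, float] = (5.0, 30.0),
    baseline: tuple[float, float] = (-0.8, 0.0),
    win_sec: float = 0.5,
    overlap: float = 0.9,
) -> TFMap:
    """Event-related spectral perturbation via a short-time Fourier
    transform (Hann window, 90% overlap by default).

    Per frequency f and frame time t: 10*log10(mean over trials of power /
    mean baseline power), where the baseline power at f averages the frames
    whose window lies entirely inside the baseline interval.
    """
    if epochs.n_trials < 1:
        raise ValueError("at least one trial required")
    x = epochs.data[:, epochs.channel_index(channel), :]
    fs = epochs.fs
    nperseg = int(round(win_sec * fs))
    noverlap = int(round(overlap * nperseg))
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        mode="psd", axis=-1,
    )
    times = times + epochs.window[0]  # frame centres in epoch time
    power = sxx.mean(axis=0)  # (freq, time)

    half = win_sec / 2.0
    base_sel = (times - half >= baseline[0] - 1e-9) & (times + half <= baseline[1] + 1e-9)
    if not base_sel.any():
        raise ValueError("baseline interval holds no complete STFT frame")
    base = power[:, base_sel].mean(axis=1, keepdims=True)

    fsel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power[fsel] / base[fsel])
    return TFMap(times=times, freqs=freqs[fsel], power_db=db, channel=channel)


@dataclass
class BandErd:
    """Mean ERSP over a band x window rectangle, in dB (negative = ERD)."""

    band: tuple[float, float]
    window: tuple[float, float]
    value: float
    channel: str


def band_erd(
    tf: TFMap,
    band: tuple[float, float] | str = "alpha",
    window: tuple[float, float] = (0.0, 3.0),
) -> BandErd:
    """Average the dB map over the band and time window (inclusive bounds)."""
    if isinstance(band, str):
        band = BANDS[band]
    fsel = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    tsel = (tf.times >= window[0]) & (tf.times <= window[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("band/window selects no cells of the map")
    value = float(tf.power_db[np.ix_(fsel, tsel)].mean())
    return BandErd(band=band, window=window, value=value, channel=tf.channel)


class UndefinedLateralityError(ValueError):
    """Raised when the LI denominator falls below the numerical guard."""


def laterality_index(
    erd_c3: BandErd | float,
    erd_c4: BandErd | float,
    convention: str = "magnitude",
    eps: float = 1e-6,
) -> float:
    """Laterality index (ERD_C3 - ERD_C4) / (ERD_C3 + ERD_C4).

    With the default ``magnitude`` convention each ERD enters as its
    desynchronization magnitude max(-dB, 0), so a deeper contralateral power
    decrease at C3 gives a positive LI (right-hand paradigms) and a deeper
    decrease at C4 a negative LI (left-hand paradigm), and same-sign inputs
    keep LI within [-1, 1]. ``signed`` uses the raw dB values.
    """
    v3 = erd_c3.value if isinstance(erd_c3, BandErd) else float(erd_c3)
    v4 = erd_c4.value if isinstance(erd_c4, BandErd) else float(erd_c4)
    if convention == "magnitude":
        v3, v4 = max(-v3, 0.0), max(-v4, 0.0)
    elif convention != "signed":
        raise ValueError("convention must be 'magnitude' or 'signed'")
    denom = v3 + v4
    if abs(denom) < eps:
        raise UndefinedLateralityError(
            f"LI undefined: |ERD_C3 + ERD_C4| = {abs(denom):.3g} below guard {eps:g}"
        )
    return (v3 - v4) / denom
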