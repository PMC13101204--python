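"""File I/O: plain EDF round trip and TSV event tables.

The continuous-recording interchange format is plain EDF (16-bit samples,
ASCII header). Writing uses a minimal single-purpose encoder; reading goes
through MNE's EDF reader, so the round trip is checked by an independent
decoder. Quantization error is bounded by the physical range divided by
2^16 (about 0.02 uV at the default +/-600 uV range).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording

_EDF_RECORD_SECONDS = 1.0


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording, physical_max: float = 600.0) -> Path:
    """Write a continuous recording as a plain EDF file.

    Samples are quantized to int16 over [-physical_max, physical_max] uV;
    the signal is clipped to that range. The recording is zero-padded to a
    whole number of 1-s data records.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs * _EDF_RECORD_SECONDS))
    if abs(spr - fs * _EDF_RECORD_SECONDS) > 1e-9:
        raise ValueError("sampling rate must give an integer number of samples per record")
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, : rec.n_samples] = np.clip(rec.data, -physical_max, physical_max)

    pmin, pmax = -physical_max, physical_max
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin) * scale + dmin).astype("<i2")

    head = b""
    head += _field("0", 8)
    head += _field("X X X X", 80)
    head += _field("Startdate X X X X", 80)
    head += _field("01.01.00", 8)
    head += _field("00.00.00", 8)
    head += _field(256 * (n_ch + 1), 8)
    head += _field("", 44)
    head += _field(n_records, 8)
    head += _field(int(_EDF_RECORD_SECONDS), 8)
    head += _field(n_ch, 4)
    for name in rec.channel_names:
        head += _field(name, 16)
    for _ in range(n_ch):
        head += _field("", 80)  # transducer
    for _ in range(n_ch):
        head += _field("uV", 8)
    for _ in range(n_ch):
        head += _field(f"{pmin:g}", 8)
    for _ in range(n_ch):
        head += _field(f"{pmax:g}", 8)
    for _ in range(n_ch):
        head += _field(dmin, 8)
    for _ in range(n_ch):
        head += _field(dmax, 8)
    for _ in range(n_ch):
        head += _field("", 80)  # prefiltering
    for _ in range(n_ch):
        head += _field(spr, 8)
    for _ in range(n_ch):
        head += _field("", 32)

    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-major within each record
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read a continuous EDF recording (via MNE) into microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def write_events_tsv(path: str | Path, events: pd.DataFrame) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
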