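"""File I/O: multichannel WAV audio and CSV event logs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .fusion import SslEvent

__all__ = ["write_wav", "read_wav", "write_events", "read_events"]

EVENT_COLUMNS = ["timestamp", "phi_A", "phi_B", "confidence", "area", "status"]


def write_wav(path: str | Path, wave: np.ndarray, sample_rate: int) -> None:
    """Write a (channels, N) float waveform as a 32-bit float PCM WAV."""
    wave = np.atleast_2d(np.asarray(wave, dtype=np.float32))
    wavfile.write(str(path), int(sample_rate), wave.T)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file to a (channels, N) float64 array in [-1, 1]-ish units.

    Integer PCM (16/32-bit) is rescaled to floats; float files pass through.
    """
    rate, data = wavfile.read(str(path))
    data = np.atleast_2d(data.T)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return data, int(rate)


def write_events(path: str | Path, events: list[SslEvent]) -> None:
    """Write an SSL event log as CSV (one row per one-second record)."""
    rows = [
        {
            "timestamp": e.timestamp,
            "phi_A": e.phi_A,
            "phi_B": e.phi_B,
            "confidence": e.confidence,
            "area": e.area,
            "status": e.status,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> list[SslEvent]:
    """Read an SSL event log CSV back into :class:`SslEvent` records."""
    # keep_default_na so the literal status "null" is not parsed as NaN
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed event log, missing columns: {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            SslEvent(
                timestamp=float(row.timestamp),
                phi_A=None if pd.isna(row.phi_A) else float(row.phi_A),
                phi_B=None if pd.isna(row.phi_B) else float(row.phi_B),
                confidence=None if pd.isna(row.confidence) else float(row.confidence),
                area=None if pd.isna(row.area) else str(row.area),
                status=str(row.status),
            )
        )
    return events
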