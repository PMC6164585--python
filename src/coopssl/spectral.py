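"""Spectrograms and rule-based categorisation of night sounds.

Four sound types dominate a laying-hen house at night, each with a
recognisable spectro-temporal signature: water-nipple pecking (broadband
1-8 kHz, very short), cock crow (broadband 0-8 kHz with a stable formant,
about 2 s), mechanical fan noise (irregular energy confined below 1 kHz,
essentially continuous) and chicken grunts (narrowband 1-2 kHz, a faint
~2 s formant).  The classifier below turns those qualitative descriptors
into explicit band-energy and active-duration rules; it is a deterministic
screening aid, not a learned model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "SoundDescriptor",
    "NIGHT_SOUND_DESCRIPTORS",
    "spectrogram",
    "band_energy_fraction",
    "active_duration",
    "classify_night_sound",
]


@dataclass(frozen=True)
class SoundDescriptor:
    """Frequency band and typical duration of one night-sound category."""

    label: str
    band_hz: tuple[float, float]
    duration_s: float

    def __post_init__(self) -> None:
        if not self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band low must be below band high")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


NIGHT_SOUND_DESCRIPTORS = (
    SoundDescriptor("pecking", (1000.0, 8000.0), 0.2),
    SoundDescriptor("crow", (0.0, 8000.0), 2.0),
    SoundDescriptor("mechanical", (0.0, 1000.0), 2.0),
    SoundDescriptor("grunt", (1000.0, 2000.0), 2.0),
)

DEFAULT_WINDOW_S = 0.032
DEFAULT_OVERLAP = 0.5


def spectrogram(
    clip: np.ndarray,
    sample_rate: float,
    window: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
):
    """STFT magnitude of a mono clip.

    Hann window of ``window`` seconds with fractional ``overlap``; returns
    ``(freqs, times, magnitude)`` with frequencies spanning 0..sample_rate/2.
    """
    clip = np.asarray(clip, dtype=float)
    nperseg = max(int(round(window * sample_rate)), 8)
    if clip.size < nperseg:
        raise ValueError("clip shorter than one analysis window")
    noverlap = int(nperseg * overlap)
    f, t, s = sps.stft(
        clip, fs=sample_rate, window="hann", nperseg=nperseg,
        noverlap=noverlap, boundary=None, padded=False,
    )
    return f, t, np.abs(s)


def band_energy_fraction(
    clip: np.ndarray, sample_rate: float, band_hz: tuple[float, float]
) -> float:
    """Fraction of total spectral energy inside ``band_hz`` (Welch PSD)."""
    clip = np.asarray(clip, dtype=float)
    f, psd = sps.welch(clip, fs=sample_rate,
                       nperseg=min(clip.size, 1024))
    total = float(np.trapezoid(psd, f))
    if total == 0.0:
        return 0.0
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    return float(np.trapezoid(psd[sel], f[sel])) / total


def active_duration(
    clip: np.ndarray,
    sample_rate: float,
    frame_s: float = DEFAULT_WINDOW_S,
    rel_threshold: float = 0.1,
) -> float:
    """Seconds during which the short-time RMS exceeds ``rel_threshold``
    times its peak — a crude voiced-duration measure."""
    clip = np.asarray(clip, dtype=float)
    hop = max(int(round(frame_s * sample_rate)), 1)
    n_frames = max(clip.size // hop, 1)
    rms = np.sqrt(
        np.mean(clip[: n_frames * hop].reshape(n_frames, hop) ** 2, axis=1)
    )
    peak = rms.max()
    if peak == 0.0:
        return 0.0
    return float(np.sum(rms > rel_threshold * peak)) * hop / sample_rate


def classify_night_sound(
    clip: np.ndarray,
    sample_rate: float,
    band_fraction: float = 0.7,
    short_max_s: float = 0.5,
    formant_range_s: tuple[float, float] = (1.5, 2.5),
) -> str:
    """Label a night-sound clip as pecking / crow / mechanical / grunt.

    Decision rules (first match wins; ``"unknown"`` when none fires):

    - mechanical: >= ``band_fraction`` of energy below 1 kHz and active for
      most of the clip (fan noise runs continuously);
    - grunt: >= ``band_fraction`` of energy in 1-2 kHz with an active
      duration around 2 s;
    - pecking: >= ``band_fraction`` of energy in 1-8 kHz and a short burst
      (< ``short_max_s``);
    - crow: energy genuinely spread across 0-8 kHz (some below 1 kHz, the
      bulk above) sustained around 2 s.
    """
    clip = np.asarray(clip, dtype=float)
    if clip.size < int(0.1 * sample_rate):
        raise ValueError("clip must be at least 0.1 s long")
    if not np.any(clip):
        return "unknown"
    frac_low = band_energy_fraction(clip, sample_rate, (0.0, 1000.0))
    frac_12 = band_energy_fraction(clip, sample_rate, (1000.0, 2000.0))
    frac_18 = band_energy_fraction(clip, sample_rate, (1000.0, 8000.0))
    dur = active_duration(clip, sample_rate)
    clip_len = clip.size / sample_rate
    lo, hi = formant_range_s

    if frac_low >= band_fraction and dur >= 0.5 * clip_len:
        return "mechanical"
    if frac_12 >= band_fraction and lo <= dur <= hi:
        return "grunt"
    if frac_18 >= band_fraction and dur < short_max_s:
        return "pecking"
    if frac_low >= 0.05 and frac_18 >= 0.5 and lo <= dur <= hi:
        return "crow"
    return "unknown"
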