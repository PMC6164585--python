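"""Delay estimation from multichannel audio frames.

Arrival-time differences between microphone pairs are estimated by plain
normalised cross-correlation, searched over the physically admissible lag
window (spacing / c) and refined to sub-sample resolution by a parabolic fit
through the peak and its two neighbours.  At a 16 kHz sampling rate one
sample corresponds to ~21 mm of path — coarser than the 40 mm inner spacing
of the array — so sub-sample interpolation is what makes bearing errors of a
couple of degrees attainable.  Plain correlation (no PHAT weighting) is used
deliberately: it is cheap enough for a 1 s real-time loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

from .geometry import MicArrayGeometry, TdoaMeasurement

__all__ = ["AudioFrame", "estimate_delay", "sound_present", "measure_frame"]

DEFAULT_SAMPLE_RATE = 16_000
DEFAULT_FRAME_SECONDS = 1.0


@dataclass(frozen=True)
class AudioFrame:
    """One analysis frame: ``samples`` is a (channels, N) float array.

    Frames default to 1 s at 16 kHz; ``timestamp`` is seconds since the start
    of the monitoring session.
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate

    def rms(self) -> float:
        """Root-mean-square amplitude averaged over channels."""
        return float(np.sqrt(np.mean(self.samples**2)))


def estimate_delay(
    ref_channel: np.ndarray,
    other_channel: np.ndarray,
    sample_rate: float,
    max_delay: float,
) -> tuple[float, float]:
    """Delay of ``ref_channel`` relative to ``other_channel``, seconds.

    Positive delay means the waveform arrived at ``ref_channel`` *later*:
    with arrival times tau_r and tau_o, the returned delay estimates
    ``tau_r - tau_o``, matching the sign convention of
    :class:`~coopssl.geometry.TdoaMeasurement` (``t12`` = arrival at S1 minus
    arrival at S2).

    The lag search is restricted to ``|lag| <= max_delay`` (set from the
    microphone spacing divided by the sound speed); the integer peak of the
    normalised cross-correlation is refined by a three-point parabolic fit.

    Returns
    -------
    (delay, peak_corr)
        ``peak_corr`` is the normalised correlation at the integer peak,
        clipped to [0, 1].

    Raises
    ------
    ValueError
        If either channel is identically zero (correlation undefined) or the
        lag window is shorter than one sample.
    """
    x = np.asarray(ref_channel, dtype=float)
    y = np.asarray(other_channel, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("channels must be 1-D arrays of equal length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("all-zero channel: correlation undefined")
    max_lag = int(round(max_delay * sample_rate))
    if max_lag < 1:
        raise ValueError(
            f"max_delay={max_delay:.3g} s is shorter than one sample at "
            f"{sample_rate} Hz"
        )

    # full cross-correlation; index n-1 corresponds to lag 0, and
    # corr[n-1+k] = sum_m x[m+k] * y[m] peaks at k = tau_r - tau_o samples.
    corr = correlate(x, y, mode="full") / (nx * ny)
    n = x.size
    lo, hi = n - 1 - max_lag, n - 1 + max_lag
    window = corr[lo : hi + 1]
    k = int(np.argmax(window))
    peak_corr = float(np.clip(window[k], 0.0, 1.0))

    # parabolic refinement over (k-1, k, k+1); at a window edge fall back to
    # the integer lag (the true peak is clipped by the physical bound anyway).
    if 0 < k < window.size - 1:
        y0, y1, y2 = window[k - 1], window[k], window[k + 1]
        denom = y0 - 2.0 * y1 + y2
        frac = 0.0 if denom == 0.0 else 0.5 * (y0 - y2) / denom
        frac = float(np.clip(frac, -0.5, 0.5))
    else:
        frac = 0.0
    lag = (k - max_lag) + frac
    return lag / sample_rate, peak_corr


def sound_present(frame: AudioFrame, energy_threshold: float) -> bool:
    """True iff the frame's channel-averaged RMS exceeds the threshold.

    Frames failing the gate yield null monitoring records downstream (no
    sound production, nothing to localise).
    """
    return frame.rms() > energy_threshold


def measure_frame(
    frame: AudioFrame,
    geometry: MicArrayGeometry,
    energy_threshold: float = 0.0,
    lag_margin_samples: int = 1,
) -> TdoaMeasurement | None:
    """Estimate (t12, t23) for one frame, or ``None`` when no sound is present.

    Channels are indexed by the geometry's solver triple: t12 is estimated
    from (S1, S2) and t23 from (S2, S3), each with its own lag window of
    spacing/c plus a one-sample margin so that end-fire sources are not
    clipped by rounding.
    """
    if frame.n_channels <= max(geometry.solver_triple):
        raise ValueError(
            f"frame has {frame.n_channels} channels, solver triple "
            f"{geometry.solver_triple} needs more"
        )
    if not sound_present(frame, energy_threshold):
        return None
    i, j, k = geometry.solver_triple
    fs = frame.sample_rate
    margin = lag_margin_samples / fs
    d12, c12 = estimate_delay(
        frame.samples[i], frame.samples[j], fs, geometry.a / geometry.c + margin
    )
    d23, c23 = estimate_delay(
        frame.samples[j], frame.samples[k], fs, geometry.b / geometry.c + margin
    )
    return TdoaMeasurement(t12=d12, t23=d23, pair_confidences=(c12, c23))


def calibrate_energy_threshold(
    frames: list[AudioFrame], multiplier: float = 3.0, n_frames: int = 10
) -> float:
    """Energy gate from the session's opening frames.

    Returns ``multiplier`` times the median channel-averaged RMS of the first
    ``n_frames`` frames — a simple noise-floor estimate assuming the session
    opens quietly.  The multiplier of 3 keeps steady background noise below
    the gate while any overlaid call clears it.
    """
    if not frames:
        return 0.0
    head = frames[:n_frames]
    return multiplier * float(np.median([f.rms() for f in head]))
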