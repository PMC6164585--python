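"""Frame-by-frame localisation pipeline: audio in, SSL event log out.

Mirrors the live monitoring loop: at one-second intervals each array's frame
is gated for sound presence, cross-correlated into arrival-time differences,
solved for a boresight angle, and the two arrays' angle signs fused into an
area label that is then validity-gated.
"""

from __future__ import annotations

from typing import Iterator, Mapping, Sequence

import numpy as np

from .fusion import (
    DEFAULT_AREA_MAPPING,
    DEFAULT_ANGLE_LIMIT,
    DEFAULT_CONF_THRESHOLD,
    SslEvent,
    assign_area,
    validate,
)
from .geometry import MicArrayGeometry, axis_to_boresight, solve_angle
from .tdoa import AudioFrame, measure_frame

__all__ = ["iter_frames", "localise_frame_pair", "localise_session"]


def iter_frames(
    wave: np.ndarray, sample_rate: int, frame_seconds: float = 1.0
) -> Iterator[AudioFrame]:
    """Split a (channels, N) waveform into whole analysis frames.

    A trailing partial frame is dropped (the live system only ever sees
    whole one-second frames).
    """
    wave = np.atleast_2d(np.asarray(wave, dtype=float))
    n = int(round(frame_seconds * sample_rate))
    for i in range(wave.shape[1] // n):
        yield AudioFrame(
            wave[:, i * n : (i + 1) * n],
            sample_rate=sample_rate,
            timestamp=i * frame_seconds,
        )


def localise_frame_pair(
    frame_A: AudioFrame,
    frame_B: AudioFrame,
    geometry_A: MicArrayGeometry,
    geometry_B: MicArrayGeometry,
    energy_threshold: float = 0.0,
    area_mapping: Mapping = DEFAULT_AREA_MAPPING,
    angle_limit: float = DEFAULT_ANGLE_LIMIT,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> SslEvent:
    """One monitoring record from a synchronous pair of array frames.

    Either frame failing the energy gate (or an unsolvable measurement)
    yields a null event; otherwise both boresight angles, the fused
    confidence (mean of the two arrays' frame confidences) and the area are
    filled in and the validity gates applied.
    """
    ts = frame_A.timestamp
    phis: list[float | None] = []
    confs: list[float] = []
    for frame, geom in ((frame_A, geometry_A), (frame_B, geometry_B)):
        meas = measure_frame(frame, geom, energy_threshold=energy_threshold)
        if meas is None:
            phis.append(None)
        else:
            try:
                phis.append(axis_to_boresight(solve_angle(meas, geom)))
                confs.append(meas.confidence)
            except ValueError:
                phis.append(None)
    if phis[0] is None or phis[1] is None:
        return SslEvent(timestamp=ts, status="null")
    event = SslEvent(
        timestamp=ts,
        phi_A=phis[0],
        phi_B=phis[1],
        confidence=float(np.mean(confs)),
        area=assign_area(phis[0], phis[1], area_mapping),
    )
    return validate(event, angle_limit=angle_limit, conf_threshold=conf_threshold)


def localise_session(
    wave_A: np.ndarray,
    wave_B: np.ndarray,
    sample_rate: int,
    geometry_A: MicArrayGeometry | None = None,
    geometry_B: MicArrayGeometry | None = None,
    frame_seconds: float = 1.0,
    energy_threshold: float = 0.0,
    area_mapping: Mapping = DEFAULT_AREA_MAPPING,
    angle_limit: float = DEFAULT_ANGLE_LIMIT,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> list[SslEvent]:
    """Localise an entire two-array recording into an event log."""
    geometry_A = geometry_A or MicArrayGeometry()
    geometry_B = geometry_B or MicArrayGeometry()
    events = []
    for fa, fb in zip(
        iter_frames(wave_A, sample_rate, frame_seconds),
        iter_frames(wave_B, sample_rate, frame_seconds),
    ):
        events.append(
            localise_frame_pair(
                fa, fb, geometry_A, geometry_B,
                energy_threshold=energy_threshold,
                area_mapping=area_mapping,
                angle_limit=angle_limit,
                conf_threshold=conf_threshold,
            )
        )
    return events
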