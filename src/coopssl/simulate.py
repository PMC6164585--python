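"""Ground-truthed acoustic scene synthesis for a two-array poultry pen.

Real recordings from the monitored pen cannot ship with the package, so every
upstream stage is exercised on synthetic scenes: a seeded hen-call model plays
from known floor positions, each microphone channel receives the call with
its exact propagation delay and 1/r spreading loss, and noise is added at a
configured SNR.  The renderer keeps a per-second ground-truth log (position,
true bearings, true area) so localisation output can be scored.

The hen call is a continuous-time harmonic stack (fundamental in the
400-800 Hz range, a handful of harmonics, slow vibrato and syllabic amplitude
modulation, ~2.5 s long and looped during active intervals).  Because the
model is analytic, a delayed copy is obtained by evaluating it at
``t - r_i/c`` — sub-sample delays are exact, which is what lets the test
suite assert estimator errors of a tenth of a sample.  Sampled (array)
source signals are supported too, delayed by windowed-sinc interpolation.

Propagation is free-field: no room reflections and no source directivity.
Arrays are modelled at their mounting height above the floor plane; a linear
array is cylindrically symmetric, so the 3-D geometry collapses exactly to a
2-D problem per array (axial coordinate, slant radial distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .fusion import DEFAULT_AREA_MAPPING, SslEvent, assign_area, validate
from .geometry import (
    MicArrayGeometry,
    TdoaMeasurement,
    axis_to_boresight,
    solve_angle,
)
from .monitoring import accuracy_table
from .tdoa import AudioFrame, measure_frame

__all__ = [
    "HenCallModel",
    "synth_hen_call",
    "ArrayPose",
    "SceneSource",
    "SceneSpec",
    "render_scene",
    "reference_grid",
    "evaluate_localiser",
    "bearing_scene",
    "DEFAULT_PEN",
    "REFERENCE_BEARINGS_DEG",
]

#: Pen floor rectangle (metres), centred on the origin: (xmin, xmax, ymin, ymax).
DEFAULT_PEN = (-0.75, 0.75, -0.675, 0.675)

#: The nine laboratory reference bearings (degrees) used for angle-error runs.
REFERENCE_BEARINGS_DEG = (-28.0, -22.0, -15.0, -8.0, 0.0, 8.0, 15.0, 22.0, 28.0)

DEFAULT_CALL_DURATION = 2.48  # seconds, looped
DEFAULT_MOUNT_HEIGHT = 1.8  # metres above the floor


@dataclass(frozen=True)
class HenCallModel:
    """Continuous-time synthetic laying-hen call.

    A stack of ``n_harmonics`` partials on a fundamental ``f0`` with a slow
    sinusoidal vibrato (depth ``vibrato_depth``, rate ``vibrato_hz``) and a
    syllabic raised-cosine amplitude envelope (``syllable_hz`` pulses per
    second).  Amplitudes decay as 1/k with seeded jitter; phases are seeded.
    All parameters are drawn once from ``seed`` so a model instance is fully
    deterministic and can be evaluated at arbitrary times.
    """

    f0: float
    n_harmonics: int
    amplitudes: tuple[float, ...]
    phases: tuple[float, ...]
    vibrato_hz: float
    vibrato_depth: float
    vibrato_phase: float
    syllable_hz: float
    duration: float = DEFAULT_CALL_DURATION

    @classmethod
    def from_seed(cls, seed: int, duration: float = DEFAULT_CALL_DURATION
                  ) -> "HenCallModel":
        rng = np.random.default_rng(seed)
        f0 = float(rng.uniform(450.0, 650.0))
        n_h = int(rng.integers(4, 7))
        amps = (1.0 / np.arange(1, n_h + 1)) * rng.uniform(0.7, 1.0, n_h)
        phases = rng.uniform(0.0, 2.0 * math.pi, n_h)
        return cls(
            f0=f0,
            n_harmonics=n_h,
            amplitudes=tuple(float(a) for a in amps),
            phases=tuple(float(p) for p in phases),
            vibrato_hz=float(rng.uniform(4.0, 8.0)),
            vibrato_depth=float(rng.uniform(0.01, 0.04)),
            vibrato_phase=float(rng.uniform(0.0, 2.0 * math.pi)),
            syllable_hz=float(rng.uniform(2.5, 4.0)),
            duration=duration,
        )

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Waveform at times ``t`` (seconds), looping every ``duration``."""
        t = np.asarray(t, dtype=float) % self.duration
        # instantaneous phase of the vibrato-modulated fundamental:
        # f(t) = f0 (1 + m sin(2 pi fv t + pv))  =>  closed-form integral.
        fv, m, pv = self.vibrato_hz, self.vibrato_depth, self.vibrato_phase
        base = self.f0 * (t - m / (2.0 * math.pi * fv)
                          * (np.cos(2.0 * math.pi * fv * t + pv) - math.cos(pv)))
        env = 0.5 - 0.5 * np.cos(2.0 * math.pi * self.syllable_hz * t)
        out = np.zeros_like(t)
        for k in range(1, self.n_harmonics + 1):
            out += self.amplitudes[k - 1] * np.sin(
                2.0 * math.pi * k * base + self.phases[k - 1]
            )
        return env * out

    def sample(self, duration: float, sample_rate: float) -> np.ndarray:
        n = int(round(duration * sample_rate))
        return self.evaluate(np.arange(n) / sample_rate)


def synth_hen_call(
    duration: float = DEFAULT_CALL_DURATION,
    sample_rate: float = 16_000,
    seed: int = 0,
) -> np.ndarray:
    """Sampled synthetic hen call (see :class:`HenCallModel`); deterministic
    under a fixed seed."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return HenCallModel.from_seed(seed).sample(duration, sample_rate)


def _sinc_interpolate(x: np.ndarray, fs: float, t: np.ndarray,
                      half_width: int = 32) -> np.ndarray:
    """Band-limited (Hann-windowed sinc) evaluation of sampled ``x`` at
    arbitrary times ``t``; zero outside the support."""
    pos = np.asarray(t) * fs
    n0 = np.floor(pos).astype(int)
    out = np.zeros(pos.shape)
    for k in range(-half_width + 1, half_width + 1):
        idx = n0 + k
        valid = (idx >= 0) & (idx < x.size)
        d = pos - idx
        w = np.sinc(d) * (0.5 + 0.5 * np.cos(math.pi * d / half_width))
        out[valid] += x[idx[valid]] * w[valid]
    return out


@dataclass(frozen=True)
class ArrayPose:
    """Placement of one linear array over the pen.

    ``origin`` is the floor point under the solver's middle microphone (S2),
    ``axis`` the unit direction from S2 toward S3, and ``height`` the
    mounting height above the floor plane.  Positive boresight angles point
    toward the S3 side of the array normal.
    """

    name: str
    geometry: MicArrayGeometry = field(default_factory=MicArrayGeometry)
    origin: tuple[float, float] = (0.0, 0.0)
    axis: tuple[float, float] = (1.0, 0.0)
    height: float = DEFAULT_MOUNT_HEIGHT

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(ax)
        if norm == 0:
            raise ValueError("axis must be a non-zero vector")
        object.__setattr__(self, "axis", tuple(ax / norm))

    def _axial_radial(self, source_xy) -> tuple[float, float]:
        v = np.asarray(source_xy, dtype=float) - np.asarray(self.origin)
        axial = float(v @ np.asarray(self.axis))
        perp2 = float(v @ v) - axial**2
        return axial, math.sqrt(max(perp2, 0.0) + self.height**2)

    def mic_distances(self, source_xy) -> np.ndarray:
        """Slant distances from a floor source to every microphone."""
        axial, radial = self._axial_radial(source_xy)
        _, j, _ = self.geometry.solver_triple
        offsets = np.asarray(self.geometry.mic_positions)
        offsets = offsets - offsets[j]
        return np.hypot(axial - offsets, radial)

    def true_bearing(self, source_xy) -> float:
        """Signed boresight bearing (degrees) of a floor source."""
        axial, radial = self._axial_radial(source_xy)
        return math.degrees(math.asin(axial / math.hypot(axial, radial)))

    def exact_tdoa(self, source_xy) -> TdoaMeasurement:
        """Analytic arrival-time differences for the solver triple."""
        i, j, k = self.geometry.solver_triple
        r = self.mic_distances(source_xy)
        c = self.geometry.c
        return TdoaMeasurement(t12=(r[i] - r[j]) / c, t23=(r[j] - r[k]) / c)


def _default_arrays() -> tuple[ArrayPose, ArrayPose]:
    return (
        ArrayPose(name="A", axis=(1.0, 0.0)),
        ArrayPose(name="B", axis=(0.0, 1.0)),
    )


@dataclass(frozen=True)
class SceneSource:
    """One emitting source: a floor position, a signal and an on/off schedule.

    ``signal`` is a :class:`HenCallModel` (looped during active intervals) or
    a sampled 1-D array interpreted at the scene sample rate.  ``schedule``
    lists half-open active intervals in seconds; ``None`` means always on.
    """

    position: tuple[float, float]
    signal: HenCallModel | np.ndarray
    schedule: tuple[tuple[float, float], ...] | None = None
    gain: float = 1.0

    def active_mask(self, t: np.ndarray) -> np.ndarray:
        if self.schedule is None:
            return np.ones(t.shape, dtype=bool)
        mask = np.zeros(t.shape, dtype=bool)
        for on, off in self.schedule:
            mask |= (t >= on) & (t < off)
        return mask

    def active_at(self, second: int) -> bool:
        mid = second + 0.5
        if self.schedule is None:
            return True
        return any(on <= mid < off for on, off in self.schedule)


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render a scene deterministically."""

    sources: tuple[SceneSource, ...]
    arrays: tuple[ArrayPose, ...] = field(default_factory=_default_arrays)
    snr_db: float | None = 20.0
    noise_model: str = "white"  # white | mechanical | mixture
    sample_rate: int = 16_000
    duration: float = 4.0
    seed: int = 0
    pen: tuple[float, float, float, float] = DEFAULT_PEN
    spreading_loss: bool = True
    area_mapping: dict = field(default_factory=lambda: dict(DEFAULT_AREA_MAPPING))

    def __post_init__(self) -> None:
        xmin, xmax, ymin, ymax = self.pen
        for s in self.sources:
            x, y = s.position
            if not (xmin <= x <= xmax and ymin <= y <= ymax):
                raise ValueError(f"source at {s.position} lies outside the pen")


def _noise(rng: np.random.Generator, shape, model: str, fs: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    if model == "white":
        return white
    sos = butter(4, 1000.0, btype="low", fs=fs, output="sos")
    mech = sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    mech /= np.sqrt(np.mean(mech**2))
    if model == "mechanical":
        return mech
    if model == "mixture":
        return (white + mech) / math.sqrt(2.0)
    raise ValueError(f"unknown noise model {model!r}")


def render_scene(spec: SceneSpec) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render per-array multichannel audio plus a per-second truth log.

    Each microphone receives every active source evaluated at the retarded
    time ``t - r_i/c`` and scaled by ``1/r_i`` (free field).  Noise is scaled
    so that the scene-wide SNR (active-signal RMS over noise RMS, averaged
    over channels) equals ``spec.snr_db``; ``snr_db=None`` renders noiseless.

    Returns
    -------
    (waves, truth)
        ``waves`` maps array name -> (n_mics, N) float array.  ``truth`` has
        one row per whole second: source position, per-array true bearing,
        the true area label and whether any source was active.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)

    waves: dict[str, np.ndarray] = {}
    sig_power_sum, sig_power_n = 0.0, 0
    for pose in spec.arrays:
        chans = np.zeros((len(pose.geometry.mic_positions), n))
        for src in spec.sources:
            r = _all_mic_distances(pose, src.position)
            for m, rm in enumerate(r):
                tau = t - rm / pose.geometry.c
                if isinstance(src.signal, HenCallModel):
                    s = src.signal.evaluate(tau)
                else:
                    s = _sinc_interpolate(np.asarray(src.signal, float), fs, tau)
                s = s * src.active_mask(tau)
                amp = src.gain / rm if spec.spreading_loss else src.gain
                chans[m] += amp * s
        active = np.zeros(n, dtype=bool)
        for src in spec.sources:
            active |= src.active_mask(t)
        if active.any():
            sig_power_sum += float(np.mean(chans[:, active] ** 2, axis=1).sum())
            sig_power_n += chans.shape[0]
        waves[pose.name] = chans

    if spec.snr_db is not None and sig_power_n:
        sig_rms = math.sqrt(sig_power_sum / sig_power_n)
        noise_rms = sig_rms * 10.0 ** (-spec.snr_db / 20.0)
        for pose in spec.arrays:
            shape = waves[pose.name].shape
            waves[pose.name] = waves[pose.name] + noise_rms * _noise(
                rng, shape, spec.noise_model, fs
            )

    rows = []
    for sec in range(int(spec.duration)):
        src = next((s for s in spec.sources if s.active_at(sec)), None)
        row: dict = {"second": sec, "active": src is not None}
        if src is not None:
            row["x"], row["y"] = src.position
            signs = []
            for pose in spec.arrays:
                brg = pose.true_bearing(src.position)
                row[f"bearing_{pose.name}"] = brg
                signs.append("+" if brg >= 0 else "-")
            if len(spec.arrays) >= 2:
                row["area"] = spec.area_mapping[tuple(signs[:2])]
        rows.append(row)
    return waves, pd.DataFrame(rows)


def _all_mic_distances(pose: ArrayPose, source_xy) -> np.ndarray:
    axial, radial = pose._axial_radial(source_xy)
    _, j, _ = pose.geometry.solver_triple
    offsets = np.asarray(pose.geometry.mic_positions)
    offsets = offsets - offsets[j]
    return np.hypot(axial - offsets, radial)


def reference_grid(
    rows: int = 9,
    cols: int = 7,
    dx: float = 0.245,
    dy: float = 0.237,
    height: float = DEFAULT_MOUNT_HEIGHT,
    area_mapping: dict | None = None,
) -> pd.DataFrame:
    """Laboratory reference-point grid, centred under the arrays.

    ``rows`` points along the x axis spaced ``dx`` and ``cols`` along y
    spaced ``dy`` (the defaults reproduce the 9 x 7 layout with 245 mm /
    237 mm pitch covering a ~1.96 m x 1.42 m test floor).  Each point is
    annotated with its true boresight bearing from each overhead array
    (mounted ``height`` above the floor: array A along x, array B along y)
    and its area label from the bearing sign pair.
    """
    mapping = dict(DEFAULT_AREA_MAPPING) if area_mapping is None else area_mapping
    xs = (np.arange(rows) - (rows - 1) / 2) * dx
    ys = (np.arange(cols) - (cols - 1) / 2) * dy
    recs = []
    for x in xs:
        for y in ys:
            brg_a = math.degrees(math.atan2(x, math.hypot(y, height)))
            brg_b = math.degrees(math.atan2(y, math.hypot(x, height)))
            area = mapping[("+" if brg_a >= 0 else "-", "+" if brg_b >= 0 else "-")]
            recs.append(
                {"x": x, "y": y, "bearing_A": brg_a, "bearing_B": brg_b,
                 "area": area}
            )
    return pd.DataFrame(recs)


def bearing_scene(
    bearing_deg: float,
    range_m: float = 1.8,
    seed: int = 0,
    snr_db: float | None = 20.0,
    duration: float = 1.0,
    noise_model: str = "white",
    sample_rate: int = 16_000,
) -> SceneSpec:
    """Single-array scene with one looping hen call at a given boresight
    bearing and range — the layout of the laboratory angle-error runs."""
    pose = ArrayPose(name="A", axis=(1.0, 0.0), height=0.0)
    phi = math.radians(bearing_deg)
    pos = (range_m * math.sin(phi), range_m * math.cos(phi))
    src = SceneSource(position=pos, signal=HenCallModel.from_seed(seed))
    margin = range_m + 0.5
    return SceneSpec(
        sources=(src,),
        arrays=(pose,),
        snr_db=snr_db,
        noise_model=noise_model,
        sample_rate=sample_rate,
        duration=duration,
        seed=seed,
        pen=(-margin, margin, -margin, margin),
    )


def evaluate_localiser(
    grid: pd.DataFrame | None = None,
    exact: bool = False,
    seed: int = 0,
    snr_db: float | None = 20.0,
    noise_model: str = "white",
    frames_per_point: int = 1,
    sample_rate: int = 16_000,
    area_mapping: dict | None = None,
    arrays: Sequence[ArrayPose] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline over a reference grid and score it.

    For every grid point a scene is rendered (or, with ``exact=True``, the
    analytic arrival-time differences are used directly — the noiseless
    oracle limit), localised frame by frame, fused into an area, and compared
    with the point's true area and bearings.

    Returns
    -------
    (table, errors)
        ``table`` is a per-area accuracy table with a totals row; ``errors``
        has one row per frame with estimated and true bearings per array,
        the absolute bearing errors and the assigned/true areas.
    """
    mapping = dict(DEFAULT_AREA_MAPPING) if area_mapping is None else area_mapping
    if grid is None:
        grid = reference_grid(area_mapping=mapping)
    poses = tuple(arrays) if arrays is not None else _default_arrays()
    rng = np.random.default_rng(seed)

    err_rows = []
    per_area: dict[str, list[int]] = {}
    for p, rec in enumerate(grid.itertuples(index=False)):
        pos = (rec.x, rec.y)
        truths = {pose.name: pose.true_bearing(pos) for pose in poses}
        true_area = rec.area
        if exact:
            measurements = [
                {pose.name: pose.exact_tdoa(pos) for pose in poses}
            ] * frames_per_point
        else:
            big = max(abs(rec.x), abs(rec.y)) + 3.0
            spec = SceneSpec(
                sources=(SceneSource(position=pos,
                                     signal=HenCallModel.from_seed(p)),),
                arrays=poses,
                snr_db=snr_db,
                noise_model=noise_model,
                sample_rate=sample_rate,
                duration=float(frames_per_point),
                seed=int(rng.integers(2**31 - 1)),
                pen=(-big, big, -big, big),
            )
            waves, _ = render_scene(spec)
            n = sample_rate  # one-second frames
            measurements = []
            for f in range(frames_per_point):
                meas = {}
                for pose in poses:
                    frame = AudioFrame(
                        waves[pose.name][:, f * n:(f + 1) * n],
                        sample_rate=sample_rate, timestamp=float(f),
                    )
                    meas[pose.name] = measure_frame(frame, pose.geometry)
                measurements.append(meas)
        for f, meas in enumerate(measurements):
            phis = {}
            for pose in poses:
                m = meas[pose.name]
                phis[pose.name] = (
                    None if m is None
                    else axis_to_boresight(solve_angle(m, pose.geometry))
                )
            row = {"point": p, "frame": f, "true_area": true_area}
            for pose in poses:
                row[f"phi_{pose.name}"] = phis[pose.name]
                row[f"true_{pose.name}"] = truths[pose.name]
                row[f"abs_err_{pose.name}"] = (
                    None if phis[pose.name] is None
                    else abs(phis[pose.name] - truths[pose.name])
                )
            if len(poses) >= 2 and all(
                phis[pose.name] is not None for pose in poses[:2]
            ):
                est_area = assign_area(
                    phis[poses[0].name], phis[poses[1].name], mapping
                )
                row["area"] = est_area
                stats = per_area.setdefault(true_area, [0, 0])
                stats[0 if est_area == true_area else 1] += 1
            err_rows.append(row)
    table = accuracy_table(
        {a: tuple(per_area[a]) for a in sorted(per_area)}
    )
    return table, pd.DataFrame(err_rows)
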