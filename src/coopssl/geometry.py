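"""Closed-form TDOA localisation for a collinear three-microphone subset.

A linear array of four microphones shares one horizontal axis.  Any three of
them (``S1``, ``S2``, ``S3`` with spacings ``a = |S1 S2|`` and ``b = |S2 S3|``)
suffice for a planar bearing-and-range fix: with the source at ``P`` and
``r_i`` the distance from ``P`` to ``S_i``, the arrival-time differences

.. math::

    t_{12} = (r_1 - r_2)/c, \\qquad t_{23} = (r_2 - r_3)/c

determine the range ``r2`` from the middle microphone and the axis angle
``theta`` (measured from the ``S2 -> S3`` direction) in closed form via the
cosine rule applied to the two triangles ``P S1 S2`` and ``P S2 S3``.

Because the array is linear, the fix is symmetric about the array axis: a
source at ``(x, y)`` and its mirror ``(x, -y)`` produce identical delays.
Monitoring code therefore works with the signed *boresight* angle
``phi = 90 deg - theta`` (positive toward ``S3``) and fuses two orthogonal
arrays to resolve a floor quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MicArrayGeometry",
    "TdoaMeasurement",
    "PolarFix",
    "FarField",
    "DegenerateSourceError",
    "InfeasibleTdoaError",
    "InconsistentMeasurementError",
    "forward_delays",
    "solve_range",
    "solve_angle",
    "solve_fix",
    "axis_to_boresight",
]

#: Default speed of sound used throughout, m/s.
SOUND_SPEED = 340.0

#: Consecutive microphone gaps of the Kinect-style array, metres (left to right).
DEFAULT_MIC_GAPS = (0.149, 0.040, 0.037)

#: |a*t23 - b*t12| below this (seconds*metres) is treated as a plane wave.
FARFIELD_TOL = 1e-12

#: Tolerated overshoot of |cos theta| beyond 1 before a measurement is rejected.
COS_TOL = 1e-9


class DegenerateSourceError(ValueError):
    """Source coincides with a microphone; delays are undefined."""


class InfeasibleTdoaError(ValueError):
    """A path difference exceeds the microphone spacing: no real source fits."""


class InconsistentMeasurementError(ValueError):
    """Delays are individually feasible but jointly violate the geometry."""


class FarField:
    """Sentinel result: the range is unresolvable (plane-wave source).

    Returned by :func:`solve_range` when the closed-form denominator vanishes,
    i.e. the two hyperbola branches are asymptotically parallel.  The bearing
    remains well defined and is reported separately by :func:`solve_angle`.
    """

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "FarField()"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FarField)

    def __hash__(self) -> int:
        return hash("FarField")


FARFIELD = FarField()


def _default_positions() -> tuple[float, ...]:
    return tuple(np.concatenate([[0.0], np.cumsum(DEFAULT_MIC_GAPS)]))


@dataclass(frozen=True)
class MicArrayGeometry:
    """Positions of the four collinear microphones and the solver triple.

    Parameters
    ----------
    mic_positions
        Scalar offsets of the microphones along the array axis, metres,
        strictly increasing.  The default reproduces the Kinect-style array
        with consecutive gaps 149 mm, 40 mm and 37 mm.
    solver_triple
        Indices ``(S1, S2, S3)`` of the three microphones used by the
        closed-form solver.  The default ``(0, 1, 3)`` takes the outermost
        pair plus the second microphone, maximising the aperture
        (``a = 0.149`` m, ``b = 0.077`` m).
    c
        Speed of sound, m/s.
    """

    mic_positions: tuple[float, ...] = field(default_factory=_default_positions)
    solver_triple: tuple[int, int, int] = (0, 1, 3)
    c: float = SOUND_SPEED

    def __post_init__(self) -> None:
        pos = tuple(float(p) for p in self.mic_positions)
        object.__setattr__(self, "mic_positions", pos)
        if len(pos) < 3:
            raise ValueError("need at least three microphones")
        if any(q <= p for p, q in zip(pos, pos[1:])):
            raise ValueError("mic_positions must be strictly increasing")
        i, j, k = self.solver_triple
        if not (0 <= i < j < k < len(pos)):
            raise ValueError("solver_triple must be increasing valid indices")
        if self.c <= 0:
            raise ValueError("sound speed must be positive")

    @property
    def a(self) -> float:
        """Distance S1 -> S2, metres."""
        i, j, _ = self.solver_triple
        return self.mic_positions[j] - self.mic_positions[i]

    @property
    def b(self) -> float:
        """Distance S2 -> S3, metres."""
        _, j, k = self.solver_triple
        return self.mic_positions[k] - self.mic_positions[j]

    def triple_offsets(self) -> tuple[float, float, float]:
        """Axis coordinates of (S1, S2, S3) with S2 at the origin."""
        i, j, k = self.solver_triple
        o = self.mic_positions[j]
        return (self.mic_positions[i] - o, 0.0, self.mic_positions[k] - o)


@dataclass(frozen=True)
class TdoaMeasurement:
    """A pair of arrival-time differences with per-pair correlation confidence.

    ``t12`` is the arrival time at S1 minus the arrival time at S2 (seconds);
    ``t23`` likewise for S2 vs S3.  A feasible source requires
    ``|c*t12| <= a`` and ``|c*t23| <= b`` (the path difference between two
    points cannot exceed their separation).
    """

    t12: float
    t23: float
    pair_confidences: tuple[float, float] = (1.0, 1.0)

    @property
    def confidence(self) -> float:
        """Mean of the two pair confidences, in [0, 1]."""
        return float(np.mean(self.pair_confidences))

    def is_feasible(self, geometry: MicArrayGeometry, slack: float = 1e-12) -> bool:
        c = geometry.c
        return (
            abs(c * self.t12) <= geometry.a + slack
            and abs(c * self.t23) <= geometry.b + slack
        )


@dataclass(frozen=True)
class PolarFix:
    """A single-array localisation: range, axis angle, boresight angle.

    ``theta_axis`` is in degrees within [0, 180], measured from the S2->S3
    direction; ``phi_boresight = 90 - theta_axis`` is the signed offset from
    the array normal, positive on the S3 side.  ``farfield`` marks fixes whose
    range could not be resolved (``r2`` is then ``inf``).
    """

    r2: float
    theta_axis: float
    confidence: float = 1.0
    farfield: bool = False

    def __post_init__(self) -> None:
        if not self.farfield and not self.r2 > 0:
            raise InconsistentMeasurementError(
                f"non-positive range r2={self.r2!r} from a finite-range solve"
            )

    @property
    def phi_boresight(self) -> float:
        return axis_to_boresight(self.theta_axis)


def forward_delays(geometry: MicArrayGeometry, source_xy) -> TdoaMeasurement:
    """Exact arrival-time differences for a known planar source (the oracle).

    The source sits at ``source_xy = (x, y)`` in the array frame: the axis is
    the x-axis with S2 at the origin and S3 on the positive side.  Distances
    ``r_i`` to the three solver microphones give ``t12 = (r1 - r2)/c`` and
    ``t23 = (r2 - r3)/c``; pair confidences are 1 (exact).

    Raises
    ------
    DegenerateSourceError
        If the source coincides with one of the microphones.
    """
    x, y = float(source_xy[0]), float(source_xy[1])
    s1, s2, s3 = geometry.triple_offsets()
    r = [math.hypot(x - s, y) for s in (s1, s2, s3)]
    if min(r) == 0.0:
        raise DegenerateSourceError("source coincides with a microphone")
    c = geometry.c
    return TdoaMeasurement(t12=(r[0] - r[1]) / c, t23=(r[1] - r[2]) / c)


def _check_feasible(tdoa: TdoaMeasurement, geometry: MicArrayGeometry) -> None:
    if not tdoa.is_feasible(geometry):
        c = geometry.c
        raise InfeasibleTdoaError(
            f"|c*t12|={abs(c * tdoa.t12):.6g} vs a={geometry.a:.6g}, "
            f"|c*t23|={abs(c * tdoa.t23):.6g} vs b={geometry.b:.6g}"
        )


def solve_range(
    tdoa: TdoaMeasurement,
    geometry: MicArrayGeometry,
    farfield_tol: float = FARFIELD_TOL,
) -> float | FarField:
    """Range from the middle microphone, or :data:`FARFIELD`.

    Closed form from the two cosine-rule triangles:

    .. math::

        r_2 = \\frac{2b(c^2 t_{12}^2 - a^2) + 2a(c^2 t_{23}^2 - b^2)}
                    {4c(a t_{23} - b t_{12})}

    The denominator vanishes when the source recedes to infinity (the two
    TDOA hyperbolas become parallel lines), so ``|a t23 - b t12|`` below
    ``farfield_tol`` returns the far-field sentinel rather than a number.

    Raises
    ------
    InfeasibleTdoaError
        If a path difference exceeds its microphone spacing.
    InconsistentMeasurementError
        If the closed form returns a non-positive range.
    """
    _check_feasible(tdoa, geometry)
    a, b, c = geometry.a, geometry.b, geometry.c
    t12, t23 = tdoa.t12, tdoa.t23
    den = a * t23 - b * t12
    if abs(den) < farfield_tol:
        return FARFIELD
    num = 2 * b * (c**2 * t12**2 - a**2) + 2 * a * (c**2 * t23**2 - b**2)
    r2 = num / (4 * c * den)
    if r2 <= 0:
        raise InconsistentMeasurementError(
            f"closed-form range r2={r2:.6g} m is non-positive"
        )
    return r2


def solve_angle(tdoa: TdoaMeasurement, geometry: MicArrayGeometry) -> float:
    """Axis angle theta in degrees, [0, 180], from the closed form.

    .. math::

        \\cos\\theta = \\frac{2 t_{12}(b^2 c - c^3 t_{23}^2)
                             + 2 t_{23}(a^2 c - c^3 t_{12}^2)}
                            {2a(b^2 - c^2 t_{23}^2) + 2b(a^2 - c^2 t_{12}^2)}

    On-axis sources (``|c*t12| = a`` and ``|c*t23| = b``) drive the expression
    to 0/0; they are resolved by the delay signs (positive delays mean the
    wave reached S1 first, i.e. the source lies on the S3 side, theta = 0).

    Raises
    ------
    InfeasibleTdoaError, InconsistentMeasurementError
    """
    _check_feasible(tdoa, geometry)
    a, b, c = geometry.a, geometry.b, geometry.c
    t12, t23 = tdoa.t12, tdoa.t23
    den = 2 * a * (b**2 - c**2 * t23**2) + 2 * b * (a**2 - c**2 * t12**2)
    if abs(den) < 1e-300 or (
        abs(abs(c * t12) - a) < 1e-12 and abs(abs(c * t23) - b) < 1e-12
    ):
        # On-axis degeneracy: both pair delays saturate at the spacings.
        return 0.0 if t12 > 0 else 180.0
    num = 2 * t12 * (b**2 * c - c**3 * t23**2) + 2 * t23 * (a**2 * c - c**3 * t12**2)
    cos_theta = num / den
    if abs(cos_theta) > 1.0 + COS_TOL:
        raise InconsistentMeasurementError(
            f"cos(theta)={cos_theta:.9g} outside [-1, 1]"
        )
    cos_theta = min(1.0, max(-1.0, cos_theta))
    return math.degrees(math.acos(cos_theta))


def solve_fix(tdoa: TdoaMeasurement, geometry: MicArrayGeometry) -> PolarFix:
    """Full single-array fix: range + axis angle + propagated confidence."""
    theta = solve_angle(tdoa, geometry)
    r2 = solve_range(tdoa, geometry)
    if isinstance(r2, FarField):
        return PolarFix(
            r2=math.inf, theta_axis=theta, confidence=tdoa.confidence, farfield=True
        )
    return PolarFix(r2=r2, theta_axis=theta, confidence=tdoa.confidence)


def axis_to_boresight(theta_axis: float) -> float:
    """Map the axis angle theta (degrees, [0, 180]) to the signed boresight
    angle ``phi = 90 - theta`` (positive toward S3, i.e. the far end of the
    array)."""
    if not 0.0 <= theta_axis <= 180.0:
        raise ValueError(f"theta_axis={theta_axis!r} outside [0, 180]")
    return 90.0 - theta_axis
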