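"""Dual-array fusion, validity gating and gross-error filtering.

Two orthogonally mounted linear arrays each deliver a signed boresight angle
per one-second frame.  The sign pair selects one of four floor areas (the
pen is partitioned into laying / activity / two feeding-drinking areas).
Events are then gated: a record is *valid* only when both angles lie within
the effective window (default +/-30 deg, beyond which the fix is outside the
region of interest) and the fused correlation confidence exceeds 0.5
(strictly).  Laboratory sessions additionally pass angle series through an
iterative two-sided Grubbs test to drop gross errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SslEvent",
    "DEFAULT_AREA_MAPPING",
    "assign_area",
    "validate",
    "grubbs_critical_value",
    "grubbs_filter",
]

#: Sign-pair -> area-label mapping matching the default pen layout:
#: the first sign is array A's boresight angle, the second array B's.
DEFAULT_AREA_MAPPING: Mapping[tuple[str, str], str] = {
    ("+", "+"): "I",
    ("-", "+"): "II",
    ("-", "-"): "III",
    ("+", "-"): "IV",
}

DEFAULT_ANGLE_LIMIT = 30.0
DEFAULT_CONF_THRESHOLD = 0.5


@dataclass(frozen=True)
class SslEvent:
    """One 1 s monitoring record.

    ``status`` is ``"null"`` when no sound was present (angles are ``None``),
    ``"valid"`` when both angles are inside the effective window and the
    confidence clears its threshold, ``"invalid"`` otherwise.  Invalid events
    keep their measured values for audit.
    """

    timestamp: float
    phi_A: float | None = None
    phi_B: float | None = None
    confidence: float | None = None
    area: str | None = None
    status: str = "null"

    def is_null(self) -> bool:
        return self.phi_A is None or self.phi_B is None


def _sign(angle: float) -> str:
    """Sign label with zero tied to the positive side (documented tie-break
    so area counts are reproducible)."""
    return "+" if angle >= 0.0 else "-"


def assign_area(
    phi_A: float,
    phi_B: float,
    mapping: Mapping[tuple[str, str], str] = DEFAULT_AREA_MAPPING,
) -> str:
    """Area label from the sign pair of the two boresight angles."""
    if not (math.isfinite(phi_A) and math.isfinite(phi_B)):
        raise ValueError("boresight angles must be finite")
    return mapping[(_sign(phi_A), _sign(phi_B))]


def validate(
    event: SslEvent,
    angle_limit: float = DEFAULT_ANGLE_LIMIT,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> SslEvent:
    """Return the event with ``status`` set per the validity gates.

    Null events stay null.  Otherwise the event is valid iff
    ``|phi_A| <= angle_limit``, ``|phi_B| <= angle_limit`` and
    ``confidence > conf_threshold`` (strict, so a confidence of exactly 0.5
    is rejected).  Idempotent.
    """
    if event.is_null():
        return replace(event, status="null", area=None)
    ok = (
        abs(event.phi_A) <= angle_limit
        and abs(event.phi_B) <= angle_limit
        and event.confidence is not None
        and event.confidence > conf_threshold
    )
    return replace(event, status="valid" if ok else "invalid")


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    From the Student-t quantile ``t = t_{alpha/(2n), n-2}``:

    .. math:: G_{crit} = \\frac{n-1}{\\sqrt n}\\sqrt{\\frac{t^2}{n-2+t^2}}
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], list[int]]:
    """Iterative two-sided Grubbs outlier removal.

    Repeatedly removes the single most extreme value while
    ``G = max|x - mean| / sd`` exceeds ``G_crit(n, alpha)``, recomputing the
    statistics after each removal.  Sequences shorter than 3, or with zero
    spread, are returned unchanged.

    Returns
    -------
    (retained, removed_indices)
        Survivors in original order, and the indices (into the original
        sequence) of the removed values in removal order.
    """
    vals = [float(v) for v in values]
    idx = list(range(len(vals)))
    removed: list[int] = []
    while len(vals) >= 3:
        arr = np.asarray(vals)
        sd = arr.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(arr - arr.mean())
        j = int(np.argmax(dev))
        if dev[j] / sd <= grubbs_critical_value(len(vals), alpha):
            break
        removed.append(idx.pop(j))
        vals.pop(j)
    return vals, removed
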