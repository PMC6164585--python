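"""Evaluation and monitoring statistics for SSL event logs.

Covers the bookkeeping used when reporting a monitoring campaign: the
percent accuracy of area recognition (correct / (correct + incorrect)),
valid-record arithmetic (valid = non-null - invalid), hourly vocalisation
counts, per-bird calling rates, and night-time area distributions.  A
"vocalisation" here is a one-second frame that produced a valid localisation
— the pipeline's proxy for flock calling activity.  Non-null counts (sound
present, localisation possibly outside the gates) are exposed separately.
"""

from __future__ import annotations

from collections import Counter
from datetime import datetime
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fusion import SslEvent

__all__ = [
    "accuracy",
    "accuracy_table",
    "validity_bookkeeping",
    "hourly_counts",
    "per_bird_rate",
    "area_distribution",
    "session_summary",
]

AREAS = ("I", "II", "III", "IV")


def accuracy(correct: int, incorrect: int) -> float:
    """Percent of successful localisations, rounded to 1 decimal (half-up).

    ``100 * correct / (correct + incorrect)``, the convention used in area
    recognition tables.  Undefined when both counts are zero.
    """
    if correct < 0 or incorrect < 0:
        raise ValueError("counts must be non-negative")
    total = correct + incorrect
    if total == 0:
        raise ZeroDivisionError("accuracy undefined: no localisations")
    pct = Decimal(100 * correct) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def accuracy_table(per_area: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-area accuracy table with a totals row.

    Parameters
    ----------
    per_area
        Mapping of area label -> (correct, incorrect) counts.

    Returns
    -------
    DataFrame indexed by area (plus ``"Total"``) with columns
    ``correct``, ``incorrect``, ``total``, ``accuracy_pct``.
    """
    rows = {}
    tot_c = tot_i = 0
    for area, (c, i) in per_area.items():
        rows[area] = (c, i, c + i, accuracy(c, i))
        tot_c += c
        tot_i += i
    rows["Total"] = (tot_c, tot_i, tot_c + tot_i, accuracy(tot_c, tot_i))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["correct", "incorrect", "total", "accuracy_pct"]
    )


def validity_bookkeeping(total_ssls: int, non_null: int, invalid: int) -> int:
    """Valid-record count from session totals: valid = non-null - invalid.

    ``total_ssls`` counts every one-second measurement attempt; ``non_null``
    those with sound present; ``invalid`` those rejected by the angle or
    confidence gates.  Raises on inconsistent logs.
    """
    if not 0 <= invalid <= non_null <= total_ssls:
        raise ValueError(
            f"inconsistent log: total={total_ssls}, non_null={non_null}, "
            f"invalid={invalid}"
        )
    return non_null - invalid


def _event_hour(event: SslEvent, session_start: datetime | None) -> int:
    if session_start is None:
        return int(event.timestamp // 3600)
    return int(
        (session_start.hour * 3600 + session_start.minute * 60
         + session_start.second + event.timestamp) // 3600
    ) % 24


def hourly_counts(
    events: Iterable[SslEvent], session_start: datetime | None = None
) -> dict[int, int]:
    """Valid vocalisations per hour.

    With ``session_start`` the keys are clock hours (0-23, wrapping);
    otherwise hours since the session began.  Only ``status == "valid"``
    events are counted — at most 3600 per hour under 1 s framing.
    """
    counts: Counter[int] = Counter()
    for ev in events:
        if ev.status == "valid":
            counts[_event_hour(ev, session_start)] += 1
    return dict(counts)


def per_bird_rate(count: int, flock_size: int) -> float:
    """Vocalisations per bird: ``count / flock_size``."""
    if flock_size <= 0:
        raise ValueError("flock_size must be positive")
    return count / flock_size


def area_distribution(
    events: Iterable[SslEvent],
    window: tuple[float, float] | None = None,
    grouping: Sequence[frozenset[str] | set[str]] | None = None,
) -> dict[str, int]:
    """Counts of valid events per area (or grouped areas) within a window.

    ``window`` is an optional half-open ``[t0, t1)`` interval in session
    seconds.  ``grouping`` optionally pools areas, e.g.
    ``[{"I", "II"}, {"III", "IV"}]`` for the nest-side vs feeder-side split
    used when screening night activity; group keys join their members with
    ``"+"``.
    """
    base: Counter[str] = Counter()
    for ev in events:
        if ev.status != "valid" or ev.area is None:
            continue
        if window is not None and not (window[0] <= ev.timestamp < window[1]):
            continue
        base[ev.area] += 1
    if grouping is None:
        return {a: base.get(a, 0) for a in AREAS}
    out: dict[str, int] = {}
    for group in grouping:
        members = sorted(group, key=AREAS.index)
        out["+".join(members)] = sum(base.get(a, 0) for a in members)
    return out


def session_summary(events: Sequence[SslEvent]) -> dict[str, int]:
    """Status bookkeeping for one event log.

    Returns total / non-null / invalid / valid counts; satisfies
    ``valid == non_null - invalid`` by construction of the statuses.
    """
    total = len(events)
    non_null = sum(1 for e in events if e.status != "null")
    invalid = sum(1 for e in events if e.status == "invalid")
    valid = sum(1 for e in events if e.status == "valid")
    return {
        "total_ssls": total,
        "non_null": non_null,
        "invalid": invalid,
        "valid": valid,
    }
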