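"""Co-occurrence events at two temporal scales, and capture-interval summaries.

Under the gambit of the group, individuals recorded in the same sampling event
are treated as associating. Two scales are supported:

* ``deployment`` — everything caught in one net soak (site, date, set number);
  this is the information a typical fishing report would give.
* ``simultaneous`` — members of a deployment whose recorded capture times
  coincide (within an optional tolerance, default 0 = identical minutes);
  the finest co-occurrence the survey clock can resolve.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catchdata import CatchRecord, DeploymentEvent

log = logging.getLogger(__name__)

SCALES = ("deployment", "simultaneous")


def _sort_key(r: CatchRecord):
    t = r.time_minutes
    return (t if t is not None else 10_000, r.record_id)


@dataclass
class CoocEvent:
    """A set of records deemed co-occurring at a given temporal scale."""
    scale: str
    members: list[CatchRecord]
    deployment_key: tuple[str, dt.date, int]
    event_time: dt.time | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}")
        if not self.members:
            raise ValueError("an event needs at least one member")
        for m in self.members:
            if m.deployment_key != self.deployment_key:
                raise ValueError("all members must share the deployment key")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def site(self) -> str:
        return self.deployment_key[0]

    @property
    def date(self) -> dt.date:
        return self.deployment_key[1]

    @property
    def event_id(self) -> str:
        site, date, setn = self.deployment_key
        base = f"{site}|{date.isoformat()}|{setn}"
        if self.scale == "simultaneous" and self.event_time is not None:
            return base + "@" + self.event_time.strftime("%H:%M")
        return base

    @property
    def tagged_ids(self) -> list[str]:
        seen, out = set(), []
        for m in self.members:
            if m.individual_id is not None and m.individual_id not in seen:
                seen.add(m.individual_id)
                out.append(m.individual_id)
        return out


def build_deployment_events(records: Sequence[CatchRecord]) -> list[CoocEvent]:
    """One event per distinct (site, date, set_number); partitions the records."""
    groups: dict[tuple, list[CatchRecord]] = {}
    for r in records:
        groups.setdefault(r.deployment_key, []).append(r)
    events = []
    for key in sorted(groups, key=lambda k: (k[0], k[1].isoformat(), k[2])):
        members = sorted(groups[key], key=_sort_key)
        events.append(CoocEvent("deployment", members, key))
    return events


def build_simultaneous_events(
    deployment_event: CoocEvent,
    tolerance_minutes: int = 0,
) -> list[CoocEvent]:
    """Greedy left-to-right time windows within one deployment.

    Members are sorted by capture time; each window is anchored at the
    earliest unassigned capture and absorbs every capture within
    ``tolerance_minutes`` of the anchor. Windows holding >= 2 members are
    returned as simultaneous events. Members without a capture time are
    excluded (with a warning). Deterministic: ties broken by record_id.
    """
    if tolerance_minutes < 0:
        raise ValueError("tolerance_minutes must be >= 0")
    timed = [m for m in deployment_event.members if m.time_minutes is not None]
    n_untimed = deployment_event.n - len(timed)
    if n_untimed:
        log.warning("%d members without capture time excluded from "
                    "simultaneous grouping in %s", n_untimed,
                    deployment_event.event_id)
    timed.sort(key=_sort_key)
    events: list[CoocEvent] = []
    i = 0
    while i < len(timed):
        anchor = timed[i].time_minutes
        j = i
        while j < len(timed) and timed[j].time_minutes - anchor <= tolerance_minutes:
            j += 1
        if j - i >= 2:
            events.append(CoocEvent(
                "simultaneous", timed[i:j], deployment_event.deployment_key,
                event_time=timed[i].capture_time))
        i = j
    return events


def build_all_simultaneous(
    deployment_events: Sequence[CoocEvent],
    tolerance_minutes: int = 0,
) -> list[CoocEvent]:
    out: list[CoocEvent] = []
    for ev in deployment_events:
        out.extend(build_simultaneous_events(ev, tolerance_minutes))
    return out


@dataclass
class IntervalSummary:
    """Per-deployment first-to-last spans and consecutive inter-capture gaps.

    Computed only over multi-shark deployments with >= 2 timed captures;
    deployments soaking longer than the exclusion threshold (night-fishing
    pilots and the like) are dropped and counted.
    """
    spans_minutes: list[float] = field(default_factory=list)
    gaps_minutes: list[float] = field(default_factory=list)
    n_excluded_long_soak: int = 0
    n_deployments_used: int = 0

    @property
    def median_span(self) -> float | None:
        return float(np.median(self.spans_minutes)) if self.spans_minutes else None

    @property
    def span_range(self) -> tuple[float, float] | None:
        if not self.spans_minutes:
            return None
        return (min(self.spans_minutes), max(self.spans_minutes))

    @property
    def median_gap(self) -> float | None:
        return float(np.median(self.gaps_minutes)) if self.gaps_minutes else None

    @property
    def gap_range(self) -> tuple[float, float] | None:
        if not self.gaps_minutes:
            return None
        return (min(self.gaps_minutes), max(self.gaps_minutes))

    def to_dict(self) -> dict:
        return {
            "n_deployments_used": self.n_deployments_used,
            "n_excluded_long_soak": self.n_excluded_long_soak,
            "median_span_minutes": self.median_span,
            "span_range_minutes": self.span_range,
            "median_gap_minutes": self.median_gap,
            "gap_range_minutes": self.gap_range,
        }


def interval_summary(
    deployment_events: Sequence[CoocEvent],
    max_span_hours_exclude: float = 20.0,
) -> IntervalSummary:
    summary = IntervalSummary()
    for ev in deployment_events:
        if ev.n < 2:
            continue
        times = sorted(m.time_minutes for m in ev.members
                       if m.time_minutes is not None)
        if len(times) < 2:
            continue
        span = float(times[-1] - times[0])
        if span > max_span_hours_exclude * 60:
            summary.n_excluded_long_soak += 1
            continue
        summary.n_deployments_used += 1
        summary.spans_minutes.append(span)
        summary.gaps_minutes.extend(
            float(b - a) for a, b in zip(times, times[1:]))
    return summary


def group_by_individual_matrix(
    events: Sequence[CoocEvent],
    tagged_only: bool = True,
) -> pd.DataFrame:
    """Binary events-by-individuals incidence (the substrate for swap nulls).

    Rows are events (by event_id, input order preserved), columns tagged
    individuals (sorted). Entry 1 iff the individual appears in the event.
    """
    del tagged_only  # identity requires tags; untagged cannot be columns
    ids = sorted({i for ev in events for i in ev.tagged_ids})
    if not ids:
        log.warning("no tagged individuals: incidence matrix is empty")
        return pd.DataFrame(index=[ev.event_id for ev in events], dtype=int)
    col = {i: k for k, i in enumerate(ids)}
    arr = np.zeros((len(events), len(ids)), dtype=int)
    for row, ev in enumerate(events):
        for i in ev.tagged_ids:
            arr[row, col[i]] = 1
    return pd.DataFrame(arr, index=[ev.event_id for ev in events],
                        columns=ids)


def events_to_frame(events: Iterable[CoocEvent]) -> pd.DataFrame:
    """One row per event: key, size, and semicolon-joined member IDs."""
    rows = []
    for ev in events:
        site, date, setn = ev.deployment_key
        rows.append({
            "event_id": ev.event_id,
            "scale": ev.scale,
            "site": site,
            "date": date.isoformat(),
            "set_number": setn,
            "year": date.year,
            "month": date.month,
            "event_time": (ev.event_time.strftime("%H:%M")
                           if ev.event_time else None),
            "n": ev.n,
            "n_tagged": len(ev.tagged_ids),
            "member_ids": ";".join(ev.tagged_ids),
            "member_records": ";".join(m.record_id for m in ev.members),
        })
    return pd.DataFrame(rows)
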