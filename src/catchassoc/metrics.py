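"""The five descriptive metrics for aggregation inference from catch data.

i.   number/density of individuals captured per event;
ii.  phenotypic trait composition (event sex ratio, fork-length range);
iii. drivers of co-occurrence (site fidelity enters here; environmental
     covariates live in the regression stage);
iv.  identification of specific individuals (recaptures, recaptured-together);
v.   kin structure among co-captured dyads.

Event-level conventions: sex ratio is males / sexed members (0 = all female,
1 = all male); "size variance" is the max-minus-min fork-length range, in mm,
square-root transformed downstream. Unsexed and unmeasured members are
excluded from the respective metric but still count toward event size.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .catchdata import CatchRecord, KinshipTable
from .events import CoocEvent

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# metric i — number of individuals captured

@dataclass
class CatchSizeSummary:
    sizes: list[int]
    histogram: dict[int, int]

    @property
    def n_single(self) -> int:
        return sum(1 for s in self.sizes if s == 1)

    @property
    def n_multi(self) -> int:
        return sum(1 for s in self.sizes if s >= 2)

    @property
    def prevalence_multi(self) -> float:
        return self.n_multi / len(self.sizes)

    @property
    def max_size(self) -> int:
        return max(self.sizes)

    def to_dict(self) -> dict:
        return {
            "n_events": len(self.sizes),
            "n_single": self.n_single,
            "n_multi": self.n_multi,
            "prevalence_multi": self.prevalence_multi,
            "max_size": self.max_size,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
        }


def catch_size_summary(events: Sequence[CoocEvent]) -> CatchSizeSummary:
    if not events:
        raise ValueError("no events: cannot summarise catch sizes")
    sizes = [ev.n for ev in events]
    return CatchSizeSummary(sizes=sizes, histogram=dict(Counter(sizes)))


# --------------------------------------------------------------------------
# metric ii — trait composition per event

@dataclass
class SexRatioPoint:
    event_id: str
    n_male: int
    n_female: int

    @property
    def ratio(self) -> float:
        return self.n_male / (self.n_male + self.n_female)

    @property
    def category(self) -> str:
        if self.n_male == 0:
            return "all_female"
        if self.n_female == 0:
            return "all_male"
        return "mixed"


def sex_ratio_points(events: Sequence[CoocEvent]) -> list[SexRatioPoint]:
    """One point per event with >= 1 sexed member; unsexed members skipped."""
    points = []
    for ev in events:
        n_m = sum(1 for m in ev.members if m.sex == "male")
        n_f = sum(1 for m in ev.members if m.sex == "female")
        if n_m + n_f == 0:
            continue
        points.append(SexRatioPoint(ev.event_id, n_m, n_f))
    return points


@dataclass
class SizeVariancePoint:
    event_id: str
    n_measured: int
    fl_range_mm: float

    @property
    def sqrt_fl_range(self) -> float:
        return math.sqrt(self.fl_range_mm)

    @property
    def singleton(self) -> bool:
        """Range of < 2 measured members is reported as 0 but flagged."""
        return self.n_measured < 2


def size_variance_points(events: Sequence[CoocEvent]) -> list[SizeVariancePoint]:
    points = []
    for ev in events:
        fls = [m.fork_length_mm for m in ev.members
               if m.fork_length_mm is not None]
        if not fls:
            continue
        rng = float(max(fls) - min(fls)) if len(fls) >= 2 else 0.0
        points.append(SizeVariancePoint(ev.event_id, len(fls), rng))
    return points


# --------------------------------------------------------------------------
# metric iv — identification of specific individuals

@dataclass
class IndividualHistory:
    """Ordered captures of one tagged individual."""
    individual_id: str
    captures: list[tuple[CoocEvent, CatchRecord]] = field(default_factory=list)

    @property
    def n_captures(self) -> int:
        return len(self.captures)

    @property
    def first_site(self) -> str:
        return self.captures[0][0].site


def _capture_order(ev: CoocEvent, rec: CatchRecord):
    t = rec.time_minutes
    return (ev.date.isoformat(), t if t is not None else 10_000, rec.record_id)


def build_histories(events: Sequence[CoocEvent]) -> dict[str, IndividualHistory]:
    """Per-individual ordered capture histories from deployment-scale events."""
    histories: dict[str, IndividualHistory] = {}
    for ev in events:
        for rec in ev.members:
            if rec.individual_id is None:
                continue
            histories.setdefault(
                rec.individual_id, IndividualHistory(rec.individual_id)
            ).captures.append((ev, rec))
    for h in histories.values():
        h.captures.sort(key=lambda pair: _capture_order(*pair))
    return histories


@dataclass
class RecaptureSummary:
    n_individuals: int = 0
    n_individuals_recaptured: int = 0
    n_recapture_events: int = 0
    n_recaptured_together: int = 0
    n_repeat_dyads: int = 0
    n_recaptures_at_first_site: int = 0
    capture_counts: dict[str, int] = field(default_factory=dict)

    @property
    def site_fidelity_fraction(self) -> float | None:
        if self.n_recapture_events == 0:
            return None
        return self.n_recaptures_at_first_site / self.n_recapture_events

    @property
    def fraction_recaptured_together(self) -> float | None:
        if self.n_recapture_events == 0:
            return None
        return self.n_recaptured_together / self.n_recapture_events

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_individuals_recaptured": self.n_individuals_recaptured,
            "n_recapture_events": self.n_recapture_events,
            "n_recaptured_together": self.n_recaptured_together,
            "n_repeat_dyads": self.n_repeat_dyads,
            "site_fidelity_fraction": self.site_fidelity_fraction,
            "fraction_recaptured_together": self.fraction_recaptured_together,
        }


def recapture_summary(
    histories: Mapping[str, IndividualHistory],
    events: Sequence[CoocEvent] | None = None,
) -> RecaptureSummary:
    """Recapture accounting per the capture-event convention.

    A *recapture event* is any capture of a tagged individual after its first
    (each later capture counts once). It is *recaptured together* iff at least
    one co-member of the current event also shared an earlier event with the
    focal individual. ``n_repeat_dyads`` additionally reports the dyad-level
    view: distinct pairs co-occurring in >= 2 events.
    """
    del events  # histories already carry the events; kept for API symmetry
    summary = RecaptureSummary()
    if not histories:
        log.warning("no tagged individuals: empty recapture summary")
        return summary
    summary.n_individuals = len(histories)
    dyad_counts: Counter[frozenset[str]] = Counter()
    for ind_id in sorted(histories):
        hist = histories[ind_id]
        summary.capture_counts[ind_id] = hist.n_captures
        if hist.n_captures < 2:
            continue
        summary.n_individuals_recaptured += 1
        past_partners: set[str] = set()
        first_site = hist.first_site
        for k, (ev, _rec) in enumerate(hist.captures):
            comembers = {i for i in ev.tagged_ids if i != ind_id}
            if k > 0:
                summary.n_recapture_events += 1
                if ev.site == first_site:
                    summary.n_recaptures_at_first_site += 1
                if comembers & past_partners:
                    summary.n_recaptured_together += 1
            past_partners |= comembers
    # dyad-level repeat co-occurrence, from the same histories
    event_pair_sets: dict[str, set[str]] = {}
    for ind_id, hist in histories.items():
        for ev, _rec in hist.captures:
            event_pair_sets.setdefault(ev.event_id, set()).add(ind_id)
    for members in event_pair_sets.values():
        ms = sorted(members)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                dyad_counts[frozenset((ms[i], ms[j]))] += 1
    summary.n_repeat_dyads = sum(1 for c in dyad_counts.values() if c >= 2)
    return summary


# --------------------------------------------------------------------------
# metric v — kin structure

@dataclass
class KinOverlapSummary:
    n_pairs_total: int = 0
    n_cocaptured_pairs_assessed: int = 0
    n_kin_pairs: int = 0
    n_unknown_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "n_pairs_total": self.n_pairs_total,
            "n_cocaptured_pairs_assessed": self.n_cocaptured_pairs_assessed,
            "n_kin_pairs": self.n_kin_pairs,
            "n_unknown_pairs": self.n_unknown_pairs,
        }


def kin_overlap(
    events: Sequence[CoocEvent],
    kinship: KinshipTable,
    restrict_to: str = "co_captured",
) -> KinOverlapSummary:
    """Sibship among co-captured dyads.

    ``restrict_to="co_captured"`` assesses every distinct pair sharing >= 1
    event; ``"recaptured_together"`` only pairs sharing >= 2 events. Pairs
    absent from the kinship table count as unknown and are excluded from the
    assessed denominator.
    """
    if restrict_to not in ("co_captured", "recaptured_together"):
        raise ValueError(f"unknown restrict_to {restrict_to!r}")
    pair_events: Counter[frozenset[str]] = Counter()
    for ev in events:
        ids = ev.tagged_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pair_events[frozenset((ids[i], ids[j]))] += 1
    min_shared = 2 if restrict_to == "recaptured_together" else 1
    summary = KinOverlapSummary()
    for pair, n_shared in pair_events.items():
        if n_shared < min_shared:
            continue
        summary.n_pairs_total += 1
        a, b = sorted(pair)
        rel = kinship.relationship(a, b)
        if rel == "unknown":
            summary.n_unknown_pairs += 1
        else:
            summary.n_cocaptured_pairs_assessed += 1
            if rel == "sibling":
                summary.n_kin_pairs += 1
    return summary


# --------------------------------------------------------------------------
# aggregate report

def metrics_report(
    events: Sequence[CoocEvent],
    kinship: KinshipTable | None = None,
) -> dict:
    """All five metrics for one scale, as a JSON-ready mapping."""
    histories = build_histories(events)
    rec = recapture_summary(histories)
    points_sex = sex_ratio_points(events)
    points_size = size_variance_points(events)
    multi_sex = [p for p in points_sex if p.n_male + p.n_female >= 2]
    report = {
        "catch_size": catch_size_summary(events).to_dict(),
        "sex_composition": {
            "n_events_sexed": len(points_sex),
            "n_multi_sexed": len(multi_sex),
            "n_all_male": sum(1 for p in multi_sex if p.category == "all_male"),
            "n_all_female": sum(1 for p in multi_sex if p.category == "all_female"),
            "n_mixed": sum(1 for p in multi_sex if p.category == "mixed"),
        },
        "size_variance": {
            "n_events_measured": len(points_size),
            "max_range_mm": (max(p.fl_range_mm for p in points_size)
                             if points_size else None),
            "mean_range_mm": (sum(p.fl_range_mm for p in points_size)
                              / len(points_size) if points_size else None),
        },
        "recapture": rec.to_dict(),
    }
    if kinship is not None:
        report["kin"] = kin_overlap(
            events, kinship, restrict_to="recaptured_together").to_dict()
        report["kin_all_cocaptures"] = kin_overlap(
            events, kinship, restrict_to="co_captured").to_dict()
    return report
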