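import itertools

import numpy as np
import pytest

from catchassoc.catchdata import KinshipTable
from catchassoc.events import build_deployment_events
from catchassoc.metrics import (
    build_histories, catch_size_summary, kin_overlap, recapture_summary,
    sex_ratio_points, size_variance_points)
from tests.conftest import rec


def events_from_layout(layout):
    """layout: list of (site, date, member individual ids)."""
    records = []
    for k, (site, date, members) in enumerate(layout):
        for ind in members:
            records.append(rec(site=site, date=date, ind=ind,
                               rid=f"r{k}-{ind}"))
    return build_deployment_events(records)


class TestCatchSize:
    def test_half_multi(self):
        events = events_from_layout([
            ("A", "2021-10-01", ["a"]), ("A", "2021-10-02", ["b"]),
            ("A", "2021-10-03", ["c", "d"]),
            ("A", "2021-10-04", ["e", "f", "g"])])
        s = catch_size_summary(events)
        assert (s.n_single, s.n_multi, s.prevalence_multi) == (2, 2, 0.5)
        assert s.histogram == {1: 2, 2: 1, 3: 1}

    def test_all_multi(self):
        events = events_from_layout(
            [("A", f"2021-10-0{d}", ["x", "y"]) for d in (1, 2, 3)])
        assert catch_size_summary(events).prevalence_multi == 1.0

    def test_empty_event_list_is_error(self):
        with pytest.raises(ValueError):
            catch_size_summary([])


class TestSexRatio:
    @pytest.mark.parametrize("sexes, ratio, category", [
        (["male"] * 3, 1.0, "all_male"),
        (["female"] * 2, 0.0, "all_female"),
        (["male", "male", "female"], 2 / 3, "mixed"),
    ])
    def test_ratio_and_category(self, sexes, ratio, category):
        records = [rec(ind=f"i{k}", sex=s, rid=f"r{k}")
                   for k, s in enumerate(sexes)]
        [point] = sex_ratio_points(build_deployment_events(records))
        assert point.ratio == pytest.approx(ratio)
        assert point.category == category

    def test_unsexed_members_skipped_and_unsexed_events_dropped(self):
        records = [rec(ind="a", sex="male", rid="r1"),
                   rec(ind="b", sex="unknown", rid="r2")]
        [point] = sex_ratio_points(build_deployment_events(records))
        assert (point.n_male, point.n_female) == (1, 0)
        unsexed = [rec(ind="c", sex="unknown", rid="r3")]
        assert sex_ratio_points(build_deployment_events(unsexed)) == []

    def test_category_partitions_ratio_space(self):
        for n_m, n_f in itertools.product(range(4), range(4)):
            if n_m + n_f == 0:
                continue
            records = ([rec(ind=f"m{i}", sex="male", rid=f"m{i}")
                        for i in range(n_m)]
                       + [rec(ind=f"f{i}", sex="female", rid=f"f{i}")
                          for i in range(n_f)])
            [p] = sex_ratio_points(build_deployment_events(records))
            assert (p.category == "all_female") == (p.ratio == 0.0)
            assert (p.category == "all_male") == (p.ratio == 1.0)
            assert (p.category == "mixed") == (0.0 < p.ratio < 1.0)


class TestSizeVariance:
    def test_range_and_sqrt_by_hand(self):
        records = [rec(ind=f"i{k}", fl=fl, rid=f"r{k}")
                   for k, fl in enumerate((400, 500, 480))]
        [p] = size_variance_points(build_deployment_events(records))
        assert p.fl_range_mm == 100.0 and p.sqrt_fl_range == 10.0

    def test_equal_lengths_zero_range(self):
        records = [rec(ind=f"i{k}", fl=450, rid=f"r{k}") for k in range(3)]
        [p] = size_variance_points(build_deployment_events(records))
        assert p.fl_range_mm == 0.0 and not p.singleton

    def test_extreme_juvenile_pair(self):
        records = [rec(ind="a", fl=392, rid="r1"),
                   rec(ind="b", fl=698, rid="r2")]
        [p] = size_variance_points(build_deployment_events(records))
        assert p.fl_range_mm == 306.0

    def test_single_measured_member_flagged(self):
        records = [rec(ind="a", fl=450, rid="r1"), rec(ind="b", rid="r2")]
        [p] = size_variance_points(build_deployment_events(records))
        assert p.singleton and p.fl_range_mm == 0.0


def recapture_oracle(events):
    """Brute force over all (individual, capture-index) pairs with explicit
    double loops over earlier events — independent of the incremental path."""
    caps = {}
    for ev in sorted(events, key=lambda e: e.date):  # chronological order
        for ind in ev.tagged_ids:
            caps.setdefault(ind, []).append(ev)
    n_recap = n_together = n_home = 0
    for ind, evs in caps.items():
        for k in range(1, len(evs)):
            n_recap += 1
            if evs[k].site == evs[0].site:
                n_home += 1
            together = False
            for other in evs[k].tagged_ids:
                if other == ind:
                    continue
                for m in range(k):
                    if other in evs[m].tagged_ids:
                        together = True
            n_together += together
    dyads = {}
    for ev in events:
        ids = ev.tagged_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                key = frozenset((ids[i], ids[j]))
                dyads[key] = dyads.get(key, 0) + 1
    return n_recap, n_together, n_home, sum(1 for v in dyads.values() if v >= 2)


class TestRecaptures:
    def test_pair_recaptured_together(self):
        events = events_from_layout([
            ("A", "2021-10-01", ["x", "y"]),
            ("A", "2021-10-10", ["x", "y"])])
        s = recapture_summary(build_histories(events))
        assert s.n_recapture_events == 2      # one per individual
        assert s.n_recaptured_together == 2
        assert s.n_repeat_dyads == 1
        assert s.site_fidelity_fraction == 1.0

    def test_lone_recapture_not_together(self):
        events = events_from_layout([
            ("A", "2021-10-01", ["x"]), ("A", "2021-10-10", ["x"])])
        s = recapture_summary(build_histories(events))
        assert (s.n_recapture_events, s.n_recaptured_together) == (1, 0)

    def test_all_first_captures(self):
        events = events_from_layout([
            ("A", "2021-10-01", ["x"]), ("A", "2021-10-10", ["y"])])
        s = recapture_summary(build_histories(events))
        assert s.n_recapture_events == 0
        assert s.site_fidelity_fraction is None

    def test_untagged_only_warns_and_is_empty(self):
        events = build_deployment_events([rec(ind=None)])
        s = recapture_summary(build_histories(events))
        assert s.n_individuals == 0

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n_events = int(rng.integers(2, 7))
            layout = []
            for k in range(n_events):
                members = list({f"i{rng.integers(6)}"
                                for _ in range(rng.integers(1, 5))})
                site = "AB"[int(rng.integers(2))]
                layout.append((site, f"2021-10-{k + 1:02d}", members))
            events = events_from_layout(layout)
            s = recapture_summary(build_histories(events))
            n_recap, n_together, n_home, n_dyads = recapture_oracle(events)
            assert s.n_recapture_events == n_recap
            assert s.n_recaptured_together == n_together
            assert s.n_recaptures_at_first_site == n_home
            assert s.n_repeat_dyads == n_dyads


class TestKinOverlap:
    @pytest.fixture
    def kinship(self):
        t = KinshipTable()
        t.add("a", "b", "sibling")
        t.add("c", "d", "sibling")
        t.add("e", "f", "unrelated")
        return t

    def test_sibling_pair_counted(self, kinship):
        events = events_from_layout([("A", "2021-10-01", ["a", "b"])])
        s = kin_overlap(events, kinship)
        assert s.n_kin_pairs == 1 and s.n_cocaptured_pairs_assessed == 1

    def test_absent_pair_is_unknown(self, kinship):
        events = events_from_layout([("A", "2021-10-01", ["a", "z"])])
        s = kin_overlap(events, kinship)
        assert s.n_unknown_pairs == 1
        assert s.n_cocaptured_pairs_assessed == 0

    def test_mixed_dyads_hand_count(self, kinship):
        events = events_from_layout([
            ("A", "2021-10-01", ["a", "b"]),
            ("A", "2021-10-02", ["c", "d"]),
            ("A", "2021-10-03", ["e", "f"]),
            ("A", "2021-10-04", ["a", "q"])])
        s = kin_overlap(events, kinship)
        assert s.n_pairs_total == 4
        assert s.n_cocaptured_pairs_assessed == 3
        assert s.n_kin_pairs == 2
        assert s.n_unknown_pairs == 1

    def test_restrict_to_recaptured_together(self, kinship):
        events = events_from_layout([
            ("A", "2021-10-01", ["a", "b"]),
            ("A", "2021-10-02", ["a", "b"]),
            ("A", "2021-10-03", ["e", "f"])])
        s = kin_overlap(events, kinship, restrict_to="recaptured_together")
        assert s.n_pairs_total == 1 and s.n_kin_pairs == 1


class TestScaleConsistency:
    def test_simultaneous_size_range_never_exceeds_deployment(
            self, small_solitary):
        from catchassoc.events import build_all_simultaneous
        deps = build_deployment_events(small_solitary.records)
        dep_ranges = {ev.event_id: p.fl_range_mm
                      for ev, p in zip(deps, size_variance_points(deps))}
        dep_by_key = {ev.deployment_key: ev.event_id for ev in deps}
        sims = build_all_simultaneous(deps)
        for ev, p in zip(sims, size_variance_points(sims)):
            parent = dep_by_key[ev.deployment_key]
            assert p.fl_range_mm <= dep_ranges[parent] + 1e-9
        # fewer simultaneous events than multi-shark deployments
        assert len(sims) <= sum(1 for ev in deps if ev.n >= 2)
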