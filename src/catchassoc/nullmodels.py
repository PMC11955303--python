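"""Permutation null models: does co-occurrence or assortment exceed chance?

Three tests, one per line of evidence:

* :func:`aggregation_test` — are multi-individual capture events more common
  than expected if individuals were scattered independently over events?
  Null: each individual is assigned independently and uniformly at random to
  one event, preserving the number of individuals and events. With ``strata``
  (e.g. site x month), assignment is uniform within each stratum, which
  conditions out sampling-design heterogeneity (effort, seasonality, site
  faithfulness) that would otherwise masquerade as aggregation.
* :func:`assortment_test` — do co-captured individuals share traits (sex,
  fork length) beyond chance? Null: trait labels permuted across individuals
  with the event-membership structure held fixed.
* :func:`companion_preference_test` — are specific dyads captured together
  repeatedly? Null: checkerboard (2x2 submatrix) swaps on the binary
  events-by-individuals incidence, preserving all row and column totals
  (event sizes and individual capture counts).

All p-values use the add-one rule p = (r + 1) / (n + 1), where r counts
null replicates at least as extreme as the observed statistic, so Monte
Carlo never reports p = 0.
"""
from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

DIRECTIONS = ("greater", "less", "two_sided")


@dataclass
class NullResult:
    statistic: str
    observed: float
    n_replicates: int
    p_value: float
    direction: str
    seed: int
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    note: str = ""
    null_values: np.ndarray | None = None

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value <= 0.05

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "n_replicates": self.n_replicates,
            "p_value": self.p_value,
            "direction": self.direction,
            "seed": self.seed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_quantiles": self.null_quantiles,
            "degenerate": self.degenerate,
            "note": self.note,
        }


def _finish(statistic, observed, null_values, direction, seed,
            degenerate=False, note="", keep_null=False) -> NullResult:
    null_values = np.asarray(null_values, dtype=float)
    n = len(null_values)
    tol = 1e-9
    if direction == "greater":
        r = int(np.sum(null_values >= observed - tol))
    elif direction == "less":
        r = int(np.sum(null_values <= observed + tol))
    elif direction == "two_sided":
        rg = int(np.sum(null_values >= observed - tol))
        rl = int(np.sum(null_values <= observed + tol))
        r = min(rg, rl) * 2
        r = min(r, n)
    else:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    p = (r + 1) / (n + 1)
    qs = np.quantile(null_values, [0.025, 0.5, 0.975]) if n else [np.nan] * 3
    return NullResult(
        statistic=statistic, observed=float(observed), n_replicates=n,
        p_value=float(min(p, 1.0)), direction=direction, seed=seed,
        null_mean=float(np.mean(null_values)) if n else float("nan"),
        null_sd=float(np.std(null_values)) if n else float("nan"),
        null_quantiles={"q025": float(qs[0]), "q50": float(qs[1]),
                        "q975": float(qs[2])},
        degenerate=degenerate, note=note,
        null_values=null_values if keep_null else None)


# --------------------------------------------------------------------------
# aggregation

@lru_cache(maxsize=None)
def _surjections(n: int, e: int) -> int:
    """Number of ways to drop n labelled balls into e labelled boxes with
    every box occupied (exact integer, inclusion-exclusion)."""
    if e == 0:
        return 1 if n == 0 else 0
    return sum((-1) ** i * math.comb(e, i) * (e - i) ** n
               for i in range(e + 1))


@lru_cache(maxsize=None)
def _first_cell_dist(n: int, e: int) -> tuple:
    """P(first box holds k | all e boxes occupied), k = 1..n-e+1."""
    total = _surjections(n, e)
    return tuple(math.comb(n, k) * _surjections(n - k, e - 1) / total
                 for k in range(1, n - e + 2))


def _sample_occupied_counts(n: int, e: int, n_reps: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Uniform-assignment counts conditioned on every event being nonempty."""
    out = np.empty((n_reps, e), dtype=np.int32)
    remaining_n = np.full(n_reps, n, dtype=np.int64)
    for cell in range(e - 1):
        e_rem = e - cell
        new_n = np.empty_like(remaining_n)
        for n_rem in np.unique(remaining_n):
            mask = remaining_n == n_rem
            probs = np.array(_first_cell_dist(int(n_rem), e_rem))
            draws = rng.choice(len(probs), size=int(mask.sum()), p=probs) + 1
            out[mask, cell] = draws
            new_n[mask] = n_rem - draws
        remaining_n = new_n
    out[:, e - 1] = remaining_n
    return out


def _size_statistic(counts: np.ndarray, statistic: str) -> np.ndarray:
    """Statistic over event-size matrices, rows = replicates."""
    counts = np.atleast_2d(counts)
    nonempty = (counts > 0).sum(axis=1)
    if statistic == "prevalence_multi":
        multi = (counts > 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nonempty > 0, multi / nonempty, 0.0)
    if statistic == "mean_size_nonempty":
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nonempty > 0, counts.sum(axis=1) / nonempty, 0.0)
    raise ValueError(f"unknown statistic {statistic!r}")


def aggregation_test(
    event_sizes: Sequence[int],
    n_individuals: int | None = None,
    n_events: int | None = None,
    strata: Sequence | None = None,
    statistic: str = "prevalence_multi",
    condition_nonempty: bool = False,
    n_reps: int = 10_000,
    seed: int = 0,
) -> NullResult:
    """Multi-capture prevalence (or mean nonempty event size) against the
    independent-assignment null.

    ``event_sizes`` are observed per-event catches (zero-catch events allowed
    and excluded from the prevalence denominator). ``strata``, when given,
    labels each event; individuals observed in a stratum are reassigned only
    within it. Direction is ``greater``: sociality or environmental clumping
    concentrates individuals into fewer events than independence would.

    ``condition_nonempty`` conditions the null on every event receiving at
    least one individual. Use it when events are catch-defined (an event
    exists only because something was caught): given which deployments were
    nonempty, independent attendance at equal within-stratum rates yields
    exactly the occupancy-conditioned uniform assignment, regardless of how
    many further deployments caught nothing. Requires all observed sizes > 0.
    """
    sizes = np.asarray(list(event_sizes), dtype=int)
    if n_events is None:
        n_events = len(sizes)
    if n_individuals is None:
        n_individuals = int(sizes.sum())
    if n_individuals <= 0 or n_events <= 0:
        raise ValueError("need positive numbers of individuals and events")
    if n_reps < 100:
        warnings.warn("fewer than 100 replicates gives a coarse p-value grid")
    if n_events > len(sizes):  # events known to exist but unobserved catches
        sizes = np.concatenate([sizes, np.zeros(n_events - len(sizes), int)])

    observed = float(_size_statistic(sizes[None, :], statistic)[0])
    rng = np.random.default_rng(seed)

    if strata is None:
        groups = [(n_individuals, n_events)]
    else:
        strata = list(strata)
        if len(strata) != len(sizes):
            raise ValueError("strata must label every event")
        members: dict = {}
        for label, size in zip(strata, sizes):
            n_s, e_s = members.get(label, (0, 0))
            members[label] = (n_s + int(size), e_s + 1)
        groups = list(members.values())

    if condition_nonempty and np.any(sizes == 0):
        raise ValueError("condition_nonempty requires all observed events "
                         "to be nonempty (catch-defined events)")
    blocks = []
    for n_s, e_s in groups:
        if condition_nonempty:
            blocks.append(_sample_occupied_counts(n_s, e_s, n_reps, rng))
            continue
        counts = np.zeros((n_reps, e_s), dtype=np.int32)
        if n_s > 0:
            assign = rng.integers(0, e_s, size=(n_reps, n_s))
            np.add.at(counts, (np.arange(n_reps)[:, None], assign), 1)
        blocks.append(counts)
    null_counts = np.concatenate(blocks, axis=1)
    null_stats = _size_statistic(null_counts, statistic)
    return _finish(f"aggregation_{statistic}", observed, null_stats,
                   "greater", seed)


# --------------------------------------------------------------------------
# trait assortment

def _single_sex_fraction(codes: np.ndarray, starts: np.ndarray,
                         sizes: np.ndarray) -> np.ndarray:
    """Fraction of events (rows: replicates) whose members share one sex."""
    sums = np.add.reduceat(codes, starts, axis=1)
    single = (sums == 0) | (sums == sizes)
    return single.mean(axis=1)


def _mean_sex_imbalance(codes: np.ndarray, starts: np.ndarray,
                        sizes: np.ndarray) -> np.ndarray:
    """Mean over events of |males - females| / members.

    The continuous counterpart of the single-sex fraction: 1 when every
    event is single-sex, 0 when every event is perfectly balanced. Its
    null distribution has no coarse lattice, so the permutation p-value
    is not tie-conservative at realistic survey sizes.
    """
    males = np.add.reduceat(codes, starts, axis=1)
    return (np.abs(2 * males - sizes) / sizes).mean(axis=1)


def _mean_range(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    hi = np.maximum.reduceat(values, starts, axis=1)
    lo = np.minimum.reduceat(values, starts, axis=1)
    return (hi - lo).mean(axis=1)


def assortment_test(
    event_traits: Sequence[Sequence],
    trait: str = "sex",
    statistic: str | None = None,
    strata: Sequence | None = None,
    event_ids: Sequence[Sequence] | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
) -> NullResult:
    """Trait assortment within events against a label-permutation null.

    ``event_traits``: per multi-member event, the trait values of its members
    (``"male"``/``"female"`` strings for sex; numbers for fork length). Members
    with missing trait should be omitted by the caller; events reduced below 2
    known-trait members are skipped. For sex the statistic is the fraction of
    events that are single-sex (direction greater); for fork length the mean
    within-event range (direction less — assortment shrinks ranges).

    Labels are permuted across *individuals*, not capture slots: when
    ``event_ids`` (parallel to ``event_traits``, tag ID per member, None for
    untagged) marks an individual appearing in several events, all its slots
    carry one canonical trait value (its first observed one) and move
    together under permutation. Recaptured individuals otherwise induce
    within-individual correlation that a slot-level shuffle would destroy,
    inflating the test under heavy recapture.

    ``strata`` (one label per event) restricts permutation to individuals
    whose first capture falls in the same stratum. Use temporal strata for
    traits whose population composition drifts over the season (fork length
    grows; sex ratio can shift by month), where pooled permutation would
    mistake the drift for assortment.
    """
    if trait == "sex":
        statistic = statistic or "excess_single_sex_fraction"
        if statistic not in ("excess_single_sex_fraction",
                             "mean_sex_imbalance"):
            raise ValueError(f"unknown sex statistic {statistic!r}")
        direction = "greater"
    elif trait == "fork_length":
        statistic = statistic or "mean_within_event_range"
        direction = "less"
    else:
        raise ValueError(f"unknown trait {trait!r}")
    if n_reps < 100:
        warnings.warn("fewer than 100 replicates gives a coarse p-value grid")

    labels = list(strata) if strata is not None else [0] * len(event_traits)
    if len(labels) != len(event_traits):
        raise ValueError("strata must label every event")
    ids = (list(event_ids) if event_ids is not None
           else [[None] * len(g) for g in event_traits])
    if len(ids) != len(event_traits) or any(
            len(a) != len(b) for a, b in zip(ids, event_traits)):
        raise ValueError("event_ids must parallel event_traits")
    keep = [i for i, g in enumerate(event_traits) if len(g) >= 2]
    groups = [list(event_traits[i]) for i in keep]
    labels = [labels[i] for i in keep]
    ids = [list(ids[i]) for i in keep]
    name = f"assortment_{trait}_{statistic}"
    if not groups:
        return _finish(name, 0.0, [0.0], direction, seed, degenerate=True,
                       note="no events with >= 2 trait-bearing members")

    def encode(v):
        if trait == "sex":
            return 1.0 if v == "male" else 0.0
        return float(v)

    # individual registry: canonical value + stratum of first capture;
    # untagged slots are singleton individuals
    ind_index: dict = {}
    ind_values: list[float] = []
    ind_strata: list = []
    slot_ind: list[int] = []
    for gi, (group, group_ids) in enumerate(zip(groups, ids)):
        for value, tag in zip(group, group_ids):
            key = ("tag", tag) if tag is not None else ("slot", len(slot_ind))
            if key not in ind_index:
                ind_index[key] = len(ind_values)
                ind_values.append(encode(value))
                ind_strata.append(labels[gi])
            slot_ind.append(ind_index[key])
    ind_values = np.asarray(ind_values)
    slot_ind = np.asarray(slot_ind)
    n_ind = len(ind_values)

    sizes = np.array([len(g) for g in groups])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    if trait != "sex":
        stat_fn = lambda m: _mean_range(m, starts)
    elif statistic == "mean_sex_imbalance":
        stat_fn = lambda m: _mean_sex_imbalance(m, starts, sizes)
    else:
        stat_fn = lambda m: _single_sex_fraction(m, starts, sizes)
    observed = float(stat_fn(ind_values[slot_ind][None, :])[0])

    if np.all(ind_values == ind_values[0]):
        warnings.warn("trait constant across individuals: degenerate null")
        return _finish(name, observed, [observed], direction, seed,
                       degenerate=True, note="constant trait")

    rng = np.random.default_rng(seed)
    codes = {lab: i for i, lab in enumerate(dict.fromkeys(ind_strata))}
    ind_codes = np.array([codes[lab] for lab in ind_strata])
    keys = rng.random((n_reps, n_ind))
    perm = np.empty((n_reps, n_ind), dtype=np.int64)
    for s in range(len(codes)):
        idx = np.flatnonzero(ind_codes == s)
        order = np.argsort(keys[:, idx], axis=1)
        perm[:, idx] = idx[order]
    null_stats = stat_fn(ind_values[perm][:, slot_ind])
    return _finish(name, observed, null_stats, direction, seed)


# --------------------------------------------------------------------------
# companion preference (fixed-margin swap null)

_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _dyad_cooc_counts(mat: np.ndarray) -> np.ndarray:
    co = mat.T.astype(np.int32) @ mat.astype(np.int32)
    k = co.shape[0]
    if k not in _TRIU_CACHE:
        _TRIU_CACHE[k] = np.triu_indices(k, k=1)
    return co[_TRIU_CACHE[k]]


def _companion_stat(mat: np.ndarray, statistic: str) -> int:
    """Companion statistic over one incidence block.

    ``repeat_pairs`` (default): sum over dyads of C(x, 2), the number of
    repeated co-occurrence pairs-of-events — sensitive to co-occurrence
    concentrating on particular dyads, which is what persistent companionship
    produces. ``repeat_dyads``: number of distinct dyads co-occurring in
    >= 2 events — easier to read but saturates (and can even decrease) when
    stable groups focus repeats on few dyads.
    """
    x = _dyad_cooc_counts(mat)
    if statistic == "repeat_pairs":
        return int((x * (x - 1) // 2).sum())
    if statistic == "repeat_dyads":
        return int(np.sum(x >= 2))
    raise ValueError(f"unknown statistic {statistic!r}")


class _SwapChain:
    """Trial-swap Markov chain on one binary matrix, margins preserved.

    Rejected proposals count as self-loops, making the stationary
    distribution uniform over the connected set of fixed-margin matrices.
    The matrix lives as parallel row/col lists of its ones plus per-row
    membership sets, so one attempt is O(1) in pure Python.
    """

    def __init__(self, mat: np.ndarray, rng: random.Random):
        self.shape = mat.shape
        pos = np.argwhere(mat != 0)
        self.rows = [int(r) for r, _ in pos]
        self.cols = [int(c) for _, c in pos]
        self.row_members = [set() for _ in range(mat.shape[0])]
        for r, c in zip(self.rows, self.cols):
            self.row_members[r].add(c)
        self.rng = rng
        self.n_success = 0

    def attempt(self) -> None:
        rows, cols, members = self.rows, self.cols, self.row_members
        L = len(rows)
        if L < 2:
            return
        rnd = self.rng.random
        i1 = int(rnd() * L)
        i2 = int(rnd() * L)
        r1, r2 = rows[i1], rows[i2]
        if r1 == r2:
            return
        c1, c2 = cols[i1], cols[i2]
        if c1 == c2 or c2 in members[r1] or c1 in members[r2]:
            return
        cols[i1] = c2
        cols[i2] = c1
        m1 = members[r1]
        m1.discard(c1)
        m1.add(c2)
        m2 = members[r2]
        m2.discard(c2)
        m2.add(c1)
        self.n_success += 1

    @property
    def mat(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.int32)
        out[self.rows, self.cols] = 1
        return out


def companion_preference_test(
    incidence,
    n_reps: int = 1_000,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int = 0,
    statistic: str = "repeat_pairs",
    check_margins: bool = False,
) -> NullResult:
    """Repeated-companion statistic against the fixed-margin swap null.

    ``incidence`` is one events-by-individuals binary matrix (array or
    DataFrame) or a list of them (e.g. one block per site when individuals
    cannot move between sites; chains then run independently per block and
    the statistic sums over blocks). Defaults: burn-in = 10x the number of
    ones, thinning = number of ones, counting attempted (not successful)
    swaps.
    """
    if isinstance(incidence, (pd.DataFrame, np.ndarray)):
        blocks = [incidence]
    else:
        blocks = list(incidence)
    mats = []
    for b in blocks:
        arr = b.to_numpy() if isinstance(b, pd.DataFrame) else np.asarray(b)
        if arr.size and arr.shape[0] >= 1 and arr.shape[1] >= 1:
            mats.append((arr > 0).astype(np.int8))
    name = f"companion_{statistic}"
    if not mats or all(m.sum() == 0 for m in mats):
        return _finish(name, 0.0, [0.0], "greater", seed, degenerate=True,
                       note="empty incidence")

    total_ones = int(sum(m.sum() for m in mats))
    if burn_in is None:
        burn_in = 10 * total_ones
    if thin is None:
        thin = total_ones

    observed = sum(_companion_stat(m, statistic) for m in mats)
    row_sums = [m.sum(axis=1).copy() for m in mats]
    col_sums = [m.sum(axis=0).copy() for m in mats]

    rng = random.Random(seed)
    chains = [_SwapChain(m, rng) for m in mats]
    # burn-in, shared across blocks proportionally to their size
    weights = np.array([len(c.rows) for c in chains], dtype=float)
    weights = weights / weights.sum()
    for c, w in zip(chains, weights):
        for _ in range(max(1, int(round(burn_in * w)))):
            c.attempt()
    null_stats = np.empty(n_reps)
    for k in range(n_reps):
        for c, w in zip(chains, weights):
            for _ in range(max(1, int(round(thin * w)))):
                c.attempt()
        if check_margins:
            for c, rs, cs in zip(chains, row_sums, col_sums):
                assert np.array_equal(c.mat.sum(axis=1), rs)
                assert np.array_equal(c.mat.sum(axis=0), cs)
        null_stats[k] = sum(_companion_stat(c.mat, statistic)
                            for c in chains)

    degenerate = all(c.n_success == 0 for c in chains)
    note = "no checkerboard swap possible" if degenerate else ""
    if degenerate:
        warnings.warn("incidence admits no checkerboard swap: degenerate null")
    return _finish(name, observed, null_stats, "greater", seed,
                   degenerate=degenerate, note=note)


# --------------------------------------------------------------------------
# convenience battery over events

def standard_test_battery(
    deployment_events,
    n_reps: int = 1_000,
    seed: int = 0,
    companion_kwargs: dict | None = None,
) -> dict[str, NullResult]:
    """Run the three tests the way the pipeline wires them.

    Aggregation: occupancy-conditioned null stratified by site x season x
    peak/off-peak (conditioning out survey design and the parturition-season
    effort weighting). Assortment: labels permuted within season-month
    strata — fork length drifts with growth and sex composition can shift
    seasonally, and either would masquerade as assortment under pooled
    permutation; within-event tilt remains fully detectable.
    Companion: incidence blocks per site x season, restricted to individuals
    captured >= 2 times (singletons cannot form repeat dyads and only slow
    the chain).
    """
    from .events import group_by_individual_matrix

    def season_year(d):
        return d.year if d.month >= 9 else d.year - 1

    peak = {10, 11, 12, 1, 2}  # parturition peak months
    sizes = [ev.n for ev in deployment_events]
    strata = [(ev.site, season_year(ev.date), ev.date.month in peak)
              for ev in deployment_events]
    results = {
        "aggregation": aggregation_test(
            sizes, strata=strata, condition_nonempty=True,
            n_reps=n_reps, seed=seed),
    }
    # chronological order so "first capture" semantics hold for recaptures
    multi = sorted((ev for ev in deployment_events if ev.n >= 2),
                   key=lambda ev: (ev.date, ev.event_id))
    sex_groups, sex_ids, fl_groups, fl_ids = [], [], [], []
    for ev in multi:
        sexed = [m for m in ev.members if m.sex != "unknown"]
        sex_groups.append([m.sex for m in sexed])
        sex_ids.append([m.individual_id for m in sexed])
        measured = [m for m in ev.members if m.fork_length_mm is not None]
        fl_groups.append([m.fork_length_mm for m in measured])
        fl_ids.append([m.individual_id for m in measured])
    month_strata = [(season_year(ev.date), ev.date.month) for ev in multi]
    results["assortment_sex"] = assortment_test(
        sex_groups, trait="sex", statistic="mean_sex_imbalance",
        strata=month_strata, event_ids=sex_ids,
        n_reps=n_reps, seed=seed + 1)
    results["assortment_size"] = assortment_test(
        fl_groups, trait="fork_length", strata=month_strata,
        event_ids=fl_ids, n_reps=n_reps, seed=seed + 2)

    blocks = []
    keys = sorted({(ev.site, season_year(ev.date))
                   for ev in deployment_events})
    for site, year in keys:
        block_events = [ev for ev in deployment_events
                        if ev.site == site and season_year(ev.date) == year]
        mat = group_by_individual_matrix(block_events)
        if mat.shape[1] == 0:
            continue
        arr = mat.to_numpy()
        arr = arr[:, arr.sum(axis=0) >= 2]      # singletons cannot repeat
        arr = arr[arr.sum(axis=1) >= 1]
        if arr.size:
            blocks.append(arr)
    kwargs = dict(n_reps=max(200, n_reps // 5), seed=seed + 3)
    if companion_kwargs:
        kwargs.update(companion_kwargs)
    results["companion"] = companion_preference_test(blocks, **kwargs)
    return results
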