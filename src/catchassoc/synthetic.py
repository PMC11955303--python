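"""Seeded simulator of nursery-survey catch datasets.

Emulates the survey design behind the case study: ~10 nursery sites sampled
twice per month at dusk (17:00-20:00) across October-April parturition
seasons, with ~94% of capture intensity falling in the October-February
peak; litters of 3-5 pups; site-faithful juveniles that disperse or die
permanently; fork lengths in the observed juvenile range growing at
individual-specific rates.

Each scenario injects the statistical structure of one aggregation
hypothesis, so every pipeline stage can be exercised against known ground
truth:

* ``solitary`` — independent attendance; no aggregation beyond chance.
* ``non_social_env`` — a few high-quality sites concentrate attendance
  (environmental driver).
* ``non_specific_social_sex`` / ``non_specific_social_size`` — attendance is
  tilted toward a per-deployment latent trait (sex, or a fork-length
  centre), producing trait assortment without individual preference.
* ``specific_social`` — persistent companion pairs co-attend with
  probability theta and share capture timestamps.
* ``kin_structured`` — littermates act as companion sets.
* ``seasonal_sex`` — male attendance boosted in one month (a pure seasonal
  composition effect for the regression stage to recover).
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catchdata import CatchRecord, KinshipTable, write_catch_table

SCENARIOS = ("solitary", "non_social_env", "non_specific_social_sex",
             "non_specific_social_size", "specific_social", "kin_structured",
             "seasonal_sex")

EXPECTED_VERDICT = {
    "solitary": "no_aggregation",
    "non_social_env": "non_social_aggregation",
    "non_specific_social_sex": "non_specific_social_group",
    "non_specific_social_size": "non_specific_social_group",
    "specific_social": "specific_social_group",
    "kin_structured": "specific_social_group",
    "seasonal_sex": "non_social_aggregation",
}

_SITE_NAMES = ("Apaura", "Haapiti", "Maharepa", "Paorea", "Papetoai",
               "Pihaena", "Tiki", "Vaiane", "Vaiare", "Valorie")


@dataclass
class ScenarioConfig:
    """Generator parameters; defaults are the survey's study conditions."""
    scenario: str = "solitary"
    n_sites: int = 10
    sets_per_site_per_month: int = 2
    months: tuple[int, ...] = (10, 11, 12, 1, 2, 3, 4)
    peak_months: tuple[int, ...] = (10, 11, 12, 1, 2)
    peak_weight: float = 0.94
    years: tuple[int, ...] = tuple(range(2014, 2024))
    n_litters_per_site_year: int = 6
    litter_size: tuple[int, int] = (3, 5)
    sex_ratio_at_birth: float = 0.5
    fl_mm_range: tuple[float, float] = (392.0, 792.0)
    growth_mm_per_day: tuple[float, float] = (0.1, 0.4)
    site_fidelity: float = 1.0
    capture_probability: float = 0.1
    dispersal_hazard: float = 0.01
    social_preference: float = 0.8   # theta: companion co-attendance prob
    assortment_strength: float = 0.7
    assortment_bandwidth_mm: float = 80.0
    env_site_boost: float = 4.0
    env_offsite_factor: float = 0.15
    n_good_sites: int = 2
    seasonal_sex_month: int = 10
    seasonal_sex_boost: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for p in (self.peak_weight, self.sex_ratio_at_birth,
                  self.site_fidelity, self.capture_probability,
                  self.dispersal_hazard, self.social_preference):
            if not (0 <= p <= 1):
                raise ValueError(f"probability {p} outside [0, 1]")
        if not set(self.months) <= {9, 10, 11, 12, 1, 2, 3, 4}:
            raise ValueError("months must lie within the Sep-Apr window")
        if not set(self.peak_months) <= set(self.months):
            raise ValueError("peak months must be sampled months")
        if self.n_litters_per_site_year < 1:
            raise ValueError("need at least one litter per site-year")

    @property
    def site_names(self) -> tuple[str, ...]:
        base = list(_SITE_NAMES)
        while len(base) < self.n_sites:
            base.append(f"Site{len(base) + 1:02d}")
        return tuple(base[: self.n_sites])

    @property
    def good_sites(self) -> tuple[str, ...]:
        return tuple(sorted(self.site_names)[: self.n_good_sites])

    def month_multiplier(self, month: int) -> float:
        """Capture-intensity multiplier, 1.0 in the parturition peak."""
        n_peak = len(self.peak_months)
        n_off = len(self.months) - n_peak
        w_peak = self.peak_weight / n_peak
        if month in self.peak_months:
            return 1.0
        if n_off == 0:
            return 1.0
        w_off = (1.0 - self.peak_weight) / n_off
        return w_off / w_peak


def config_from_yaml(path) -> "ScenarioConfig":
    """Load a ScenarioConfig from a YAML mapping of field names to values."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("months", "peak_months", "years", "litter_size",
                "fl_mm_range", "growth_mm_per_day"):
        if key in data:
            data[key] = tuple(data[key])
    scenario = data.pop("scenario", "solitary")
    return scenario_config(scenario, **data)


_SCENARIO_DEFAULTS: dict[str, dict] = {
    "solitary": {"capture_probability": 0.035},
    "non_social_env": {"capture_probability": 0.15},
    "non_specific_social_sex": {"capture_probability": 0.1},
    "non_specific_social_size": {"capture_probability": 0.1},
    "specific_social": {"capture_probability": 0.1},
    "kin_structured": {"capture_probability": 0.1},
    "seasonal_sex": {"capture_probability": 0.15},
}


def scenario_config(scenario: str, **overrides) -> ScenarioConfig:
    """A ScenarioConfig with that scenario's default effect sizes."""
    kwargs = dict(_SCENARIO_DEFAULTS.get(scenario, {}))
    kwargs.update(overrides)
    return ScenarioConfig(scenario=scenario, **kwargs)


@dataclass
class Individual:
    uid: str
    natal_site: str
    site: str
    sex: str
    fl0_mm: float
    growth_mm_per_day: float
    cohort_year: int
    litter_id: str
    companions: list[str] = field(default_factory=list)
    alive: bool = True


@dataclass
class Deployment:
    site: str
    date: dt.date
    set_number: int = 1

    @property
    def season_year(self) -> int:
        return self.date.year if self.date.month >= 9 else self.date.year - 1


@dataclass
class GroundTruth:
    scenario: str
    expected_verdict: str
    parameters: dict
    litters: dict[str, str]
    companion_pairs: list[tuple[str, str]]
    n_individuals: int

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "expected_verdict": self.expected_verdict,
            "parameters": self.parameters,
            "litters": dict(sorted(self.litters.items())),
            "companion_pairs": sorted(map(list, self.companion_pairs)),
            "n_individuals": self.n_individuals,
        }


def _season_start(cohort_year: int) -> dt.date:
    return dt.date(cohort_year, 9, 1)


def simulate_population(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Individual], KinshipTable]:
    """Pups per site-year cohort, in litters of 3-5, with sibship recorded.

    Within-litter pairs are siblings; same-cohort same-site pairs across
    litters are recorded as unrelated; everything else is unknown (mirrors a
    genotyping effort that covers each nursery cohort).
    """
    rng = rng or np.random.default_rng(config.seed)
    sites = sorted(config.site_names)
    individuals: list[Individual] = []
    kinship = KinshipTable()
    lo, hi = config.litter_size
    for year in sorted(config.years):
        for site in sites:
            cohort: list[Individual] = []
            for l in range(config.n_litters_per_site_year):
                litter_id = f"{site}-{year}-L{l:02d}"
                size = int(rng.integers(lo, hi + 1))
                for p in range(size):
                    uid = f"{site}-{year}-L{l:02d}P{p}"
                    sex = ("male" if rng.random() < config.sex_ratio_at_birth
                           else "female")
                    resident = site
                    if rng.random() > config.site_fidelity and len(sites) > 1:
                        others = [s for s in sites if s != site]
                        resident = others[int(rng.integers(len(others)))]
                    cohort.append(Individual(
                        uid=uid, natal_site=site, site=resident, sex=sex,
                        fl0_mm=float(rng.uniform(*config.fl_mm_range)),
                        growth_mm_per_day=float(
                            rng.uniform(*config.growth_mm_per_day)),
                        cohort_year=year, litter_id=litter_id))
            for i in range(len(cohort)):
                for j in range(i + 1, len(cohort)):
                    a, b = cohort[i], cohort[j]
                    rel = ("sibling" if a.litter_id == b.litter_id
                           else "unrelated")
                    kinship.add(a.uid, b.uid, rel)
            individuals.extend(cohort)
    if not individuals:
        raise ValueError("zero litters configured")

    if config.scenario in ("specific_social", "kin_structured"):
        _assign_companions(individuals, config, rng)
    return individuals, kinship


def _assign_companions(individuals, config, rng) -> None:
    if config.scenario == "kin_structured":
        by_litter: dict[tuple, list[Individual]] = {}
        for ind in individuals:
            by_litter.setdefault((ind.site, ind.cohort_year,
                                  ind.litter_id), []).append(ind)
        for group in by_litter.values():
            ids = [g.uid for g in group]
            for g in group:
                g.companions = [i for i in ids if i != g.uid]
    else:  # specific_social: random persistent pairs within site-cohort
        by_cohort: dict[tuple, list[Individual]] = {}
        for ind in individuals:
            by_cohort.setdefault((ind.site, ind.cohort_year), []).append(ind)
        for group in by_cohort.values():
            idx = rng.permutation(len(group))
            for a, b in zip(idx[::2], idx[1::2]):
                group[a].companions = [group[b].uid]
                group[b].companions = [group[a].uid]


def simulate_surveys(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> list[Deployment]:
    """Twice-monthly dusk deployments per site per sampled month."""
    rng = rng or np.random.default_rng(config.seed + 1)
    deployments: list[Deployment] = []
    for year in sorted(config.years):
        for month in config.months:
            cal_year = year if month >= 9 else year + 1
            for site in sorted(config.site_names):
                days = rng.choice(np.arange(1, 29),
                                  size=config.sets_per_site_per_month,
                                  replace=False)
                for day in sorted(days):
                    deployments.append(Deployment(
                        site=site, date=dt.date(cal_year, month, int(day))))
    deployments.sort(key=lambda d: (d.date, d.site, d.set_number))
    return deployments


def simulate_captures(
    population: list[Individual],
    schedule: list[Deployment],
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[CatchRecord], GroundTruth]:
    """Run the attendance/capture process over the survey schedule.

    Attendance is independent per individual at its resident site, scaled by
    the seasonal month multiplier, then modified by the scenario (see module
    docstring). Captured companions recruited by a partner share the
    partner's capture minute with probability theta — the generative
    analogue of simultaneous capture. After each deployment every exposed
    individual disperses/dies permanently with the configured hazard.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    by_cohort: dict[tuple[str, int], list[Individual]] = {}
    for ind in sorted(population, key=lambda i: i.uid):
        by_cohort.setdefault((ind.site, ind.cohort_year), []).append(ind)
    index = {ind.uid: ind for ind in population}

    records: list[CatchRecord] = []
    rec_counter = 0
    theta = config.social_preference
    a = config.assortment_strength
    for dep in schedule:
        cohort = [i for i in by_cohort.get((dep.site, dep.season_year), [])
                  if i.alive]
        if not cohort:
            continue
        mult = config.month_multiplier(dep.date.month)
        base = config.capture_probability * mult

        if config.scenario == "non_social_env":
            base *= (config.env_site_boost if dep.site in config.good_sites
                     else config.env_offsite_factor)

        tilt_sex = None
        tilt_centre = None
        if config.scenario == "non_specific_social_sex":
            tilt_sex = "male" if rng.random() < 0.5 else "female"
        elif config.scenario == "non_specific_social_size":
            tilt_centre = float(rng.uniform(*config.fl_mm_range))

        probs = np.empty(len(cohort))
        age_days = (dep.date - _season_start(dep.season_year)).days
        for k, ind in enumerate(cohort):
            p = base
            if tilt_sex is not None:
                p *= (1 + a) if ind.sex == tilt_sex else (1 - a)
            elif tilt_centre is not None:
                fl = ind.fl0_mm + ind.growth_mm_per_day * age_days
                p *= 0.3 + 1.7 * math.exp(
                    -abs(fl - tilt_centre) / config.assortment_bandwidth_mm)
            elif (config.scenario == "seasonal_sex"
                  and dep.date.month == config.seasonal_sex_month):
                # composition-preserving skew: male odds x boost, expected
                # event size unchanged (a pure sex-ratio month effect)
                b = config.seasonal_sex_boost
                p *= (2 * b / (1 + b)) if ind.sex == "male" else 2 / (1 + b)
            probs[k] = min(p, 0.95)

        draws = rng.random(len(cohort))
        captured: dict[str, str | None] = {}   # uid -> recruiter uid or None
        for k, ind in enumerate(cohort):
            if draws[k] < probs[k]:
                captured[ind.uid] = None
        if config.scenario in ("specific_social", "kin_structured"):
            for uid in list(captured):
                for comp_uid in index[uid].companions:
                    comp = index.get(comp_uid)
                    if (comp is None or not comp.alive
                            or comp.site != dep.site
                            or comp.cohort_year != dep.season_year
                            or comp_uid in captured):
                        continue
                    if rng.random() < theta:
                        captured[comp_uid] = uid

        times: dict[str, int] = {}
        for uid in captured:
            recruiter = captured[uid]
            if (recruiter is not None and recruiter in times
                    and rng.random() < theta):
                times[uid] = times[recruiter]
            else:
                times[uid] = int(rng.integers(17 * 60, 20 * 60))

        for uid in sorted(captured):
            ind = index[uid]
            fl = ind.fl0_mm + ind.growth_mm_per_day * age_days
            minute = times[uid]
            records.append(CatchRecord(
                record_id=f"c{rec_counter:06d}",
                site=dep.site, date=dep.date, set_number=dep.set_number,
                capture_time=dt.time(minute // 60, minute % 60),
                individual_id=uid, sex=ind.sex,
                fork_length_mm=round(fl, 1)))
            rec_counter += 1

        if config.dispersal_hazard > 0:
            gone = rng.random(len(cohort)) < config.dispersal_hazard
            for k, ind in enumerate(cohort):
                if gone[k]:
                    ind.alive = False

    pairs = {frozenset((ind.uid, c))
             for ind in population for c in ind.companions}
    truth = GroundTruth(
        scenario=config.scenario,
        expected_verdict=EXPECTED_VERDICT[config.scenario],
        parameters=_config_dict(config),
        litters={ind.uid: ind.litter_id for ind in population},
        companion_pairs=[tuple(sorted(p)) for p in pairs],
        n_individuals=len(population))
    return records, truth


@dataclass
class SimulatedDataset:
    records: list[CatchRecord]
    kinship: KinshipTable
    ground_truth: GroundTruth
    schedule: list[Deployment]


def simulate_dataset(config: ScenarioConfig) -> SimulatedDataset:
    """Population + schedule + captures in one seeded call."""
    rng = np.random.default_rng(config.seed)
    population, kinship = simulate_population(config, rng)
    schedule = simulate_surveys(config, rng)
    records, truth = simulate_captures(population, schedule, config, rng)
    return SimulatedDataset(records=records, kinship=kinship,
                            ground_truth=truth, schedule=schedule)


def _config_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def write_fixture_suite(
    out_dir: str | Path,
    configs: list[ScenarioConfig] | None = None,
    seed: int = 0,
) -> list[Path]:
    """One catch CSV + kinship CSV + ground-truth JSON per scenario.

    Byte-stable at fixed seed. Default suite: every scenario at a reduced
    survey footprint (4 sites, 2 seasons) so the files stay small.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if configs is None:
        configs = [scenario_config(s, seed=seed + i, n_sites=4,
                                   years=(2021, 2022))
                   for i, s in enumerate(SCENARIOS)]
    written: list[Path] = []
    for cfg in configs:
        ds = simulate_dataset(cfg)
        stem = cfg.scenario
        catch_path = out / f"{stem}_catch.csv"
        write_catch_table(ds.records, catch_path)
        kin_path = out / f"{stem}_kinship.csv"
        ds.kinship.to_csv(kin_path)
        truth_path = out / f"{stem}_truth.json"
        truth_path.write_text(
            json.dumps(ds.ground_truth.to_dict(), indent=1, sort_keys=True))
        written += [catch_path, kin_path, truth_path]
    return written
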