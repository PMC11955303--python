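"""Calibration and scenario-recovery experiments.

These tie the simulator to the inference stack: type-I error of each
permutation test under independent attendance, verdict recovery per
generating scenario, and the seasonal capture fraction. Used by the test
suite and the acceptance script; problem sizes here are deliberately small
(a few sites, one season) so hundreds of seeded replicates run quickly.
"""
from __future__ import annotations

import numpy as np

from .classify import Thresholds, apply_framework
from .events import build_deployment_events
from .metrics import metrics_report
from .nullmodels import standard_test_battery
from .synthetic import ScenarioConfig, scenario_config, simulate_dataset

#: dense solitary config: independence as in the solitary scenario, but at a
#: capture density where all three test statistics have non-degenerate nulls
CALIBRATION_OVERRIDES = dict(
    n_sites=4, years=(2021, 2022), capture_probability=0.25)

#: reduced survey footprints for verdict-recovery replicates
RECOVERY_OVERRIDES: dict[str, dict] = {
    "solitary": dict(n_sites=3, years=(2021,)),
    "non_social_env": dict(n_sites=5, years=(2021,)),
    "non_specific_social_sex": dict(n_sites=3, years=(2021,)),
    "non_specific_social_size": dict(n_sites=5, years=(2021,)),
    "specific_social": dict(n_sites=3, years=(2021,)),
    "kin_structured": dict(n_sites=3, years=(2021,)),
    "seasonal_sex": dict(n_sites=3, years=(2021,)),
}


def child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic stream of sub-2^31 seeds derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)


def classify_run(
    config: ScenarioConfig,
    n_reps: int = 200,
    thresholds: Thresholds | None = None,
):
    """Simulate one dataset and push it through metrics, nulls, classifier."""
    ds = simulate_dataset(config)
    events = build_deployment_events(ds.records)
    if not events:
        return None, {}
    report = metrics_report(events, ds.kinship)
    nulls = standard_test_battery(events, n_reps=n_reps, seed=config.seed)
    ledger = apply_framework(report, nulls, thresholds=thresholds)
    return ledger, nulls


def type_i_error_rates(
    n_seeds: int = 1000,
    base_seed: int = 0,
    n_reps: int = 200,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rate of each test on independently generated catch data."""
    seeds = child_seeds(base_seed, n_seeds)
    rejections = {"aggregation": 0, "assortment_sex": 0,
                  "assortment_size": 0, "companion": 0}
    n_valid = {k: 0 for k in rejections}
    for s in seeds:
        cfg = scenario_config("solitary", seed=int(s),
                              **CALIBRATION_OVERRIDES)
        ds = simulate_dataset(cfg)
        events = build_deployment_events(ds.records)
        nulls = standard_test_battery(events, n_reps=n_reps, seed=int(s))
        for name in rejections:
            res = nulls[name]
            if res.degenerate:
                continue
            n_valid[name] += 1
            if res.p_value <= alpha:
                rejections[name] += 1
    return {name: rejections[name] / max(n_valid[name], 1)
            for name in rejections}


def scenario_recovery(
    scenario: str,
    n_runs: int = 100,
    base_seed: int = 0,
    n_reps: int = 200,
) -> dict:
    """Fraction of seeded runs whose verdict matches the generating scenario."""
    import zlib
    seeds = child_seeds(zlib.crc32(scenario.encode()) % (2**20) + base_seed,
                        n_runs)
    counts: dict[str, int] = {}
    expected = None
    for s in seeds:
        cfg = scenario_config(scenario, seed=int(s),
                              **RECOVERY_OVERRIDES.get(scenario, {}))
        ledger, _ = classify_run(cfg, n_reps=n_reps)
        verdict = ledger.verdict if ledger is not None else "no_data"
        counts[verdict] = counts.get(verdict, 0) + 1
        from .synthetic import EXPECTED_VERDICT
        expected = EXPECTED_VERDICT[scenario]
    return {
        "scenario": scenario,
        "expected_verdict": expected,
        "n_runs": n_runs,
        "verdict_counts": counts,
        "recovery_rate": counts.get(expected, 0) / n_runs,
    }


def season_capture_fractions(
    n_seeds: int = 50,
    base_seed: int = 0,
    **config_overrides,
) -> list[float]:
    """Fraction of captures falling in the Oct-Feb peak, per seed."""
    overrides = dict(n_sites=4, years=(2021,))
    overrides.update(config_overrides)
    fractions = []
    for s in child_seeds(base_seed, n_seeds):
        cfg = scenario_config("solitary", seed=int(s), **overrides)
        ds = simulate_dataset(cfg)
        if not ds.records:
            continue
        n_peak = sum(1 for r in ds.records
                     if r.date.month in cfg.peak_months)
        fractions.append(n_peak / len(ds.records))
    return fractions
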