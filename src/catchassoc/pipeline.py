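"""End-to-end orchestration: load -> filter -> events -> metrics -> nulls ->
models -> classify -> report, with plain-file artifact handoff.

Every artifact is written under the output directory together with a
manifest recording input paths, the seed, thresholds, and a SHA-256 per
artifact, so a rerun with the same config and seed is verifiably identical.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .catchdata import (KinshipTable, filter_juveniles, read_catch_table)
from .classify import Thresholds, apply_framework, render_report
from .events import (build_all_simultaneous, build_deployment_events,
                     events_to_frame, interval_summary)
from .gammodels import ModelSpec, build_event_table, fit_with_null, month_filter
from .metrics import metrics_report
from .nullmodels import standard_test_battery

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    catch_csv: str
    out_dir: str
    kinship_csv: str | None = None
    seed: int = 0
    n_reps: int = 1000
    max_fl_mm: float = 1000.0
    simultaneous_tolerance: int = 0
    scales: tuple[str, ...] = ("deployment", "simultaneous")
    thresholds: Thresholds = field(default_factory=Thresholds)
    run_models: bool = True
    schema: dict | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.to_dict()
        d["scales"] = list(self.scales)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def write_json(name: str, obj) -> None:
        p = out / name
        p.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
        artifacts[name] = p

    # -- load + filter -----------------------------------------------------
    try:
        records, load_report = read_catch_table(
            config.catch_csv, schema=config.schema)
        records, juv_report = filter_juveniles(records, config.max_fl_mm)
        kinship = (KinshipTable.from_csv(config.kinship_csv)
                   if config.kinship_csv else None)
        write_json("validation.json", {
            "load": load_report.to_dict(), "juvenile_filter":
            juv_report.to_dict()})
    except StageError:
        raise
    except Exception as e:
        raise StageError("load", e) from e

    # -- events ------------------------------------------------------------
    try:
        dep_events = build_deployment_events(records)
        sim_events = build_all_simultaneous(
            dep_events, config.simultaneous_tolerance)
        by_scale = {"deployment": dep_events, "simultaneous": sim_events}
        for scale in config.scales:
            frame = events_to_frame(by_scale[scale])
            p = out / f"events_{scale}.csv"
            frame.to_csv(p, index=False)
            artifacts[p.name] = p
        write_json("intervals.json", interval_summary(dep_events).to_dict())
    except Exception as e:
        raise StageError("events", e) from e

    # -- metrics -----------------------------------------------------------
    try:
        reports = {scale: metrics_report(by_scale[scale], kinship)
                   for scale in config.scales if by_scale[scale]}
        write_json("metrics.json", reports)
    except Exception as e:
        raise StageError("metrics", e) from e

    # -- null models (deployment scale carries identity and effort info) ---
    try:
        nulls = standard_test_battery(
            dep_events, n_reps=config.n_reps, seed=config.seed)
        write_json("null_results.json",
                   {k: v.to_dict() for k, v in nulls.items()})
    except Exception as e:
        raise StageError("nulls", e) from e

    # -- models ------------------------------------------------------------
    model_fits = {}
    model_rows = []
    lrt_results = {}
    if config.run_models:
        try:
            for scale in config.scales:
                if not by_scale[scale]:
                    continue
                table = build_event_table(by_scale[scale])
                table = table[table["n_sharks"] >= 2]
                if len(table) < 10:
                    log.warning("too few multi-shark events at %s scale; "
                                "models skipped", scale)
                    continue
                table = month_filter(table, scale)
                for response in ("sex_ratio_binomial", "sqrt_size_variance"):
                    label = f"{response}_{scale}"
                    try:
                        spec = ModelSpec(response=response, scale=scale)
                        full, null, lrt = fit_with_null(spec, table)
                    except ValueError as err:
                        log.warning("model %s skipped: %s", label, err)
                        continue
                    model_fits[label] = full
                    lrt_results[label] = lrt.to_dict()
                    st = full.summary_table()
                    st.insert(0, "model", label)
                    model_rows.append(st)
            if model_rows:
                import pandas as pd
                p = out / "model_table.csv"
                pd.concat(model_rows).to_csv(p, index=False)
                artifacts[p.name] = p
            write_json("lrt_results.json", lrt_results)
        except Exception as e:
            raise StageError("models", e) from e

    # -- classify + report -------------------------------------------------
    try:
        scale0 = config.scales[0]
        ledger = apply_framework(reports[scale0], nulls,
                                 model_fits or None, config.thresholds)
        write_json("classification.json", ledger.to_dict())
        report_md = render_report(ledger, reports[scale0], nulls)
        p = out / "report.md"
        p.write_text(report_md)
        artifacts[p.name] = p
    except Exception as e:
        raise StageError("classify", e) from e

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "created": dt.datetime.now().isoformat(timespec="seconds"),
        "verdict": ledger.verdict,
        "hashes": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
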