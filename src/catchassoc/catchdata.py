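"""Catch-record data model, tabular I/O, validation, and record-level filters.

A *catch record* is one individual shark (or ray/skate) removed from one gear
deployment: where it was caught (site), when (date, set number, clock time of
capture), who it is (tag ID, if tagged), and its phenotype (sex, fork length).
Deployments — one gillnet soak at one site on one date — are the coarse unit
over which co-occurrence is later assessed.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

SEXES = ("female", "male", "unknown")

#: field name -> default CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    "record_id": "record_id",
    "site": "site",
    "date": "date",
    "set_number": "set_number",
    "capture_time": "capture_time",
    "individual_id": "individual_id",
    "sex": "sex",
    "fork_length_mm": "fork_length_mm",
}

_SEX_ALIASES = {
    "f": "female", "female": "female",
    "m": "male", "male": "male",
    "u": "unknown", "unknown": "unknown", "": "unknown",
}


@dataclass(frozen=True, order=True)
class CatchRecord:
    """One individual capture.

    ``sex`` is one of :data:`SEXES`; untagged individuals have
    ``individual_id=None`` and can contribute to identity-free metrics only.
    """
    record_id: str
    site: str
    date: dt.date
    set_number: int = 1
    capture_time: dt.time | None = None
    individual_id: str | None = None
    sex: str = "unknown"
    fork_length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.fork_length_mm is not None and self.fork_length_mm <= 0:
            raise ValueError("fork_length_mm must be positive when present")
        if self.set_number < 1:
            raise ValueError("set_number must be a positive integer")

    @property
    def year(self) -> int:
        return self.date.year

    @property
    def month(self) -> int:
        return self.date.month

    @property
    def deployment_key(self) -> tuple[str, dt.date, int]:
        return (self.site, self.date, self.set_number)

    @property
    def time_minutes(self) -> int | None:
        """Capture time as minutes past midnight (minute resolution)."""
        if self.capture_time is None:
            return None
        return self.capture_time.hour * 60 + self.capture_time.minute


@dataclass
class DeploymentEvent:
    """All records sharing one (site, date, set_number) key."""
    key: tuple[str, dt.date, int]
    records: list[CatchRecord]

    @property
    def n_sharks(self) -> int:
        return len(self.records)

    @property
    def span_minutes(self) -> float | None:
        times = [r.time_minutes for r in self.records if r.time_minutes is not None]
        if len(times) < 2:
            return None
        return float(max(times) - min(times))


@dataclass
class ValidationReport:
    """Accounting of rows dropped (``reasons``) or flagged (``warnings``)."""
    n_records: int = 0
    n_dropped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.n_dropped += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    def warn(self, reason: str) -> None:
        self.warnings[reason] = self.warnings.get(reason, 0) + 1

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_dropped": self.n_dropped,
            "reasons": dict(self.reasons),
            "warnings": dict(self.warnings),
        }


class KinshipTable:
    """Symmetric pairwise relationships: sibling / unrelated / unknown.

    Pairs absent from the table are reported as ``"unknown"``. Full and half
    siblings are collapsed into ``"sibling"``.
    """

    RELATIONSHIPS = ("sibling", "unrelated", "unknown")

    def __init__(self) -> None:
        self._pairs: dict[frozenset[str], str] = {}

    def add(self, id_a: str, id_b: str, relationship: str) -> None:
        if id_a == id_b:
            raise ValueError(f"self-pair not allowed: {id_a}")
        rel = relationship.strip().lower()
        if rel in ("full_sibling", "half_sibling", "sib"):
            rel = "sibling"
        if rel not in self.RELATIONSHIPS:
            raise ValueError(f"unknown relationship {relationship!r}")
        self._pairs[frozenset((id_a, id_b))] = rel

    def relationship(self, id_a: str, id_b: str) -> str:
        if id_a == id_b:
            raise ValueError("no self-pairs in a kinship table")
        return self._pairs.get(frozenset((id_a, id_b)), "unknown")

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        for pair, rel in self._pairs.items():
            a, b = sorted(pair)
            yield a, b, rel

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str = ",") -> "KinshipTable":
        df = pd.read_csv(path, sep=delimiter, dtype=str)
        needed = {"id_a", "id_b", "relationship"}
        if not needed.issubset(df.columns):
            raise ValueError(f"kinship table must have columns {sorted(needed)}")
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.id_a, row.id_b, row.relationship)
        return table

    def to_csv(self, path: str | Path) -> None:
        rows = sorted(self)
        pd.DataFrame(rows, columns=["id_a", "id_b", "relationship"]).to_csv(
            path, index=False)


def load_schema(path: str | Path) -> dict[str, str]:
    """Column-name mapping from a YAML (or flat ``key=value``) config file."""
    import yaml

    text = Path(path).read_text()
    if "=" in text and ":" not in text:
        mapping = dict(line.split("=", 1) for line in text.splitlines()
                       if line.strip() and not line.startswith("#"))
    else:
        mapping = yaml.safe_load(text) or {}
    unknown = set(mapping) - set(DEFAULT_SCHEMA)
    if unknown:
        raise ValueError(f"unknown schema fields: {sorted(unknown)}")
    return {k: str(v).strip() for k, v in mapping.items()}


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value.strip())


def _parse_time(value: str) -> dt.time:
    h, m = value.strip().split(":")[:2]
    return dt.time(int(h), int(m))


def read_catch_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> tuple[list[CatchRecord], ValidationReport]:
    """Read a delimited catch table into validated :class:`CatchRecord` s.

    ``schema`` maps record fields to column names (defaults in
    :data:`DEFAULT_SCHEMA`). Site and date columns are mandatory; any other
    missing column leaves the field empty. Unparseable rows are dropped and
    counted in the returned :class:`ValidationReport`, never silently lost.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for required in ("site", "date"):
        if colmap[required] not in df.columns:
            raise ValueError(
                f"mandatory column {colmap[required]!r} (field {required}) "
                f"missing from {path}")

    report = ValidationReport()
    records: list[CatchRecord] = []
    seen_keys: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))

        def cell(fieldname: str) -> str:
            col = colmap.get(fieldname)
            if col is None or col not in df.columns:
                return ""
            return str(rowd[col]).strip()

        site = cell("site")
        if not site:
            report.drop("missing_site")
            continue
        try:
            date = _parse_date(cell("date"))
        except (ValueError, TypeError):
            report.drop("bad_date")
            continue

        raw_set = cell("set_number")
        if raw_set:
            try:
                set_number = int(float(raw_set))
                if set_number < 1:
                    raise ValueError
            except ValueError:
                report.drop("bad_set_number")
                continue
        else:
            set_number = 1  # single dusk set per site-date by default

        raw_time = cell("capture_time")
        capture_time = None
        if raw_time:
            try:
                capture_time = _parse_time(raw_time)
            except (ValueError, IndexError):
                report.warn("bad_time")

        raw_fl = cell("fork_length_mm")
        fork_length = None
        if raw_fl:
            try:
                fork_length = float(raw_fl)
                if fork_length <= 0:
                    raise ValueError
            except ValueError:
                fork_length = None
                report.warn("bad_fork_length")

        sex_raw = cell("sex").lower()
        sex = _SEX_ALIASES.get(sex_raw)
        if sex is None:
            sex = "unknown"
            report.warn("bad_sex")

        individual_id = cell("individual_id") or None
        record_id = cell("record_id") or f"r{i:06d}"

        if individual_id is not None:
            key = (site, date, set_number, capture_time, individual_id)
            if key in seen_keys:
                report.drop("duplicate_record")
                continue
            seen_keys.add(key)

        records.append(CatchRecord(
            record_id=record_id, site=site, date=date, set_number=set_number,
            capture_time=capture_time, individual_id=individual_id,
            sex=sex, fork_length_mm=fork_length))

    report.n_records = len(records)
    return records, report


def records_to_frame(records: Iterable[CatchRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "site": r.site,
            "date": r.date.isoformat(),
            "set_number": r.set_number,
            "capture_time": (None if r.capture_time is None
                             else r.capture_time.strftime("%H:%M")),
            "individual_id": r.individual_id,
            "sex": r.sex,
            "fork_length_mm": r.fork_length_mm,
        })
    return pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA))


def write_catch_table(
    records: Sequence[CatchRecord],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write records back out in the default schema (CSV by default)."""
    records_to_frame(records).to_csv(path, sep=delimiter, index=False)


def filter_juveniles(
    records: Sequence[CatchRecord],
    max_fl_mm: float = 1000.0,
) -> tuple[list[CatchRecord], ValidationReport]:
    """Drop individuals at or above the maturity size cut (~1 m fork length).

    Records with missing fork length are retained: the filter only acts when
    size is known. Idempotent.
    """
    if max_fl_mm <= 0:
        raise ValueError("max_fl_mm must be positive")
    report = ValidationReport()
    kept = []
    for r in records:
        if r.fork_length_mm is not None and r.fork_length_mm >= max_fl_mm:
            report.drop("adult_size")
        else:
            kept.append(r)
    report.n_records = len(kept)
    return kept, report


def require_nonempty_deployments(
    deployments: Sequence[DeploymentEvent],
) -> list[DeploymentEvent]:
    """Remove zero-catch deployments (possible after joining an effort table)."""
    kept = [d for d in deployments if d.n_sharks > 0]
    n_removed = len(deployments) - len(kept)
    if n_removed:
        log.warning("removed %d zero-catch deployments", n_removed)
    if not kept:
        log.warning("no deployments with catches remain")
    return kept
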