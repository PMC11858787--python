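"""Reading and curating occurrence tables.

Raw herbarium downloads arrive as Darwin-Core-style CSV/TSV.  Curation
follows the usual phenology-prep sequence: resolve names against a local
synonym table, drop duplicate vouchers, and remove records that cannot
contribute to a flowering calendar (no label text, unresolvable name, or
no collection month).  Every drop is counted so the report balances.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SpecimenRecord",
    "CurationReport",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_DEDUP_KEY",
    "read_occurrence_table",
    "resolve_names",
    "deduplicate",
    "filter_usable",
    "records_to_frame",
    "write_records",
]

DEFAULT_COLUMN_MAP: dict[str, str] = {
    "raw_name": "scientificName",
    "event_date": "eventDate",
    "year": "year",
    "month": "month",
    "day": "day",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "label_text": "fieldNotes",
    "catalog_number": "catalogNumber",
    "family": "family",
    "source": "source",
}

DEFAULT_DEDUP_KEY = ("accepted_name", "year", "month", "day", "catalog_number")


@dataclass
class SpecimenRecord:
    record_id: str
    raw_name: str
    accepted_name: str | None = None
    family: str | None = None
    year: int | None = None
    month: int | None = None
    day: int | None = None
    latitude: float | None = None
    longitude: float | None = None
    label_text: str | None = None
    source: str | None = None
    catalog_number: str | None = None

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and self.month is None:
            raise ValueError("day present without month")


@dataclass
class CurationReport:
    """Per-step record accounting; always balances to the input count."""

    read: int = 0
    dropped_duplicates: int = 0
    dropped_no_label: int = 0
    dropped_unresolved_name: int = 0
    dropped_no_month: int = 0
    retained: int = 0

    @property
    def balanced(self) -> bool:
        drops = (self.dropped_duplicates + self.dropped_no_label
                 + self.dropped_unresolved_name + self.dropped_no_month)
        return self.read == self.retained + drops

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _parse_int(v) -> int | None:
    try:
        if v is None or (isinstance(v, float) and v != v):
            return None
        s = str(v).strip()
        if not s:
            return None
        return int(float(s))
    except (ValueError, TypeError):
        return None


def _parse_float(v, lo: float, hi: float) -> float | None:
    try:
        x = float(str(v).strip())
    except (ValueError, TypeError, AttributeError):
        return None
    if x != x or not lo <= x <= hi:
        return None
    return x


_DATE_RE = re.compile(r"^\s*(\d{4})(?:[-/](\d{1,2}))?(?:[-/](\d{1,2}))?")


def _parse_event_date(v) -> tuple[int | None, int | None, int | None]:
    """ISO-ish eventDate → (year, month, day); anything unparseable → absent."""
    if v is None:
        return None, None, None
    m = _DATE_RE.match(str(v))
    if not m:
        return None, None, None
    year = int(m.group(1))
    month = int(m.group(2)) if m.group(2) else None
    day = int(m.group(3)) if m.group(3) else None
    if month is not None and not 1 <= month <= 12:
        month, day = None, None
    if day is not None and not 1 <= day <= 31:
        day = None
    return year, month, day


def read_occurrence_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    source: str | None = None,
) -> list[SpecimenRecord]:
    """Read one occurrence CSV/TSV into records.

    Unparseable coordinates or dates become absent fields rather than
    errors; explicit year/month/day columns take precedence over
    ``eventDate`` when present and non-empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if cmap["raw_name"] not in df.columns:
        raise ValueError(f"missing mandatory name column {cmap['raw_name']!r}")

    def col(row, key):
        c = cmap.get(key)
        if c and c in df.columns:
            v = row[c]
            return v if str(v).strip() != "" else None
        return None

    records = []
    for idx, row in df.iterrows():
        year = _parse_int(col(row, "year"))
        month = _parse_int(col(row, "month"))
        day = _parse_int(col(row, "day"))
        if year is None and month is None:
            year, month, day = _parse_event_date(col(row, "event_date"))
        if month is not None and not 1 <= month <= 12:
            month, day = None, None
        if day is not None and not 1 <= day <= 31:
            day = None
        if month is None:
            day = None
        catalog = col(row, "catalog_number")
        records.append(SpecimenRecord(
            record_id=catalog or f"row-{idx}",
            raw_name=str(col(row, "raw_name") or "").strip(),
            family=col(row, "family"),
            year=year, month=month, day=day,
            latitude=_parse_float(col(row, "latitude"), -90, 90),
            longitude=_parse_float(col(row, "longitude"), -180, 180),
            label_text=col(row, "label_text"),
            source=source or col(row, "source"),
            catalog_number=catalog,
        ))
    return records


def normalize_name(name: str) -> str:
    """Matching key for a scientific name: lowercase, collapsed whitespace,
    authorship stripped (only the first two tokens are compared)."""
    tokens = re.sub(r"\s+", " ", name.strip().lower()).split(" ")
    return " ".join(tokens[:2])


def load_synonym_table(table: pd.DataFrame | Mapping[str, str]) -> dict[str, str]:
    if isinstance(table, Mapping):
        items = table.items()
    else:
        items = zip(table["synonym"], table["accepted"])
    out: dict[str, str] = {}
    for syn, acc in items:
        key = normalize_name(str(syn))
        if key in out and out[key] != str(acc):
            raise ValueError(f"conflicting synonym entries for {key!r}")
        out[key] = str(acc)
    return out


def resolve_names(
    records: Iterable[SpecimenRecord],
    synonym_table: pd.DataFrame | Mapping[str, str],
) -> list[SpecimenRecord]:
    """Set ``accepted_name`` by exact normalized match; misses stay None."""
    mapping = load_synonym_table(synonym_table)
    return [replace(r, accepted_name=mapping.get(normalize_name(r.raw_name)))
            for r in records]


_ABSENT = object()


def deduplicate(
    records: Sequence[SpecimenRecord],
    key_fields: Sequence[str] = DEFAULT_DEDUP_KEY,
) -> tuple[list[SpecimenRecord], int]:
    """Keep the first occurrence of each key, in input order.

    An absent field acts as its own value: two records that both lack a
    catalogue number but agree on everything else are duplicates.
    """
    if not key_fields:
        raise ValueError("key_fields must be non-empty")
    seen: set[tuple] = set()
    kept: list[SpecimenRecord] = []
    for r in records:
        key = tuple(getattr(r, f) if getattr(r, f) is not None else "\0absent"
                    for f in key_fields)
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    removed = len(records) - len(kept)
    return kept, removed


def filter_usable(
    records: Sequence[SpecimenRecord],
    dedup_removed: int = 0,
) -> tuple[list[SpecimenRecord], CurationReport]:
    """Drop records unusable for phenology and account for every drop.

    A usable record has non-empty label text, a resolved accepted name and
    a collection month.  Records with month but no day are retained (the
    angular mapping mid-months them later).
    """
    report = CurationReport(read=len(records) + dedup_removed,
                            dropped_duplicates=dedup_removed)
    kept = []
    for r in records:
        if not r.label_text or not str(r.label_text).strip():
            report.dropped_no_label += 1
        elif not r.accepted_name:
            report.dropped_unresolved_name += 1
        elif r.month is None:
            report.dropped_no_month += 1
        else:
            kept.append(r)
    report.retained = len(kept)
    log.info("curation: %s", asdict(report))
    return kept, report


def records_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def write_records(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
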