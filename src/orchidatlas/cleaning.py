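"""Seven-rule cleaning of Darwin-Core-style occurrence tables.

A raw herbarium export is reduced to analysis-ready records by removing
rows that are

    (a) not identified to species level (genus-only names, "Genus sp."),
    (b) collected outside the target country,
    (c) lacking latitude or longitude,
    (d) duplicates (nonunique species name + latitude + longitude),
    (e) cultivated specimens,
    (f) hybrid combinations between species,
    (g) not native (establishment means "naturalized").

Rules (a,b,c,e,f,g) are per-record predicates; duplicates (d) are detected
among records that no predicate flags, keeping the first row of each
(name, latitude, longitude) group.  Consequently the retained set does not
depend on the order in which rules are applied; ``rule_order`` only decides
which rule a multiply-flagged row is attributed to in the report.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, FormatError
from .synth import CLEANING_RULES, OCCURRENCE_COLUMNS

logger = logging.getLogger(__name__)

_HYBRID_MARKERS = ("×", " x ")


@dataclass
class OccurrenceRecord:
    """One vouchered collection event."""

    record_id: str
    scientific_name: str
    genus: str
    family: str
    latitude: float | None  # decimal degrees, None when not georeferenced
    longitude: float | None
    country: str
    cultivated: bool
    hybrid: bool
    establishment: str  # native | naturalized | unknown

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise FormatError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise FormatError(f"longitude out of range: {self.longitude}")

    @property
    def georeferenced(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass
class CleaningReport:
    input_count: int
    retained_count: int
    removed_by_rule: dict[str, int]
    rule_order: tuple[str, ...]

    def check_conservation(self) -> bool:
        return self.input_count == self.retained_count + sum(
            self.removed_by_rule.values()
        )

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "retained_count": self.retained_count,
            "removed_by_rule": dict(self.removed_by_rule),
            "rule_order": list(self.rule_order),
        }


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_coord(raw: str, lo: float, hi: float, row_id: str, what: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        val = float(raw)
    except ValueError:
        logger.warning("row %s: unparseable %s %r treated as missing", row_id, what, raw)
        return None
    if not lo <= val <= hi:
        logger.warning("row %s: %s %r out of bounds, treated as missing", row_id, what, raw)
        return None
    return val


def _parse_flag(raw: str) -> bool:
    return raw.strip().lower() in {"1", "true", "yes", "t", "y"}


def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read an occurrence CSV into records.

    Blank or unparseable coordinate cells become missing coordinates (the
    row stays and is removable by rule (c)); a missing required column is
    a :class:`FormatError` naming the column.
    """
    path = Path(path)
    records: list[OccurrenceRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header required")
        for col in OCCURRENCE_COLUMNS:
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        for row in reader:
            rid = row["record_id"]
            records.append(
                OccurrenceRecord(
                    record_id=rid,
                    scientific_name=row["scientificName"].strip(),
                    genus=row["genus"].strip(),
                    family=row["family"].strip(),
                    latitude=_parse_coord(row["decimalLatitude"], -90, 90, rid, "latitude"),
                    longitude=_parse_coord(
                        row["decimalLongitude"], -180, 180, rid, "longitude"
                    ),
                    country=row["country"].strip(),
                    cultivated=_parse_flag(row["cultivated"]),
                    hybrid=_parse_flag(row["hybrid"]),
                    establishment=row["establishmentMeans"].strip().lower() or "unknown",
                )
            )
    return records


def _coord_str(value: float | None) -> str:
    """Canonical decimal string for a coordinate (no rounding).

    Trims a trailing ``.0`` so 12 and 12.0 compare equal, but otherwise
    preserves every decimal the source carried.
    """
    if value is None:
        return ""
    text = repr(float(value))
    return text[:-2] if text.endswith(".0") else text


def write_occurrences(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    """Write records back to the occurrence CSV dialect (lossless round trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OCCURRENCE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.scientific_name,
                    r.genus,
                    r.family,
                    _coord_str(r.latitude),
                    _coord_str(r.longitude),
                    r.country,
                    int(r.cultivated),
                    int(r.hybrid),
                    r.establishment,
                ]
            )


def records_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    """DataFrame view in the occurrence CSV column layout."""
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "scientificName": r.scientific_name,
                "genus": r.genus,
                "family": r.family,
                "decimalLatitude": math.nan if r.latitude is None else r.latitude,
                "decimalLongitude": math.nan if r.longitude is None else r.longitude,
                "country": r.country,
                "cultivated": int(r.cultivated),
                "hybrid": int(r.hybrid),
                "establishmentMeans": r.establishment,
            }
            for r in records
        ],
        columns=OCCURRENCE_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[OccurrenceRecord]:
    records = []
    for row in frame.itertuples(index=False):
        lat = getattr(row, "decimalLatitude")
        lon = getattr(row, "decimalLongitude")
        records.append(
            OccurrenceRecord(
                record_id=str(getattr(row, "record_id")),
                scientific_name=str(getattr(row, "scientificName")),
                genus=str(getattr(row, "genus")),
                family=str(getattr(row, "family")),
                latitude=None if pd.isna(lat) else float(lat),
                longitude=None if pd.isna(lon) else float(lon),
                country=str(getattr(row, "country")),
                cultivated=bool(getattr(row, "cultivated")),
                hybrid=bool(getattr(row, "hybrid")),
                establishment=str(getattr(row, "establishmentMeans")).lower(),
            )
        )
    return records


# ---------------------------------------------------------------------------
# the seven rules
# ---------------------------------------------------------------------------

def is_genus_only(name: str) -> bool:
    """Rule (a): name is genus-only ('Caladenia', 'Caladenia sp.')."""
    tokens = name.split()
    if len(tokens) <= 1:
        return True
    return tokens[1].rstrip(".").lower() == "sp"


def is_hybrid_name(name: str) -> bool:
    """Rule (f) name test: a hybrid marker between epithets."""
    return any(marker in name for marker in _HYBRID_MARKERS)


def duplicate_key(record: OccurrenceRecord) -> tuple[str, str, str]:
    """Rule (d) identity: exact species name + canonical coordinate strings."""
    return (
        record.scientific_name,
        _coord_str(record.latitude),
        _coord_str(record.longitude),
    )


def apply_filters(
    records: Sequence[OccurrenceRecord],
    target_country: str | None = "Australia",
    rule_order: Sequence[str] = CLEANING_RULES,
) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Apply the seven cleaning rules; return retained records + report.

    ``target_country=None`` disables rule (b) (useful when the table is
    known to be single-country).  The retained set is invariant to
    ``rule_order``; attribution of rows flagged by several rules follows
    the first applicable rule in ``rule_order``.
    """
    order = tuple(rule_order)
    if sorted(order) != sorted(CLEANING_RULES):
        raise ConfigError(
            f"rule_order must be a permutation of {CLEANING_RULES}, got {order}"
        )

    predicates = {
        "a": lambda r: is_genus_only(r.scientific_name),
        "b": lambda r: target_country is not None and r.country != target_country,
        "c": lambda r: not r.georeferenced,
        "e": lambda r: r.cultivated,
        "f": lambda r: r.hybrid or is_hybrid_name(r.scientific_name),
        "g": lambda r: r.establishment == "naturalized",
    }

    removed = {rule: 0 for rule in CLEANING_RULES}
    retained: list[OccurrenceRecord] = []
    seen_keys: set[tuple[str, str, str]] = set()

    for record in records:
        flags = {rule for rule, pred in predicates.items() if pred(record)}
        if not flags:
            key = duplicate_key(record)
            if key in seen_keys:
                flags.add("d")
            else:
                seen_keys.add(key)
        if flags:
            first = next(rule for rule in order if rule in flags)
            removed[first] += 1
        else:
            retained.append(record)

    report = CleaningReport(
        input_count=len(records),
        retained_count=len(retained),
        removed_by_rule=removed,
        rule_order=order,
    )
    assert report.check_conservation()
    return retained, report
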