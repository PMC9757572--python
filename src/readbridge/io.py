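"""Readers and writers for the tab-separated interchange formats.

All files are UTF-8 TSV with a header row, matching the shape of the
upstream artifacts this toolkit consumes (UK Biobank ``coding*.txt``
dictionaries, TRUD lookup-sheet exports, ``gp_clinical``-style event
extracts). Readers are total: malformed rows either raise a typed error or
are dropped and counted in a :class:`ParseReport`, per each reader's
contract; rows are never reordered.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import IO, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import DuplicateKeyError, ParseError, SchemaError
from .terminology import CodeSystem, Concept, Ontology

__all__ = [
    "KNOWN_MAPPING_STATUSES",
    "MappingEntry",
    "ClinicalEvent",
    "MappingRecord",
    "ParseReport",
    "read_coding_table",
    "read_mapping_table",
    "read_events",
    "write_mapping_records",
    "read_mapping_records",
]

#: Mapping-status flags with defined semantics: Exact, more General,
#: Default, Alternative, Requires checking. Other characters are preserved
#: but reported.
KNOWN_MAPPING_STATUSES = frozenset({"E", "G", "D", "A", "R"})


@dataclass
class ParseReport:
    """Recoverable problems encountered while reading one file."""

    warnings: List[str] = field(default_factory=list)
    dropped_rows: int = 0
    row_errors: List[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)


@dataclass(frozen=True)
class MappingEntry:
    """One source Read code -> target code pair with TRUD-style flags."""

    source_code: str
    target_code: str
    target_system: CodeSystem
    source_version: Optional[CodeSystem] = None
    mapping_status: str = ""
    refine_flag: str = ""
    add_code_flag: str = ""
    element_num: Optional[int] = None
    block_num: Optional[int] = None
    provenance: str = "TRUD"

    def __post_init__(self) -> None:
        if (self.element_num is None) != (self.block_num is None):
            raise ParseError(
                f"element_num/block_num must be present together for "
                f"{self.source_code!r} -> {self.target_code!r}"
            )


@dataclass(frozen=True)
class ClinicalEvent:
    """One coded primary-care event for one participant."""

    eid: str
    data_provider: int
    event_dt: dt.date
    read_2: Optional[str] = None
    read_3: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.read_2 and not self.read_3:
            raise ParseError(f"event for {self.eid} carries no Read code")
        if self.data_provider not in (1, 2, 3, 4):
            raise ParseError(f"data_provider must be 1-4, got {self.data_provider}")


@dataclass
class MappingRecord:
    """The pipeline's verdict for one Read code.

    ``targets`` may be empty only for codes the pipeline could not map,
    which are always flagged for review. ``similarity`` is present exactly
    when the record came from fuzzy description matching.
    """

    read_code: str
    read_version: CodeSystem
    targets: List[Tuple[str, CodeSystem]] = field(default_factory=list)
    method: str = "LOOKUP"  # LOOKUP | ICD9_BRIDGE | FUZZY | MANUAL | CROSSMAP
    similarity: Optional[float] = None
    review_needed: bool = False

    def __post_init__(self) -> None:
        if (self.method == "FUZZY") != (self.similarity is not None):
            raise ParseError(
                f"similarity must be present iff method is FUZZY "
                f"({self.read_code}: method={self.method})"
            )


def _read_tsv(stream: IO[str], required: Sequence[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")
    return df


def read_coding_table(
    stream: IO[str], system: CodeSystem = CodeSystem.ICD10
) -> Ontology:
    """Read a UK Biobank-style coding dictionary (columns coding, meaning).

    An optional ``parent`` column populates the concept hierarchy. Duplicate
    codes raise a :class:`DuplicateKeyError`.
    """
    df = _read_tsv(stream, ["coding", "meaning"], "coding table")
    dupes = df["coding"][df["coding"].duplicated()].tolist()
    if dupes:
        raise DuplicateKeyError(f"duplicate coding value(s): {sorted(set(dupes))}")
    has_parent = "parent" in df.columns
    ontology = Ontology(system=system)
    for row in df.itertuples(index=False):
        parent = getattr(row, "parent", "") if has_parent else ""
        ontology.add(
            Concept(
                system=system,
                code=row.coding,
                description=row.meaning,
                active=True,
                parent_code=parent or None,
            )
        )
    return ontology


def read_mapping_table(stream: IO[str]) -> Tuple[List[MappingEntry], ParseReport]:
    """Read a TRUD-style lookup export into mapping entries, in file order."""
    df = _read_tsv(stream, ["read_code", "target_code", "target_system"], "mapping table")
    report = ParseReport()
    entries: List[MappingEntry] = []

    def cell(row, name: str) -> str:
        return getattr(row, name, "") if name in df.columns else ""

    for i, row in enumerate(df.itertuples(index=False), start=2):
        status = cell(row, "mapping_status").strip()
        if status and status not in KNOWN_MAPPING_STATUSES:
            report.warn(
                f"row {i}: unknown mapping_status {status!r} for "
                f"{row.read_code!r} (kept)"
            )
        nums = {}
        for name in ("element_num", "block_num"):
            raw = cell(row, name).strip()
            if raw:
                try:
                    nums[name] = int(raw)
                except ValueError:
                    raise ParseError(f"row {i}: non-integer {name} {raw!r}") from None
            else:
                nums[name] = None
        version_raw = cell(row, "read_version").strip()
        entries.append(
            MappingEntry(
                source_code=row.read_code,
                source_version=CodeSystem.parse(version_raw) if version_raw else None,
                target_code=row.target_code,
                target_system=CodeSystem.parse(row.target_system),
                mapping_status=status,
                refine_flag=cell(row, "refine_flag").strip(),
                add_code_flag=cell(row, "add_code_flag").strip(),
                element_num=nums["element_num"],
                block_num=nums["block_num"],
                provenance=cell(row, "provenance").strip() or "TRUD",
            )
        )
    return entries, report


def _parse_event_date(raw: str) -> dt.date:
    for fmt in ("%Y-%m-%d", "%d/%m/%Y"):
        try:
            return dt.datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date {raw!r}")


def read_events(stream: IO[str]) -> Tuple[List[ClinicalEvent], ParseReport]:
    """Read a gp_clinical-style event extract.

    Rows with no Read code in either column are dropped and counted; rows
    with unparseable dates are dropped and recorded as row errors. Extra
    columns (the free-text value fields) are ignored.
    """
    df = _read_tsv(
        stream, ["eid", "data_provider", "event_dt", "read_2", "read_3"], "events table"
    )
    report = ParseReport()
    events: List[ClinicalEvent] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        read_2, read_3 = row.read_2.strip(), row.read_3.strip()
        if not read_2 and not read_3:
            report.dropped_rows += 1
            continue
        try:
            when = _parse_event_date(row.event_dt.strip())
            provider = int(row.data_provider)
        except ValueError as exc:
            report.row_errors.append(f"row {i}: {exc}")
            report.dropped_rows += 1
            continue
        events.append(
            ClinicalEvent(
                eid=row.eid,
                data_provider=provider,
                event_dt=when,
                read_2=read_2 or None,
                read_3=read_3 or None,
            )
        )
    return events, report


_RECORD_HEADER = [
    "read_code",
    "read_version",
    "target_code",
    "target_system",
    "method",
    "similarity",
    "review_needed",
]


def write_mapping_records(records: Sequence[MappingRecord], stream: IO[str]) -> None:
    """Write records as TSV, one row per (record, target) pair.

    Unmapped records emit a single row with empty target columns so that
    writing then re-reading reproduces the record list exactly.
    """
    stream.write("\t".join(_RECORD_HEADER) + "\n")
    for rec in records:
        sim = "" if rec.similarity is None else repr(rec.similarity)
        review = "true" if rec.review_needed else "false"
        rows = rec.targets or [("", None)]
        for code, system in rows:
            stream.write(
                "\t".join(
                    [
                        rec.read_code,
                        rec.read_version.value,
                        code,
                        system.value if system is not None else "",
                        rec.method,
                        sim,
                        review,
                    ]
                )
                + "\n"
            )


def read_mapping_records(stream: IO[str]) -> List[MappingRecord]:
    """Inverse of :func:`write_mapping_records` (round-trip identity)."""
    df = _read_tsv(stream, _RECORD_HEADER, "mapping records")
    records: List[MappingRecord] = []
    for row in df.itertuples(index=False):
        key = (row.read_code, row.read_version, row.method, row.similarity,
               row.review_needed)
        if not records or records[-1]._key != key:  # type: ignore[attr-defined]
            rec = MappingRecord(
                read_code=row.read_code,
                read_version=CodeSystem.parse(row.read_version),
                targets=[],
                method=row.method,
                similarity=float(row.similarity) if row.similarity else None,
                review_needed=row.review_needed == "true",
            )
            rec._key = key  # type: ignore[attr-defined]
            records.append(rec)
        if row.target_code:
            records[-1].targets.append(
                (row.target_code, CodeSystem.parse(row.target_system))
            )
    for rec in records:
        del rec._key  # type: ignore[attr-defined]
    return records
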