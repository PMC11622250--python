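"""Readers and case-level plumbing for FAERS-style quarterly ASCII tables.

The quarterly archives distribute seven tables as "$"-delimited text with a
single header line and no quoting: DEMO (demographics/administration), DRUG,
REAC (reactions as MedDRA preferred terms), OUTC (outcomes), RPSR (report
sources), THER (therapy dates) and INDI (indications).  A case may appear
several times across quarters as successive versions sharing a CASEID;
deduplication keeps the version with the latest FDA receipt date (FDA_DT).
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
AGE_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
OCCUPATION_CODES = frozenset({"CN", "MD", "PH", "OT", "HP"})


class PartialDate(NamedTuple):
    """A possibly incomplete date: year always present, month/day optional."""

    year: int
    month: int | None = None
    day: int | None = None

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def is_full(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> date:
        if not self.is_full():
            raise ValueError("partial date has no day-level resolution")
        return date(self.year, self.month, self.day)


def parse_partial_date(raw: str | None) -> PartialDate | None:
    """Parse a FAERS date stamp (YYYYMMDD, YYYYMM or YYYY).

    Anything else — wrong length, non-digits, impossible calendar values —
    yields ``None``.  No imputation is performed here.
    """
    if raw is None:
        return None
    s = raw.strip()
    if not s.isdigit():
        return None
    if len(s) == 8:
        try:
            d = date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return None
        return PartialDate(d.year, d.month, d.day)
    if len(s) == 6:
        year, month = int(s[:4]), int(s[4:6])
        if not 1 <= month <= 12:
            return None
        return PartialDate(year, month, None)
    if len(s) == 4:
        return PartialDate(int(s), None, None)
    return None


# --------------------------------------------------------------------------
# Typed records
# --------------------------------------------------------------------------


@dataclass(slots=True)
class DemoRecord:
    primaryid: str
    caseid: str | None = None
    case_version: int | None = None
    fda_dt: str | None = None
    event_dt: str | None = None
    age: float | None = None
    age_cod: str | None = None
    sex: str | None = None
    reporter_country: str | None = None
    occp_cod: str | None = None
    extras: dict = field(default_factory=dict)


@dataclass(slots=True)
class DrugRecord:
    primaryid: str
    drug_seq: int = 1
    role_cod: str | None = None
    drugname: str | None = None
    route: str | None = None
    canonical: str | None = None  # filled in by harmonization, not by the reader
    extras: dict = field(default_factory=dict)


@dataclass(slots=True)
class ReacRecord:
    primaryid: str
    pt: str = ""
    extras: dict = field(default_factory=dict)


@dataclass(slots=True)
class OutcRecord:
    primaryid: str
    outc_cod: str = ""
    extras: dict = field(default_factory=dict)


@dataclass(slots=True)
class RpsrRecord:
    primaryid: str
    rpsr_cod: str = ""
    extras: dict = field(default_factory=dict)


@dataclass(slots=True)
class TherRecord:
    primaryid: str
    dsg_drug_seq: int = 1
    start_dt: str | None = None
    end_dt: str | None = None
    extras: dict = field(default_factory=dict)


@dataclass(slots=True)
class IndiRecord:
    primaryid: str
    indi_drug_seq: int = 1
    indi_pt: str = ""
    extras: dict = field(default_factory=dict)


@dataclass(slots=True)
class CaseReport:
    """One deduplicated case: a DEMO record joined with its satellite rows."""

    demo: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)
    outcomes: list[OutcRecord] = field(default_factory=list)
    sources: list[RpsrRecord] = field(default_factory=list)
    therapies: list[TherRecord] = field(default_factory=list)
    indications: list[IndiRecord] = field(default_factory=list)

    @property
    def primaryid(self) -> str:
        return self.demo.primaryid

    @property
    def caseid(self) -> str | None:
        return self.demo.caseid


_RECORD_CLASSES = {
    "DEMO": DemoRecord,
    "DRUG": DrugRecord,
    "REAC": ReacRecord,
    "OUTC": OutcRecord,
    "RPSR": RpsrRecord,
    "THER": TherRecord,
    "INDI": IndiRecord,
}

# header name -> (record attribute, converter); anything else lands in extras
_INT_FIELDS = {"caseversion", "drug_seq", "dsg_drug_seq", "indi_drug_seq"}
_FLOAT_FIELDS = {"age"}
_FIELD_MAP = {
    "DEMO": {
        "primaryid": "primaryid",
        "caseid": "caseid",
        "caseversion": "case_version",
        "fda_dt": "fda_dt",
        "event_dt": "event_dt",
        "age": "age",
        "age_cod": "age_cod",
        "sex": "sex",
        "gndr_cod": "sex",  # legacy column name in early quarters
        "reporter_country": "reporter_country",
        "occp_cod": "occp_cod",
    },
    "DRUG": {
        "primaryid": "primaryid",
        "drug_seq": "drug_seq",
        "role_cod": "role_cod",
        "drugname": "drugname",
        "route": "route",
    },
    "REAC": {"primaryid": "primaryid", "pt": "pt"},
    "OUTC": {"primaryid": "primaryid", "outc_cod": "outc_cod"},
    "RPSR": {"primaryid": "primaryid", "rpsr_cod": "rpsr_cod"},
    "THER": {
        "primaryid": "primaryid",
        "dsg_drug_seq": "dsg_drug_seq",
        "start_dt": "start_dt",
        "end_dt": "end_dt",
    },
    "INDI": {
        "primaryid": "primaryid",
        "indi_drug_seq": "indi_drug_seq",
        "indi_pt": "indi_pt",
    },
}

_MANDATORY = {
    "DEMO": ("primaryid",),
    "DRUG": ("primaryid", "drugname"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "RPSR": ("primaryid",),
    "THER": ("primaryid", "dsg_drug_seq"),
    "INDI": ("primaryid", "indi_pt"),
}


@dataclass
class TableReport:
    """Per-table parse accounting."""

    table: str
    path: str
    rows_read: int = 0
    rows_rejected: int = 0
    reject_reasons: Counter = field(default_factory=Counter)
    flags: Counter = field(default_factory=Counter)


@dataclass
class ParseReport:
    tables: dict[str, TableReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            name: {
                "path": t.path,
                "rows_read": t.rows_read,
                "rows_rejected": t.rows_rejected,
                "reject_reasons": dict(t.reject_reasons),
                "flags": dict(t.flags),
            }
            for name, t in self.tables.items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass
class QuarterData:
    """Typed record sequences for one (or several concatenated) quarters."""

    demo: list[DemoRecord] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReacRecord] = field(default_factory=list)
    outc: list[OutcRecord] = field(default_factory=list)
    rpsr: list[RpsrRecord] = field(default_factory=list)
    ther: list[TherRecord] = field(default_factory=list)
    indi: list[IndiRecord] = field(default_factory=list)
    report: ParseReport = field(default_factory=ParseReport)

    def table(self, name: str) -> list:
        return getattr(self, name.lower())

    def extend(self, other: "QuarterData") -> None:
        for name in TABLE_NAMES:
            self.table(name).extend(other.table(name))
        self.report.tables.update(other.report.tables)


def _read_text(path: Path) -> str:
    # Real archives mix encodings; fall back to latin-1, which never fails.
    raw = path.read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


def _clean(value: str) -> str | None:
    v = value.strip()
    return v if v else None


def _validate_record(table: str, rec, report: TableReport) -> None:
    if table == "DEMO":
        if rec.age is not None and rec.age_cod is None:
            report.flags["age_without_unit"] += 1
        if rec.fda_dt is not None and parse_partial_date(rec.fda_dt) is None:
            report.flags["unparseable_fda_dt"] += 1
    elif table == "DRUG":
        if rec.role_cod is not None and rec.role_cod.upper() not in ROLE_CODES:
            report.flags["unknown_role_cod"] += 1
    elif table == "OUTC":
        if rec.outc_cod.upper() not in OUTCOME_CODES:
            report.flags["unknown_outc_cod"] += 1


def read_table(table: str, path: str | Path) -> tuple[list, TableReport]:
    """Parse one "$"-delimited table file into typed records.

    Rows whose field count disagrees with the header are rejected and
    counted, never silently dropped.  A missing mandatory column is a hard
    error naming the file and the column.
    """
    table = table.upper()
    if table not in TABLE_NAMES:
        raise ValueError(f"unknown FAERS table name: {table!r}")
    path = Path(path)
    report = TableReport(table=table, path=str(path))
    text = _read_text(path)
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, no header line")
    header = [h.strip().casefold() for h in lines[0].split("$")]
    for col in _MANDATORY[table]:
        if col not in header:
            raise ValueError(f"{path}: mandatory column {col!r} missing from header")
    fmap = _FIELD_MAP[table]
    cls = _RECORD_CLASSES[table]
    ncols = len(header)
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        report.rows_read += 1
        values = line.split("$")
        if len(values) != ncols:
            report.rows_rejected += 1
            report.reject_reasons["field_count_mismatch"] += 1
            continue
        kwargs: dict = {}
        extras: dict = {}
        bad = None
        for col, raw in zip(header, values):
            value = _clean(raw)
            attr = fmap.get(col)
            if attr is None:
                extras[col] = value
                continue
            if value is None:
                kwargs[attr] = None
                continue
            if col in _INT_FIELDS:
                try:
                    kwargs[attr] = int(value)
                except ValueError:
                    bad = f"non_integer_{col}"
                    break
            elif col in _FLOAT_FIELDS:
                try:
                    kwargs[attr] = float(value)
                except ValueError:
                    bad = f"non_numeric_{col}"
                    break
            else:
                kwargs[attr] = value
        if bad is not None:
            report.rows_rejected += 1
            report.reject_reasons[bad] += 1
            continue
        missing = [c for c in _MANDATORY[table] if kwargs.get(fmap[c]) is None]
        if missing:
            report.rows_rejected += 1
            report.reject_reasons[f"missing_{missing[0]}"] += 1
            continue
        # dataclass defaults fill anything the file did not carry
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        rec = cls(**kwargs)
        rec.extras = extras
        _validate_record(table, rec, report)
        records.append(rec)
    return records, report


def read_quarter(paths: Mapping[str, str | Path]) -> QuarterData:
    """Read a set of quarterly table files keyed by table name.

    Unknown keys are ignored with a warning; the seven canonical names are
    DEMO, DRUG, REAC, OUTC, RPSR, THER and INDI (case-insensitive).
    """
    data = QuarterData()
    for name, path in paths.items():
        upper = name.upper()
        if upper not in TABLE_NAMES:
            warnings.warn(f"ignoring unknown table {name!r}", stacklevel=2)
            continue
        records, treport = read_table(upper, path)
        data.table(upper).extend(records)
        data.report.tables[upper] = treport
    return data


# --------------------------------------------------------------------------
# Deduplication
# --------------------------------------------------------------------------


@dataclass
class DedupResult:
    kept: list[DemoRecord]
    removed_count: int
    unparseable_date_warnings: int = 0

    def to_dict(self) -> dict:
        return {
            "raw": len(self.kept) + self.removed_count,
            "kept": len(self.kept),
            "removed": self.removed_count,
            "unparseable_date_warnings": self.unparseable_date_warnings,
        }


def _dedup_sort_key(rec: DemoRecord) -> tuple:
    d = parse_partial_date(rec.fda_dt)
    if d is None:
        # an unparseable receipt date is never preferred over a parseable one
        return (0, 0, 0, 0, rec.primaryid)
    return (1, *d.sort_key(), rec.primaryid)


def deduplicate_cases(demo: Sequence[DemoRecord]) -> DedupResult:
    """Keep one version per CASEID: the one with the latest FDA_DT.

    Ties on the receipt date are broken by the lexicographically greatest
    PRIMARYID (which embeds the case version), so the result is a pure
    function of the input set, independent of row order.  Records without a
    CASEID form singleton groups keyed by PRIMARYID.
    """
    groups: dict[str, DemoRecord] = {}
    order: list[str] = []
    sizes: Counter = Counter()
    unparseable_keys: set[str] = set()
    for rec in demo:
        key = rec.caseid if rec.caseid is not None else f"\x00pid:{rec.primaryid}"
        sizes[key] += 1
        if parse_partial_date(rec.fda_dt) is None:
            unparseable_keys.add(key)
        cur = groups.get(key)
        if cur is None:
            groups[key] = rec
            order.append(key)
        elif _dedup_sort_key(rec) > _dedup_sort_key(cur):
            groups[key] = rec
    warnings_n = sum(1 for key in unparseable_keys if sizes[key] > 1)
    kept = [groups[k] for k in sorted(order)]
    return DedupResult(kept=kept, removed_count=len(demo) - len(kept),
                       unparseable_date_warnings=warnings_n)


def assemble_cases(data: QuarterData, kept: Sequence[DemoRecord]) -> list[CaseReport]:
    """Join satellite tables onto the kept DEMO versions by PRIMARYID."""
    by_pid: dict[str, CaseReport] = {}
    cases = []
    for demo in kept:
        case = CaseReport(demo=demo)
        by_pid[demo.primaryid] = case
        cases.append(case)
    buckets = (
        ("drug", "drugs"),
        ("reac", "reactions"),
        ("outc", "outcomes"),
        ("rpsr", "sources"),
        ("ther", "therapies"),
        ("indi", "indications"),
    )
    for table_attr, case_attr in buckets:
        for rec in getattr(data, table_attr):
            case = by_pid.get(rec.primaryid)
            if case is not None:
                getattr(case, case_attr).append(rec)
    return cases


def filter_primary_suspect(cases: Sequence[CaseReport], drug: str) -> list[CaseReport]:
    """Cases with at least one primary-suspect (PS) entry for the given drug.

    Drug names are compared after harmonization: a record's ``canonical``
    name is used when set, otherwise its raw name case-folded.  Order of the
    input is preserved.
    """
    target = " ".join(drug.split()).casefold()

    def matches(rec: DrugRecord) -> bool:
        if rec.role_cod is None or rec.role_cod.upper() != "PS":
            return False
        name = rec.canonical if rec.canonical is not None else rec.drugname
        if name is None:
            return False
        return " ".join(name.split()).casefold() == target

    out = [c for c in cases if any(matches(d) for d in c.drugs)]
    if not out:
        warnings.warn(f"no primary-suspect reports found for {drug!r}", stacklevel=2)
    return out


# --------------------------------------------------------------------------
# Writing (round-trip support)
# --------------------------------------------------------------------------

_WRITE_COLUMNS = {
    "DEMO": ("primaryid", "caseid", "case_version", "fda_dt", "event_dt", "age",
             "age_cod", "sex", "reporter_country", "occp_cod"),
    "DRUG": ("primaryid", "drug_seq", "role_cod", "drugname", "route"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "RPSR": ("primaryid", "rpsr_cod"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt", "end_dt"),
    "INDI": ("primaryid", "indi_drug_seq", "indi_pt"),
}

_HEADER_NAMES = {"case_version": "caseversion"}


def write_table(table: str, records: Iterable, path: str | Path) -> None:
    """Write typed records back to the "$"-delimited quarterly dialect."""
    table = table.upper()
    cols = _WRITE_COLUMNS[table]
    header = "$".join(_HEADER_NAMES.get(c, c) for c in cols)
    lines = [header]
    for rec in records:
        values = []
        for c in cols:
            v = getattr(rec, c)
            if v is None:
                values.append("")
            elif isinstance(v, float) and v == int(v):
                values.append(str(int(v)))
            else:
                values.append(str(v))
        lines.append("$".join(values))
    Path(path).write_text("\n".join(lines) + "\n")


def read_directory(input_dir: str | Path, pattern: str = "{table}*.txt") -> QuarterData:
    """Read every quarterly file in a directory, concatenating quarters.

    Files are matched per table with ``pattern`` (``{table}`` expands to the
    table name; matching is case-sensitive on the table prefix, as in the
    real archives).
    """
    input_dir = Path(input_dir)
    data = QuarterData()
    for table in TABLE_NAMES:
        for path in sorted(input_dir.glob(pattern.format(table=table))):
            records, treport = read_table(table, path)
            data.table(table).extend(records)
            data.report.tables[f"{table}:{path.name}"] = treport
    return data
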