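"""Vocabulary harmonization: drug synonyms, PT-to-SOC mapping, age units.

Spontaneous reports carry free-text drug names (brand names, misspellings,
salt forms) and MedDRA preferred terms (PTs).  Signal statistics are only
meaningful after collapsing synonyms onto canonical drug names and after
assigning each PT its System Organ Class (SOC) for organ-level tabulation.
Both mappings are plain two-column TSV dictionaries supplied by the user
(the licensed MedDRA hierarchy cannot be redistributed); each PT is assigned
exactly one primary SOC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from faersig.faers_io import CaseReport, DrugRecord


def norm_term(s: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return " ".join(s.split()).casefold()


# --------------------------------------------------------------------------
# Drug synonym dictionary
# --------------------------------------------------------------------------


@dataclass
class DrugSynonymMap:
    """Mapping from normalized raw drug strings to canonical names.

    Canonical names always map to themselves, so lookup is idempotent.
    Unmapped strings pass through in normalized form with ``matched=False``.
    """

    entries: dict[str, str] = field(default_factory=dict)
    unmatched: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        normalized = {norm_term(k): norm_term(v) for k, v in self.entries.items()}
        for canonical in list(normalized.values()):
            normalized.setdefault(canonical, canonical)
        self.entries = normalized

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugSynonymMap":
        """Load a two-column (raw, canonical) TSV; '#' lines are comments."""
        entries: dict[str, str] = {}
        errors = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                errors.append(f"line {lineno}: expected two tab-separated columns")
                continue
            entries[parts[0]] = parts[1]
        if errors:
            raise ValueError(f"{path}: " + "; ".join(errors))
        return cls(entries=entries)

    def lookup(self, raw: str) -> tuple[str, bool]:
        key = norm_term(raw)
        canonical = self.entries.get(key)
        if canonical is None:
            self.unmatched.add(key)
            return key, False
        return canonical, True


def standardize_drug(raw: str, synonym_map: DrugSynonymMap) -> tuple[str, bool]:
    """Resolve one raw drug string to its canonical name.

    Returns ``(canonical, matched)``; an unknown string comes back in
    normalized form with ``matched=False`` rather than raising.
    """
    return synonym_map.lookup(raw)


def apply_drug_map(cases: Iterable[CaseReport] | Iterable[DrugRecord],
                   synonym_map: DrugSynonymMap) -> int:
    """Fill ``DrugRecord.canonical`` in place; returns the unmatched count."""
    unmatched = 0
    for item in cases:
        records = item.drugs if isinstance(item, CaseReport) else [item]
        for rec in records:
            if rec.drugname is None:
                continue
            rec.canonical, ok = synonym_map.lookup(rec.drugname)
            if not ok:
                unmatched += 1
    return unmatched


# --------------------------------------------------------------------------
# PT -> SOC dictionary
# --------------------------------------------------------------------------


@dataclass
class TermMap:
    """Single-assignment mapping from preferred terms to System Organ Classes."""

    entries: dict[str, str] = field(default_factory=dict)
    unmapped_count: int = 0

    def __post_init__(self) -> None:
        self.entries = {norm_term(k): norm_term(v) for k, v in self.entries.items()}

    @property
    def soc_vocabulary(self) -> set[str]:
        return set(self.entries.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermMap":
        """Load a two-column (PT, SOC) TSV; a PT mapped twice is an error."""
        entries: dict[str, str] = {}
        errors = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                errors.append(f"line {lineno}: expected two tab-separated columns")
                continue
            pt, soc = norm_term(parts[0]), norm_term(parts[1])
            if pt in entries and entries[pt] != soc:
                errors.append(f"line {lineno}: PT {pt!r} mapped to two SOCs")
                continue
            entries[pt] = soc
        if errors:
            raise ValueError(f"{path}: " + "; ".join(errors))
        return cls(entries=entries)

    def lookup(self, pt: str) -> str | None:
        soc = self.entries.get(norm_term(pt))
        if soc is None:
            self.unmapped_count += 1
        return soc


def map_pt_to_soc(pt: str, term_map: TermMap) -> str | None:
    """SOC for a preferred term, or ``None`` when the PT is not in the map.

    Unmapped PTs are counted on the map and excluded from SOC-level
    tabulation only; they still participate at PT level.
    """
    return term_map.lookup(pt)


# --------------------------------------------------------------------------
# Age normalization
# --------------------------------------------------------------------------

# Conversion to years; week/day constants use mean calendar lengths.
AGE_FACTORS: Mapping[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

MAX_PLAUSIBLE_AGE_YEARS = 120.0


class AgeYears(NamedTuple):
    value: float
    provenance: str  # the original unit code ("YR" when the code was absent)
    assumed_unit: bool = False


def normalize_age(age: float | None, age_cod: str | None) -> AgeYears | None:
    """Convert a (value, unit-code) pair to years.

    An absent unit is treated as years and flagged via ``assumed_unit``.
    Negative values, unknown unit codes and results above 120 years are
    implausible and yield ``None``.
    """
    if age is None or age < 0:
        return None
    if age_cod is None:
        value = float(age)
        if value > MAX_PLAUSIBLE_AGE_YEARS:
            return None
        return AgeYears(value=value, provenance="YR", assumed_unit=True)
    code = age_cod.strip().upper()
    factor = AGE_FACTORS.get(code)
    if factor is None:
        return None
    value = float(age) * factor
    if value > MAX_PLAUSIBLE_AGE_YEARS:
        return None
    return AgeYears(value=value, provenance=code)
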