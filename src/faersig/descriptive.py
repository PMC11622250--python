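"""Descriptive profile of a drug's deduplicated primary-suspect reports.

Nine tabulations summarize who reported what, when: report counts per year,
reporter country, patient sex, age distribution, reporter occupation,
outcome codes, top indications, top administration routes, and the
time-to-onset distribution (days from therapy start to the adverse event).
Missing values are always reported as their own category — never silently
dropped — so every single-valued block sums to the number of reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from faersig.faers_io import CaseReport, parse_partial_date
from faersig.harmonize import norm_term, normalize_age

UNKNOWN = "unknown"

# decade bins 0-10 ... 110-120 by default; onset bins chosen so the share of
# events within the first 80 days of treatment is directly readable
DEFAULT_AGE_EDGES = tuple(range(0, 130, 10))
DEFAULT_ONSET_BINS = ((0, 30), (31, 60), (61, 80), (81, 180), (181, 360), (361, None))


@dataclass
class DescriptiveConfig:
    age_bin_edges: Sequence[int] = DEFAULT_AGE_EDGES
    onset_bins: Sequence[tuple[int, int | None]] = DEFAULT_ONSET_BINS
    top_k: int = 10


@dataclass
class DescriptiveProfile:
    n_reports: int = 0
    annual_counts: dict[str, int] = field(default_factory=dict)
    country_counts: dict[str, dict] = field(default_factory=dict)
    sex_counts: dict[str, dict] = field(default_factory=dict)
    age_bins: dict[str, int] = field(default_factory=dict)
    occupation_counts: dict[str, int] = field(default_factory=dict)
    outcome_counts: dict[str, dict] = field(default_factory=dict)
    indication_top: list[tuple[str, int]] = field(default_factory=list)
    route_top: list[tuple[str, int]] = field(default_factory=list)
    onset_bins: dict[str, dict] = field(default_factory=dict)
    onset_defined: int = 0
    onset_negative_flagged: int = 0

    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "annual_counts": self.annual_counts,
            "country_counts": self.country_counts,
            "sex_counts": self.sex_counts,
            "age_bins": self.age_bins,
            "occupation_counts": self.occupation_counts,
            "outcome_counts": self.outcome_counts,
            "indication_top": self.indication_top,
            "route_top": self.route_top,
            "onset_bins": self.onset_bins,
            "onset_defined": self.onset_defined,
            "onset_negative_flagged": self.onset_negative_flagged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _ps_drug_seqs(case: CaseReport, drug: str) -> set[int]:
    """drug_seq values of the target drug's primary-suspect entries."""
    target = norm_term(drug)
    seqs = set()
    for rec in case.drugs:
        if rec.role_cod is None or rec.role_cod.upper() != "PS":
            continue
        name = rec.canonical if rec.canonical is not None else rec.drugname
        if name is not None and norm_term(name) == target:
            seqs.add(rec.drug_seq)
    return seqs


def time_to_onset(case: CaseReport, drug: str) -> int | None:
    """Days from the earliest therapy start of the drug's PS entries to the event.

    Undefined when either date is partial/absent or the difference is
    negative (a start date after the event is an inconsistency, not a
    zero-day onset).
    """
    event = parse_partial_date(case.demo.event_dt)
    if event is None or not event.is_full():
        return None
    seqs = _ps_drug_seqs(case, drug)
    starts = []
    for ther in case.therapies:
        if ther.dsg_drug_seq in seqs:
            start = parse_partial_date(ther.start_dt)
            if start is not None and start.is_full():
                starts.append(start.to_date())
    if not starts:
        return None
    days = (event.to_date() - min(starts)).days
    if days < 0:
        return None
    return days


def _share_block(counts: dict[str, int], denom: int) -> dict[str, dict]:
    return {k: {"count": v, "share": (v / denom if denom else 0.0)}
            for k, v in sorted(counts.items())}


def _onset_label(bin_: tuple[int, int | None]) -> str:
    lo, hi = bin_
    return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"


def profile(cases: Sequence[CaseReport], drug: str,
            config: DescriptiveConfig | None = None) -> DescriptiveProfile:
    """Build the full descriptive profile of PS-filtered, deduplicated cases.

    Single-valued blocks (year, country, sex, age, occupation) count
    reports; multi-valued blocks (outcomes, routes, indications) count code
    occurrences, with shares reported against the number of reports in both
    cases.  The report year comes from the receipt date (FDA_DT) of the kept
    case version, since event dates are frequently missing.
    """
    cfg = config or DescriptiveConfig()
    prof = DescriptiveProfile(n_reports=len(cases))
    annual: dict[str, int] = {}
    country: dict[str, int] = {}
    sex: dict[str, int] = {}
    ages: dict[str, int] = {}
    occp: dict[str, int] = {}
    outc: dict[str, int] = {}
    indi: dict[str, int] = {}
    route: dict[str, int] = {}
    onset_counts = {_onset_label(b): 0 for b in cfg.onset_bins}
    onset_values: list[int] = []
    negative_flagged = 0

    edges = list(cfg.age_bin_edges)
    age_labels = [f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]

    for case in cases:
        demo = case.demo
        fda = parse_partial_date(demo.fda_dt)
        annual[str(fda.year) if fda else UNKNOWN] = \
            annual.get(str(fda.year) if fda else UNKNOWN, 0) + 1
        ctry = demo.reporter_country.strip().upper() if demo.reporter_country else UNKNOWN
        country[ctry] = country.get(ctry, 0) + 1
        sx = demo.sex.strip().upper() if demo.sex else "UNK"
        if sx not in ("F", "M"):
            sx = "UNK"
        sex[sx] = sex.get(sx, 0) + 1
        age = normalize_age(demo.age, demo.age_cod)
        if age is None:
            ages[UNKNOWN] = ages.get(UNKNOWN, 0) + 1
        else:
            label = UNKNOWN
            for lo, hi, lab in zip(edges[:-1], edges[1:], age_labels):
                if lo <= age.value < hi or (hi == edges[-1] and age.value == hi):
                    label = lab
                    break
            ages[label] = ages.get(label, 0) + 1
        oc = demo.occp_cod.strip().upper() if demo.occp_cod else UNKNOWN
        occp[oc] = occp.get(oc, 0) + 1
        for rec in case.outcomes:
            code = rec.outc_cod.strip().upper()
            outc[code] = outc.get(code, 0) + 1
        for rec in case.indications:
            pt = norm_term(rec.indi_pt)
            indi[pt] = indi.get(pt, 0) + 1
        seqs = _ps_drug_seqs(case, drug)
        for rec in case.drugs:
            if rec.drug_seq in seqs and rec.route is not None:
                rt = norm_term(rec.route)
                route[rt] = route.get(rt, 0) + 1
        days = time_to_onset(case, drug)
        if days is None:
            event = parse_partial_date(demo.event_dt)
            starts = [parse_partial_date(t.start_dt) for t in case.therapies
                      if t.dsg_drug_seq in seqs]
            if (event is not None and event.is_full()
                    and any(s is not None and s.is_full() for s in starts)):
                negative_flagged += 1
        else:
            onset_values.append(days)
            for b in cfg.onset_bins:
                lo, hi = b
                if days >= lo and (hi is None or days <= hi):
                    onset_counts[_onset_label(b)] += 1
                    break

    n = prof.n_reports
    prof.annual_counts = dict(sorted(annual.items()))
    prof.country_counts = _share_block(country, n)
    prof.sex_counts = _share_block(sex, n)
    prof.age_bins = dict(sorted(ages.items()))
    prof.occupation_counts = dict(sorted(occp.items()))
    prof.outcome_counts = _share_block(outc, n)
    prof.indication_top = sorted(indi.items(), key=lambda kv: (-kv[1], kv[0]))[: cfg.top_k]
    prof.route_top = sorted(route.items(), key=lambda kv: (-kv[1], kv[0]))[: cfg.top_k]
    prof.onset_defined = len(onset_values)
    prof.onset_negative_flagged = negative_flagged
    cum = 0
    onset_block: dict[str, dict] = {}
    for b in cfg.onset_bins:
        label = _onset_label(b)
        cum += onset_counts[label]
        onset_block[label] = {
            "count": onset_counts[label],
            "cumulative_share": (cum / len(onset_values)) if onset_values else 0.0,
        }
    prof.onset_bins = onset_block
    return prof


def write_profile_tsvs(prof: DescriptiveProfile, out_dir: str | Path) -> None:
    """One TSV per block plus the combined JSON profile."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _write(name: str, header: list[str], rows: list[list]) -> None:
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        (out_dir / f"{name}.tsv").write_text("\n".join(lines) + "\n")

    _write("annual_counts", ["year", "count"],
           [[k, v] for k, v in prof.annual_counts.items()])
    _write("country_counts", ["country", "count", "share"],
           [[k, v["count"], f"{v['share']:.4f}"] for k, v in prof.country_counts.items()])
    _write("sex_counts", ["sex", "count", "share"],
           [[k, v["count"], f"{v['share']:.4f}"] for k, v in prof.sex_counts.items()])
    _write("age_bins", ["bin_years", "count"],
           [[k, v] for k, v in prof.age_bins.items()])
    _write("occupation_counts", ["occupation", "count"],
           [[k, v] for k, v in prof.occupation_counts.items()])
    _write("outcome_counts", ["outcome", "count", "share"],
           [[k, v["count"], f"{v['share']:.4f}"] for k, v in prof.outcome_counts.items()])
    _write("indication_top", ["indication", "count"],
           [[k, v] for k, v in prof.indication_top])
    _write("route_top", ["route", "count"],
           [[k, v] for k, v in prof.route_top])
    _write("onset_bins", ["days", "count", "cumulative_share"],
           [[k, v["count"], f"{v['cumulative_share']:.4f}"]
            for k, v in prof.onset_bins.items()])
    prof.to_json(out_dir / "profile.json")
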