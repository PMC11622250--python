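"""Synthetic FAERS-style report generator with a known ground truth.

The generator emits the same multi-table case structure as the real
quarterly archives — DEMO/DRUG/REAC/OUTC/RPSR/THER/INDI rows keyed by
PRIMARYID/CASEID, case-version duplicates distinguished by FDA_DT, role-coded
drug entries, multi-PT reaction lists, partial dates — driven by a compact
configuration with per-(drug, PT) reporting-rate multipliers that define
which pairs are true signals.

Sampling model: each report has one primary-suspect drug D drawn from a
categorical distribution; every preferred term pt in the vocabulary then
enters the report independently with probability min(1, rho[D,pt] * p[pt]),
where p[pt] is the PT's baseline occurrence probability and rho defaults
to 1 (no signal).  A report that draws no PT is given one, sampled
proportionally to its inclusion probabilities.  The per-report PT count is
therefore Poisson-binomial with mean ~ sum(p), calibrated to about 5.3
distinct terms per report, the ratio of pair count to report count typical
of a single-drug extraction.  Expected fourfold tables under this model are
available in closed form for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from faersig.faers_io import (
    DemoRecord,
    DrugRecord,
    IndiRecord,
    OutcRecord,
    QuarterData,
    ReacRecord,
    RpsrRecord,
    TherRecord,
    write_table,
)

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class DrugSpec:
    name: str
    share: float  # probability of being the report's primary-suspect drug
    synonyms: dict[str, float] = field(default_factory=dict)  # spelling -> weight

    def spellings(self) -> tuple[list[str], list[float]]:
        if not self.synonyms:
            return [self.name], [1.0]
        names = list(self.synonyms)
        w = np.array([self.synonyms[s] for s in names], dtype=float)
        return names, list(w / w.sum())


@dataclass
class PtSpec:
    name: str
    soc: str
    base_prob: float  # baseline per-report occurrence probability


@dataclass
class Demographics:
    sex_probs: dict[str, float] = field(default_factory=lambda: {
        "F": 0.6025, "M": 0.3377, "": 0.0598})
    country_probs: dict[str, float] = field(default_factory=lambda: {
        "US": 0.5979, "CA": 0.1055, "IT": 0.0538, "DE": 0.0373,
        "GB": 0.0326, "FR": 0.0900, "JP": 0.0829})
    occp_probs: dict[str, float] = field(default_factory=lambda: {
        "CN": 0.3007, "MD": 0.2782, "PH": 0.1819, "OT": 0.1575, "HP": 0.0817})
    # outcomes are drawn independently per code: a report can carry several
    outcome_probs: dict[str, float] = field(default_factory=lambda: {
        "HO": 0.3845, "DE": 0.1240, "LT": 0.0583, "OT": 0.2500,
        "DS": 0.0300, "RI": 0.0200, "CA": 0.0050})
    route_probs: dict[str, float] = field(default_factory=lambda: {
        "ORAL": 0.8748, "INTRAVENOUS": 0.0600, "INTRAMUSCULAR": 0.0300,
        "UNKNOWN": 0.0352})
    rpsr_probs: dict[str, float] = field(default_factory=lambda: {
        "HP": 0.4, "CSM": 0.3, "FGN": 0.2, "LIT": 0.1})
    indication_probs: dict[str, float] = field(default_factory=lambda: {
        "anxiety": 0.5, "insomnia": 0.2, "agitation": 0.1,
        "product used for unknown indication": 0.2})
    age_mean: float = 55.0
    age_sd: float = 20.0
    age_missing_rate: float = 0.08


@dataclass
class SimConfig:
    seed: int = 0
    n_reports: int = 50_000  # unique cases; duplicates are emitted on top
    quarters: list[tuple[int, int]] = field(
        default_factory=lambda: [(2022, 1), (2022, 2), (2022, 3), (2022, 4)])
    drugs: list[DrugSpec] = field(default_factory=list)
    pts: list[PtSpec] = field(default_factory=list)
    signal_spec: dict[tuple[str, str], float] = field(default_factory=dict)
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.05
    concomitant_rate: float = 0.30
    onset_lag_mean_days: float = 40.0
    reporting_delay_max_days: int = 60
    demographics: Demographics = field(default_factory=Demographics)

    def drug_names(self) -> list[str]:
        return [d.name for d in self.drugs]

    def pt_names(self) -> list[str]:
        return [p.name for p in self.pts]

    def rate_matrix(self) -> np.ndarray:
        """Per-(drug, PT) inclusion probabilities min(1, rho * base_prob)."""
        p = np.array([pt.base_prob for pt in self.pts], dtype=float)
        q = np.tile(p, (len(self.drugs), 1))
        d_index = {d.name: i for i, d in enumerate(self.drugs)}
        pt_index = {pt.name: j for j, pt in enumerate(self.pts)}
        for (drug, pt), rho in self.signal_spec.items():
            q[d_index[drug], pt_index[pt]] = min(1.0, rho * p[pt_index[pt]])
        return q

    @property
    def mean_pts_per_report(self) -> float:
        shares = np.array([d.share for d in self.drugs], dtype=float)
        return float(shares @ self.rate_matrix().sum(axis=1))


def validate(config: SimConfig) -> None:
    """Reject infeasible configurations before any sampling happens."""
    if config.n_reports < 1:
        raise ValueError("n_reports must be >= 1")
    if not config.drugs or not config.pts:
        raise ValueError("drug and PT vocabularies must be non-empty")
    if not config.quarters:
        raise ValueError("at least one quarter is required")
    shares = np.array([d.share for d in config.drugs], dtype=float)
    if (shares < 0).any() or abs(shares.sum() - 1.0) > 1e-6:
        raise ValueError("drug shares must be non-negative and sum to 1")
    for pt in config.pts:
        if not 0.0 <= pt.base_prob <= 1.0:
            raise ValueError(f"base probability out of [0,1] for PT {pt.name!r}")
    names = set(config.drug_names())
    pt_names = set(config.pt_names())
    for (drug, pt), rho in config.signal_spec.items():
        if rho < 0:
            raise ValueError(f"rate multiplier must be >= 0 for {(drug, pt)}")
        if drug not in names or pt not in pt_names:
            raise ValueError(f"signal pair {(drug, pt)} not in the vocabularies")
    if not 0.0 <= config.duplicate_rate < 1.0:
        raise ValueError("duplicate_rate must be in [0, 1)")
    if config.mean_pts_per_report > len(config.pts):
        raise ValueError("mean PTs per report exceeds the vocabulary size")
    if config.mean_pts_per_report <= 0:
        raise ValueError("mean PTs per report must be positive")


# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------

# (pt, soc, raw weight); weights are rescaled so the mean number of distinct
# PTs per report is ~5.3, the pair-to-report ratio of a typical single-drug
# extraction.  SOC names follow the MedDRA System Organ Classes.
_DEFAULT_PTS: list[tuple[str, str, float]] = [
    ("sopor", "psychiatric disorders", 0.080),
    ("drug abuse", "psychiatric disorders", 0.200),
    ("suicide attempt", "psychiatric disorders", 0.150),
    ("delirium", "psychiatric disorders", 0.120),
    ("psychotic disorder", "psychiatric disorders", 0.100),
    ("insomnia", "psychiatric disorders", 0.250),
    ("anxiety", "psychiatric disorders", 0.220),
    ("hallucination", "psychiatric disorders", 0.060),
    ("catatonia", "psychiatric disorders", 0.020),
    ("bradyphrenia", "psychiatric disorders", 0.015),
    ("somnolence", "nervous system disorders", 0.280),
    ("sedation", "nervous system disorders", 0.100),
    ("dizziness", "nervous system disorders", 0.250),
    ("headache", "nervous system disorders", 0.300),
    ("seizure", "nervous system disorders", 0.080),
    ("tremor", "nervous system disorders", 0.120),
    ("neuroleptic malignant syndrome", "nervous system disorders", 0.020),
    ("serotonin syndrome", "nervous system disorders", 0.030),
    ("parkinsonism", "nervous system disorders", 0.015),
    ("fatigue", "general disorders and administration site conditions", 0.300),
    ("drug ineffective", "general disorders and administration site conditions", 0.350),
    ("death", "general disorders and administration site conditions", 0.120),
    ("malaise", "general disorders and administration site conditions", 0.180),
    ("gait disturbance", "general disorders and administration site conditions", 0.050),
    ("nausea", "gastrointestinal disorders", 0.300),
    ("vomiting", "gastrointestinal disorders", 0.200),
    ("diarrhoea", "gastrointestinal disorders", 0.180),
    ("constipation", "gastrointestinal disorders", 0.080),
    ("duodenal ulcer perforation", "gastrointestinal disorders", 0.005),
    ("sinus tachycardia", "cardiac disorders", 0.040),
    ("pericarditis", "cardiac disorders", 0.010),
    ("palpitations", "cardiac disorders", 0.070),
    ("bradycardia", "cardiac disorders", 0.030),
    ("pneumonia", "infections and infestations", 0.080),
    ("pneumonia aspiration", "infections and infestations", 0.020),
    ("urinary tract infection", "infections and infestations", 0.060),
    ("folliculitis", "infections and infestations", 0.008),
    ("blood pressure increased", "investigations", 0.100),
    ("weight decreased", "investigations", 0.090),
    ("heart rate increased", "investigations", 0.050),
    ("c-reactive protein abnormal", "investigations", 0.010),
    ("fall", "injury, poisoning and procedural complications", 0.150),
    ("muscle injury", "injury, poisoning and procedural complications", 0.010),
    ("overdose", "injury, poisoning and procedural complications", 0.080),
    ("decreased appetite", "metabolism and nutrition disorders", 0.100),
    ("obesity", "metabolism and nutrition disorders", 0.010),
    ("hypercholesterolaemia", "metabolism and nutrition disorders", 0.008),
    ("arthralgia", "musculoskeletal and connective tissue disorders", 0.140),
    ("muscle rigidity", "musculoskeletal and connective tissue disorders", 0.015),
    ("myalgia", "musculoskeletal and connective tissue disorders", 0.090),
    ("dyspnoea", "respiratory, thoracic and mediastinal disorders", 0.160),
    ("respiratory depression", "respiratory, thoracic and mediastinal disorders", 0.020),
    ("atelectasis", "respiratory, thoracic and mediastinal disorders", 0.008),
    ("cough", "respiratory, thoracic and mediastinal disorders", 0.120),
    ("rash", "skin and subcutaneous tissue disorders", 0.180),
    ("pruritus", "skin and subcutaneous tissue disorders", 0.100),
    ("pemphigus", "skin and subcutaneous tissue disorders", 0.004),
    ("acute kidney injury", "renal and urinary disorders", 0.050),
    ("hypotension", "vascular disorders", 0.090),
    ("deep vein thrombosis", "vascular disorders", 0.020),
]

_DEFAULT_DRUGS: list[tuple[str, float, dict[str, float]]] = [
    # the target drug's share mirrors a ~1% slice of the database
    ("lorazepam", 0.012, {"lorazepam": 0.5, "ATIVAN": 0.3,
                          "Lorazepam": 0.1, "LORAZEPAM  TABLETS": 0.1}),
    ("alprazolam", 0.150, {"alprazolam": 0.7, "XANAX": 0.3}),
    ("sertraline", 0.200, {"sertraline": 0.6, "ZOLOFT": 0.4}),
    ("metformin", 0.250, {"metformin": 0.8, "GLUCOPHAGE": 0.2}),
    ("atorvastatin", 0.200, {"atorvastatin": 0.7, "LIPITOR": 0.3}),
    ("omeprazole", 0.188, {"omeprazole": 0.8, "PRILOSEC": 0.2}),
]

DEFAULT_TARGET_DRUG = "lorazepam"
DEFAULT_PLANTED_PAIR = ("lorazepam", "sopor")


def default_config(seed: int = 0, n_reports: int = 50_000,
                   signal_spec: dict[tuple[str, str], float] | None = None,
                   mean_pts_per_report: float = 5.3) -> SimConfig:
    """The standard study conditions: one planted signal at rho = 5.

    The default plants a five-fold reporting-rate multiplier on the
    (lorazepam, sopor) pair; pass ``signal_spec={}`` for a pure-null
    configuration.
    """
    raw_total = sum(w for _, _, w in _DEFAULT_PTS)
    scale = mean_pts_per_report / raw_total
    pts = [PtSpec(name=n, soc=s, base_prob=w * scale) for n, s, w in _DEFAULT_PTS]
    drugs = [DrugSpec(name=n, share=s, synonyms=dict(syn))
             for n, s, syn in _DEFAULT_DRUGS]
    if signal_spec is None:
        signal_spec = {DEFAULT_PLANTED_PAIR: 5.0}
    cfg = SimConfig(seed=seed, n_reports=n_reports, drugs=drugs, pts=pts,
                    signal_spec=dict(signal_spec))
    validate(cfg)
    return cfg


def null_config(seed: int = 0, n_reports: int = 50_000) -> SimConfig:
    """Default conditions with every rate multiplier at 1 (no true signals)."""
    return default_config(seed=seed, n_reports=n_reports, signal_spec={})


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass
class ExpectedTable:
    """Closed-form expected fourfold counts (real-valued)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def expected_table(config: SimConfig, drug: str, pt: str) -> ExpectedTable:
    """Expected fourfold table for one pair under the sampling model.

    Pure mixture arithmetic: with q[D, pt] = min(1, rho * p) and drug shares
    s, E[a] = n * s_D * q[D, pt], E[a + b] = n * s_D * sum_pt q[D, .], and
    the other-drug column follows the same sums over D' != D.  The
    force-one-PT rule applied to empty draws is ignored here (it perturbs
    expectations by O(e^-mean)).
    """
    names = config.drug_names()
    pt_names = config.pt_names()
    if drug not in names:
        raise ValueError(f"unknown drug {drug!r}")
    if pt not in pt_names:
        raise ValueError(f"unknown PT {pt!r}")
    q = config.rate_matrix()
    shares = np.array([d.share for d in config.drugs], dtype=float)
    di = names.index(drug)
    pj = pt_names.index(pt)
    n = config.n_reports
    e_a = n * shares[di] * q[di, pj]
    e_ab = n * shares[di] * q[di].sum()
    e_c = n * float(np.delete(shares, di) @ np.delete(q[:, pj], di))
    e_n = n * float(shares @ q.sum(axis=1))
    return ExpectedTable(a=e_a, b=e_ab - e_a, c=e_c, d=e_n - e_ab - e_c)


@dataclass
class TruthTable:
    """Generator-side oracle: planted pairs and realized emission counts."""

    planted: dict[tuple[str, str], float]
    counts: pd.DataFrame  # columns drug, event, a — realized unique-case counts
    n_pairs: int  # total realized (report, PT) pairs over unique cases
    n_unique: int
    n_duplicates: int

    def count(self, drug: str, pt: str) -> int:
        m = (self.counts["drug"] == drug) & (self.counts["event"] == pt)
        sub = self.counts.loc[m, "a"]
        return int(sub.iloc[0]) if len(sub) else 0


@dataclass
class SimResult:
    data: QuarterData
    truth: TruthTable
    config: SimConfig
    files: dict[str, Path] | None = None
    quarter_of_case: list[int] | None = None


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _quarter_bounds(year: int, quarter: int) -> tuple[int, int]:
    start = date(year, 3 * (quarter - 1) + 1, 1)
    end_month = 3 * quarter
    if end_month == 12:
        end = date(year + 1, 1, 1)
    else:
        end = date(year, end_month + 1, 1)
    return start.toordinal(), (end - start).days


def _fmt(ordinal: int) -> str:
    d = date.fromordinal(ordinal)
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _choice_keys(rng: np.random.Generator, dist: dict[str, float], n: int) -> list[str]:
    keys = list(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return [keys[i] for i in idx]


def generate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Draw a full synthetic report set; optionally write quarterly files.

    Generation is a pure function of the configuration (which carries the
    seed): repeated calls produce identical records and identical bytes on
    disk.  The returned :class:`TruthTable` holds the realized per-(drug,
    PT) emission counts over unique cases, which the pipeline's contingency
    builder must reproduce exactly on the same data.
    """
    validate(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.drugs
    pts = config.pts
    n_drugs, n_pts = len(drugs), len(pts)
    shares = np.array([d.share for d in drugs], dtype=float)
    q = config.rate_matrix()

    drug_idx = rng.choice(n_drugs, size=n, p=shares)
    incl = rng.random((n, n_pts)) < q[drug_idx]
    empty = np.flatnonzero(incl.sum(axis=1) == 0)
    for i in empty:
        w = q[drug_idx[i]]
        incl[i, rng.choice(n_pts, p=w / w.sum())] = True

    # realized emission ledger (unique cases)
    counts_rows = []
    for di, spec in enumerate(drugs):
        col = incl[drug_idx == di].sum(axis=0)
        for pj, pt in enumerate(pts):
            if col[pj] > 0:
                counts_rows.append((spec.name, pt.name, int(col[pj])))
    counts = pd.DataFrame(counts_rows, columns=["drug", "event", "a"])

    # calendar scaffolding
    bounds = [_quarter_bounds(y, qq) for y, qq in config.quarters]
    q_idx = rng.integers(0, len(config.quarters), size=n)
    starts = np.array([bounds[i][0] for i in q_idx])
    lens = np.array([bounds[i][1] for i in q_idx])
    event_ord = starts + rng.integers(0, lens)
    fda_ord = event_ord + rng.integers(0, config.reporting_delay_max_days + 1, size=n)
    lag = np.floor(rng.exponential(config.onset_lag_mean_days, size=n)).astype(int)
    ther_ord = event_ord - lag
    partial_event = rng.random(n) < config.partial_date_rate

    # demographics
    dem = config.demographics
    sex = _choice_keys(rng, dem.sex_probs, n)
    country = _choice_keys(rng, dem.country_probs, n)
    occp = _choice_keys(rng, dem.occp_probs, n)
    route = _choice_keys(rng, dem.route_probs, n)
    rpsr = _choice_keys(rng, dem.rpsr_probs, n)
    indication = _choice_keys(rng, dem.indication_probs, n)
    age_years = np.clip(rng.normal(dem.age_mean, dem.age_sd, size=n), 0.0, 100.0)
    age_missing = rng.random(n) < dem.age_missing_rate
    age_unit = _choice_keys(rng, {"YR": 0.93, "MON": 0.05, "DEC": 0.02}, n)
    outcome_draws = {code: rng.random(n) < p for code, p in dem.outcome_probs.items()}
    conc_mask = rng.random(n) < config.concomitant_rate
    conc_drug = rng.integers(0, n_drugs, size=n)
    spelling_pick = rng.random(n)

    dup_count = int(round(config.duplicate_rate * n))
    dup_set = set(rng.choice(n, size=dup_count, replace=False)) if dup_count else set()
    dup_back = rng.integers(1, 90, size=n)  # how far the stale version lags

    spell_cache = {di: drugs[di].spellings() for di in range(n_drugs)}

    data = QuarterData()
    quarter_of_case: list[int] = []

    def emit(i: int, primaryid: str, caseid: str, fda: int) -> None:
        ev = _fmt(event_ord[i])
        if partial_event[i]:
            ev = ev[:6]
        if age_missing[i]:
            age_val, age_cod = None, None
        elif age_unit[i] == "MON":
            age_val, age_cod = float(round(age_years[i] * 12)), "MON"
        elif age_unit[i] == "DEC":
            age_val, age_cod = round(age_years[i] / 10.0, 1), "DEC"
        else:
            age_val, age_cod = float(round(age_years[i])), "YR"
        data.demo.append(DemoRecord(
            primaryid=primaryid, caseid=caseid,
            case_version=int(primaryid[-1]), fda_dt=_fmt(fda), event_dt=ev,
            age=age_val, age_cod=age_cod,
            sex=sex[i] or None, reporter_country=country[i], occp_cod=occp[i]))
        names, weights = spell_cache[drug_idx[i]]
        cum = np.cumsum(weights)
        spelled = names[int(np.searchsorted(cum, spelling_pick[i] * cum[-1]))]
        data.drug.append(DrugRecord(primaryid=primaryid, drug_seq=1,
                                    role_cod="PS", drugname=spelled,
                                    route=route[i]))
        if conc_mask[i] and conc_drug[i] != drug_idx[i]:
            data.drug.append(DrugRecord(primaryid=primaryid, drug_seq=2,
                                        role_cod="C",
                                        drugname=drugs[conc_drug[i]].name))
        for pj in np.flatnonzero(incl[i]):
            data.reac.append(ReacRecord(primaryid=primaryid, pt=pts[pj].name))
        for code, mask in outcome_draws.items():
            if mask[i]:
                data.outc.append(OutcRecord(primaryid=primaryid, outc_cod=code))
        data.rpsr.append(RpsrRecord(primaryid=primaryid, rpsr_cod=rpsr[i]))
        data.ther.append(TherRecord(primaryid=primaryid, dsg_drug_seq=1,
                                    start_dt=_fmt(ther_ord[i])))
        data.indi.append(IndiRecord(primaryid=primaryid, indi_drug_seq=1,
                                    indi_pt=indication[i]))

    base = 10_000_000
    for i in range(n):
        caseid = str(base + i)
        if i in dup_set:
            # stale earlier version first, then the current one
            emit(i, caseid + "1", caseid, int(fda_ord[i]) - int(dup_back[i]))
            emit(i, caseid + "2", caseid, int(fda_ord[i]))
            quarter_of_case.append(int(q_idx[i]))
            quarter_of_case.append(int(q_idx[i]))
        else:
            emit(i, caseid + "1", caseid, int(fda_ord[i]))
            quarter_of_case.append(int(q_idx[i]))

    truth = TruthTable(
        planted={pair: rho for pair, rho in config.signal_spec.items() if rho != 1.0},
        counts=counts,
        n_pairs=int(incl.sum()),
        n_unique=n,
        n_duplicates=dup_count,
    )
    result = SimResult(data=data, truth=truth, config=config,
                       quarter_of_case=quarter_of_case)
    if out_dir is not None:
        result.files = write_quarter_files(result, out_dir)
    return result


def write_quarter_files(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the generated records as quarterly ASCII files (DEMO22Q1.txt ...)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = result.config
    data = result.data
    # quarter per DEMO row, then per satellite row via its primaryid
    demo_quarter = dict(zip((r.primaryid for r in data.demo), result.quarter_of_case))
    files: dict[str, Path] = {}
    tables = {
        "DEMO": data.demo, "DRUG": data.drug, "REAC": data.reac,
        "OUTC": data.outc, "RPSR": data.rpsr, "THER": data.ther,
        "INDI": data.indi,
    }
    for qi, (year, qq) in enumerate(config.quarters):
        tag = f"{year % 100:02d}Q{qq}"
        for table, records in tables.items():
            subset = [r for r in records if demo_quarter[r.primaryid] == qi]
            path = out_dir / f"{table}{tag}.txt"
            write_table(table, subset, path)
            files[f"{table}{tag}"] = path
    return files


def synonym_map(config: SimConfig):
    """In-memory drug synonym dictionary matching the config's spellings."""
    from faersig.harmonize import DrugSynonymMap

    entries = {}
    for d in config.drugs:
        for spelling in (d.synonyms or {d.name: 1.0}):
            entries[spelling] = d.name
    return DrugSynonymMap(entries=entries)


def term_map(config: SimConfig):
    """In-memory PT->SOC map matching the config's vocabulary."""
    from faersig.harmonize import TermMap

    return TermMap(entries={pt.name: pt.soc for pt in config.pts})


def write_maps(config: SimConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the synonym dictionary and PT->SOC map matching the config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    syn_path = out_dir / "drug_synonyms.tsv"
    lines = ["# raw\tcanonical"]
    for d in config.drugs:
        for spelling in (d.synonyms or {d.name: 1.0}):
            lines.append(f"{spelling}\t{d.name}")
    syn_path.write_text("\n".join(lines) + "\n")
    soc_path = out_dir / "pt_soc.tsv"
    lines = ["# pt\tsoc"]
    for pt in config.pts:
        lines.append(f"{pt.name}\t{pt.soc}")
    soc_path.write_text("\n".join(lines) + "\n")
    return syn_path, soc_path
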