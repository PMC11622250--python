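"""Disproportionality statistics over drug-event 2x2 contingency tables.

For one drug D and one event E (a MedDRA preferred term, or a System Organ
Class after collapsing PTs), the database of report-event pairs is split
into the classic fourfold table

    a = pairs where the report's primary-suspect drug is D and the event is E
    b = D pairs with any other event
    c = other-drug pairs with event E
    d = everything else,      N = a + b + c + d.

Four statistics are computed on that table, each with the positivity
threshold conventional in pharmacovigilance:

* ROR  = ad / bc, 95% CI on the log scale; positive when the lower bound
  exceeds 1 and a >= 3.
* PRR  = [a/(a+b)] / [c/(c+d)] with the uncorrected Pearson chi-square;
  positive when PRR >= 2, chi2 >= 4 and a >= 3.
* IC   = log2( aN / ((a+b)(a+c)) ), the information component of the BCPNN
  family; positive when IC025 (IC minus two standard errors) exceeds 0.
* EBGM = aN / ((a+c)(a+b)), the observed-to-expected relative reporting
  ratio on the natural scale; positive when EBGM05 exceeds 2.

The quantities here are the unshrunk relative-reporting ratios: EBGM is
exactly 2**IC and no gamma-Poisson (MGPS) or Bayesian-posterior shrinkage is
applied.  All confidence bounds are delta-method intervals with standard
error sqrt(1/a + 1/b + 1/c + 1/d) on the log scale (for PRR, the standard
sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from faersig.faers_io import CaseReport
from faersig.harmonize import TermMap, norm_term

Z95 = 1.96
LN2 = math.log(2.0)

MIN_CASE_COUNT = 3  # reported-frequency screen applied before any rule fires


@dataclass(frozen=True)
class TwoByTwo:
    """Fourfold table for one drug-event pair at PT or SOC level."""

    a: int
    b: int
    c: int
    d: int
    drug_name: str = ""
    event_name: str = ""
    level: str = "PT"

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty dataset: N = a+b+c+d must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalStats:
    """All four statistics, with interval bounds, for one fourfold table."""

    ror: float | None = None
    ror_low: float | None = None
    ror_high: float | None = None
    prr: float | None = None
    prr_low: float | None = None
    prr_high: float | None = None
    chi2: float | None = None
    ic: float | None = None
    ic025: float | None = None
    ebgm: float | None = None
    ebgm05: float | None = None
    ebgm95: float | None = None
    n_reported: int = 0
    zero_cell_corrected: bool = False
    reason: str | None = None  # set when the statistics are undefined


@dataclass
class SignalDecision:
    ror_positive: bool = False
    prr_positive: bool = False
    bcpnn_positive: bool = False
    ebgm_positive: bool = False
    reason: str | None = None

    @property
    def all_four(self) -> bool:
        return (self.ror_positive and self.prr_positive
                and self.bcpnn_positive and self.ebgm_positive)


# --------------------------------------------------------------------------
# Statistic formulas (elementwise; accept scalars or numpy arrays)
# --------------------------------------------------------------------------


def compute_ror(a, b, c, d):
    """Reporting odds ratio with its 95% log-scale confidence interval."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    ror = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * np.exp(-Z95 * se), ror * np.exp(Z95 * se)


def compute_prr_chi2(a, b, c, d):
    """Proportional reporting ratio, its 95% CI, and uncorrected chi-square."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, prr * np.exp(-Z95 * se), prr * np.exp(Z95 * se), chi2


def compute_ic(a, b, c, d):
    """Information component (log2 observed/expected) and its lower bound.

    IC025 = IC - 2 * SE with SE = sqrt(1/a + 1/b + 1/c + 1/d) / ln 2, the
    delta-method standard error transferred to the log2 scale.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    ic = np.log2(a * n / ((a + b) * (a + c)))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d) / LN2
    return ic, ic - 2.0 * se


def compute_ebgm(a, b, c, d):
    """Relative reporting ratio aN/((a+c)(a+b)) with 95% log-scale CI."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, ebgm * np.exp(-Z95 * se), ebgm * np.exp(Z95 * se)


def compute_stats(table: TwoByTwo, zero_cell_correction: bool = True) -> SignalStats:
    """All four statistics for one table, applying the zero-cell policy.

    Tables with a = 0 never reach analysis (the frequency screen removes
    them) and come back undefined with a reason code.  When b, c or d is 0,
    0.5 is added to every cell of that table only (Haldane-Anscombe) so the
    intervals stay finite; the result is flagged ``zero_cell_corrected``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0:
        return SignalStats(n_reported=0, reason="zero_observed_count")
    corrected = False
    if min(b, c, d) == 0:
        if not zero_cell_correction:
            return SignalStats(n_reported=a, reason="zero_cell_uncorrected")
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        corrected = True
    ror, ror_low, ror_high = compute_ror(a, b, c, d)
    prr, prr_low, prr_high, chi2 = compute_prr_chi2(a, b, c, d)
    ic, ic025 = compute_ic(a, b, c, d)
    ebgm, ebgm05, ebgm95 = compute_ebgm(a, b, c, d)
    return SignalStats(
        ror=float(ror), ror_low=float(ror_low), ror_high=float(ror_high),
        prr=float(prr), prr_low=float(prr_low), prr_high=float(prr_high),
        chi2=float(chi2), ic=float(ic), ic025=float(ic025),
        ebgm=float(ebgm), ebgm05=float(ebgm05), ebgm95=float(ebgm95),
        n_reported=table.a, zero_cell_corrected=corrected,
    )


def classify_signal(stats: SignalStats) -> SignalDecision:
    """Apply the four positivity rules and their conjunction.

    Every rule requires at least 3 reported cases (the reported-frequency
    screen), so no flag can fire on a rarer pair.  Undefined statistics
    yield an all-false decision carrying the reason code.
    """
    if stats.reason is not None:
        return SignalDecision(reason=stats.reason)
    enough = stats.n_reported >= MIN_CASE_COUNT
    return SignalDecision(
        ror_positive=bool(enough and stats.ror_low > 1.0),
        prr_positive=bool(enough and stats.prr >= 2.0 and stats.chi2 >= 4.0),
        bcpnn_positive=bool(enough and stats.ic025 > 0.0),
        ebgm_positive=bool(enough and stats.ebgm05 > 2.0),
    )


# --------------------------------------------------------------------------
# Pair tables and contingency construction
# --------------------------------------------------------------------------


def pairs_from_cases(cases: Iterable[CaseReport]) -> pd.DataFrame:
    """Unique (report, PS drug, event) pairs from deduplicated cases.

    Each report contributes one pair per *distinct* preferred term; a PT
    repeated within one report counts once.  Reports without a
    primary-suspect drug entry are skipped (they cannot be attributed).
    The drug name is the harmonized canonical name when available.
    """
    rows = []
    for case in cases:
        drug = None
        for rec in case.drugs:
            if rec.role_cod is not None and rec.role_cod.upper() == "PS":
                name = rec.canonical if rec.canonical is not None else rec.drugname
                if name is not None:
                    drug = norm_term(name)
                    break
        if drug is None:
            continue
        seen: set[str] = set()
        for reac in case.reactions:
            pt = norm_term(reac.pt)
            if pt and pt not in seen:
                seen.add(pt)
                rows.append((case.primaryid, drug, pt))
    return pd.DataFrame(rows, columns=["report", "drug", "event"])


def soc_pairs(pairs: pd.DataFrame, term_map: TermMap) -> pd.DataFrame:
    """Collapse PT-level pairs to SOC level (one pair per report per SOC).

    PTs absent from the map are excluded from SOC tabulation; their count
    accumulates on ``term_map.unmapped_count``.
    """
    socs = pairs["event"].map(term_map.entries)
    unmapped = socs.isna()
    term_map.unmapped_count += int(unmapped.sum())
    out = pairs.loc[~unmapped, ["report", "drug"]].copy()
    out["event"] = socs[~unmapped]
    return out.drop_duplicates(["report", "event"], ignore_index=True)


def build_table(pairs: pd.DataFrame, drug: str, event: str, level: str = "PT") -> TwoByTwo:
    """Fourfold table for one drug-event pair from the full pair table.

    ``pairs`` must hold unique (report, event) rows at the chosen level;
    duplicates are dropped defensively so a repeated PT cannot double-count.
    """
    if len(pairs) == 0:
        raise ValueError("empty dataset: no report-event pairs")
    pairs = pairs.drop_duplicates(["report", "event"])
    drug = norm_term(drug)
    event = norm_term(event)
    is_drug = pairs["drug"] == drug
    is_event = pairs["event"] == event
    a = int((is_drug & is_event).sum())
    b = int((is_drug & ~is_event).sum())
    c = int((~is_drug & is_event).sum())
    d = int(len(pairs) - a - b - c)
    return TwoByTwo(a=a, b=b, c=c, d=d, drug_name=drug, event_name=event, level=level)


def screen_pts(pairs: pd.DataFrame, drug: str, min_count: int = MIN_CASE_COUNT) -> pd.DataFrame:
    """Events reported at least ``min_count`` times for the target drug.

    Returns a frame with columns ``event`` and ``a`` (the drug's pair count
    for that event), sorted by descending count then event name.
    """
    drug = norm_term(drug)
    sub = pairs.loc[pairs["drug"] == drug].drop_duplicates(["report", "event"])
    counts = sub.groupby("event").size().rename("a").reset_index()
    counts = counts.loc[counts["a"] >= min_count]
    return counts.sort_values(["a", "event"], ascending=[False, True],
                              ignore_index=True)


def signal_table(pairs: pd.DataFrame, drug: str, level: str = "PT",
                 min_count: int = MIN_CASE_COUNT,
                 zero_cell_correction: bool = True,
                 term_map: TermMap | None = None) -> pd.DataFrame:
    """Per-event statistics and decisions for every screened event.

    Vectorized equivalent of calling :func:`build_table` /
    :func:`compute_stats` / :func:`classify_signal` event by event over all
    events passing the frequency screen.  When ``term_map`` is given, a
    ``soc`` column annotates each PT.
    """
    pairs = pairs.drop_duplicates(["report", "event"])
    if len(pairs) == 0:
        raise ValueError("empty dataset: no report-event pairs")
    drug = norm_term(drug)
    n_total = len(pairs)
    is_drug = pairs["drug"] == drug
    drug_total = int(is_drug.sum())
    event_totals = pairs.groupby("event").size()
    a_counts = pairs.loc[is_drug].groupby("event").size()
    a_counts = a_counts.loc[a_counts >= min_count]
    events = a_counts.index.to_numpy()
    a = a_counts.to_numpy(dtype=float)
    b = drug_total - a
    c = event_totals.loc[events].to_numpy(dtype=float) - a
    d = n_total - a - b - c

    corrected = np.minimum(np.minimum(b, c), d) == 0
    half = np.where(corrected, 0.5, 0.0)
    aa, bb, cc, dd = a + half, b + half, c + half, d + half

    ror, ror_low, ror_high = compute_ror(aa, bb, cc, dd)
    prr, prr_low, prr_high, chi2 = compute_prr_chi2(aa, bb, cc, dd)
    ic, ic025 = compute_ic(aa, bb, cc, dd)
    ebgm, ebgm05, ebgm95 = compute_ebgm(aa, bb, cc, dd)

    if not zero_cell_correction:
        undefined = corrected.copy()
        for col in (ror, ror_low, ror_high, prr, prr_low, prr_high,
                    chi2, ic, ic025, ebgm, ebgm05, ebgm95):
            col[undefined] = np.nan
    else:
        undefined = np.zeros_like(corrected)

    enough = a >= MIN_CASE_COUNT
    ror_pos = enough & (ror_low > 1.0) & ~undefined
    prr_pos = enough & (prr >= 2.0) & (chi2 >= 4.0) & ~undefined
    bcpnn_pos = enough & (ic025 > 0.0) & ~undefined
    ebgm_pos = enough & (ebgm05 > 2.0) & ~undefined

    out = pd.DataFrame({
        "event": events,
        "level": level,
        "a": a.astype(int),
        "b": b.astype(int),
        "c": c.astype(int),
        "d": d.astype(int),
        "ror": ror, "ror_low": ror_low, "ror_high": ror_high,
        "prr": prr, "prr_low": prr_low, "prr_high": prr_high,
        "chi2": chi2,
        "ic": ic, "ic025": ic025,
        "ebgm": ebgm, "ebgm05": ebgm05, "ebgm95": ebgm95,
        "zero_cell_corrected": corrected,
        "ror_positive": ror_pos,
        "prr_positive": prr_pos,
        "bcpnn_positive": bcpnn_pos,
        "ebgm_positive": ebgm_pos,
    })
    out["all_four"] = ror_pos & prr_pos & bcpnn_pos & ebgm_pos
    if term_map is not None and level == "PT":
        out.insert(1, "soc", out["event"].map(term_map.entries))
    return out.sort_values(["a", "event"], ascending=[False, True],
                           ignore_index=True)


def rank_results(results: pd.DataFrame, by: str = "case_count",
                 top_k: int | None = None,
                 min_cases: int | None = None) -> pd.DataFrame:
    """Rank a signal table by case count or by EBGM.

    Stable descending sort with ties broken by event name ascending; an
    optional minimum-case filter (``a > min_cases``) mirrors reporting
    tables restricted to frequent events.
    """
    key = {"case_count": "a", "ebgm": "ebgm"}.get(by)
    if key is None:
        raise ValueError(f"unknown ranking key: {by!r}")
    out = results
    if min_cases is not None:
        out = out.loc[out["a"] > min_cases]
    out = out.sort_values([key, "event"], ascending=[False, True],
                          kind="mergesort", ignore_index=True)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out


def write_signal_table(results: pd.DataFrame, path, precision: int = 2) -> None:
    """Write a signal table as TSV, rounding statistics to ``precision``."""
    out = results.copy()
    float_cols = out.select_dtypes(include=[float]).columns
    out[float_cols] = out[float_cols].round(precision)
    out.to_csv(path, sep="\t", index=False)
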