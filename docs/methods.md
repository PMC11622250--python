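# Methods

## Problem and data model

Spontaneous-reporting databases such as FAERS collect voluntary adverse
event (AE) reports. Each case carries demographics (DEMO), one or more
drug entries with role codes (DRUG: PS = primary suspect, SS = secondary
suspect, C = concomitant, I = interacting), a list of MedDRA preferred
terms (REAC), outcomes (OUTC), report sources (RPSR), therapy dates (THER)
and indications (INDI), all keyed by PRIMARYID. The same case may be
resubmitted: versions share a CASEID and differ in FDA receipt date
(FDA_DT) and in the version digit embedded in PRIMARYID.

`faersig` analyzes one *target drug* at a time, restricted to reports
where that drug is the primary suspect, against the background of all
other reports in the same database.

### Counting unit

The analysis unit is the unique **(deduplicated report, event) pair**: a
PT repeated inside one report counts once, and `N` is the total pair count
over the database at the chosen level (PT, or SOC after collapsing each
report's PTs to distinct SOCs). This convention matches the ratio of
~5.35 event terms per primary-suspect report seen in large single-drug
extractions, and it is isolated inside `signal_engine.build_table` /
`pairs_from_cases` so an alternative report-level convention could be
substituted without touching the statistics.

## Deduplication

One record per CASEID is kept: the one with the latest FDA_DT. Within-group
ties are broken by the lexicographically greatest PRIMARYID, which embeds
the case version, so the rule is deterministic and version-monotone under
any input ordering. An unparseable FDA_DT sorts before any parseable date
(records with auditable dates are preferred) and increments a warning
counter when it occurs inside a duplicate group. The identity
`kept = raw − removed` is asserted on every run.

## Statistics

For a fourfold table `(a, b, c, d)` with `N = a+b+c+d`:

* `ROR = ad/bc`, 95% CI `exp(ln ROR ± 1.96·SE)`, `SE = √(1/a+1/b+1/c+1/d)`.
* `PRR = [a/(a+b)] / [c/(c+d)]`, 95% CI on the log scale with
  `SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d))` (the standard delta-method SE;
  the source formulas print the point estimate only).
* `χ² = (ad−bc)²·N / ((a+b)(c+d)(a+c)(b+d))` — the uncorrected Pearson
  statistic (no Yates continuity correction). The χ² ≥ 4 positivity cut
  corresponds to p < 0.05 at 1 df (critical value 3.84).
* `IC = log2(aN/((a+b)(a+c)))`; `IC025 = IC − 2·SE_IC` with
  `SE_IC = √(1/a+1/b+1/c+1/d)/ln 2`, i.e. the EBGM log-scale SE
  transferred to the log2 scale with the conventional multiplier 2.
* `EBGM = aN/((a+c)(a+b))` with the same log-scale 95% CI as ROR.

These are deliberately the **unshrunk** observed-to-expected quantities:
`EBGM = 2^IC` holds as an exact algebraic identity (asserted to 1e−12
relative error), and no MGPS gamma-Poisson shrinkage or BCPNN posterior is
applied. Consequences worth knowing: estimates for very small `a` are
noisier than shrunk versions, and the three ratio statistics obey a strict
ordering law — `sign(ad − bc)` determines `ROR ≷ PRR ≷ EBGM ≷ 1`
(each pairwise difference has the sign of `ad − bc`).

### Thresholds and screening

PTs with fewer than 3 reports for the target drug are screened out before
analysis. The four positivity rules are applied with the printed
strict/non-strict comparisons — ROR: a ≥ 3 and CI lower bound > 1; PRR:
PRR ≥ 2, χ² ≥ 4, a ≥ 3; BCPNN: IC025 > 0; EBGM: EBGM05 > 2 — and the
`a ≥ 3` screen gates all four, so no rule can fire on a rarer pair. The
`all_four` conjunction marks pairs flagged by every algorithm. No
multiple-testing adjustment is applied.

### Degenerate tables

`a = 0` tables are undefined (reason-coded; they cannot pass the screen
anyway). If `b`, `c` or `d` is 0, 0.5 is added to all four cells of that
table only (Haldane–Anscombe) so every interval stays finite; the row is
flagged `zero_cell_corrected`. With the correction disabled such tables
are reported as undefined rather than infinite.

## Synthetic-report generator

The generator is the test bed standing in for the real archive. Per
report: a primary-suspect drug `D` is drawn from a categorical share
vector; every PT enters the report independently with probability
`min(1, ρ[D, pt] · p[pt])`, where `p` is the baseline occurrence
probability and the rate multiplier `ρ` (default 1) plants true signals.
A report drawing no PT receives one sampled proportionally to its
inclusion probabilities (probability ~`e^−5.3` ≈ 0.005 of happening, a
negligible perturbation that the closed-form expectations ignore).

Default conditions, chosen once as a realistic single-drug study: a 60-PT
vocabulary over 14 SOCs with baselines scaled to **5.3 distinct PTs per
report**; target drug share **0.012** (a ~1% slice of the database, with
brand/case/spacing synonym spellings); five background drugs; duplicate
case-version rate **0.05**; partial-date rate 0.05; 30% concomitant
entries; therapy start preceding the event by an exponential lag of mean
**40 days**; demographic marginals (sex 60/34/6, country, occupation,
outcome, route) mirroring a large anxiolytic extraction. The default
planted signal is `(lorazepam, sopor)` at **ρ = 5** with baseline
probability ≈0.07.

`expected_table` gives the exact expected fourfold counts by mixture
arithmetic. Note that the expected EBGM of a planted pair is slightly
below ρ — with drug share `s` and planted inclusion probability `q`,
the drug's own pair margin `(a+b)` and the event margin `(a+c)` are both
inflated by the signal itself, giving ≈ ρ · (1 + (ρ−1)q/Σq)⁻¹ ·
(1 + s(ρ−1))⁻¹ ≈ 4.5 under the defaults. This is a property of
relative-reporting estimators in finite databases, shared with the real
analysis, and the recovery tests check against it.

What the generator does **not** emulate: drug co-prescription correlation
structure, free-text drug noise beyond the listed spellings, PT
co-occurrence syndromes, reporting-rate drift over calendar time, or
between-version content changes (duplicate versions differ only in
FDA_DT/PRIMARYID). Passing recovery tests therefore demonstrate correct
arithmetic and a working pipeline under a known mechanism, not robustness
to real-world reporting artefacts.

## Descriptive profile

Computed on deduplicated primary-suspect reports only. Report year comes
from FDA_DT of the kept version (event dates are frequently missing).
Single-valued blocks (year, country, sex, age decade bins 0–120 plus
unknown, occupation) count reports and sum to the report count;
multi-valued blocks (outcomes, routes, indications) count code
occurrences, with shares reported against reports in both cases.
Time-to-onset is `event_dt − earliest therapy start` among the target
drug's PS entries, defined only when both dates are day-resolved and the
difference is non-negative; onset bins `[0–30, 31–60, 61–80, 81–180,
181–360, >360]` make the cumulative share at 80 days directly readable.
Missing values always form their own category.

## Numerical and I/O choices

* Dates: YYYYMMDD/YYYYMM/YYYY parsed without imputation; impossible
  calendar values are undefined, not errors.
* Age: unit factors DEC×10, YR×1, MON×1/12, WK×1/52.1775, DY×1/365.25,
  HR×1/8766 (mean calendar lengths); ages above 120 years are implausible
  and become undefined; a missing unit is read as years and flagged.
* Files are read as UTF-8 with per-file latin-1 fallback (real archives
  mix encodings). Rows with the wrong field count are rejected and
  counted; a missing mandatory column is a hard error naming file and
  column.
* Ranking: stable descending sort, ties broken by event name ascending;
  output tables are rendered at 2 decimals by default.
* All sampling flows from one `numpy` Generator seeded from the run
  configuration; equal seeds give byte-identical outputs.

## Problem sizes used in the checks

The identity and ordering laws are checked over 10,000 random tables;
oracle equivalence of the contingency builder over 50 datasets of 60–140
reports against a nested-loop count; null behaviour and signal recovery
at 50,000 reports, the latter over 20 seeded replicates (the recovery
check asserts the median EBGM across replicates lies in [4, 6.25] and the
pair is flagged by all four rules in ≥95% of replicates). The acceptance
script repeats the recovery measurement with 5 replicates.

## Known limitations

* No probabilistic record linkage: deduplication is exactly the
  CASEID/latest-FDA_DT rule.
* No fuzzy drug-name matching; unmapped spellings pass through flagged.
* PT→SOC mapping is single-assignment (MedDRA multi-axiality collapsed to
  one primary SOC), and only the PT and SOC levels exist (no HLT/HLGT).
* Statistics are unshrunk; small-count rankings (e.g. top-EBGM tables)
  are noisier than MGPS/BCPNN-posterior equivalents and should be read
  with their confidence bounds.
* Disproportionality quantifies reporting, not risk: no causal reading.
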