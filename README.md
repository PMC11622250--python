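# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports.

Pharmacovigilance teams mine the FDA Adverse Event Reporting System
(FAERS) — tens of millions of voluntary case reports distributed as
quarterly `"$"`-delimited ASCII tables — to find drug–event pairs reported
more often than the rest of the database would predict. `faersig`
implements that workflow end to end as a tested Python library and CLI:

* **Ingestion** of the seven quarterly tables (DEMO, DRUG, REAC, OUTC,
  RPSR, THER, INDI) with strict row validation and a parse report.
* **Case deduplication**: one version per CASEID, keeping the latest
  FDA receipt date (FDA_DT).
* **Harmonization**: raw drug strings → canonical names via a synonym
  dictionary; MedDRA preferred terms (PTs) → System Organ Classes (SOCs)
  via a user-supplied two-column map; age-unit normalization.
* **Signal statistics** on the drug–event fourfold table
  (`a, b, c, d`; `N = a+b+c+d`):

  | statistic | formula | positive when |
  |---|---|---|
  | ROR | `ad/bc`, CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | lower CI > 1, a ≥ 3 |
  | PRR | `[a/(a+b)]/[c/(c+d)]`, Pearson `χ²` (uncorrected) | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
  | IC (BCPNN) | `log2(aN/((a+b)(a+c)))`, `IC025 = IC − 2·SE` | IC025 > 0 |
  | EBGM | `aN/((a+c)(a+b))`, CI on the log scale | EBGM05 > 2 |

  These are the unshrunk relative-reporting quantities (`EBGM ≡ 2^IC`
  exactly); no gamma-Poisson shrinkage is applied. A drug–event pair
  flagged by all four rules simultaneously is reported in the
  `all_four` column.
* **Descriptive profiling** of a drug's primary-suspect reports (year,
  country, sex, age, reporter, outcomes, indications, routes,
  time-to-onset).
* **A synthetic-FAERS generator** that emits schema-faithful quarterly
  files with case-version duplicates, drug-name synonyms, partial dates and
  per-(drug, PT) reporting-rate multipliers, plus the closed-form expected
  contingency tables — so every stage is testable without the multi-GB
  download or the licensed MedDRA dictionary.

## Worked example

```sh
faersig run-all --simulate 20000 --seed 2 --out-dir out
```

generates a 20,000-report archive (with a planted five-fold
reporting-rate signal on the pair *lorazepam → sopor*), runs every stage,
and logs per-stage counts:

```
"dedup":      {"raw": 21000, "kept": 20000, "removed": 1000}
"pairs":      {"total_pairs": 106119, "ps_reports": 252, "target_pairs": 1416}
"signals_pt": {"screened_pts": 52, "all_four": 1}
```

`out/signals_pt.tsv` then contains, for the planted pair:

```
event  a   ror   prr   chi2    ic    ic025  ebgm  ebgm05  all_four
sopor  90  5.36  5.08  279.95  2.27  1.95   4.82  3.87    True
```

Read: 90 deduplicated reports name lorazepam as primary suspect with
sopor; the pair is reported ~5× more often than the database baseline
(ROR 5.36, EBGM 4.82), every lower confidence bound clears its threshold,
and the pair — and only this pair — is flagged by all four algorithms,
matching the generator's ground truth. The same run writes SOC-level
tables, case-count and EBGM rankings, and the descriptive profile under
`out/`.

The same statistics are available programmatically:

```python
from faersig import TwoByTwo, compute_stats, classify_signal
s = compute_stats(TwoByTwo(a=10, b=90, c=100, d=9900))
s.ror, s.prr, s.chi2, s.ebgm      # 11.0, 10.0, 74.45, 9.18
classify_signal(s).all_four       # True
```

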