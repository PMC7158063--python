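# addrexp

Residential address-history cleaning and life-stage exposure assignment for
longitudinal cohort studies.

## The problem

Birth cohort studies usually assign environmental exposures (air pollution,
noise, area deprivation, ...) from the mother's residential address *at the
time of birth*. But people move: typically 6–30% of women change address
during pregnancy, so the birth address misrepresents where many members
actually lived during the first trimester or early infancy, and the
resulting exposure misclassification can bias effect estimates.

Cohorts rarely keep residence histories — but they do keep **contact
databases**: administrative systems that audit members' *current* addresses.
Those are messy by design: a new row is created every time anything changes
(including spelling corrections), start dates are database time stamps, end
dates are often missing or imputed, and some addresses cannot be geocoded.
`addrexp` turns such an extract into a contiguous one-location-per-day
residence history per member, builds pregnancy/infancy exposure windows,
assigns daily exposures from a modelled concentration surface, and
quantifies how much the birth-address convention misclassifies exposure.

## The method

**Life stages.** With DoB the date of birth and gestational age *w* in
completed weeks, the date of conception is DoC = DoB − 7*w* − 1 day, and the
closed daily windows are

| stage | start | end |
|---|---|---|
| P (pregnancy) | DoC | DoB |
| T1 | DoC | DoC + 92 d |
| T2 | DoC + 93 d | DoC + 183 d |
| T3 | DoC + 184 d | DoB − 1 d |
| EI (early infancy) | DoB | DoB + 6 months − 1 d |
| LI (late infancy) | DoB + 6 months | DoB + 12 months − 1 d |

For very premature births (7*w* < 185) T3 is empty: it is dropped and T2 is
truncated to end at DoB − 1 d, so T1…LI always tile [DoC, LI end] exactly.

**Cleaning** rests on *start-date primacy*: in an audit system start dates
are time stamps and therefore trusted; end dates are not. Missing starts are
imputed with DoC, missing ends with the configured current date; rows
sharing a start date are treated as corrections (newest wins); every gap or
overlap between successive periods is repaired by setting the earlier
period's end to the day before the successor's start. An address period
without a usable geocode is absorbed by the following valid period, provided
it overlaps no life stage by more than 25% of the stage's days; otherwise it
is retained and the stages it touches are marked unreliable.

**Exposure.** Each day of each life stage is joined to a daily concentration
surface (location × date, e.g. modelled PM₁₀ in µg/m³) under two methods —
the full mobility history, and the birth address applied to every day — and
aggregated per member × stage into mean, median and cumulative exposure.
The two methods are then compared per stage: difference range, 5th/95th
percentiles, R² and Spearman's ρ.

Because real contact databases are not public, `addrexp.simulate` generates
the whole study synthetically — ground-truth cohorts, audit-style corrupted
extracts, and exposure surfaces — with the corruption constructed so the
cleaning protocol provably recovers the truth (`strict_recoverable` mode).

## Worked example

```python
from addrexp import (SimulationConfig, simulate_study, members_from_frame,
                     clean_cohort, ExposureSurface, summarize_cohort,
                     compare_methods, mobility_summary)

config = SimulationConfig(n_members=500, seed=7)
study = simulate_study(config)

members = members_from_frame(study.truth.members_frame)
cleaning = clean_cohort(study.contact_records, members, config.current_date)
print("audit:", cleaning.audit.summary())

surface = ExposureSurface(study.surface)
summaries = summarize_cohort(cleaning.periods, study.truth.stages,
                             study.truth.members_frame, surface,
                             cleaning.reliability)
pregnancy = summaries[(summaries.method == "mobility") & (summaries.stage_name == "P")]
print(f"pregnancy mean exposure: {pregnancy['mean'].mean():.1f} "
      f"ug/m3 (SD {pregnancy['mean'].std():.1f})")

mobility = mobility_summary(cleaning.histories, study.truth.stages)
print(f"moved during pregnancy: {mobility['pct_moved_pregnancy']:.1f}%  "
      f"infancy: {mobility['pct_moved_infancy']:.1f}%")

comparison = compare_methods(summaries)
print(comparison.by_stage[["stage_name", "n_pairs", "min_difference",
                           "max_difference", "r_squared", "spearman_rho"]]
      .round(3).to_string(index=False))
```

which prints

```
audit: {'n_records_in': 756, 'n_periods_out': 625, 'n_dropped': 131, 'n_subsumed': 15,
        'n_with_any_date_changed': 414, 'n_with_more_than_one_date_changed': 36}
pregnancy mean exposure: 31.5 ug/m3 (SD 3.1)
moved during pregnancy: 7.8%  infancy: 15.6%
stage_name  n_pairs  min_difference  max_difference  r_squared  spearman_rho
        EI      500          -4.921           8.854      0.964         0.982
        LI      500          -8.092           8.669      0.883         0.935
         P      500          -6.839           6.534      0.951         0.969
        T1      500          -8.477           8.126      0.947         0.973
        T2      500          -8.842           7.022      0.947         0.972
        T3      500          -4.060           4.469      0.992         0.995
```

Reading this: cleaning turned 756 audit rows into 625 contiguous address
periods (changing at least one date on 414 of them); the synthetic cohort's
pregnancy-average exposure is 31.5 µg/m³; and using the birth address alone
instead of the mobility history shifts individual stage means by up to
≈ ±9 µg/m³ even though the two methods correlate strongly (R² 0.88–0.99) —
exactly the kind of individual-level misclassification the tool is built to
expose.

The same pipeline runs from the shell:

```bash
addrexp simulate --n-members 500 --seed 7 --out-dir study/
addrexp run-all --members study/members.csv --contact-records study/contact_records.csv \
        --surface study/surface.csv --out-dir out/ --current-date 1994-12-31
```

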