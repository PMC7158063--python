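# Methods

This note documents the models, rules and numerical choices behind
`addrexp`, in the order the pipeline runs them.

## Life-stage calendar

All windows are **closed daily intervals** — both endpoints are occupied
days. This is forced by the "−1 day" end-date constructions of the stage
formulas, which only make sense with inclusive ends. Conception is dated
DoC = DoB − 7·weeks − 1 day from the gestational age at birth in *completed*
weeks; fractional weeks are rejected rather than rounded, since the formula
is defined on integers and silent rounding would move every prenatal window
by up to three days.

Stage boundaries use fixed day offsets for the trimesters (92/93/183/184
days from DoC, last prenatal day DoB − 1) and **calendar-month arithmetic**
for infancy ("DoB + 6 months"), clamping the day-of-month to the target
month's last day (31 Aug + 6 months → 28/29 Feb). Fixed 182/183-day infancy
windows would have been equally defensible; calendar months were chosen
because they match administrative follow-up practice, and the boundary
helpers are isolated in `lifestages` so alternative definitions can be
swapped in.

Two deliberate asymmetries are preserved literally rather than "fixed":

* the pregnancy stage P runs [DoC, DoB] *inclusive of the delivery day*,
  while no trimester contains DoB (T3 ends at DoB − 1). The day of birth
  therefore belongs to P and EI but to no trimester.
* for births premature enough that 7·weeks < 185, T3 is empty: it is
  dropped and T2 is truncated to DoB − 1, keeping T1…LI an exact partition
  of [DoC, LI end]. Gestations below 14 weeks would leave T2 itself empty;
  such members are rejected with an explicit reason rather than given
  degenerate windows. Gestations outside 20–44 weeks draw a warning.

Pregnancy aggregates are computed over P by default; the trimester union
[DoC, DoB − 1] differs from it by exactly the delivery day and can be
recovered from the per-trimester summaries.

## Cleaning protocol

The single governing assumption is **start-date primacy**: in an audit
database a start date is a creation time stamp, an end date is usually
derived, so every conflict is resolved by adjusting end dates. Concretely:

1. **Imputation.** Missing start → DoC; missing end → the configured
   `current_date`. `current_date` is a mandatory parameter, never the wall
   clock, so runs are reproducible. A row with no location and no dates is
   dropped as empty.
2. **Ordering.** Sort by (start date, record sequence). Rows sharing an
   identical start date are correction chains: only the highest sequence
   (newest entry) survives, whatever the older rows' locations said. The
   database never records which field a correction targeted, so the newest
   full row is taken as authoritative.
3. **Contiguity.** For each consecutive pair, the earlier period's end is
   set to the day before the successor's start whenever the two are not
   already contiguous. One rule covers both gaps (end extended forward —
   never the later start pulled back) and overlaps (end pulled back). The
   final period's end is never touched here.
4. **Invalid-geocode subsumption.** A period whose geocode is unusable
   (failed geocoding, outside the study area, or no location at all) is
   absorbed by the *following* period — whose start moves back over it —
   iff that follower has a usable geocode and the invalid period overlaps
   no life stage by more than `max_overlap_fraction` (default 0.25) of the
   stage's days. The bound is non-strict: exactly 25% is still subsumable,
   reading "not more than 25%" as the disallowed side being strictly above.
   Chains of consecutive invalid periods are resolved to a fixpoint
   (innermost-first): the invalid period adjacent to a valid one is
   absorbed, then its predecessor becomes eligible in turn, each still
   subject to its own overlap test. The fixpoint formulation is what makes
   cleaning idempotent — re-cleaning a cleaned history changes nothing —
   which a single left-to-right sweep would not guarantee.
5. **Validation.** Every day of [DoC, LI end] must map to exactly one
   period; internal contiguity holds by construction, so only edge
   shortfalls (history starting late / ending early) can occur and are
   reported.

A stage touched by a retained invalid period, or not fully covered by the
history, is **unreliable**: it is still emitted, but with null aggregates
and a reason, never silently imputed. Every date mutation is logged
(member, record, field, old, new, rule) to a JSON-lines audit so data
managers can trace each change.

## Exposure assignment

The daily location series contains one row per (member, stage, day); a
calendar day appears once per stage containing it (P overlaps the
trimesters by design). The surface join is exact on (location, date);
a missing key is an error by default (`missing_policy="fail"`), because a
silently skipped day corrupts cumulative sums; `flag_day` opt-in marks the
day and excludes it from aggregates while counting it.

The birth-address method takes the location covering DoB in the *cleaned*
history — not the raw record active at DoB — so the two methods are
compared on identical data, and uses it for every day of every stage
through the identical join/aggregation machinery. Members whose cleaned
history does not cover DoB are excluded from the comparison with a reason.

Aggregates per member × stage: arithmetic mean, median (even counts: the
midpoint of the two central order statistics), and cumulative sum of the
valid dailies. Invariants the tests enforce: cumulative = mean ×
n_valid_days (relative tolerance 1e-9); mean and median within [min, max]
of the dailies; adding a constant to the surface shifts means/medians by it
and cumulative by it × n_valid_days; on a single-location member the two
methods agree bitwise.

## Mobility and comparison statistics

A *move* is a day d in (window_start, window_end] whose location differs
from day d − 1; a transition exactly on the window's first day belongs to
the preceding window (pregnancy counts moves in (DoC, DoB], infancy in
(DoB, LI end], so a delivery-day move is a pregnancy move and is never
double-counted). Consecutive periods at the same location are not moves.

Method differences are birth_address − mobility, with percent differences
over the mobility estimate: the mobility history is the reference the
birth-address convention is being judged against. Cohort statistics per
stage: min/max difference, 5th/95th percentiles by linear interpolation
between order statistics (the most common convention), R² as the squared
Pearson correlation of the paired means (identical to the R² of the simple
linear fit either way), and Spearman's ρ with average ranks on ties.
The "up to X%" headline is the maximum |percent difference|. Pearson,
Spearman and the least-squares fit line are delegated to scipy/numpy; the
test suite checks them against brute-force definitional implementations to
1e-12.

## Synthetic-data generator

The generator emulates exactly the features the cleaning algorithm
exercises, and nothing else. Defaults (all surfaced in `SimulationConfig`,
none hard-coded):

| parameter | default | why |
|---|---|---|
| births window | 1991-04-01 – 1992-12-31 | a ~21-month recruitment window typical of a single-city birth cohort |
| gestation | normal(39.5, 2) wk, rounded, clamped to [30, 44] | realistic term distribution; clamp keeps every member's stages valid |
| P(move in pregnancy) | 0.067 | observed pregnancy-mobility rate in a large English birth cohort restricted to its study area |
| P(move in infancy) | 0.18 | same source, first year of life |
| moves per mover-window | 1/2/3 w.p. 0.95/0.045/0.005 | observed mover move-count distribution |
| surface baseline | lognormal, median ≈ 31 µg/m³, log-sd 0.10 | early-1990s urban PM₁₀ levels with ~10% between-location spread |
| seasonal amplitude / daily noise | 4 / 3 µg/m³ | visible seasonality and day-to-day variation without dominating the baseline |
| current_date | 1994-12-31 | a plausible extraction date after every member's infancy |

The move-count distribution applies **per mover-window**; the ~1% of
members who move in both windows therefore aggregate more total moves than
the per-window distribution alone implies.

Corruption in `strict_recoverable` mode is *constructive*: every corrupted
extract is recoverable by design. End dates may be removed or perturbed
freely on non-final periods (contiguity rebuilds them from the successor's
start); the final period ends at `current_date`, so a removed final end is
re-imputed exactly, and is never noise-perturbed; start dates are removed
only from first periods, which always begin at DoC; duplicate rows share a
start date with their correction, which always receives a higher record
sequence; invalid-geocode periods are short (3–10 days) chunks carved from
the front of a true period, inserted only after verifying the ≤ 25% overlap
test against that member's actual stages (a 10-day chunk can exceed 25% of
a very short T3). Freeform mode lifts these guarantees to demonstrate what
breaks when the start-date-primacy assumption fails.

What the generator does **not** emulate: geographic coordinates and move
distances, spatially correlated exposure fields, address-string errors,
members leaving and re-entering the study area, or non-random missingness.
Passing the recovery test therefore shows the protocol implements its own
rules exactly and recovers truth *whenever the audit errors are of the
modelled kinds*; it does not show that real contact-database errors are all
of those kinds.

## Problem sizes and runtime choices

The flagship recovery check runs 1 000-member cohorts across five seeds
under aggressive corruption (every end date missing, 30% duplicates, 10%
invalid geocodes) and demands 100% exact recovery of histories *and* of
exposure summaries; mobility-rate fidelity is checked at 5 000 members
against three binomial standard errors. These sizes give per-member
corruption events in the thousands and mover counts in the hundreds while
keeping the whole suite under a minute on a laptop-class single core.

## Known limitations

* Residence is a proxy for personal exposure: no time-activity weighting,
  indoor sources, or workplace exposure.
* The tie-break for rows sharing a start date (newest wins) and the move
  counting rule are conventions; contact databases differ, and both are
  isolated behind small functions for adaptation.
* Exposure surfaces are consumed, not modelled; surface error propagates
  untouched into every aggregate.
* Reliability is binary per member × stage; no partial-coverage weighting.
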