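# Methods

## The problem and the data model

A multi-antenna HDX PIT reader reports one row per scan: tag ID, antenna ID
and a timestamp (1-second resolution, fixed UTC offset — no daylight-saving
logic anywhere in the package, because field readers run on a fixed clock).
Scans are collapsed into *detection events* (contiguous reads of one tag at
one antenna, merge gap `max_gap_s`, default 10 s — readers do not publish a
canonical value, and anything between the scan period and the fastest
plausible inter-antenna transit works; 10 s sits comfortably inside that
window for both bundled geometries).  All downstream processing consumes
typed objects; no stage re-reads raw files, and malformed rows are
quarantined with a reason rather than dropped, so the filter ledger
accounts for every input record.

## Movement events and the cleaning cascade

A *movement event* is a transition of one tag between two antennas, bounded
by the first detection at each.  Over a per-tag, time-ordered sequence of
detection events, each consecutive pair at different antennas yields one
movement from the *last* event at the origin to the first detection at the
destination — the only construction consistent with reading transitions off
an event sequence while keeping first-detection bounds (repeated detections
at the origin re-anchor the start).  Events with identical start times at
different antennas (degenerate input) are ordered by antenna position in
the geometry, with a warning, so output is deterministic.

Filters run in a fixed order; each is a per-movement (or per-event)
predicate, so the final kept set does not depend on the rate/transit order:

1. **Overlap filter** (on detection events): per tag, any maximal set of
   events whose closed intervals intersect pairwise or transitively while
   spanning ≥ 2 antennas is removed *in full*.  Same-antenna overlaps are
   merged, not removed: re-detection at one antenna is ordinary, only
   simultaneous presence at two antennas is physically impossible.
2. **Rate filter** (default ceiling 1 m·s⁻¹, strict `>`): applies only to
   first-order movements, the only ones with a defined rate.
3. **Transit filter** (default ceiling 180 s, strict `>`): removes
   transits long enough to imply mid-transit resting.  Boundary values are
   kept in both filters ("exceeded", "more than").

Non-first-order movements carry no distance or rate — on a circular channel
even their direction is ambiguous — so per-fish distance totals sum
first-order distances only and are lower bounds ("at least" totals).  The
ledger reports transit-filter removals against two denominators (all
movements, and movements surviving the rate filter) because the two
conventions differ by ~0.1–0.2 percentage points at realistic counts and
published reports are not always explicit about which they use.

## Solar model and diel classification

Sunrise and sunset come from the NOAA solar-position equations
(Julian-century series for solar longitude, anomaly, obliquity and the
equation of time; zenith 90.833° for refraction plus solar semidiameter).
Against an independent implementation (Astronomical Almanac low-precision
ephemeris + altitude bisection) the two agree within ~25 s across
November–February at the bundled mid-latitude sites; the test bound is
±2 min.  Sites at or beyond the polar circles are rejected rather than
approximated.  A user-supplied `date,sunrise,sunset` table overrides
computation so an analysis can be pinned to any almanac.

Day is the half-open interval [sunrise, sunset); night runs from sunset to
the next sunrise.  A movement's diel class is anchored at its **start
time**: transits are capped at 3 min by the transit filter, so the anchor
choice rarely matters, and movements whose start and end straddle a solar
boundary carry an explicit flag making the choice auditable.  Daily
activity uses calendar days at the site offset (midnight boundary), and a
tag counts as active on a day if it has ≥ 1 downstream movement that day.

## Statistics

* **Class proportions.** Per fish, the proportion of classified movements
  (known direction and diel) in each of the four direction × diel classes;
  fish with zero classified movements are excluded rather than zero-filled,
  so rows always sum to 1.
* **Kruskal–Wallis** (tie-corrected, chi-square reference with k − 1 df)
  over the per-fish proportions, four groups of n_fish observations —
  proportions with many zeros guarantee heavy ties, so midranks and the tie
  correction matter.  The chi-square reference is the field-standard
  choice; at very small samples (N ≤ 12) it deviates from the exact
  permutation null by several percentage points, which is inherent to the
  approximation, not to this implementation (the statistic itself is exact,
  and is tested against an independent rank-formula oracle and a
  permutation Monte-Carlo null).
* **Nemenyi all-pairs post-hoc** via the studentized-range (Tukey)
  distribution with ∞ df: qᵢⱼ = √2·|R̄ᵢ − R̄ⱼ| / √[N(N+1)/12·(1/nᵢ + 1/nⱼ)]
  over the pooled midranks, p from the upper tail.  No additional tie
  correction is applied in this variant, and no further multiplicity
  adjustment beyond the family-wise construction; α = 0.05.  scipy's
  studentized-range tail is cross-checked in the tests against frozen
  values of R's `ptukey`.
* **Clopper–Pearson** exact binomial interval via Beta quantiles, with the
  conventional closures (lower = 0 at k = 0, upper = 1 at k = n).  The
  tests verify agreement with binomial-tail bisection to 1e−9 for all
  0 ≤ k ≤ n ≤ 100, and empirical coverage at n = 48.  Detection
  probability is k = |recaptured ∩ detected| over n = |recaptured|.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
fish biomechanics.  Behaviour is a two-state (burrowed/moving) hourly
Bernoulli process: each hour a burrowed fish initiates a downstream bout
with probability `p_night` (default 0.05) at night or `p_day` (default
0.002) by day — values chosen once to give strongly nocturnal cohorts with
per-fish movement counts in the tens-to-hundreds over a season, the
magnitude such raceway studies report; the data cannot constrain them more
tightly.  A bout covers a geometric number of antenna-to-antenna transits
(mean 12, i.e. ~3 laps) at a truncated-normal speed (mean 0.11 m·s⁻¹, sd
0.015, the raceway's flow band).  Nocturnal bouts truncate at sunrise
(negative phototaxis: fish stop at first light), which is what makes a
`p_day = 0` cohort *strictly* nocturnal.  After a bout the fish burrows
where it stopped and stays ≥ 3 min, so between-bout transitions always trip
the transit filter and never alias as clean movements.

Cohort defaults are the raceway study conditions: 47 fish, 91 days starting
1200 local 2014-11-06, mover fraction 25/47.  Noise channels are
independently switchable and each maps to exactly one filter:

| channel | default | removed by |
|---|---|---|
| missed detections (per-antenna read prob.) | 0.95 | surfaces as non-first-order transitions |
| cross-talk (spurious simultaneous event at another antenna) | 5 / 1000 detections | overlap filter (2 events per injection) |
| mid-transit rest (180 s + lognormal, median ≈ 9.5 min total) | 0.02 / transit | transit filter |
| teleport (spurious next-antenna detection 2 s later) | 0 | rate filter |

With every channel off the emitted log is exactly identifiable: the
pipeline recovers the true transition sequence transition-for-transition,
and detection efficiency is exactly 1.  With read probability q < 1 the
first-order fraction estimates q (gaps between observed passages are
geometric, so P(adjacent) ≈ q).  Deterministic channel-to-filter count
identities hold when one channel is active at a time; with several active,
an injection can mask another's transition, so combined-noise runs are
validated statistically rather than by exact counts.

The linear-stream scenario models the release-and-drift design: 290 fish,
transit night geometric with first-night mass 0.81, drift speed uniform on
0.67–0.83 m·s⁻¹, three arrays 200 m apart 4.8–5.2 km below release,
per-array detection probability defaulting to 0.1335 (so the probability of
detection at ≥ 1 of 3 arrays is 0.35), recapture probability 48/290.  The
resulting ground-truth inter-array transits of 4–5 min and the
detection-probability interval are the recovery targets.  Stream transits
exceed the raceway's 3-minute resting threshold by construction — that
threshold is a raceway-specific filter, so stream analyses either raise
`--max-transit` or skip movement filtering entirely (the
detection-probability estimate uses only detected/recaptured sets).

What the generator does **not** emulate: temperature-driven seasonal
modulation of activity, inter-individual heterogeneity beyond the
mover/non-mover split, tag loss and mortality, antenna outages, and
correlated detection failures (e.g. high-flow periods degrading both
detection and recapture).  Passing recovery tests therefore demonstrates
that the pipeline's event logic and statistics are correct on data meeting
its assumptions — not that those assumptions hold in any particular river.

## Numerical and design choices

* Timestamps are written at 1-s resolution in a fixed UTC offset; the
  generator rounds passage times to whole seconds before computing ground
  truth, so truth-vs-pipeline comparisons are exact, not tolerance-based.
* Raceway antenna spacing defaults to circumference/4 = 3.75 m; the true
  per-pair spacing of such channels is rarely surveyed, and the geometry
  config makes any other spacing explicit.
* Simulation sizes in the test and acceptance suites (10–25 fish,
  6–20 days, 200 statistical replicates) are chosen to give thousands of
  movement events per run — enough for every statistical check — while a
  full default-size cohort (47 fish × 91 days) remains a single-command
  run for users.
* Degenerate inputs: empty movement lists raise on undefined quantities
  (detection efficiency, detection probability) rather than returning 0;
  identical observations across Kruskal–Wallis groups return H = 0, p = 1
  instead of erroring on zero variance.

## Known limitations

* Direction requires adjacency; a fish missed at ≥ 1 intermediate antenna
  contributes an unknown-direction movement, biasing per-fish totals low —
  the "at least" convention, inherited by design.
* The overlap filter removes true detections shadowed by cross-talk; at
  high cross-talk rates this depresses detection efficiency estimates.
* The solar model is adequate between the polar circles at 1-minute
  accuracy; it is not an ephemeris.
* The CLI's statistics report needs ≥ 2 fish with classified movements for
  the rank tests and ≥ 3 groups for a meaningful all-pairs comparison.
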