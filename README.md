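# pitmove

Movement-event analysis for multi-antenna PIT (passive integrated
transponder) telemetry, built for diel activity studies of
downstream-migrating fish such as newly metamorphosed juvenile sea lamprey
(*Petromyzon marinus*).

Stationary PIT antennas log every pass of a tagged animal, but raw reader
output is noisy: tag-signal collisions and antenna cross-talk produce
detections that place one animal at two antennas at once, and an animal that
burrows between antennas produces transits that look like movements but are
mostly rest.  `pitmove` turns raw detection logs into a defensible set of
movement events, classifies each by swim direction and day/night period, and
runs the nonparametric statistics this kind of study reports.

## What the pipeline does

1. **Collapse** contiguous same-tag same-antenna scans into *detection
   events* (presence intervals).
2. **Overlap filter** — for each tag, every group of detection events whose
   time intervals overlap across two or more antennas is removed in full
   (one fish cannot be in two places at once).
3. **Movement events** — consecutive detection events of a tag at different
   antennas become transitions, bounded by the first detection at each
   antenna.  A transition between *adjacent* antennas is *first-order*: only
   then are direction (from flow order), centerline distance and movement
   rate defined.  The fraction of first-order transitions is a coarse
   detection-efficiency estimate.
4. **Rate filter** — first-order movements faster than 1 m·s⁻¹ (beyond
   juvenile lamprey swimming ability) are removed.
5. **Transit-time filter** — movements taking more than 3 min indicate the
   animal rested mid-transit and are removed.
6. **Diel classification** — sunrise/sunset from the NOAA solar equations
   (zenith 90.833°); day is [sunrise, sunset).  Movements are grouped into
   the four direction × diel classes (downstream-night, upstream-night,
   downstream-day, upstream-day).
7. **Statistics** — per-fish class proportions compared across classes with
   a tie-corrected Kruskal–Wallis test
   (H = [12/(N(N+1))] Σ nᵢ(R̄ᵢ − (N+1)/2)² / C, C the tie correction)
   and Nemenyi's all-pairs post-hoc test referenced to the studentized-range
   (Tukey) distribution; detection probability p̂ = k/n from mark–recapture
   with an exact Clopper–Pearson binomial interval.

A `FilterLedger` carries counts through every stage, so each input record is
accounted for (kept, merged, quarantined, or removed at a named filter).

Two site presets are bundled: a 4-antenna circular raceway (15 m centerline
circumference) and a linear stream reach with three antenna arrays 200 m
apart.  A synthetic detection-log generator (`pitmove.simulate`) emulates
both — nocturnal bout schedules, missed detections, cross-talk, mid-transit
resting — and emits full ground truth, so the entire pipeline is testable
without field data.

## Worked example

Simulate eight days of a small raceway cohort and analyse it:

```
$ pitmove simulate --preset raceway --seed 2 --n-fish 4 --study-days 4 --out demo
$ pitmove run --log demo/detections.csv --preset raceway --out demo_out
377 records -> 67 detection events -> 64 movements -> 60 kept
```

`demo_out/ledger.csv` shows the cleaning cascade:

```
n_records,n_rejects,n_detection_events,n_overlap_removed,n_movement_events,n_first_order,n_rate_removed,n_transit_removed,n_final,...
377,0,67,0,64,60,0,4,60,...
```

377 raw scans collapsed into 67 presence intervals; 64 transitions were
built, of which 60 were first-order (93.8% detection efficiency — the
generator's default per-antenna read probability is 0.95); 4 transitions
exceeded 3 minutes (between-bout burrowing) and were removed.  The movement
table gives one row per kept transition:

```
tag_id,origin,dest,t_start,t_end,duration_s,distance_m,rate_m_s,direction,first_order,diel,...
F004,A2,A3,2014-11-07 18:18:08,2014-11-07 18:18:43,35.0,3.75,0.107143,downstream,1,night,...
```

— fish F004 swam the 3.75 m from antenna A2 to A3 in 35 s (0.107 m·s⁻¹,
close to the 0.10–0.12 m·s⁻¹ flow), after dark.  `stats_report.txt` holds
the rank tests over the per-fish class proportions, e.g.

```
Kruskal-Wallis over 3 fish x 4 diel/direction classes: H = 11.000, df = 3, p = 0.0117
```

Everything is also available as a library:

```python
from pitmove import raceway_geometry, run_cleaning, SolarTable
from pitmove.diel import assign_diel_to_movements
from pitmove.simulate import SimulationConfig, simulate_raceway

site = raceway_geometry()
records, truth = simulate_raceway(SimulationConfig(seed=1), site)
movements, ledger, stages = run_cleaning(records, site)
movements = assign_diel_to_movements(movements, SolarTable(site))
```

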