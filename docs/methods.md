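# Methods

## Problem and scope

Given synchronized GPS fixes of every member of a group-living population,
the package infers (i) which individuals form a social group at each time
step, (ii) when and where groups split and merge, and (iii) how those events
pattern in time (relative to activity) and space (relative to resource
locations and overall space use). Everything operates on projected metric
coordinates; no geographic CRS handling is included, and callers must supply
metres.

## Preprocessing

Raw fixes pass through three filters and a resampler.

- **Boundary filter.** Fixes outside the paddock polygon are removed. The
  test is edge-inclusive: GPS jitter at a fence should not delete true
  positions.
- **Satellite filter.** Fixes triangulated from fewer than `min_satellites`
  (default 3, the minimum for a two-dimensional position) are removed. Fixes
  lacking a satellite count are kept, with a warning, because the field is
  optional in the input dialect.
- **Speed filter.** A fix is removed iff it is unreachable at `v_max`
  (default 1.5 m/s, a measured flight speed for merino sheep) from *both* of
  its up-to-two nearest preceding retained fixes *and* from both of its
  up-to-two nearest following fixes; whole passes repeat until no fix is
  removed, so the result is independent of scan order. The AND rule targets
  isolated spikes while sparing fast-but-real runs: a track whose every
  consecutive implied speed is within `v_max` is provably untouched. Known
  limitation: two consecutive spikes displaced to the *same* off-track spot
  are mutually reachable and therefore survive; spikes on opposite sides of
  the track are mutually unreachable and are both removed.
- **Regularization.** Each individual is linearly interpolated onto the
  shared grid `t0 + k*dt` (default `dt` 6 s; `t0` defaults to the first fix
  time rounded down to a whole minute, since nothing pins the grid phase). A
  grid step is *supported* when a raw fix falls within half a grid interval
  of it; an unsupported run longer than `max_gap` steps (default 2) becomes
  MISSING. This makes "at most two consecutive missing locations" operational
  on the regular grid. Positions are never extrapolated beyond an
  individual's first/last fix, except that a supported step just outside the
  bracketed range snaps to its single nearest fix (so a one-fix track
  populates exactly one step). Regularization is idempotent on its own
  output, which the tests assert on randomized tracks.
- **Handling periods** (collar changes etc.) are masked via user-supplied
  half-open time intervals; there is no automatic detection rule.

## Grouping

- **Single radius.** With minimum group size 1, per-step grouping is the
  connected components of the graph joining individuals within `r`
  (inclusive `<= r`; a `strict` switch exists for oracle comparisons).
  Components below a larger `min_group_size` are labelled unassigned rather
  than silently dropped.
- **Double radius (sticky).** Formalized dyadically. For each pair, the
  candidate intervals are maximal runs of steps with distance strictly below
  `r_out`; a candidate is kept iff it contains at least one step with
  distance strictly below `r_in` — anywhere in the run, not necessarily
  before the first outer-radius excursion. The kept interval spans the whole
  run: joins are backdated to the outer crossing, leaves occur at the outer
  crossing. Missing distances inherit the last observed connection state and
  never terminate a run; a never-observed dyad is never connected; an
  interval may start at step 0 when the series begins inside `r_out`.
  Per-step groups are connected components over the active dyads, with
  individuals missing at the step excluded from that step's partition.
- **Boundary conventions.** "Below the inner radius" and "below the outer
  radius" are strict (`<`); with `r_in == r_out` the sticky timeline equals
  per-step strict-`<` single-radius grouping exactly, which the tests verify
  bit-identically against a brute-force transitive-closure oracle on
  randomized instances.
- **Defaults.** `r_in` 30 m / `r_out` 50 m: cohesion-scale grouping for
  sheep, well beyond contact distance but within conspecific perception
  range. Group labels are deterministic (numbered by first member index), so
  identical inputs give byte-identical outputs.
- **Memory.** Distances are evaluated one dyad at a time; only a boolean
  pairs-by-steps activity matrix is held, never the full distance tensor.

## Events

Per-step groups are nodes of a directed graph; edges join groups at
consecutive steps whose member sets intersect after restriction to
individuals present at both steps. Out-degree ≥ 2 yields one fission dated
at that node (the last step the parent existed); in-degree ≥ 2 yields one
fusion dated at that node (the step the merged group formed). Counting is
per node: a three-way split is one fission whose parts are retained in
`branches`, so per-branch counts can be re-derived. A node can yield both a
fusion and a fission; the fusion sorts first. Because overlap ignores absent
individuals, dropout and reappearance never create events: a returning
individual re-enters whatever group its still-active together-intervals
place it in. Event locations are the mean position of the reference group's
present members; an event whose members are all missing keeps its place in
the list with an undefined (NaN) location and a warning.

Group identity across steps is defined purely by edges; node labels are
arbitrary per-step tokens.

## Temporal metrics

- Experienced group size `sum(N_i^2)/sum(N_i)`; equals the mean over
  individuals of their own group's size (asserted against that oracle), and
  is bounded below by the observer mean group size (Cauchy–Schwarz),
  with equality iff all groups are equal-sized.
- Activity: displacement per grid interval, assigned to the interval's end
  step; population activity is the mean over individuals with both endpoints
  observed.
- Minute-of-day aggregation averages across all observed days in a
  configurable IANA timezone (the synthetic data use UTC). Event counts per
  minute divide by the number of days that minute was observed. Fissions and
  fusions are pooled by default; per-kind series are available.
- Activity normalization divides per-minute events by per-minute mean
  motion; minutes with zero or missing motion are NaN with a warning.
- Moving-average smoothing (default window 10 minutes) is centered with
  edge truncation — no phase lag — and excludes missing values per window.
- Time-of-day bins: night 22:00–05:00, morning 05:00–11:00, midday
  11:00–16:00, evening 16:00–22:00; high activity = morning ∪ evening, low =
  night ∪ midday. Bin summaries report the histogram of integer-rounded
  values as proportions, the mean, the integer mode, and a t-interval 95% CI
  of the mean over all step observations in the bin (the CI method is a
  package convention, stated here so the numbers are auditable).

## Spatial analysis

- Grid: 50 m square cells (matching the outer radius), anchored at the
  floor of the data bounding box to the cell size — reproducible without a
  paddock shapefile. Cells are half-open, boundary positions assign upward.
  Positions and events outside the grid go to flagged overflow tallies.
- Occupancy = animal-time-steps per cell; event counts per cell (optionally
  by hour of day); normalized rate = events per animal-time-step, defined
  only at occupancy ≥ 50 (small-sample guard).
- Resource distance: cell center to nearest food/water point.
- Correlations: Pearson r with two-sided p, pairwise deletion of missing
  cells, computed over cells.
- Mixed model: `events ~ distance + activity + distance:activity +
  (1 | cell)`, predictors z-scaled, fit by REML; one-degree-of-freedom Wald
  chi-square per fixed effect. Raw counts and occupancy-normalized counts
  are both supported as responses (pooled across fission/fusion kinds; a
  kind column in the event table supports re-analysis). A singular or
  non-converging random-effect fit is flagged and refit as
  fixed-effects-only OLS. The hourly activity covariate is the mean per-6 s
  displacement over all animals for that hour of day pooled across days.

## Synthetic data

The herd generator is a test harness, not a behavioural model. Individuals
follow their scheduled group centroid plus an isotropic AR(1) offset
(autocorrelation 0.9, so paths are smooth; marginal sd = `spread`) plus
white GPS noise; fixes drop out i.i.d. Defaults emulate the motivating
study's conditions: 50 individuals, 6 s sampling, 5 m within-group spread,
1 m GPS noise, 3% missing fixes. Scheduled partitions must differ by exactly
one split or one merge, and distinct scheduled groups must actually separate
(validated before simulation). What it does not emulate: attraction to
resources, grazing kinematics, heterogeneous social bonds, autocorrelated
missingness — so passing recovery tests demonstrates correctness of the
detection pipeline under clean group structure, not performance on real
herds with ambiguous, drifting subgroup boundaries.

Ground-truth recovery is checked inside a geometric tolerance window: the
detected event time is anchored at dyadic outer-radius crossings, which
straddle the inter-centroid crossing by up to the combined offsets, so the
window is the centroid crossing step widened by `8 * (spread + noise)`
metres divided by the local separation speed, plus 2 steps.

Two constructed fixtures pin the grouping semantics: a five-animal
stationary-plus-movers scene covering join-backdating, leaving, the
never-inside case and the never-outside case at exact hand-computed steps;
and a jittering two-subgroup scene whose separation hovers just above the
inner radius and excurses past the outer radius once per cycle, on which
total events are ordered sticky(30, 50) < single(50) < single(30) and sticky
membership churn is lowest.

Problem sizes in the test suite (e.g. 30 individuals × 5000 steps for
recovery, 100 random instances ≤ 12 × 200 for the degeneracy oracle,
200 cells × 24 h for model recovery, 500 cells for the occupancy contrast)
are the package's choices for exact, quickly reproducible checks.

## Known limitations

- The speed filter's AND rule keeps co-located consecutive spikes (above).
- Sticky grouping carries connection state through arbitrarily long dropout;
  with very high missingness a reappearing individual may be placed in a
  group it has physically left, until the next observed outer-radius
  crossing.
- The mixed model treats cells as exchangeable (no spatial autocorrelation
  structure beyond the random intercept) and fits counts with a Gaussian
  linear model rather than a count family, matching the analysis it
  implements.
- Group identity is purely edge-based; no repeated-subgroup (community)
  tracking across separated occurrences.
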