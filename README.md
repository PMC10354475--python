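# fisfus

Fission–fusion event detection from synchronized multi-animal GPS
trajectories.

Animal groups split (fission) and merge (fusion) as the cost–benefit balance
of grouping shifts through the day and across space. Given high-frequency GPS
fixes of every member of a group-living population — the motivating system is
a herd of 50 free-ranging sheep tracked every 6 s for 16 days — this package
turns the raw fixes into time-resolved social groups, extracts each fission
and fusion event with a time and a location, and provides the temporal
(activity-normalized) and spatial (occupancy-normalized, resource-distance)
analyses of those events. It is aimed at movement ecologists working on
collective behaviour with whole-group telemetry.

## Method

**Groups per time step.** With minimum group size 1, single-radius DBSCAN
reduces to the connected components of the proximity graph joining
individuals within a radius *r* (the "gambit of the group"). Because a dyad
hovering near *r* flickers in and out of connection, the package's core is a
double-radius ("sticky") variant with hysteresis on every dyad: a pair joins
only when its distance falls below the inner radius *r_in* (default 30 m),
with the join backdated to the crossing of the outer radius *r_out*
(default 50 m), and the pair separates only when its distance exceeds
*r_out* again. Per-step groups are the connected components over the dyads
whose together-interval covers the step. Missing fixes inherit the last
observed connection state.

**Events.** Per-step groups become nodes of a directed temporal graph with
an edge between groups at consecutive steps that share a member (members
missing at either step are ignored, so data dropout never creates events). A
node with out-degree ≥ 2 is a fission, dated at the last step the parent
group existed; a node with in-degree ≥ 2 is a fusion, dated at the step the
merged group formed. Each event is located at the mean position of the
reference group's present members.

**Analyses.** The experienced group size of a partition with group sizes
N_1, …, N_n is

    (Σ N_i²) / (Σ N_i)

— the average group size from the individuals' own perspective (for four
animals split 3 + 1: (3·3 + 1·1)/4 = 2.5). Event counts per minute of day
are normalized by population activity (mean displacement per 6 s interval);
event counts per 50 m grid cell are normalized by occupancy
(animal-time-steps per cell, minimum 50), related to the distance to the
nearest food/water resource by Pearson correlation, and modelled per cell
and hour as

    events ~ distance + activity + distance×activity + (1 | cell)

via a REML linear mixed model with Wald chi-square tests.

## Worked example

Simulate a herd with scripted splits/merges and recover them:

```python
import fisfus as ff

script = ff.split_merge_script(n_individuals=30, n_steps=5000, n_cycles=10,
                               spread=5.0, gps_noise_sd=1.0, seed=42)
traj, truth = ff.simulate_herd(script)
print(f"coverage: {traj.coverage():.3f}")

timeline = ff.sticky_groups(traj, ff.RadiusConfig(r_in=30, r_out=50))
events = ff.detect_events(traj, timeline)
print("detected:", events.counts(), " scripted:", truth.counts())

first = events[0]
print(f"first event: {first.kind} at step {first.step}, "
      f"location ({first.x:.1f}, {first.y:.1f}), "
      f"{len(first.reference)} -> {[len(b) for b in first.branches]} individuals")

sizes = ff.experienced_series(timeline)
print(f"experienced group size: mean {sizes.mean():.2f}, "
      f"min {sizes.min():.2f}, max {sizes.max():.2f}")
```

prints

```
coverage: 0.970
detected: {'fission': 10, 'fusion': 10}  scripted: {'fission': 10, 'fusion': 10}
first event: fission at step 112, location (1038.0, 999.6), 29 -> [14, 15] individuals
experienced group size: mean 22.51, min 12.52, max 30.00
```

Coverage is 97% because the simulator drops 3% of fixes at random; all 10
scripted fissions and 10 fusions are recovered, and nothing else. The first
split is detected at step 112 — the scheduled split is at step 100 and the
two half-herd centroids (15 + 15 animals; one animal's fix is missing at the
event step, hence 29 located members) separate at 1 m/s, so the last dyadic
outer-radius crossing lands ~12 steps later. Experienced group size moves
between ~12.5 (two separated halves, where (15² + 15²)/30 = 15 less the
individuals dropped by missing fixes) and 30 (whole herd together).

The same pipeline is available from the shell:

```sh
fisfus simulate --seed 5 --out traj.csv --truth truth.csv
fisfus groups   --traj traj.csv --r-in 30 --r-out 50 --out timeline.csv
fisfus events   --timeline timeline.csv --traj traj.csv --out events.csv
fisfus metrics  --timeline timeline.csv --traj traj.csv --events events.csv \
                --tz UTC --out metrics/
```

Real data enter through `fisfus preprocess` (boundary, satellite and speed
filters, then linear interpolation to the exact 6 s grid) from a CSV of
`id,time,x,y[,nsat]` fixes in projected metre coordinates.

## Layout

- `fisfus.io` — CSV dialects for fixes, resources, boundaries, trajectories,
  timelines and events (lossless round-trips).
- `fisfus.preprocess` — cleaning filters and grid regularization.
- `fisfus.grouping` — together-intervals, sticky and single-radius grouping.
- `fisfus.events` — temporal group graph and event extraction.
- `fisfus.metrics` — experienced group size, activity, time-of-day analyses.
- `fisfus.spatial` — grid occupancy, resource distances, correlations, the
  cell-hour mixed model.
- `fisfus.simulate` — scripted herds with ground truth and the constructed
  fixtures used by the tests.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical conventions.
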