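# Model and methods

`roostsim` simulates nightly roost switching in a colony of tree-dwelling
bats (modelled on adult-female *Nyctalus leisleri* groups) as an agent-based
system, and ships the statistical machinery used to compare its outputs with
field observations. This note documents the model, the synthetic habitat
generator, the numerical choices, and what the shipped defaults do and do
not capture.

## The simulated system

A colony of `n_agents` (default 100) bats shares a roosting habitat of 944
tree cavities in a ~128 ha woodland patch, centred in a 9 km × 9 km plane
that bounds nightly flight. Each simulated day is an 8-h night of 28,800
one-second steps (sunset anchored at 21:00, so "midnight" is t = 10,800 s
and sunrise t = 28,800 s) followed by a bulk 16-h daytime update. A season
is 120 such days; desk-scale analyses in the test suite and acceptance
script use 15-day seasons with several seeds and discard the first five
days: the colony starts artificially fused in a single roost and needs a
few nights to reach its quasi-stationary fission-fusion regime.

### Cavities and roost quality

Every cavity has a position, an entrance height CH (m) and a load of
excrements LE ∈ [0, 100], a proxy for the parasite load of accumulated
guano. Its attractiveness is

    QR = (100 · CH / max CH) · w_CH + (−(LE − 100)) · w_LE,

with both weights 0.5 by default, so QR ∈ [0, 100]. A bat only advertises a
cavity with QR strictly above 30. While bats roost through the day, LE grows
by 5·10⁻⁵ per bat per second; at the end of each day an occupied cavity
additionally gains 0.1·(occupants) and an empty one loses 10, clamped to
[0, 100].

### Flight

Agents fly a correlated random walk: each second the heading changes by a
uniform swerve within ±30° and the speed is drawn from a shifted gamma
distribution (shape 2) clipped to [2.5, 11.1] m/s whose median is the
species' commuting speed of 3.7 m/s. Positions reflect at the plane
boundary. Goal-directed legs (flying to a chosen roost) head straight at the
target at the same speeds.

### Perception and recruitment

A flying bat detects cavities within a 270°/150 m forward field of
perception (FoP; the 90° cone behind it is blind). A swarming (signalling)
roost advertises itself within an attraction radius drawn once per bout from
80–100 m; any searcher inside that circle is recruited with probability
`receiver_rate` per second (default 0.08) and, when several advertised
roosts are in range, joins the one with the most signallers (ties: nearest,
then lowest id). An *occupied but silent* roost is always worth inspecting
once perceived; an empty cavity is inspected only with probability
`explore_rate` per second (default 0.015). This ordering implements the
model's recruitment-priority rule — an advertised or occupied roost is far
more likely to be selected than a fresh cavity — and keeps searchers
receptive between inspections.

### Swarming bouts and the group-size threshold

A bat that accepts a cavity swarms around it for

    t_attr = (CH² + 1) + NRB + 1000/TTS   seconds,

where NRB is the number already inside and TTS the time to sunrise, extended
while co-swarming by te_attr = NSB²/2 (NSB = number of co-signallers). The
extension is evaluated continuously: a bout ends when t exceeds
start + t_attr + NSB(t)²/2, so a growing swarm stays aloft collectively and
collapses into the roost as a cascade when growth stalls. When the last
signaller of a roost enters, the group compares its size against the
group-size threshold

    GST(t) = b                                  for t ≤ o,
    GST(t) = b − (b−a)(t−o)/(T_sim − t)         for t > o,

clamped to [a, b] = [10, 100] (the decay branch diverges as t → T_sim), with
o at midnight. A group at or above GST settles until the next emergence;
otherwise all bats leave and resume searching from within the swarming disc
around the abandoned cavity.

### Memory and site fidelity

Each bat remembers recently used day roosts with a penalization distance PD
that grows by 50 m per day of consecutive use (cap 150 m) and decays by
50 m per unused day (entries are forgotten at zero). Cavities within the PD
radius of a remembered roost are not inspected — repeated advertising of
the same location is treated as a predation risk.

Three further rules shape where searching happens; the source model's
published outputs (few groups per day, switching distances of tens of
metres) require both strong nightly re-aggregation and tight site fidelity,
neither of which is achievable by unbiased random walking across a plane in
which the habitat occupies ~2.6 % of the area:

- **Homing.** After foraging, a searcher returns to the neighbourhood
  (within `home_radius_m` = 150 m) of the roost where it spent the previous
  day before searching locally, so group lineages keep a compact nightly
  territory and switch roosts over short distances.
- **Prospecting.** Each night a bat forgoes its familiar neighbourhood with
  probability `prospect_rate` (default 0.3) and instead roams the roosting
  area at large, ignoring roosts within 300 m of the site it disperses from.
  This is the individual-level group switching of fission–fusion societies
  and the main source of new group lineages.
- **Local exhaustion.** After `max_failures_per_night` (15) failed bouts a
  bat stops homing and roams the habitat, which lets chronic stragglers
  reach other swarms.

### The nightly cycle

At t = 0 all bats emerge and forage for a uniform 2–3 h without interacting,
dispersing over the whole plane. Searching, swarming, settling and
dissolution then proceed as above. Five minutes before sunrise every bat
must secure a roost. Swarms below `dawn_viability_min` (5) bats have not
"found" a roost; their members fall back to their group: each returns to
the neighbourhood of its *day roost* (where it last spent a day — not a
cavity briefly entered during a failed nocturnal bout) and joins the
nearest occupied roost within `fallback_radius_m` (150 m) of it, or roosts
alone at the day roost itself when no group settled nearby. Viable swarms
enter their cavity, and agents still in transit at sunrise are housed at
their target. Failed group-mates therefore rejoin their relocated group at
dawn rather than being recorded as scattered singletons.

The daily record is the set of occupied cavities with group sizes, taken at
the first step after 4:00 at which every agent is inside a roost (the
sunrise rule guarantees this by the end of the cycle); the largest group of
the day is flagged (ties: lowest cavity id). Consecutive-day distances
between maximum-group roosts are the switching distances.

## Synthetic habitat generator

The generator reproduces the published summary of the study habitat rather
than any mapped cavity field (which is not public):

- 37 equal hexagonal cells (pointy-top lattice, rows of 3/4/5/4/5/4/5/4/3)
  jointly covering 128.2 ha, centred in the plane;
- 944 cavities allocated to cells by an exponentially weighted multinomial,
  repaired into the published per-cell range [8, 92] while conserving the
  total — the published field is strongly heterogeneous, with roosts
  concentrating in the densest cells;
- per-cell mean entrance heights drawn from Beta(1.5, 7.5) scaled to the
  published range [4.8, 13.5] m (habitat-wide mean ≈ 6.3 m, below the
  >7.5 m entrances that groups select — the study reports selected roosts
  sitting significantly above the available average), with individual
  heights normal within a cell (sd 1.5 m, truncated to (0, 16] m; realised
  heights span ≈ 1.5–15.5 m, matching the span of roosts the source model
  reports); cell samples are redrawn until the realised cell mean lies in
  the published range;
- positions uniform within each hexagon.

The same seed reproduces a field bit-for-bit. What the generator does *not*
emulate: spatial autocorrelation between neighbouring cells, correlation
between cavity density and height, within-cell clustering of trees, and any
terrain or vegetation structure. Passing tests on this habitat show the
behavioural model reproduces the published summary statistics under a
statistically matched habitat, not under the real one.

## Statistical suite

- **Spatial point pattern test.** Area-based and nonparametric: per hex
  cell, the base pattern's point percentage is compared with a percentile
  interval built from 200 subsamples of 85 % of the test pattern (drawn
  without replacement). S_global is the share of similar cells among all
  cells; the robust S counts only cells containing points of either pattern.
- **Mann–Whitney U** from midranks; exact p by the counting recurrence when
  the data are tie-free and n₁·n₂ ≤ 400, otherwise the tie-corrected normal
  approximation with continuity correction. All values identical across
  both samples yields p = 1.
- **Hedges' g** with the small-sample correction J = 1 − 3/(4·df − 1), an
  asymptotic-variance CI, Cohen magnitude labels (0.2/0.5/0.8), and a
  seeded 10,000-resample percentile bootstrap CI for the raw mean
  difference.

## Numerical and design choices

- One `numpy` PCG64 generator per season drives every stochastic element;
  a season is a pure function of (config, seed). Replicates derive
  independent seeds from the master seed.
- Agent updates run in ascending id order; movement is vectorised; cavity
  lookups use a k-d tree built once per season.
- Once every agent is housed and no swarm is active, the remainder of the
  night cannot change state and is skipped.
- Tunable constants live in `BehaviourConfig`/`EnvironmentConfig` with the
  study's values as defaults; the free parameters the source leaves
  unstated (`explore_rate`, `receiver_rate`, `prospect_rate`,
  `home_radius_m`, `max_failures_per_night`, swerve bound, height sd) are
  fixed once at values that place the model in its documented operating
  regime — a handful of co-dominant groups per night, maximum groups of
  ~40–70, switching over tens to a hundred metres — and are not intended as
  per-study fitting knobs.

## Known limitations

- Group fission–fusion statistics are sensitive to the recruitment
  parameters; far outside the shipped regime the colony either fuses into a
  single permanent group or shreds into transient fragments.
- Heights enter bout length quadratically (CH²), so the model's height
  selectivity is strong; recorded roost heights sit 2–4 m above the habitat
  average.
- The sunrise fallback can create small "rump" groups at the previous day's
  roost; these are recorded like any other group.
- Daylight length is fixed (no seasonal variation), juveniles and midseason
  births are not modelled, and bats are behaviourally identical.
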