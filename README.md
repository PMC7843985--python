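# colonyforage

Foraging-niche analysis for colonial seabirds (and other central-place
foragers): from raw GPS fix tables and feeding-watch photographs to
behaviour-classified tracks, foraging-trip metrics, kernel
utilization-distribution overlap with a permutation null, and diet
composition tables.

Sympatric seabirds breeding on the same island must partition prey
species, prey sizes or foraging space to coexist. Testing that with
biologging data requires a chain of standard but fiddly steps, each with
choices that matter. This package implements the whole chain as a typed,
tested library, plus a synthetic-data generator that produces GPS tracks
and bill-load observations *with known ground truth*, so every stage can
be validated without any field data.

## The methods

**Behaviour classification.** Each GPS fix of a bird is labelled
`colony` when it lies within a species-specific splash-down radius of
the colony (1000 m razorbills, 3000 m murres, 5000 m kittiwakes — birds
rest and wash on the water near the colony), otherwise `flying` when the
instantaneous speed from the previous fix is at or above a threshold,
else `foraging`. The threshold is the harmonic mean of drift and flight
speed,

```
v* = 2 (v_drift · v_flight) / (v_drift + v_flight)
```

giving 9.41 km/h for murres/razorbills (5, 80 km/h) and 9.04 km/h for
kittiwakes (5, 47 km/h), averaged to a common 9.29 km/h. Maximal runs of
consecutive non-colony fixes with ≥ 5 positions are complete foraging
trips.

**Trip metrics.** Seven per-trip statistics: maximum distance, duration,
departure hour, distance of first stop, number of patches (foraging
runs), the Foraging Range Index `FRI = mean(dist to colony | foraging)`
and the commuting index `CI = 1 − 2·MAD(X)` where `X` are foraging
distances rescaled by the trip maximum — CI = 1 when all foraging
happens at one distance, → 0.5 when foraging is spread uniformly along
the route.

**Space use.** Foraging fixes are projected on an azimuthal equidistant
plane at the colony and smoothed with an isotropic bivariate-normal
kernel (bandwidth `h_ref = 0.5(sd_x + sd_y) n^{−1/6}`) into a gridded
utilization distribution (UD). Overlap between species at the 25/50/75/
95% percent-volume contours is measured by Bhattacharyya's affinity
`BA = Σ√(p₁p₂)` and `UDOI = A_overlap · Σ d₁d₂ ΔA`; significance of
*low* overlap comes from reassigning species labels to whole trips,
rebuilding both UDs, and recomputing the indices (default 1000
permutations).

**Diet.** Bill-load photographs give prey and bill lengths in pixels;
`length_mm = (prey_px / bill_px) · bill_mm`, mass by allometry
`m = a·L^b` (capelin: `2.7×10⁻⁵·L^2.76` g), larval prey fixed at 2 g,
unknown prey assigned the mean identified item mass. Composition is
summarised as frequency of occurrence, numerical abundance and mass,
with percentages per predator species, and compared with χ² (prey with
< 5 observations dropped), quasi-Poisson load-size models and a prey
size-vs-number regression.

## Worked example

`examples/` holds one short script per capability. For instance
`python examples/02_trip_metrics.py` simulates three murres commuting to
a single patch 20 km from the colony and prints, per trip:

```
MURR02_trip005            20.57        0.50   20.52          20.57          1 1.00
MURR02_trip006            20.00        0.50   19.96          20.00          1 1.00
...
mean FRI (km): 19.9  — the single patch sits 20 km out
mean CI: 0.98     — near 1: pure commute-then-forage trips
```

The recovered FRI matches the true patch distance and CI ≈ 1 flags pure
commuting trips. `examples/03_space_use_overlap.py` runs the overlap
randomization on two species sharing one of two patches:

```
observed BA   = 0.407   (0 = disjoint space use, 1 = identical)
null mean BA  = 0.939
p(BA lower than null)   = 0.005
```

i.e. the species share far less space than random trip assignment would
produce. The full pipeline (both arms, all artifacts, manifest) is
driven by `colonyforage.run_pipeline(RunConfig(...))` or a YAML config.

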