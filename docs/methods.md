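# Methods

`parep` implements a temporal gap analysis of protected-area (PA)
networks: how well an expanding reserve system represents a species pool,
whether each decade's additions out-performed randomly placed reserves of
identical number, size and shape, and what happens to representation when
species ranges shift under climate change. This note documents the model,
its assumptions, the tunable parameters, and the numerical choices.

## Representation targets and gap analysis

Each species *s* with modelled range size *R_s* (km²) receives a
representation target

    t(R) = 1                                          R ≤ L
    t(R) = 1 − (1 − f) · (ln R − ln L)/(ln U − ln L)  L < R < U
    t(R) = f                                          R ≥ U

with defaults L = 1000 km², U = 55,000 km², floor f = 0.2: small-ranged
species must be fully covered, wide-ranged species only to 20%, log-linear
in between (the logarithm base cancels in the ratio; natural log is used).
The curve is continuous and non-increasing, and both boundary conventions
("≤ L" vs "< L") coincide because the interior formula agrees at the
endpoints. L, U and f are configuration values so the curve can be
rescaled to synthetic worlds much smaller than a subcontinent.

A species is *represented* under a network snapshot if its covered
fraction — presence cells whose center lies inside a PA polygon, divided
by all presence cells — reaches its target. Group summaries report the
percent of species represented per stratum (five taxonomic groups;
threatened vs non-threatened), per decadal snapshot, per scenario.
Targets are always computed from the **current** range size and reused
for future scenarios; a species whose future range vanishes stays in the
denominator as unrepresented (dropping it would inflate future
representation).

Rasterization uses the cell-center rule rather than area weighting: it is
deterministic, fast, and at the ~5 km² working resolution the error is
below one cell row per polygon edge. Coverage is therefore exactly a
Boolean matrix product, which is what makes the randomization test cheap.

## The spatial null model

For each decadal cohort, the null model asks: would the same reserves,
placed at random, have represented species equally well? Each replicate
rigidly moves every cohort polygon — uniform rotation in [0°, 360°), a
fair-coin mirror, and a translation drawn uniformly over all positions of
the rotated polygon's bounding box inside the study bounding box —
accepting a placement when the polygon lies inside the study polygon
(boundary contact allowed) and overlaps neither previously placed null
polygons nor the *real* PAs of earlier decades. Number, size and shape of
reserves are thus preserved exactly; total protected area is conserved.
Multi-part reserves move as one rigid unit. Polygons are placed
largest-first (large polygons dominate feasibility); if any polygon
exhausts its rejection budget the whole replicate restarts, so partial
configurations cannot bias placement order. Replicate seeds derive from
the master seed by a fixed affine rule and are recorded for replay.

Earlier-decade PAs always enter at their real locations; null cohorts of
different decades are independent. Rotation is continuous rather than in
90° steps, and touching (zero-area contact) between polygons is allowed —
overlap means positive intersection area.

The significance rule is the standard one-sided permutation p-value

    p = (1 + #{null ≥ observed}) / (N + 1),   reject at p ≤ α,

with N = 100 replicates by default, so the smallest attainable p is
1/101 ≈ 0.0099. This rule is exact for continuous statistics and
conservative under ties.

## Type-I-error calibration and the discreteness problem

When the "observed" network is itself drawn from the null generator,
the rejection probability at α = 0.05, N = 100 should be 5/101 ≈ 4.95%.
That statement holds only for an effectively continuous statistic.
Percent-of-species-meeting-targets over ~30 species is discrete, and on a
generic small world the met-count distribution concentrates on ~10 values
(tie probability between two exchangeable networks ≈ 0.14); the measured
rejection rate then drops to ≈ 2.6% — the permutation rule is being
conservative, exactly as theory predicts, not miscalibrated.

The calibration world in `parep.calibration` is therefore constructed so
that the statistic has fine granularity where it matters, near the upper
5% of its null distribution: 30 species with nested disc ranges around an
off-symmetry hotspot on a 20×20 grid (nesting makes met events strongly
positively correlated, so the met-count behaves like a graded "how deeply
did the network hit the hotspot" depth), with per-species targets placed
at graded upper quantiles of each species' null coverage distribution
(marginal met probabilities geometric from 0.10 down to 0.004). The
quantiles are estimated once from 4000 placements drawn with a frozen
fixture seed that is independent of the trial seed. These calibration
targets are fixture parameters chosen for granularity — they are not
outputs of the range-size target curve, which has its own exact tests.
With this construction the measured rejection rate over 2000 trials is
statistically consistent with 4.95% (binomial SE ≈ 0.49%).

## Climate scenarios and dispersal restrictions

Future ranges (two representative concentration pathways, RCP4.5 and
RCP8.5, nominally 2070) enter the same machinery. In real-data mode the
post-processing module supplies them: per-GCM suitability projections are
averaged cell-wise, binarised at the species' 10-percentile presence
threshold, and then restricted by dispersal — future presence is zeroed
beyond a taxon-specific distance from the current (distance-refined)
range, where distance is zero inside the range and Euclidean
cell-center distance to the nearest current presence cell outside it (the
minimum is attained on the range edge, defined as presence cells with an
absent 4-neighbour, the grid border counting as absent). Default
dispersal distances are 20 km for birds and mammals and 5–8 km for
amphibians, reptiles and plants, reflecting their weaker dispersal; they
are configuration values, not estimates.

The climate randomization mirrors the decadal test but randomizes only
the most recent cohort against the future ranges, holding all earlier
reserves fixed.

## SDM post-processing

Model fitting is out of scope; the post-processing contract is: member
models are kept only if TSS > 0.8 **and** AUC > 0.8 (strict); the
ensemble is the cell-wise convex combination weighted by raw member TSS
(weights ∝ TSS; transformed weights were rejected for auditability);
ensembles are discarded if TSS < 0.7 or AUC < 0.8 (so boundary values
pass); binarisation takes the 10th percentile — linear interpolation
between order statistics — of ensemble suitability at the training
presences as threshold and marks cells with suitability ≥ threshold
(presences exactly at the threshold count as present, so ≥ 90% of
training presences fall inside the predicted range). AUC is the rank
statistic with ties counted one half; TSS is sensitivity + specificity −
1. A species whose members all fail the filter is reported as
unmodellable rather than silently skipped. The
threshold → occurrence-clip → dispersal chain is anti-extensive (never
adds presence cells), and the filters are idempotent; both properties are
enforced by tests.

## The synthetic world generator

The generator produces the statistical structure the analysis assumes,
not realistic biogeography:

* **Terrain.** A rectangular study area covering a configurable fraction
  of the grid bounding box; elevation is a linear ramp along a
  configurable direction (default relief 3000 m) plus Gaussian-filtered
  noise (default SD 150 m, correlation length 3 cells). Zero-noise
  configurations give an exactly monotone ramp, which the tests exploit.
* **Species.** Per group, range areas are log-normal (defaults place
  birds/mammals at ~5000–6000 km² medians in the lowlands and
  amphibians/reptiles at ~300–500 km² in the highlands, preserving the
  group ordering that matters for the analysis); each range is a
  connected cell set grown by random frontier accretion from a seed cell
  drawn from a Gaussian elevation density, clipped to the study area.
  Occurrences are uniform over range cells. The threatened flag is
  Bernoulli with a logistic probability decreasing in log range size
  (default: half of the very small-ranged species, midpoint 1000 km²).
* **Reserve history.** Eight decadal cohorts (1937–2015) whose default
  totals peak in 1986–1995 and whose placement elevation drifts from
  ~2800 m down to ~600 m; per-decade totals are met exactly by rescaling
  log-normal size draws, and placements are rejection-sampled squares
  (random rotation) that must not overlap anything placed earlier. When
  no history is configured the default decade totals are scaled to the
  study-area size (they are written for ~18,000 km²). Infeasible
  configurations fail loudly, naming the decade.
* **Futures.** Each scenario translates ranges upslope by a configured
  displacement (defaults 6 km for RCP4.5, 12 km for RCP8.5), clips to the
  study area, and randomly erodes boundary cells until the configured
  fraction of the original area remains (defaults 0.7 and 0.5). Ranges
  pushed off the study area disappear — the analogue of a vanished
  bioclimatic niche.

Everything is a pure function of (config, seed); per-stage generators are
spawned from the master seed with fixed spawn keys, so stages can be
regenerated independently.

What the generator does **not** emulate: spatial autocorrelation of
occurrence effort, climate variables (futures are geometric shifts, not
bioclimatic projections), range fragmentation, PA shape complexity, or
downgrading/degazettement of reserves. Tests passing on synthetic worlds
therefore certify the *machinery* — bookkeeping, monotonicity,
conservation, calibration, directional responses — not the realism of any
particular empirical number.

## Pipeline and problem sizes

The pipeline stages (world → postprocess → represent → randomize →
climate → plots) communicate through plain files (GeoJSON, ESRI ASCII
grids, CSV) under one run directory with a JSON manifest recording config
hash, seeds and timings; completed stages are skipped on resume unless
forced. Fractions in CSV outputs carry six decimals. Real-data mode
expects pre-projected equal-area inputs on a single grid and validates
grid consistency, polygon validity, year coverage and table/raster
cross-references before any compute.

Default problem sizes were chosen so that a full synthetic run (60×60
cells, 150 species, 24 reserves, 100 replicates × 8 decades × 7 strata)
completes in well under a minute, and the 2000-trial calibration
experiment in a few minutes, on one CPU core.

## Known limitations

* The cell-center rasterization slightly under-represents polygons
  narrower than one cell; reserve polygons at the default sizes are much
  larger than a cell.
* Under heavy ties (tiny species pools) the permutation test is
  conservative; this is a property of the rule, documented above, and the
  package reports the p-value rather than "correcting" it.
* The erosion step of future-range generation is stochastic, so a
  species' covered *fraction* can occasionally rise even as its range
  shrinks; directional claims about representation decline are therefore
  statements about configured worlds with strong displacement, not
  theorems.
* Null-model feasibility degrades as protection approaches the packing
  limit of the study area; the generator and the null model both fail
  loudly rather than degrade silently.
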