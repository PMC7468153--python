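# Methods

This note documents the models, conventions and numerical choices behind
`lakebiogeo`, in the order the pipeline runs them, together with what the
synthetic worlds do and do not emulate.

## Geometry

All distances are great-circle (haversine) distances on a sphere of radius
6,371.0 km (`lakebiogeo.geometry.EARTH_RADIUS_KM`, configurable). The
haversine form is numerically stable at short range, where the spherical
law of cosines loses precision; the two agree to < 1e-6 relative error away
from antipodal pairs, which the tests assert. Ellipsoidal geodesics are out
of scope: at continental scale the sphere-vs-ellipsoid discrepancy (~0.3%)
is far below the Monte-Carlo noise of the null model.

**Bounding-box area.** The endemism criterion needs the area of the
lat/lon-aligned rectangle containing a taxon's lakes. We measure it as the
geodesic width along the mid-latitude parallel times the geodesic height
along the mid-longitude meridian, isolated in one function
(`bounding_box_area_km2`) so an alternative convention (e.g.
equirectangular at the box centre) can be swapped in; for European extents
the conventions agree within a few percent. Longitude spans ≥ 180° are
rejected — the supported study regions never cross the antimeridian.

**Geometric centres** of distribution areas are unit-vector means on the
sphere re-projected to lat/lon, not naive coordinate averages, so they are
immune to longitude wrap-around. A perfectly antipodally balanced point set
has no defined centre and raises a degenerate-data error.

## Amplicon processing

The chain reproduces the standard paired V9–ITS1 workflow on already
merged, chimera-free reads (upstream read QC is out of scope):

1. **Dereplication**: exact-string (v9, its, lake) uniqueness, length
   variants distinct, counts summed. Read totals are conserved.
2. **Pair filter**: each ITS1 sequence keeps only its most abundant V9
   partner (total reads across lakes); minority pairings are treated as
   erroneous cross-pairings and dropped. Ties break to the
   lexicographically smallest V9 sequence (deterministic). Afterwards
   ITS → V9 is a function while a V9 keeps many ITS variants.
3. **V9-groups**: equivalence classes of identical first-150-bp V9
   prefixes. Sequences shorter than the prefix length group by full
   sequence. Group ids are assigned in lexicographic prefix order, so
   outputs are independent of record order.
4. **Sample filter**: lakes with read totals strictly below 15% of the
   median per-lake total are dropped. The threshold is always computed
   from the data at hand, never hard-coded.
5. **Low-abundance filter**: per lake, ITS variants strictly below 0.001%
   of the lake's total are dropped in that lake only (equality kept). This
   runs before swarm clustering — variants are filtered, then clustered.
6. **ITS-SWARMs**: connected components of the variant graph with edges at
   Levenshtein distance ≤ d (d = 1 default), i.e. single-linkage
   agglomeration, the core SWARM growth rule. SWARM's fastidious phase and
   abundance-based chain breaking are deliberately not implemented: at
   d = 1 on filtered variants they rarely change components, and the plain
   rule is exactly checkable against a brute-force all-pairs oracle.
   `N` characters count as mismatches; edit distances come from edlib.

Metazoan and higher-plant groups are removed when taxon annotations are
supplied; taxonomy itself is an input (TSV), never computed.

## Restriction null model

For each taxon with occupancy n ≥ 2, R = 1,000 subsets of n lakes are
drawn without replacement from the reference pool (all retained lakes at
the V9 level; the parent V9-group's lakes at the swarm level).
q = (#draws with observed < draw)/R, with ties counted against restriction
(they have probability ~0 with continuous distances). Flags:
restricted ⇔ q > 0.5; endemic ⇔ q ≥ 0.9 ∧ bbox ≤ 10⁶ km² (both boundaries
inclusive). The restricted threshold is exposed (`restricted_q`) because a
"smaller than expected" reading admits either a median comparison or a
significance rule; q itself is always reported so any convention can be
recovered downstream. The cohort paired t-test pairs each taxon's observed
mean with the mean of its own null draws.

Swarms whose parent occupies < 3 lakes, or which fill the parent's whole
range, have a zero-variance null; they are reported with
`untestable = True` and q = 0 rather than silently dropped.

**Reproducibility.** One master seed; each taxon's draws come from an
independent substream seeded by (master, CRC32(taxon id)), so per-taxon
results do not depend on iteration order or on which other taxa are
present. Draw generation is vectorized (argpartition over random keys)
with a 2×10⁷-element chunk cap to bound memory.

## Regional richness

Lakes are binned into half-open 2.5° × 2.5° cells anchored at (0°, 0°) so
cell edges align with multiples of 2.5° (the anchor is configurable; the
analysis is translation-covariant). Within a cell with L lakes, expected
richness of a random n-lake subset is the analytic hypergeometric
expectation S_exp(n) = Σᵢ [1 − C(L−Lᵢ, n)/C(L, n)], computed via log-gamma
(no resampling noise); a Monte-Carlo mode exists for cross-validation and
is tested to agree within 3 standard errors. The curve n = 1..L is fitted
by unweighted least squares to S = a·log(n+1) + b (natural log; base-10
switchable) and read off at n = 1. Single-lake cells use the raw richness
of their lake. Groups with fewer than 50 V9-groups overall are skipped as
too sparse for regional comparison. The fitted curve is a monotone
2-parameter family fitted to a concave non-decreasing sequence, so the
interpolated one-lake value never exceeds the cell's observed richness.

## Altitude contrasts

Mountain lakes are those strictly above 1,500 m. Richness and
microdiversity (ITS-SWARMs per V9-group per lake) are compared by
two-sided Wilcoxon rank-sum tests (exact enumeration when both samples are
≤ 8 and untied; tie-corrected normal approximation otherwise). Because the
lowland pool is much larger, exclusivity is resampled: each of 100 draws
samples |mountain| lowland lakes; the reference is the lowland lakes
outside the draw; both the mountain set's and the drawn set's exclusive
fractions are computed against that same reference. Recomputing the
mountain fraction per draw keeps the two fractions exchangeable under a
null of no altitude effect — the property the calibration experiment
checks (the mountain fraction falls in the draws' central 95% band ~95% of
the time when placement ignores altitude).

## Subpopulation ecophysiology

For every V9-group with ≥ 2 swarms that each occupy ≥ 2 lakes with a
measured value, the per-lake values (pH, conductivity µS/cm, temperature
°C, altitude m) of each swarm's lakes are compared by a tie-corrected
Kruskal–Wallis test (χ², k−1 df) followed by Dunn's pairwise z tests with
the standard tie term; for two groups Dunn's z² equals the tie-corrected H
(asserted numerically). A lake occupied by several swarms of one V9
contributes its value once per swarm. P-values are Benjamini–Hochberg
adjusted across V9-groups within each parameter at α = 0.05 by default;
`--no-adjust` gives the raw-α reading, and the calibration experiments use
raw α because the BH-adjusted rejection fraction under a global null is
not designed to equal α. All tests are rank-based and therefore invariant
under monotone transformations of the environmental variable.

## Synthetic worlds

The generator emulates the structure of a continental lake survey, not its
biology:

* **Lakes** (default 217, of which 27 mountain): placed in Gaussian "lake
  district" clusters (σ = 150 km) whose centres scatter around a
  central-European mean, with two high-altitude districts (alpine and
  pyrenean analogues) hosting the mountain lakes; coordinates are clipped
  to lon [−10, 30], lat [36, 70]. Clustering is deliberate: uniform
  placement over that box yields a mean pairwise distance near 1,700 km,
  roughly double what such surveys report, and leaves no local density for
  narrow-range taxa to occupy. The default world's mean pairwise distance
  is ~660 km.
* **Environment**: altitude U[0, 1500) / U(1500, 2800]; pH ~ N(7.5, 0.8)
  truncated to [4, 10]; conductivity log-normal (median ~245 µS/cm);
  temperature ~ N(18, 4) °C. Environmental fields are independent of
  coordinates by default so spatial and environmental signals can be
  planted and recovered separately; `env_gradient` couples pH to latitude
  for integration tests.
* **Occupancy**: truncated zeta law with the exponent solved numerically
  so that P(occupancy = 1) = 0.56, the singleton share typical of V9-group
  tables at this scale.
* **Taxon classes**: cosmopolitan (uniform over lakes), restricted
  (nearest lakes to a feasible anchor within 400 km), endemic (same with
  150 km, which bounds the box area ≤ 10⁶ km² by construction), and
  mountain-exclusive. Radius-constrained occupancies are capped by lake
  density (no anchor can host more lakes than its radius contains; the
  generator scans all anchors and errors only when none is feasible).
* **Swarms**: per V9-group, a group-dependent mean number of swarms
  (1.6–8.6 across the taxonomic profile) partitions the parent's lakes —
  geographically (random spatial direction), environmentally (parameter
  order), or randomly with a heavy first-swarm bias that keeps most later
  swarms single-lake (~64–70% singleton swarms). Each swarm may
  additionally bleed into other parent lakes with probability 0.08, since
  real subpopulations co-occur within lakes; every swarm's lakes remain a
  subset of the parent's.
* **Reads**: log-normal per presence, rescaled so per-lake totals are
  ~N(100,000, 15,000) — the depth regime in which the 0.001% per-lake
  filter corresponds to roughly one read.
* **Amplicons**: each V9-group gets a distinct random 150–170-nt sequence
  (unique 150-prefixes), each swarm a chain of ~60-nt ITS variants at
  consecutive edit distance 1 (different swarms' variants are far apart
  with overwhelming probability). Noise spikes — 1-read variants in lakes
  deep enough that they fall below the 0.001% threshold, and minority V9
  pairings of existing ITS variants — exercise the two filters that exist
  to remove exactly those artefacts.

What the generator does **not** emulate: sequencing error profiles,
chimeras beyond simple cross-pairing, spatially autocorrelated
environments, realistic sequence evolution, or abundance dynamics. Passing
recovery tests therefore demonstrate that the statistics detect the
structures they claim to detect at survey-like sparsity and scale — not
that any particular real dataset contains them.

## Problem sizes and determinism

The validation experiments use 500 taxa × 1,000 draws for type-I
calibration, 100 + 100 planted taxa for endemism recovery, 100 replicate
worlds (50 in the acceptance script) for mountain-exclusivity detection
and coverage, 400 shuffled groups for the environmental calibration, and a
217-lake, 13,000-taxon world for the end-to-end smoke run — sizes chosen
so each experiment's binomial error is small relative to the band it
checks while the whole suite stays desk-scale. All randomness flows from
explicit seeds through numpy Generators; per-taxon substreams make results
independent of iteration order, and `biogeo all` writes a manifest of
SHA-256 hashes that reproduces byte-for-byte under a fixed seed.

## Known limitations

* The restricted/endemic flags inherit the null's conditioning: they ask
  "tighter than equal-occupancy random lakes", not "tighter than expected
  given habitat preferences" — habitat-matched or spatially stratified
  nulls are out of scope.
* The chi-square approximation behind Kruskal–Wallis is coarse below ~5
  values per group (deviations of order 0.1 from the exact permutation p
  at total n = 8); with the default minimum of 2 lakes per swarm,
  borderline groups should be read through their reported p, not the
  binary flag.
* Low-occupancy cosmopolitan taxa (n ≈ 5) land inside one lake district by
  chance a few percent of the time and are then indistinguishable from
  endemics by any occupancy-conditioned test; the ~9% false-flag rate in
  the worked example is this geometry, not an implementation artefact.
* SWARM is approximated by its d=1 single-linkage growth rule only.
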