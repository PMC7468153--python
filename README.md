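# lakebiogeo

Do free-living protists have biogeography? `lakebiogeo` implements the
statistical machinery for answering that question from continental-scale
lake metabarcoding surveys: paired 18S V9 / ITS1 amplicon tables over a
network of georeferenced lakes, analysed for geographic restriction,
putative endemism, regional richness, high-mountain (azonal) diversity, and
the geographic and ecophysiological differentiation of subpopulations.

It is written for microbial ecologists working with OTU-by-site occurrence
tables at two nested resolutions: **V9-groups** (OTUs sharing an identical
first-150-bp 18S V9 sequence; a species-level proxy) and **ITS-SWARMs**
(d=1 single-linkage clusters of ITS1 variants within one V9-group; a
subpopulation proxy).

## The core statistic

For a taxon occurring in *n* lakes, let *d̄_obs* be the mean pairwise
great-circle (haversine) distance among those lakes. The null model draws
*R* = 1,000 random *n*-lake subsets (without replacement) from a reference
pool and records each subset's mean pairwise distance *d̄₁…d̄_R*. The
empirical quantile

    q = #{ r : d̄_obs < d̄_r } / R

measures how much tighter the taxon's range is than an equal-occupancy
random range. A taxon is

* **geographically restricted** when q > 0.5 (observed below the null
  median; threshold configurable), and
* **putatively endemic** when q ≥ 0.9 **and** all its lakes fit inside a
  latitude/longitude-aligned rectangle of area ≤ 1,000,000 km².

A cohort-level paired t-test compares observed vs null-mean distances
across all tested taxa. At the ITS-SWARM level the same screen runs with
the reference pool restricted to the parent V9-group's lakes, asking
whether subpopulations subdivide their species' range. Around this core sit
a 2.5° × 2.5° gridded richness analysis (analytic rarefaction per cell,
interpolated to one lake through S = a·log(n+1) + b), a mountain/lowland
exclusivity resampling (size-matched lowland draws), and Kruskal–Wallis +
Dunn screens for ecophysiological differentiation of swarms (pH,
conductivity, temperature, altitude).

Because survey-scale raw data are not shipped, the package includes a
first-class synthetic-world generator that plants cosmopolitan, restricted,
endemic, mountain-exclusive and environmentally split taxa with serialized
ground truth, so every claim the pipeline makes is testable against known
labels.

## Worked example

```
python analysis/01_simulate_world.py --seed 1
python analysis/03_geographic_restriction.py --seed 1
```

prints

```
lakes: 217 (27 above 1,500 m)
V9-groups: 4000 (56.2% single-lake)
ITS-SWARMs: 5717 (63.6% single-lake)
mean pairwise lake distance: 664.1 km (median 620.7 km)

tested 1751 multi-lake V9-groups; 2249 singletons excluded
restricted: 64.2%; endemic: 36.3%
cohort paired t: t = -20.87, p = 1.39e-86, mean obs-null = -175.6 km

by planted class (mean q / flag rates):
                        q  restricted  endemic
cosmopolitan        0.497       0.490    0.091
endemic             0.997       1.000    1.000
mountain_exclusive  0.643       0.581    0.290
restricted          0.997       1.000    0.997
```

Reading it: the world contains 217 European-style lakes (27 alpine), 4,000
V9-groups with the survey-typical 56% single-lake occupancy. Of the 1,751
taxa occurring in ≥ 2 lakes, planted endemic/restricted taxa are recovered
essentially completely (mean q ≈ 1, flag rates ≈ 1), while cosmopolitan
taxa behave exactly as the null predicts (mean q ≈ 0.5, ~9% false endemic
flags, mostly low-occupancy ranges that land in one lake district by
chance). The strongly negative cohort t says observed ranges are, on
average, 176 km tighter than equal-occupancy random ranges — driven by the
planted structure. The remaining drivers (`02_process_amplicons`,
`04_regional_richness`, `05_altitude_contrast`,
`06_subpopulation_differentiation`, `07_validation_experiments`) cover the
other stages and write their tables under `results/`.

The same stages are scriptable via the `biogeo` CLI (`biogeo synth`,
`process`, `run`, `grid`, `altitude`, `swarms`, `all`); `biogeo all` writes
every stage plus a manifest of SHA-256 content hashes that reproduces
byte-for-byte under a fixed seed.

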