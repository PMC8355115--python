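# Methods

This note documents the models, parameter choices and numerical conventions
behind `dustgeo`, and what the synthetic benchmarks do and do not show.

## Pipeline model and assumptions

The pipeline treats a dust sample as a bag of plant taxa drawn from the
flora the dust was exposed to, observed through two noisy channels: the
metabarcoding channel (OTU tables with replicate read counts) and the
biogeography channel (species occurrence records). Attribution assumes that
(i) species detected in the dust grow predominantly near the collection
site, and (ii) occurrence records are a usable proxy for where a species
grows. Both assumptions degrade for cosmopolitan species and in winter,
which is exactly what the metrics are designed to expose.

### OTU stringency filter

An OTU survives iff: total reads across replicates ≥ `min_total_reads`
(default 3), present in ≥ `min_replicates_present` of the replicates
(default 3 of 3), and relative abundance strictly greater than
`min_rel_abundance` (default 10⁻⁴). The relative-abundance denominator is
the sample's **pre-filter** read total for that marker, replicates pooled;
the original total is recorded on the filtered table so the operation is
idempotent. The boundary is strict (`>`); at the default threshold a
boundary-exact OTU is practically impossible in real data. Control
subtraction matches on exact representative-sequence identity, not OTU ids,
because control swabs are clustered independently.

### Species assignment

"100% identity" is realized as exact containment of the full OTU sequence
in a reference barcode, checking both strands (deposited strand is not
guaranteed). This is the deterministic equivalent of a 100%-identity,
full-coverage BLAST hit and avoids an aligner dependency; no gaps or
mismatches are tolerated. All matching species are retained (short
minibarcodes often cannot separate congeners); names are trimmed to
binomials with infraspecific ranks removed, placeholder taxa (uncultured /
environmental / sp.) are dropped, and an optional user-supplied synonym
table (single hop, never chained) harmonizes nomenclature with the
occurrence store. Per sample, each species is kept on at most one OTU —
OTUs are processed in descending total-read order (ties by otu_id) so the
best-supported OTU keeps the species. The ordering is a package choice; any
fixed order satisfies the uniqueness property, and read order retains the
most information in the common case.

### Occurrence store

A local Darwin-Core-style CSV stands in for a live biodiversity API.
QC drops provider-flagged records, coordinates outside valid ranges, and
the (0, 0) placeholder. Queries resolve by taxonomic serial number first,
then by binomial, and are capped at 10⁵ records; over-cap species are
uniformly subsampled with a per-species seed derived from the base seed and
a CRC of the name, making results independent of both provider order and
the order in which species are queried.

### Grid and point-to-grid surface

Equal-area cells are essential since the surface compares per-cell record
counts. Points are projected with a Lambert azimuthal equal-area projection
on the authalic sphere (R = 6371.0072 km), centred at (98° W, 39.5° N); the
default extent is a 6000 × 4000 km box of 250-km cells (24 × 16 = 384)
covering the conterminous U.S. Projection and inverse are the closed-form
spherical LAEA equations, implemented directly and verified against the
closed form and a round-trip tolerance of 10⁻⁶ km in the tests. Binning is
half-open with edge points assigned to the higher-index cell; off-extent
points are excluded. There is no land/sea mask: empty ocean cells count as
zeros in the TP denominator, which makes TP values conservative relative to
a land-only denominator.

Per OTU, records of all its assigned species are pooled **before** the
positivity threshold (≥ 2 records per cell), so two species each
contributing one record make a cell positive. OTUs with no positive cell
are unmapped and excluded from the overlay denominator.

### Mixture fit and peaks

The surface is converted to a point cloud — each nonzero cell's centroid
replicated `round(fraction × n_rep)` times (`n_rep` = 100, minimum one) —
and fitted with scikit-learn's `BayesianGaussianMixture`
(Dirichlet-process prior, `k_max` = 10 components, full covariances, fixed
seed, single initialization) so the effective number of components is
inferred. Replication rather than per-point weights keeps the fit
backend-agnostic at the cost of quantizing weights to 1/`n_rep`.
`reg_covar` defaults to (cell/4)² = 62.5² km², encoding that a component
narrower than a grid cell is not meaningful; this also keeps fits on
replicated identical points well-posed. Components below weight 10⁻³ are
reported as pruned but all components enter density evaluation.

Peaks are the five grid cells with the highest fitted mixture density at
their centroids (ties broken by (row, col)). This follows the definition of
the resolution metric as distances to the top-5 highest-likelihood grids.
Two alternative modes are provided for comparison: `local_maxima`
(8-neighborhood local maxima first, densest cells as fill) and `count`
(raw overlay fractions instead of the fitted density). The local-maxima
variant systematically promotes weak broad-background modes into the top
five whenever a sample contains wide-ranging OTUs, inflating AT5PE by
thousands of km on surfaces whose densest peak sits within one cell of the
truth site, so it is not the default.

### Metrics and decision

TP counts cells **strictly** below the truth cell's value over all 384
extent cells (ties score zero credit, so a uniform surface gives TP = 0).
AT5PE is the arithmetic mean of great-circle distances (haversine,
R = 6371.0 km) from the truth point to the five peaks. Positivity is
TP ≥ 90 (inclusive) and AT5PE < 600 km (exclusive). Samples that lose every
OTU to filtering, assignment or mapping are reported as explicit negatives
with a reason and stay in cohort denominators. Cohort summaries report
per-site and overall counts, plus the same restricted to samples with
≥ 20 mapped OTUs, with percentages to one decimal.

## Synthetic scenarios

The generator emulates the study conditions, not real aerobiology. A
species pool (default 120 species) contains 20% cosmopolitan species
(records uniform over the extent, 10× the record count of localized
species, reflecting common widespread taxa) and localized species whose
isotropic Gaussian ranges (σ ≈ 150 km, jittered ±40%) centre near the four
study sites with 120 km spread. Occurrence counts are log-normal (median
300, σ = 0.7); 5% of records carry a QC flag. Sample composition draws
species without replacement with probability proportional to each species'
range density at the truth site — the model's statement that local flora
dominates settled airborne eDNA. Reads per replicate are
negative-binomial (mean 200, dispersion 2). Each sample also receives
below-threshold OTUs (e.g. reads (1,0,0)) and contaminant OTUs mirrored
into control tables so the filters are exercised. Spring-like samples
target 30 OTUs (the study's per-marker averages of ~40 OTUs combined with
its ~38% species-level assignment rate put mapped OTUs in the 20–30
range); the winter preset scales OTU count by 0.2, forces half the OTUs to
be cosmopolitan, and draws localized OTUs with a 0.7 transported-material
fraction (weights flattened toward uniform over all sites), modelling
dormant local flora and long-range winter transport.

What passing synthetic tests show: the pipeline recovers a known source
region when ≥ 20 localized OTUs are present, degrades gracefully in the
winter regime, and never produces a confidently wrong positive. What they
do not show: performance under real taxonomic gaps in references,
nomenclature mismatches, spatially biased occurrence sampling, anisotropic
or disjunct species ranges, or real seasonal phenology — the synthetic
ranges are deliberately idealized.

## Problem sizes and numerical choices

Simulated benchmark cohorts use 20 spring-like and 12 winter-like samples
on the 384-cell grid, sizes chosen so the whole study runs in minutes on a
single core while keeping binomial noise on cohort rates modest. Mixture
fitting uses up to 500 iterations; all randomness (species pools,
occurrence draws, read counts, query subsampling, mixture initialization)
derives from explicit seeds, and two runs with the same seed produce
byte-identical result CSVs. Degenerate inputs are handled explicitly:
zero-read samples filter to empty with a warning, empty control lists are
identity, all-zero surfaces and truth points outside the extent raise named
errors, and an antipodal projection input is rejected.

## Known limitations

* The 250-km grid bounds attainable resolution; AT5PE below ~125 km is not
  meaningful.
* TP's denominator includes ocean/empty cells, inflating TP slightly for
  coastal truth sites relative to a land-masked variant.
* Exact-containment assignment is stricter than a 100%-identity local
  alignment with gaps; marginally divergent reference sequences are missed.
* The DP mixture quantizes cell weights to 1/`n_rep` and its component
  count is sensitive to `reg_covar` on near-uniform surfaces.
* Occurrence QC reduces provider flag semantics to a single boolean.
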