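# Methods

## The inference problem

Given windowed recombination maps for several species with rearranged
karyotypes, the package identifies intervals that have remained in the low
or high tail of the recombination-rate distribution across all (or all but
one) species — ancestrally low/high recombining regions, ALR/AHR — and then
characterises their gene content, pathway composition, and phylogenomic
behaviour. The comparison is carried out on a reference genome and projected
onto a reconstructed ancestral karyotype supplied as a synteny table;
computing the reconstruction itself, estimating rates from variants, and
inferring orthology or maximum-likelihood trees are all upstream of this
package and enter only as inputs.

## Rate windowing and quartile tracks

Raw rate tracks may optionally be smoothed into 2 Mb blocks on a 50 kb
sliding start grid (`sliding_average`), the standard post-processing of
machine-learned recombination maps; the synthetic generator emits map-level
tracks directly, so the pipeline default skips this step. Each chromosome is
tiled into consecutive 1.5 Mb windows (terminal windows truncated and
retained), and each window receives the unweighted mean of the source
intervals overlapping it — the common default of interval-map tooling; a
length-weighted mean is available behind a flag. Windows with no data are
missing; missing windows inside a declared recombination desert (the X
chromosome desert being the motivating case) can be zero-filled, asserting
negligible recombination rather than absent evidence.

Quartile categories are assigned **genome-wide per species**, not per
chromosome: all rated windows are sorted from highest to lowest rate, ties
broken by genomic coordinate for determinism, and split into four groups,
the remainder going to the highest categories. Q1 holds the lowest rates.
An all-tied track is legal but flagged, since its categories are then pure
coordinate artefacts.

## Conserved-region calling

Candidate regions are maximal runs of at least `min_run = 2`
coordinate-adjacent reference windows in the extreme quartile (Q1 for low,
Q4 for high). Seeding on the extreme category keeps candidates anchored to
genuine rate tails; requiring two windows suppresses one-window noise, and
matches the generator's guarantee that planted regions span at least two
windows. Each candidate is lifted through reference→species synteny; the
lifted windows are classified with the mixture rule — low set {Q1, Q2},
high set {Q3, Q4}, majority (≥ 50 % of windows) wins, an exact 50/50 tie is
ambiguous and yields no class. The fraction is counted in windows, not base
pairs, because ranking operates on windows. Note the rule does not require
the extreme itself: an all-Q2 region classifies low. A call is emitted when
at least `min_support = 3` of the species (reference included) share the
class; support is recorded. Same-class calls within 1 Mb on a chromosome
are merged (support = max of constituents; idempotent), and any residual
ALR/AHR overlap is resolved by cutting at the integer midpoint of the
overlapped interval, each class keeping its own side; a call fully contained
in an opposite-class call is dropped and logged. Manual curation present in
comparable analyses is replaced here by these deterministic rules; every
merge, drop, and tie is written to the run log so the decision surface
stays auditable.

Species lacking synteny coverage at a candidate count as `none` there.
Window slivers thinner than 1 kb produced by projection rounding are
ignored when collecting lifted categories.

## Coordinate projection

A syntenic fragment maps coordinates by linear interpolation between its
destination bounds; inverted fragments read from the far end. Results are
rounded half-up and clamped into the destination fragment, so round trips
err by at most 1 bp. The co-oriented formula is the standard one; its
extension to '−' fragments is this package's decision and is flagged in the
output provenance column. Region projection clips the query to each
overlapping fragment, projects endpoints per fragment, and reports unmapped
gaps rather than dropping them. Maps compose (species→reference→ancestor),
exactly for length-preserving fragments and to nearest-bp otherwise.

## Gene retention

LOC placeholder symbols (`LOC` + digits) are renamed when their orthogroup
contains exactly one named symbol carried by an anchor species (human, dog,
mouse by default; the synthetic pipeline anchors on its reference species)
or by at least two species; conflicting candidates or multi-orthogroup LOCs
stay unresolved. A gene's category is the category of the windows it
overlaps, majority by window count, with remaining ties broken by a seeded
uniform draw — reproducible per seed and marginally uniform over the tied
categories. The shared gene set keeps symbols categorised exactly once in
every species. Retention percentages use the two-quartile sets ({Q1, Q2}
for ALR, {Q3, Q4} for AHR), matching the region-classification sets; the
all-species intersection uses the strict single extreme quartile (Q1 / Q4).
Both definitions are parameters and echoed in the result, because either
reading is defensible and they answer different questions.

## Pathway skew

Each pathway forms a 2×2 table of pathway membership against high/low
class, over classified genes only. "Controlling for pathway size" is
implemented as this pathway-versus-rest contingency design — pathway size
enters the expected counts — tested with Pearson's chi-squared, df = 1,
without continuity correction (the plain statistic is reproducible by
hand), and corrected across pathways by Benjamini–Hochberg. Direction is
the sign of the pathway's high-fraction relative to the background's, and
is reported as `none` when the adjusted p fails α = 0.05 (configurable).
Zero-margin tables are untestable and excluded from the correction. Under a
resampling null the raw p < 0.05 rate sits at ~6 % for 30-gene pathways —
the mild discreteness of the 2×2 design, within the expected band.

## Region phylogenomics

Alignment columns with **strictly more than** 10 % missing cells
(`-`, `N`, `?`, case-insensitive; configurable) are removed — a column at
exactly 10 % is retained. Column subsampling is uniform without
replacement, deterministic per seed, and preserves genomic order. Tree
comparison matches branches by the taxon bipartition they induce on the
shared taxon set (rooting-invariant; the two root-child edges of a rooted
binary tree collapse to one bipartition with summed length) and matches
node heights — root-to-node path lengths — by identical descendant clades.
The summary reports the median B/A branch ratio. Tree inference is
delegated to an external fitter; a neighbour-joining helper over
Jukes–Cantor-corrected distances (negative branch estimates clamped to
zero) is provided and recovers a 2× simulated rate contrast to within a few
percent at 5,000 columns. Conservation scores over regions are aggregated
per base without materialising per-base arrays (overlap-weighted means and
inverse-CDF quantiles); each base counts once per region containing it.

## The synthetic generator

The generator emulates the study conditions end to end. Defaults: four
species; a six-chromosome, 199.5 Mb ancestor (63, 49.5, 39, 28.5, 12 and
7.5 Mb — the last two below the 15 Mb short-chromosome threshold); per
species 2 fissions, 1 fusion, 2 inversions; 15 planted cold + 15 planted
hot regions of 3 Mb (two analysis windows); telomere boost 3.0 with decay
length L/10; log-normal rate noise with σ = 0.25 on 100 kb tiles; 800 genes
of 10 kb; three 30-gene pathways with planted hot fractions 0.9, 0.1 and
0.5; 15 % LOC replacement outside the reference.

Design choices worth knowing:

- **Rate model.** Long chromosomes follow
  `rate(x) = base × (1 + boost × exp(−min(x, L−x) / (L/10)))`; short
  chromosomes are uniformly `base × (1 + boost)`. This reproduces the
  qualitative U-shape of real landscapes without claiming any species'
  exact form; the boost magnitude and noise level are free knobs, not
  estimates from data.
- **Planted regions** are placed on the ancestor (long chromosomes only,
  one window clear of each end, at least one window between regions so
  neighbouring calls cannot merge) and propagated through the
  rearrangements, so four-species conservation holds by construction. Cold
  regions are overwritten with draws strictly below the background's 10th
  percentile, hot regions with draws around and above its maximum, so
  planted windows rank in Q1/Q4 essentially always and, with σ = 0, every
  planted cold window ranks strictly below every planted hot window.
- **Breakpoints** snap to a 1.5 Mb lattice (the analysis window size) and
  by default avoid planted-region interiors. The lattice keeps planted
  regions window-aligned in every species, which is what makes exact-recall
  assertions meaningful; the split-region code path (warning plus
  multi-interval ground truth) remains available by disabling protection or
  applying explicit operations.
- **Fissions, then fusions, then inversions**, counts validated against
  what the chromosome count permits.
- **Genes** of a pathway with planted-high fraction f land inside a planted
  hot region independently with probability f, otherwise uniformly
  elsewhere; non-pathway genes are uniform over the whole ancestor.
  Orthologs are one-to-one by construction.
- **Toy alignments** evolve i.i.d. columns under an equal-rates four-state
  (Jukes–Cantor) process — the simplest model sufficient to test
  branch-length recovery; missing cells are injected independently.

What the generator does **not** emulate: linkage disequilibrium or
coalescent noise in rate estimates, PRDM9-style hotspot fine structure,
gene family expansion/contraction, unequal synteny-block resolution, or
assembly error. Passing the planted-recovery tests therefore demonstrates
that the calling logic is correct under landscape-scale signal and
rearrangement, not that real maps of any particular quality will yield a
given locus count.

## Determinism and numerics

Every stochastic step draws from `numpy` generators seeded from the
configuration (independent named streams per stage and species), so a fixed
configuration reproduces byte-identical outputs. Coordinates are 0-based
half-open throughout (GFF3 converted on I/O); projection rounds half-up;
quartile and classification ties resolve by genomic coordinate; gene-category
ties resolve by seeded draw. Problem sizes used by the test-suite and the
acceptance script — four ~200 Mb genomes, 20 permutation replicates,
50–100 skew seeds, 5,000-column alignments — were chosen as the smallest
sizes at which the stochastic checks are comfortably stable.

## Known limitations

- The '−'-fragment projection and the composition of synteny maps are exact
  only for length-preserving fragments; distorted fragments are nearest-bp.
- `resolve_overlaps` compares calls pairwise within chromosomes (quadratic;
  fine at realistic call counts).
- The permutation null permutes categories within species; swapping whole
  tracks between species is undefined when karyotypes differ.
- Reference choice matters: calls are emitted per reference, and
  reconciling calls across two references is left to the caller (the
  per-reference BED outputs are the supported surface).
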