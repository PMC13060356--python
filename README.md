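# ancrecomb

Tools for inferring **ancestrally conserved low- and high-recombining
regions** (ALR / AHR) of genomes from per-species recombination maps and
synteny, and for asking what those regions contain.

Recombination rate varies along chromosomes — elevated toward the ends of
long chromosomes, depressed in their middles, uniformly high on short
chromosomes — and parts of this landscape are conserved across species that
diverged over a hundred million years ago. Given windowed recombination maps
for several species, an ancestral karyotype reconstruction, and synteny
linking each genome to a reference and to the ancestor, `ancrecomb`:

1. averages each species' rate track into genomic windows (1.5 Mb default)
   and ranks every window genome-wide into rate **quartiles** Q1–Q4
   (Q1 lowest);
2. finds runs of extreme-quartile windows on a reference genome, lifts them
   through synteny to every other species, classifies each lifted region as
   *low* ({Q1, Q2}), *high* ({Q3, Q4}) or mixed (the side covering ≥ 50 % of
   the windows wins; exact ties are left uncalled), and emits an **ALR** or
   **AHR** call when ≥ 3 of 4 species agree; same-class calls within 1 Mb
   are merged and residual ALR/AHR overlaps are cut at the midpoint;
3. projects calls onto the ancestral karyotype by per-fragment linear
   interpolation: for a syntenic fragment SF mapped to ancestor coordinates,

   ```
   mapped = AncestorStart + (attr − SFStart)/(SFEnd − SFStart) × (AncestorEnd − AncestorStart)
   ```

   (read from `AncestorEnd` for inverted fragments; rounded half-up);
4. assigns genes to rate quartiles (seeded random tie-breaking for genes
   straddling a category boundary), resolves LOC placeholder symbols through
   orthogroups, and summarises per-species **gene retention** in ALR/AHR
   territory plus the strict all-species intersection;
5. tests each pathway for **skew** toward AHR or ALR gene sets with a 2×2
   Pearson chi-squared (df = 1, no continuity correction) and
   Benjamini–Hochberg correction;
6. compares trees fitted to alignments from ALR vs AHR regions (column
   missingness filtering at > 10 %, uniform column subsampling, branch
   matching by bipartition, node heights from the root) and aggregates
   per-base conservation scores (e.g. PhyloP) over region coordinates.

Because real inputs for such a study are enormous, the package ships a
first-class **synthetic-data generator**: multi-species karyotypes derived
from an ancestor by fission/fusion/inversion with exact synteny bookkeeping,
telomere-shaped recombination landscapes with planted cold/hot regions whose
cross-species conservation holds by construction, gene/pathway annotations
with controllable skew, and toy alignments evolved at contrasting rates.
Every downstream stage is exercised against this planted ground truth.

## Worked example

```python
from ancrecomb.pipeline import RunConfig, run_pipeline

results = run_pipeline(RunConfig(), "out")   # default: 4 species, ~200 Mb,
print(results["summary"])                    # 15+15 planted regions, seed 0
```

prints (abridged):

```
{'n_alr_calls': 15, 'n_ahr_calls': 16,
 'planted_recovery_rate': 1.0, 'mean_planted_jaccard': 0.989,
 'n_shared_genes': 800, 'n_alr_genes': 156, 'n_ahr_genes': 230,
 'min_retention_percent': 94.2,
 'significant_pathways': ['HM_HOT_SKEW', 'HM_BALANCED'],
 'phylo_median_branch_ratio': 2.04}
```

All 15 planted cold regions are recovered as ALR calls and all 15 planted
hot regions as AHR calls (one extra AHR call comes from a conserved
short-chromosome run — a real feature of the landscape, not an error), with
a mean Jaccard of 0.99 against the planted intervals. Gene retention stays
above 94 % in every species, the pathway planted with 90 % of its genes in
hot regions is flagged `direction=high` (BH-adjusted p ≈ 3 × 10⁻⁵), and the
branch-length ratio recovered from the toy alignment pair simulated at a
2× rate contrast is 2.04. `out/` contains the quartile tracks, call BEDs
(reference and ancestor coordinates), retention and skew tables, and a run
log recording every merge, drop, and tie decision.

The same stages are available as a CLI (`ancrecomb simulate | windows |
quartiles | call-regions | project-ancestor | genes | skew | phylo-compare |
filter-alignment | run`) operating on bedGraph/BED/TSV/GFF3/GMT/FASTA/newick
files.

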