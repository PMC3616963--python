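# Methods

`cohesim` asks a single question of a two-clade bacterial pangenome: do
the clades behave as distinct species that recombine freely within but
only marginally between groups?  It answers it with four largely
independent lines of evidence — gene-tree topology incongruence, the
dispersion of per-gene synonymous divergences, direct intragenic
recombination detection, and the ratio of recombination- to
mutation-driven substitutions — plus a gene-content comparison.  This
note records the models behind each step, the defaults and why they were
chosen, and what the bundled simulator does and does not emulate.

## The synthetic study system

All desk-scale experiments run on a fixed 6-taxon species tree with two
clades of three strains each (labelled like the *Wolbachia* supergroup-A
strains wMel/wRi/wHa and supergroup-B strains wPip/wAlbB/wNo):

```
((wRi:0.010,wHa:0.010):0.018,wMel:0.014,
 ((wPip:0.024,wAlbB:0.024):0.022,wNo:0.034):0.35);
```

Branch lengths are in substitutions/site and were set to reproduce the
divergence scales typical of such systems: pairwise distances of
0.02–0.05 within clade A, 0.05–0.08 within clade B, and ~0.3 between
clades (synonymous-site divergence between clades then lands around
0.4–0.5 after multiple-hit correction).  The within-clade internal
branches (0.018 and 0.022) are long enough that a clonal 1-kb gene
resolves its within-clade relationships with ≥95% accuracy — a
deliberate property: the topology-census contrast is only meaningful if
clonal data *can* recover the generating tree.

Sequences evolve under GTR+Γ (4 discrete categories, mean-of-quantile-bin
discretization) with mildly AT-rich stationary frequencies
(0.33/0.17/0.17/0.33) and a 4:1 transition bias, site-independent and
gap-free.  A codon-aware mode re-draws any codon column that would place
an internal stop in any taxon, so simulated genes are valid substrates
for dN/dS counting; this trims a negligible fraction of state space and
leaves pairwise divergences unchanged at the scales used.

### Recombination, two ways

*Tract replacement.*  `apply_recombination`/`plant_tract` model gene
conversion as homologous replacement: an event draws a recipient, a
donor (within or between clades), a uniform start and a geometric tract
length (means 500 bp within, 120 bp between — the within/between size
contrast the analysis is designed to exhibit), then re-evolves the tract
columns with the recipient regrafted onto the donor's pendant edge near
the present.  This produces exactly the mosaic alignments the detectors
target, at a fraction of the complexity of an ancestral recombination
graph.  A donor may also be "unsampled": the recipient is regrafted as a
basal lineage of its own clade, emulating conversion from the clade's
wider gene pool rather than from one of the three sequenced strains.

*Whole-gene history randomization.*  For the census and spread
experiments the relevant limit is *free* within-clade recombination,
where each gene effectively has its own within-clade genealogy.
`sample_gene_tree` draws, per clade and per gene, a small coalescent:
the cherry pair is uniform over the three resolutions; its coalescence
time is a two-component exponential mixture (probability 0.75 of a
"recent" time at 0.08× the clade's base time — what a fresh conversion
tract produces — otherwise a deep time, scaled so the mean matches the
species tree); the third lineage joins after an additional exponential
increment; and per-lineage lognormal rate multipliers (σ = 0.5) break
the clock.  The deep split is always retained with only mild (lognormal
σ = 0.3) length variation.  The recent-coalescence mass is the load-
bearing choice: with milder history variation (single lognormal or
exponential multipliers, or tract-level mosaicism, all of which were
evaluated) the per-gene relative-dS triples stay near their mean and the
spread statistic plateaus around 0.15–0.23, well below what freely
recombining datasets actually show.

### What the simulator does not emulate

No indels (gap handling is exercised with hand-made fixtures), no
selection, no rate variation across genes beyond the per-gene histories,
no intra-gene breakpoint structure in the randomized mode (each gene is
one history), and no sequencing or annotation error.  Passing tests
therefore demonstrate that the *inference machinery* behaves as designed
under its own generative assumptions — not that real data meet those
assumptions.

## Phylogenetics

The likelihood core is Felsenstein pruning over unique site patterns
under GTR+Γ4, gaps and IUPAC ambiguity codes as (partial) missing data,
eigendecomposition via symmetrization (exact for reversible models), and
a numba-compiled kernel.  Because the analysis never needs more than 8
taxa, tree search is exhaustive over all (2n−5)!! unrooted topologies:
every topology gets least-squares branch lengths from Jukes–Cantor
pairwise distances, and candidates are refined by per-branch Brent
coordinate ascent (bounded, with an explicit boundary comparison so
zero-length branches collapse cleanly).  Two effort levels exist: the
default refines every topology; the large census experiments rank all
105 topologies by least-squares-initialized likelihood and refine the
top 5 (one sweep, 1e-4 branch tolerance), which changed no census
assignment in side-by-side checks but is ~10× faster.  Branch-length
optimization tolerance is 1e-6 log-likelihood units; minimum branch
length 1e-8.

Gene trees are summarised two ways: branch-score weighted
Robinson–Foulds distances (sum of |Δlength| over the union of internal
bipartitions, absent = 0) feed complete-linkage clustering cut at height
1.0 — this distance is unnormalized, so the cutoff is scale-sensitive
and is surfaced as a parameter — and the 9-class census records, per
gene, whether the deep A|B bipartition is present and which cherry each
clade shows (3 × 3 classes; trees without the split, or with a
polytomy, count as incongruent).  A bootstrap support floor, when set,
is strict: a tree is counted only if *every* internal support exceeds
the floor.

## Divergence and the spread statistic

Pairwise dN/dS uses Nei–Gojobori counting: per-codon synonymous-site
fractions, observed differences averaged with equal weight over
substitution paths (stop-codon intermediates excluded when avoidable),
pairwise deletion of gapped codon columns, and Jukes–Cantor multiple-hit
correction.  Saturation and zero-synonymous-site cases are flagged, not
raised.  This is a deliberate stand-in for ML codon models: at the
divergences involved (dS ≲ 0.6) NG86 is monotone with ML estimates, and
an adapter point accepts externally computed per-pair dS tables.

For each gene and each clade trio the three pairwise dS values are
normalized to a relative triple summing to 1 and plotted in ternary
coordinates.  The *spread* is the median Euclidean distance of the
per-gene triples from their mean — computed on the raw 3-simplex
coordinates, not the 2-D plot embedding.  The two differ only by a
factor √2, but the simplex scale is the one on which the statistic's
conventional landmarks live: an "edge" gene (one pair identical, the
other two equal) lies 0.408 from the centroid on the simplex but only
0.289 in the 2-D embedding, which would put the 0.3–0.45 range quoted
for freely recombining datasets out of reach.  Note that because
per-site differences obey |S_ac − S_bc| ≤ S_ab, relative triples are
always near-metric: points crowd the edge midpoints, never the
vertices, and spreads above ~0.41 can only arise through estimator
noise.  Divergence comparisons between gene classes use the
Mann–Whitney U test (exact for small tie-free samples, tie-corrected
normal approximation otherwise).

## Recombination detectors

Four methods per gene alignment, each with permutation significance
(add-one corrected, p = (1 + #extreme)/(n_perm + 1), seeds mandatory):

* **Phi** — mean *refined* incompatibility (minimum extra state
  changes, computed as the cycle count of the bipartite partition-
  intersection graph of a site pair) over ordered pairs of parsimony-
  informative sites at most 100 informative sites apart.  Recombination
  makes nearby sites more compatible, so small observed values are
  significant.
* **NSS** — fraction of *adjacent* informative-site pairs that are
  compatible; large values significant.
* **MaxChi** — per sequence pair, a breakpoint slides over the
  polymorphic columns and a 2×2 χ² compares mismatch proportions left
  vs right; the statistic is the maximum over pairs and positions.  The
  API default uses full left/right halves (the classical test); the
  detection battery windows the halves at 70 polymorphic columns so an
  *interior* tract, which has two boundaries, retains local contrast.
* **Gene-conversion fragments** — per pair, polymorphic columns score
  +1 for a shared polymorphism and −penalty for a mismatch, with
  penalty = (total polymorphic columns) × gscale / (pair differences);
  gscale 0 makes mismatches break fragments.  Disjoint maximal-scoring
  segments (recursive Kadane) are tested against the permutation null
  of the pair's maximum segment score, Bonferroni-corrected across
  pairs ("KA" p < 0.05).  Only these global inner fragments are
  reported, with 1-based inclusive coordinates in alignment bp.  "All
  variable columns" (not just informative ones) count as polymorphisms
  in the penalty; this is the natural reading and the one implemented.

Permutation counts default to 1000 (Phi/NSS/MaxChi) and 10000
(gene conversion); experiments use 2000 for the latter where tract
counts, not tail precision, are the question.

A gene counts as recombination-positive when at least one method fires
(Phi/NSS/MaxChi at α = 0.01; gene conversion by its fragment rule), and
the ensemble tier (0–4 methods significant) mirrors the conventional
"all four methods" / "three methods" reporting.  The power claim
validated in the acceptance suite is for this battery.  The division of
labour is real and worth knowing: a conversion tract between two
*sampled* strains is nearly invisible to Phi/NSS (a handful of
conflicting informative sites against hundreds dominated by the deep
split — measured single-tract power ≈ 0–10%) and marginal for windowed
MaxChi (≈ 0.7), but is exactly the shared-polymorphism run the
gene-conversion statistic targets (power ≈ 0.95).  Tracts from
*divergent* donors, conversely, light up MaxChi/Phi.  Mean-
incompatibility statistics only reach high single-tract power when the
tract involves substantially divergent sequence, which is also the
regime in which such methods are reported to perform well elsewhere.

## r/m post-processing

Per-site posterior tracks (S = substitution, R = recombination) from any
clonal-genealogy sampler are post-processed, never produced, here: a
site is a mutation substitution when (1−R)·S ≥ 0.95, a recombination
substitution when R·S ≥ 0.95, r/m is their ratio (flagged undefined at
zero mutations), and events are maximal runs with R ≥ 0.5 throughout
containing at least one site with R ≥ 0.95.

## Orthology and gene content

All-vs-all protein similarities (from the built-in aligner at desk scale
or imported 12-column tabular hits at genome scale) are filtered — the
shorter protein must be ≥60% of the longer's length and the alignment
must cover ≥80% of the shorter — then clustered with a dense Markov
clustering implementation (column-stochastic matrix with maximum
self-loops, expansion/inflation to a fixed point, clusters = connected
components of the attractor).  Inflation defaults to 1.5 with the
sensitivity set {1.2, 1.5, 2.0} surfaced in tests; edge weight is the
bitscore.  The single-copy core is the set of clusters with exactly one
member per genome.

Clade-specific calling: a query is *present* in an outside genome if any
intact hit clears (e < 1e−5 and ≥60% of the protein aligned) or
(e < 1e−20, ≥30% aligned, ≥35% identity); a threshold-clearing hit whose
matched region is disrupted (internal stop or frameshift) makes it a
*pseudogene*; otherwise *absent*.  Coverage thresholds are inclusive
(≥), and coverage means the fraction of the query protein covered by
the hit span.  A cluster is clade-specific iff it covers exactly its
clade's genomes and every outside genome (including configured
outgroups) is absent or pseudogene.

## Numerical and procedural choices

* All randomness flows through `numpy` generators seeded from explicit
  integers; per-gene and per-method sub-seeds come from
  `SeedSequence([seed, tag])`, kept below 2³¹.
* Experiment sizes (300-gene censuses, 500-gene calibration, 200-gene
  spreads, 20-fixture gene-content recovery) are the package's standard
  desk-scale conditions; the analysis drivers use 150/200-gene versions
  of the same experiments for quick turnaround.
* Ties in tree search break on the canonical topology string and are
  flagged; MCL non-convergence returns the partial partition with a
  warning (or raises in strict mode).
* The progressive protein aligner (k-mer + neighbor-joining guide tree,
  profile-profile Gotoh merges, lexicographic tie-breaks) is a
  deliberately small self-contained component adequate for ≤10 closely
  related sequences; externally produced alignments can be imported
  whenever a production aligner is preferred.

## Known limitations

Exhaustive search caps at 8 taxa by design.  NG86 underestimates dS at
high divergence relative to ML codon models.  The gene-conversion
significance uses a permutation KA variant rather than the original
analytic option, and a pair that matches at *every* polymorphic site has
a degenerate null (p = 1): whole-gene identity is treated as relatedness,
not conversion.  The census requires exactly 3 + 3 taxa.  Spread values
are comparable only between datasets analysed with the same estimator,
since part of the statistic is estimator noise at low divergence.
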