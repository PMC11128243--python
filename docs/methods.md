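# Methods

## Quantification model

The unit of observation is a (sample, GVMAG) pair. From a per-contig depth
table (jgi_summarize_bam_contig_depths dialect) the pipeline computes, over
a genome's member contigs:

* read-depth coverage — the length-weighted mean of contig average depths,
  `Σ len_c·depth_c / Σ len_c` (reads per base);
* horizontal (breadth) fraction — `Σ covered_c / Σ len_c` in [0, 1].

Coverage is divided by the sample's library size (total reads) and scaled by
a constant, 10⁹ by default, giving "coverage per 10⁹ reads". The constant is
exposed as a parameter (`normalize(..., constant=...)`) because only its
consistency across samples matters for every downstream analysis; any fixed
scale yields identical distances, ordinations, tests and presence calls
(scale equivariance is property-tested).

Presence calling uses breadth, not depth: cross-mapping onto genes shared
between related genomes inflates depth on small genome subsets, but it
cannot cover most of a genome. Two cutoffs are wired as named products:

* 0.25 — the quantification table feeding Hellinger/Bray–Curtis/NMDS/
  PERMANOVA and UniFrac;
* 0.70 — the strict binary table feeding endemism/UpSet analyses.

Both comparisons are inclusive (breadth ≥ cutoff keeps the entry): "at
least" semantics, fixed so boundary behaviour is reproducible. Entries below
the cutoff are set to exactly zero before any transform (filter-then-
transform ordering); the strict presence set is therefore always nested in
the loose one. Contigs absent from a sample's depth export count as zero
depth and zero covered bases rather than erroring, since sparse exports are
common.

The depth dialect carries a non-standard `coveredBases` column: the stock
jgi format has no breadth information, and deriving it would require BAM
pileups, which are out of scope. Real-data users compute covered bases
upstream (e.g. `samtools depth | awk`); the synthetic generator emits the
column directly.

## Community structure

* Hellinger transform: per-sample square root of relative abundances;
  all-zero rows map to all-zero rows with a warning.
* Bray–Curtis on the transformed table; a pair of all-zero rows gets
  distance 0 with a warning.
* NMDS: Kruskal stress-1 minimized by monotone regression (SMACOF with
  isotonic regression), k = 2, 20 random starts, 300 iterations max,
  relative improvement threshold 10⁻⁶, best-of-starts returned,
  deterministic under a fixed seed. k = 2 matches standard ordination
  figures; starts/iterations are the canonical metaMDS-equivalent defaults
  and are configurable.
* PERMANOVA: one-way design, pseudo-F from squared-distance partitions
  (`SS_total = Σ_{j<k} d²/N`, `SS_within = Σ_g Σ_{j<k∈g} d²/n_g`), free
  permutation of labels, `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` with
  999 permutations by default. Ties count toward the numerator. Zero
  within-group dispersion gives F = +∞ by convention; permuted statistics
  that are also infinite count as ties, so the p-value floor 1/(n_perm+1)
  is reached only when no permutation rebuilds the degenerate split. The
  permutation loop is vectorised (one einsum over all permutations), which
  is what makes the 200-dataset calibration study run in seconds. The
  statistic is cross-checked against scikit-bio's PERMANOVA in the tests.
* Composition summaries average per-sample relative abundances within lakes
  or regions (mean of proportions, not pooled sums), which is robust to
  library-size differences; unassigned taxa form an explicit
  "undetermined" category.

## Phylogenetic comparison

Unweighted UniFrac is computed from the 25 %-cutoff presence pattern and a
rooted species tree whose tips cover every detected GVMAG (scikit-bio
backend, verified exactly against a brute-force branch enumeration oracle
on random trees). Abundance magnitudes play no role. The input tree's root
is used as-is; a multifurcating root is bifurcated with zero-length
branches, which provably leaves the metric unchanged. Genomes present in
some sample but missing from the tree are an error (silent dropping would
bias distances); a pair of empty samples is an error.

The sample dendrogram uses WPGMA ("mcquitty"): the merged cluster's
distance to any third cluster is the simple mean of its two members'
distances. Samples are processed in lexicographic label order so
equidistant merge candidates resolve deterministically to the first pair.
Exported newick branch lengths are parent merge height minus child merge
height.

Tree-inclusion filtering follows marker content: genomes with at least four
of the seven GVOG7 markers present and no marker above four copies.

## Endemism and gene content

Sample-level presence (70 % cutoff) is OR-collapsed to lakes and regions;
collapsing is associative (samples→lakes→regions equals samples→regions).
Intersection counts use exact-subset semantics — each detected genome
contributes to exactly one subset of units — and are verified against
exhaustive enumeration. Pairwise sharing is directional
(`|u ∩ v| / |u present|`), since two units of different richness share the
same set but different percentages; percentages below 0.1 % are flagged for
display but retained.

Protein clusters map to regions through each member GVMAG's *origin* lake
(the lake a genome was assembled from), not through detection: gene-content
biogeography asks where genomes carrying a gene family come from. A
cluster is region-specific if all members map to one region, and
polar-specific if its region set is a subset of {LIM, Arctic_subarctic,
Antarctic}. Presence-based region assignment remains available for
detection-based questions. The geNomad-style sensitivity re-run
(`restrict_to_viral`) drops non-viral contigs, recomputes genome lengths,
and removes genomes falling under the 75 kb catalog floor.

## Virus–host association

Counts of each eukaryote clade are binarized per clade at the mean over all
samples; a count exactly at the mean is "rare" (the strictly-above rule
needs a tie convention; this one is configurable). Features are virus
*family* sums of normalized coverage from the 25 %-cutoff table,
untransformed (a Hellinger option exists). For each clade a random-forest
classifier is fit with an mtry search starting at ⌊√p⌋, stepping by factor
1.5 in both directions and continuing only while the out-of-bag error
improves by more than 1 % relative; the final 1000-tree forest at the best
mtry supplies both the OOB error used by the reporting filter (error
strictly < 0.25, plus ≥ 1 % relative abundance in at least one lake) and
the mean-decrease-Gini importances. Edge selection keeps the top family
and up to three more with importance ≥ 0.8 × top, ties broken by family
name. The 80 % window is ratio-based, hence invariant to the importance
normalization scikit-learn applies. Degenerate (single-class) targets are
reported and skipped.

## Synthetic data: what it emulates, and what it does not

The generator plants a known biogeography: per-lake endemic pools,
within-region shared pools, and between-region shared pools (polar pairs
share more than polar–temperate pairs). Defaults give the
integration-scale community used throughout development and in
`scripts/acceptance.py`: 4 regions × 5 lakes × 2 samples (40 samples),
20 endemic genomes per lake, 15 shared per region, ~475 GVMAGs of
75 kb–2.126 Mb over 1–8 contigs, library sizes 5–50 M reads, 8 eukaryote
clades with three planted family associations, 300 protein clusters of
which 30 % are polar-specific. Presence in a home-range sample is Bernoulli
(p = 0.85, forced to at least one sample).

Key generative choices:

* Present genomes draw a log-normal genome depth (heavy-tailed coverage
  heterogeneity) and a covered fraction `0.75 + 0.25·Beta(6, 2)`. The floor
  at 0.75 means truly present genomes always clear the 70 % rule, so true
  presence is exactly recoverable and ground-truth comparisons measure the
  pipeline, not simulation shot noise.
* Absent genomes receive cross-mapping noise with probability 0.2: one
  contig partially covered, capped at 20 % of the genome, always below the
  25 % rule. The breadth filter therefore does real work (depth alone would
  miscall these), while presence remains identifiable.
* Planted eukaryote counts are Poisson with rate modulated by
  `exp(effect · z)`, where z is the min–max-scaled *rank* of the paired
  family's per-sample abundance (effect 1.5). Rank-based modulation keeps
  the association monotone in family abundance while producing balanced
  rare/abundant classes despite heavy-tailed coverage.
* Non-planted protein clusters always include at least one temperate-origin
  member. Without this, a random cluster over a 75 %-polar catalog would be
  all-polar by chance at rate ~0.75^k, and the planted polar-specific
  fraction would not be identifiable.
* The species tree is a random sequential coalescent with exponential
  waiting times — any strictly-positive-branch-length tree exercises
  UniFrac fully.

Not emulated: read-level artefacts (the generator writes depth summaries,
not FASTQ), sequence content, assembly/binning errors, uneven lakes per
region, depth–breadth correlation beyond the present/absent dichotomy, and
environmental gradients (conductivity is carried as metadata only). Tests
passing on these fixtures show the computations are correct and the
planted structure is recoverable at realistic scale; they do not show that
real lake communities satisfy the generative assumptions.

## Numerical conventions and degenerate inputs

* All threshold comparisons on breadth are inclusive; the clade-filter OOB
  rule is strict (< 0.25), and a tie at the clade mean is "rare".
* Distance matrices must be symmetric with zero diagonal; NaNs are errors
  at clustering time.
* Seeds: every stochastic stage (simulation, NMDS, PERMANOVA, forest
  tuning) takes an explicit seed and is bit-reproducible; per-clade forest
  seeds derive deterministically from the stage seed.
* Empty structures are explicit: an empty association network exports
  empty but valid files; a catalog emptied by the viral-contig restriction
  warns.

## Limitations

* PERMANOVA is one-way with free permutation; stratified designs and
  dispersion tests (PERMDISP) are out of scope.
* UniFrac is unweighted only; weighted/generalized variants and tree
  inference are not provided.
* The association stage expresses co-occurrence. With few samples the OOB
  filter is conservative (few clades pass), and correlated virus families
  can share credit for one true association — the 80 % window reports such
  families as co-explainers rather than forcing a unique attribution.
* Breadth must be supplied (`coveredBases`); the pipeline does not parse
  alignments.
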