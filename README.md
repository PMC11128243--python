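# gvlake

Biogeography of lacustrine giant-virus metagenome-assembled genomes
(GVMAGs) from read-coverage data.

Giant viruses (*Nucleocytoviricota*) are abundant in lakes, yet their
distribution across lakes and climate zones — which genomes are endemic to a
single lake, which are shared within a region, and whether a polar/temperate
barrier separates communities — is hard to measure directly. `gvlake`
implements the full coverage-based analysis chain used for this question, for
researchers who have mapped metagenomic reads from many lake samples against
a dereplicated GVMAG catalog:

1. **Quantification.** Per-sample GVMAG abundance from jgi-style per-contig
   depth tables:
   `coverage(g, s) = Σ_c len_c · depth_c / Σ_c len_c` over the member contigs
   of genome *g*, normalized by library size and scaled,
   `A_gs = coverage / N_s · 10⁹`. A genome is *present* only if its
   horizontal (breadth) fraction `Σ_c covered_c / Σ_c len_c` reaches a
   cutoff: **25 %** for distance-based analyses, **70 %** for strict
   presence/absence — this guards against reads that map onto genes shared
   between related genomes.
2. **Community structure.** Hellinger transform
   `y_gs = √(A_gs / Σ_g A_gs)`, Bray–Curtis dissimilarity, non-metric
   multidimensional scaling (Kruskal stress-1), and one-way PERMANOVA on
   region labels with 999 free label permutations.
3. **Phylogenetic comparison.** Unweighted UniFrac between samples on a
   species tree over the GVMAGs, summarized with a WPGMA ("mcquitty")
   dendrogram.
4. **Endemism.** Exact-subset (UpSet-style) intersection counts of the
   70 %-cutoff presence sets per lake and region; directional pairwise
   sharing percentages; marker-based (GVOG7) tree-inclusion filtering and a
   geNomad-style viral-contig sensitivity restriction.
5. **Gene-content biogeography.** Region distribution of MMseqs2-style
   protein clusters via each member GVMAG's origin lake, with
   polar-specificity fractions.
6. **Virus–host association.** Each 18S eukaryote clade is binarized to
   rare/abundant around its mean count and predicted from per-sample virus
   *family* abundances with a random forest (mtry tuned tuneRF-style:
   1000 trees, step factor 1.5, relative OOB improvement 0.01). Clades with
   ≥1 % relative abundance in ≥1 lake and OOB error < 25 % contribute edges:
   the top mean-decrease-Gini family plus up to three more within 80 % of
   the top importance. Edges are co-occurrence, not proof of infection.

A seeded synthetic-data generator (`gvlake.simulate`) produces complete,
internally consistent inputs — region-structured communities with endemic
and shared genome pools, depth/breadth tables, species tree, eukaryote
counts with planted virus associations, region-biased protein clusters —
with the ground truth recorded, so every stage can be validated end to end.

## Worked example

Simulate a small survey (3 regions × 2 lakes × 2 samples, ~45 GVMAGs) and
run the ordination and endemism stages:

```sh
gvlake --seed 7 --out-dir demo/fixture simulate --size small
gvlake --seed 7 --out-dir demo/out ecology  --in-dir demo/fixture
gvlake --seed 7 --out-dir demo/out endemism --in-dir demo/fixture --unit lake
gvlake --seed 7 --out-dir demo/out clusters --in-dir demo/fixture
```

prints

```
stress=0.0817 PERMANOVA F=5.391 R2=0.545 p=0.0010
                      total  unique  uniqueness_fraction
Arctic_subarctic_L01     14       6             0.428571
Arctic_subarctic_L02     14       6             0.428571
LIM_L01                  14       6             0.428571
LIM_L02                  14       6             0.428571
Temperate_L01            11       7             0.636364
Temperate_L02            10       6             0.600000
polar-specific fraction: 0.300
```

Reading this: the NMDS embeds the 12 samples at stress 0.08 (a good 2-D
fit); PERMANOVA attributes 54.5 % of community variance to the region
factor at the smallest attainable p (0.001 with 999 permutations); each
lake detects 10–14 GVMAGs of which 43–64 % occur in no other lake; and 30 %
of protein clusters are found only in polar-origin genomes — exactly the
fraction this simulation planted. TSV products (distance matrices,
ordination coordinates, intersection counts, association edge lists in SIF)
are written to `demo/out/` for plotting with UpSet/ordination/network tools.

The same stages are available as library functions and scikit-learn-style
estimators (`HellingerTransformer`, `NMDS`, `TunedRandomForestClassifier`)
for use in notebooks and pipelines.

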