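# dietniche

Seasonal diet composition and trophic-niche analysis for DNA-metabarcoding
OTU tables.

`dietniche` is aimed at wildlife ecologists who study what sympatric
herbivores eat from fecal amplicon data (e.g. trnL P6-loop metabarcoding of
sika deer, Reeves' muntjac and Chinese hare sharing a reserve). It takes
the three tables that come out of any standard read-processing workflow —
an OTU count table, a taxonomy table (BLAST/LCA-style lineage strings per
OTU) and sample metadata (species × season) — and computes:

* **diet profiles**: lowest-common-ancestor collapsing of ambiguous OTU
  assignments, conversion to relative read abundance (RRA), pooling of
  samples into one profile per species × season, top-N taxa and growth-form
  (herb/shrub/arbor) composition;
* **alpha diversity** per sample at the OTU level: bias-corrected Chao1,
  Shannon–Wiener (nats), Gini–Simpson, Pielou evenness, Good's coverage,
  with seeded rarefaction curves (median over replicate subsamples) and
  Kruskal–Wallis group comparisons;
* **community structure**: Bray–Curtis dissimilarity, non-metric
  multidimensional scaling (NMDS, Kruskal stress-1, best-of-restarts),
  within/between-group distance comparison, UPGMA dendrograms (Newick),
  and shared/specific OTU (Venn) counts per season;
* **trophic niche statistics** — the heart of the package:

```
Levins' breadth        B   = 1 / Σᵢ Pᵢ²
Hurlbert standardized  Bₐ  = (B − 1) / (S − 1)
Pianka's overlap       Q_jk = Σᵢ P_ij P_ik / √(Σᵢ P_ij² · Σᵢ P_ik²)
```

where `Pᵢ` is the proportion of food category *i* in a consumer's pooled
diet, `S` the number of categories it uses, and `Q_jk` the cosine-type
overlap between consumers *j* and *k* (`Q > 0.6` is conventionally read as
significant overlap; the test is strict).

A fully seeded synthetic-data generator (`dietniche.simulate`) emulates the
3 species × 4 seasons × 30 samples design with Dirichlet-multinomial read
noise and analytically known true profiles, so every stage of the pipeline
is testable against exact truths without any sequencing data.

## Worked example

Simulate a full study-scale dataset and analyse it:

```bash
dietniche simulate --out sim/ --seed 1
dietniche analyze \
    --otu-table sim/otu_table.tsv --metadata sim/metadata.tsv \
    --taxonomy sim/taxonomy.tsv --growth-forms sim/growth_forms.tsv \
    --out results/ --seed 1
```

The first command writes 360 samples × ~220 OTUs; the second writes the
result bundle (15 tables plus a `manifest.json` with a SHA-256 of every
output, so reruns are verifiably byte-identical). Highlights from this
exact run:

`results/niche_breadth.tsv` (one row per species × season):

```
season  species       B            S   Ba             dietary_shannon
fall    chinese_hare  3.172190177  25  0.09050792404  1.633303965
spring  chinese_hare  3.695571806  25  0.1123154919   1.570252345
```

`B` is the effective number of equally-used food genera, `Ba` rescales it
to [0, 1] given the `S = 25` genera this consumer used, and
`dietary_shannon` is the Shannon index of the pooled diet profile in nats.

`results/niche_overlap.tsv` (pairwise Pianka Q per season):

```
season  species_j       species_k        Q               significant
fall    chinese_hare    reeves_muntjac   0.0001138006095 False
fall    reeves_muntjac  sika_deer        0.9858162664    True
```

The two ruminant-like consumers overlap almost completely (Q ≈ 0.99 > 0.6)
while the hare's diet is essentially disjoint from both — exactly the
overlap structure the generator encodes (its analytic truths are written in
the dataset's `SyntheticTruth`, and the recovery test in
`tests/test_acceptance.py` checks the pipeline re-estimates Ba and Q within
±0.02 of them).

`results/alpha_diversity.tsv` gives per-sample indices, e.g.
`sd_spring_01: observed_otus 54, chao1 55.2, shannon 2.13, goods 0.99997`;
`results/nmds_coordinates.tsv` carries the 2-D ordination (stress-1 ≈ 0.16
for this dataset) and `results/upgma_groups.nwk` the average-linkage
dendrogram of the 12 group profiles.

### Input formats

All inputs are UTF-8 TSV. The OTU table has one ID column and one header
row (either orientation; see `--orientation`). Metadata columns are
`sample_id`, `species` (`sika_deer` / `reeves_muntjac` / `chinese_hare`,
case-insensitive), `season` (`spring`/`summer`/`fall`/`winter`; `autumn`
accepted). Taxonomy rows are `otu_id<TAB>lineage`, one row per candidate
lineage (repeated `otu_id` = multiple BLAST candidates; empty lineage =
unassigned). Lineage strings are either bare `family;genus;species` paths
or QIIME-style rank-prefixed paths (`k__Plantae;...;g__Rubus;s__Rubus
hirsutus`), which can start above family. The growth-form map is
`taxon<TAB>growth_form` with forms `herb`/`shrub`/`arbor`.

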