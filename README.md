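# specdelim

Integrative species delimitation for recently diverged radiations — the
kind of problem posed by allopatric populations (classically, the brown
lemur complex of Madagascar) where no single data type settles whether
hypothesized lineages are separately evolving. Under the general lineage
concept, independent evidence streams — multilocus genetics, skull shape,
pelage coloration, loud-call acoustics — are each tested for group
separation and then summarized in a concordance matrix: a lineage is
supported when several independent data types agree.

The package provides every quantitative stage as a tested, reusable
library plus a thin CLI, and a synthetic-data generator with known ground
truth so the whole chain is verifiable end to end.

## What's inside

| module | contents |
| --- | --- |
| `specdelim.syndata` | multispecies-coalescent gene trees (via msprime) with JC69 sequences; 454-style amplicon reads with MID tags, primers, homopolymer indels and two-parent chimeras (truth-labeled); landmark configurations; group-structured Gaussian feature tables |
| `specdelim.amplicon` | demultiplexing by exact MID-pair match, primer trimming, deduplication with copy counts, the three-rule filter chain (coverage < 10×, singleton indels, single-breakpoint chimeras of the top-2 variants), top-2 diploid allele calls with a full audit trail |
| `specdelim.geometry` | TPS input, generalized Procrustes superimposition (proper rotations, unit centroid size), pairwise mean-shape permutation tests |
| `specdelim.ordination` | between-group PCA with variance decomposition and a 999-randomization test, PERMANOVA with pairwise comparisons, Benjamini–Hochberg FDR, correlation pruning at \|r\| > 0.8, DAPC with the a-score |
| `specdelim.lineage` | haplotype collapsing, neighbor joining on p-distances with pairwise deletion, the genealogical sorting index (gsi) with 10,000-permutation inference and the multilocus gsiT, Evanno's ΔK |
| `specdelim.integrate` | the pairwise evidence matrix across data types, lineage-support classification, a one-command pipeline |

## The core statistic

For a group of *k* tips on a rooted gene tree, walk from each group
member toward the root and collect the *uniting nodes* — the internal
nodes of the subtree joining the group through its most recent common
ancestor. With *d(u)* the number of child branches of node *u*:

```
gs   = (k − 1) / Σᵤ (d(u) − 1)          over uniting nodes u
gsi  = (gs − gs_min) / (1 − gs_min)
```

where `gs_min` is the value when every internal node of the tree is
required. The index is exactly 1 at monophyly, 0 at maximal dispersal,
ignores branch lengths, and handles polytomies through the node degrees.
Significance comes from permuting group labels across tips; the
multilocus gsiT is the equal-weight mean across loci with one joint
relabeling of individuals per permutation replicate. All permutation
p-values in the package use the (b+1)/(B+1) convention, so 999
randomizations bound p below by 0.001.

## Worked example

```python
import numpy as np
from specdelim import syndata, amplicon, lineage, ordination

cfg = syndata.default_config(seed=4, n_groups=3, species_tree_depths=(2.0, 4.0),
                             n_individuals_per_group=4,
                             landmark_mean_shapes=syndata.default_mean_shapes(3),
                             feature_group_means=syndata.default_feature_params(3)[0])
truth = syndata.simulate_genetic_data(cfg)
reads = syndata.simulate_amplicon_reads(truth, cfg)

locus = "locus2"
sub = [amplicon.Read(r.id, r.sequence) for r in reads if r.locus_id == locus]
calls, _ = amplicon.genotype_pipeline(sub, syndata.mid_table(cfg),
                                      cfg.primer_pair, locus)

res = lineage.gsi_test(truth.gene_trees,
                       [i for i in cfg.individual_ids if i.startswith("g1")],
                       n_permutations=999, seed=4, group_label="g1")

table = syndata.simulate_feature_table(cfg)
bg = ordination.bgpca(table, n_randomizations=999, seed=4)
```

Output:

```
simulated 6670 reads across 3 diploid loci
locus2: 12 individuals called (10 heterozygous), 12/12 match the simulated truth
group g1: gsiT = 0.96 (pT = 0.005)
 locus  gsi     p
locus1 1.00 0.005
locus2 0.82 0.007
locus3 1.00 0.005
locus4 1.00 0.007
loud calls: between-group share = 0.38, randomization p = 0.005
```

Reading it: every allele call at the nuclear locus matches the simulated
truth after the filter chain; group g1 is monophyletic at three of four
loci, and its combined exclusive ancestry is significant (pT = 0.005 with
999 permutations); 38% of the acoustic-trait variance lies between groups
and the randomization test rejects the no-structure null. The pipeline
version of the same analysis (`specdelim all --config run.yaml`) ends in
`evidence_matrix.tsv` and `lineage_support.tsv`, which report per group
pair which data types separate them and whether each lineage is supported
under the stated rule.

## Documentation

`docs/methods.md` describes the models, the filter rules, the
permutation conventions, the synthetic-data assumptions, and the known
limitations.
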