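# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic data do and do not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data (`syndata`)

**Coalescent model.** Gene trees are drawn from a multispecies coalescent
(msprime) on a *ladder* species tree: group *i*+2 joins the ancestor of
groups 1..*i*+1 at `species_tree_depths[i]`. Time is measured in
coalescent units (`effective_size` generations for one haploid lineage);
`mutation_rate` is substitutions per site per coalescent unit, passed to
msprime's JC69 mutation model. Loci are independent, with no migration,
no gene flow and no within-locus recombination: chimeric molecules are
laboratory artifacts and are injected after sequence simulation, not
modeled in the genealogy. A single-rate symmetric substitution model is
deliberate — the sorting statistics under test depend on tree topology,
not on substitution-model realism.

**Defaults as study conditions.** The default configuration is seven
allopatric groups with recent, laddered divergence (split depths 0.5 to
2.0 coalescent units, which leave nuclear loci heavily unsorted while the
deeper splits sort more often), four loci — one haploid organelle-like
locus and three diploid nuclear loci of roughly intron length (288, 231,
290 bp) — per-allele read depth negative-binomial with mean 100
(comparable to deep amplicon genotyping), homopolymer indels at 0.01 per
run of ≥3 identical bases, and chimeras at 0.02 per read of a
heterozygous individual. The error rates are stated defaults, not
calibrated to any particular instrument run. Feature tables default to
six variables with group means ~3 within-group SD apart; landmark mean
shapes are a common 17-point outline with per-group displacements of
scale 0.05 (centroid size ≈ 1) and specimen noise 0.02.

**Read structure.** A read is
`fwdMID + fwdPrimer + insert + revcomp(revPrimer) + revcomp(revMID)`, all
on the forward strand (flowgram noise, quality scores and strand mixing
are out of scope). Each read carries a truth label (clean / indel /
chimera; a chimera keeps its label if it also acquires an indel), so
filter sensitivity and specificity are directly computable. MID tag
tables default to 10 forward × 10 reverse combinations assigned to
individuals in row-major order; requesting more individuals than
combinations is a configuration error.

**What passing tests show.** The generators reproduce the statistical
structure the analysis assumes — group-structured Gaussians, isotropic
landmark noise, exact-copy amplicon errors. They do not reproduce real
measurement pathologies (heteroscedastic acoustic variables, correlated
landmark digitizing error, PCR bias, strand-specific errors), so green
tests certify the machinery, not robustness to every field artifact.

## Amplicon allele calling (`amplicon`)

Demultiplexing requires an **exact** MID-pair match (no edit-distance
rescue) and both primers: the forward primer at the 5′ end of the
de-tagged read and the reverse complement of the reverse primer at its 3′
end; failures get per-read reason codes (`too_short`, `mid_mismatch`,
`primer_missing`). The minimum read length defaults to combined tag +
primer length + 50.

The filter chain runs in a fixed order; coverage first minimizes
alignment cost, and the chimera test last uses the individual's post-filter
top-2 variants:

1. **Coverage** — variants under 10 copies (configurable) are removed.
2. **Singleton indels** — all surviving distinct sequences of a locus are
   aligned to the locus's most frequent sequence with Biopython's global
   affine aligner (match 1, mismatch −1, open −4, extend −1). Indel
   events are keyed by reference coordinate; any sequence carrying an
   event supported by exactly one distinct sequence in the whole locus is
   removed. Removal iterates to a fixed point, because discarding one
   sequence can orphan an indel another sequence shared — the fixed point
   makes the chain idempotent. The reference-anchored event set stands in
   for a full multiple alignment; the reference itself (zero events) is
   never removed by this rule.
3. **Chimeras** — per individual, a variant is removed if it equals, for
   some single breakpoint, a prefix of the highest-coverage variant
   concatenated with a suffix of the second-highest (or vice versa).
   Exact equality is the default for determinism; a ≤*k*-mismatch
   relaxation is available behind `chimera_max_mismatch`.

Calling takes the two highest-coverage survivors as the alleles
(heterozygote), one survivor as a homozygote — the standard diploid
reading of the one-variant case — and none as no-call. A coverage tie
between ranks 2 and 3 is broken lexicographically and flagged in the
audit. The audit accounts for every variant not retained, and kept +
discarded reads equal input reads at every stage.

## Procrustes superimposition (`geometry`)

Full generalized Procrustes: every configuration is centered, scaled to
unit centroid size (scale is not re-estimated per iteration), and rotated
to the running consensus with **proper rotations only** (the morphometric
convention; reflections would equate mirror-image shapes). Convergence is
declared when the consensus moves < 1e-10 in Frobenius norm (max 100
iterations). Degenerate configurations (coincident landmarks) are
rejected by specimen name. The pairwise mean-shape statistic is the
squared Procrustes distance between group mean shapes of the jointly
aligned coordinates, with labels permuted within the pair; the aligned
coordinates feed `ordination.bgpca` unchanged as 2k flattened variables.
The choice of statistic is this package's own — other shape-testing
statistics exist and need not give identical p-values.

## Ordination and inference (`ordination`)

**bgPCA.** Variables are centered and by default standardized to unit
variance (appropriate for heterogeneous units; disable for Procrustes
coordinates). Axes are the principal axes of the group-means matrix
weighted by group size — the classical between-group analysis — and
individuals are projected onto them. The between-group share is the
size-weighted variance of group means over total variance; its
randomization test permutes group labels.

**PERMANOVA.** Pseudo-F from the Gower partition of squared Euclidean
distances (among-group mean square over within-group mean square), by
default on the leading bgPCA scores (4 components for acoustic-style
tables, 2 for color-style, both configurable). The permutation comparison
uses the among-group sum of squares, which is monotone-equivalent to
pseudo-F under permutation (total SS is invariant) and stays finite when
within-group variance is zero; the reported pseudo-F is `inf` in that
degenerate case. Pairwise tests reuse the machinery per pair, skip
singleton groups with a warning, and attach BH-FDR-adjusted p-values.

**Permutation conventions.** Monte-Carlo p-values are (b+1)/(B+1), never
zero, with B = 999 as the default randomization count (matching the
bgPCA convention; the floor is then 0.001). Random relabelings are drawn
uniformly, so on very small permutation spaces a redrawn identity can tie
the observed statistic; every test here also offers `method="exact"`,
which enumerates all distinct relabelings and returns the exact tail
proportion (identity included, so p > 0). Exact enumeration is
implemented for two-group comparisons, which is where it is used.

**DAPC.** PCA reduction (default 6 components) followed by linear
discriminant analysis (default 5 discriminant functions, capped at
groups − 1); posteriors come from an equal-covariance Gaussian classifier
in the discriminant space, so memberships sum to 1 per individual. The
a-score — observed correct-reassignment proportion minus its mean under
group-label permutation — guards against retaining too many components
and can drive the choice of that number over a grid.

**BH-FDR** delegates to statsmodels' step-up implementation; inputs are
validated to [0, 1] and order is preserved. **Pruning** walks columns
left to right and drops any with |Pearson r| > 0.8 against an already
retained column (deterministic in column order); constant columns are
dropped with a warning. Aggregation of repeated measurements to
individual means is a loader concern
(`GroupedFeatureTable.from_measurements`), not a statistical operation.

## Genealogical sorting (`lineage`)

The gsi formula is given in the README. Choices worth recording:

* **Uniting set** — internal nodes on the paths from group tips to their
  MRCA (the spanning subtree through the MRCA), found by parent walks;
  the test suite checks the same quantity against an independent
  leaf-set-scan oracle.
* **Normalization** — min-max: 1 exactly at monophyly (the numerator
  `k − 1` equals the uniting-node degree sum if and only if the group is
  a clade), 0 when every internal node is needed. A star tree (single
  internal node) is degenerate and returns 1.
* **Rootedness** — the statistic is defined on rooted trees only;
  unrooted input without an outgroup is rejected. Polytomies are allowed
  and enter through node degrees. Branch lengths are ignored.
* **gsiT** — equal-weight mean of per-locus values (no locus weights);
  its permutation relabels *individuals* once per replicate, applied
  jointly to all loci (tips are matched to individuals by the `_a<j>`
  allele suffix). Joint relabeling preserves the across-locus dependence
  of the null; per-locus p-values come from the same replicates.

Neighbor joining uses p-distances with pairwise deletion (sites with a
gap or non-ACGT base in either sequence are ignored per pair; a pair with
no comparable sites is an error naming the pair); the agglomeration is
scikit-bio's NJ, with optional outgroup rooting. Haplotype collapsing is
exact string identity, case-insensitive, with `N` and gaps treated as
literal characters (documented policy: two sequences differing only at an
N site are distinct haplotypes); ids are assigned by descending frequency
then lexicographic order. Evanno's ΔK is the absolute second difference
of mean lnP across K over the among-run SD at K; an SD of zero is an
explicit error, and the statistic is only defined for interior K with
both neighbors present and ≥2 runs.

## Concordance (`integrate`)

Each data type contributes FDR-adjusted pairwise p-values; genetics
contributes per-group gsiT significance, and a pair's genetic cell is
significant only when **both** groups show significant exclusive ancestry
(a pair-level reading of a per-group statistic, chosen so the genetic
column is comparable with the pairwise columns). α = 0.05 on adjusted
values by default. Missing data types are marked unavailable, never
imputed. The support rule — significant in ≥2 independent data types
against every neighbor, with "every other group" as the default neighbor
set — is a package default printed with every output, configurable via
`classify_lineages`. Raw and adjusted p-values are both stored so any
other rule can be re-applied.

The pipeline (`run_pipeline`, CLI `specdelim all`) validates all named
inputs before computing, writes every intermediate table, and logs
version, seed and thresholds; with a fixed seed the statistical outputs
are byte-identical across reruns.

## Problem sizes in the test suite

The suite favors many small, exactly checkable instances: exhaustive
permutation oracles run on ≤8 observations (70 or fewer relabelings),
the gsi oracle on ≤8-tip trees, type-I simulations on 200 replicates of
99 permutations each, and monotonic-sorting checks on 100 replicate loci
per depth at three depths. These sizes were chosen to make the oracles
exhaustive and the Monte-Carlo bands tight (3 binomial SE), not to
stress throughput.

## Known limitations

* The coalescent generator has no migration or hybridization, while real
  recently diverged groups may exchange genes; gsiT significance under
  gene flow is untested here.
* The singleton-indel rule is reference-anchored rather than a true
  multiple alignment; pathological loci where the most frequent sequence
  is itself aberrant would mis-key events.
* Exact permutation enumeration covers two-group designs only.
* DAPC's a-score optimization refits one LDA per candidate and
  permutation, which is quadratic-ish in the grid size; it is meant for
  the modest dimensionalities of delimitation datasets.
* The landmark pipeline is strictly 2-D; no semilandmarks, no allometry
  correction.
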