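# Methods

This note records the models, conventions and numerical choices behind
`mitoconcord`, in the places where a different reasonable choice existed.

## Trees and topology metrics

Trees are read from Newick (NEXUS trees blocks are accepted read-only).
Node support lives in the internal-node *label*, the MrBayes/IQ-TREE
consensus convention; a bracketed-comment convention is also accepted at
parse time and normalised to labels. The support scale is auto-detected per
tree (all values ≤ 1 → posterior probability, otherwise bootstrap percent).

Root handling follows what each metric means on a consensus tree:

- *Polytomy branches*, *bifurcating nodes* and *mean node support* use the
  rooted orientation as given. A fully resolved rooted tree on n leaves has
  n−1 bifurcating internal nodes (root included); this is the reading that
  makes a resolved 51-taxon consensus yield 50.
- *Bipartition-based* quantities (RF, concordance factors) unroot first: the
  two edges meeting a degree-2 root describe the same split and are merged.

Mean node support averages only the nodes that carry an annotation —
consensus polytomies contribute nothing rather than zero. A tree with no
annotated node raises an explicit error instead of returning 0.

RF distance is the plain symmetric-difference count over nontrivial splits,
with no normalisation and no requirement that trees be binary; comparing a
poorly resolved tree against a resolved one simply counts the splits each
has that the other lacks (this is what makes odd values possible).

## Alignment metrics

Parsimony-informative: a column with at least two unambiguous nucleotide
states each present in at least two sequences. Gaps **and** IUPAC ambiguity
codes are treated as missing data, never as states (the PAUP*/IQ-TREE
convention; toolchains differ here, so the choice is declared rather than
inferred). SIC = 1000·PI/length, reported to 2 decimals.

Distances use pairwise deletion — rRNA-style gap-rich alignments would lose
most of their columns under complete deletion. Corrections: JC69
(d = −¾ ln(1 − 4p/3)), K80 and TN93 closed forms; an optional gamma-rates
generalisation of JC69 replaces each −ln(w) term by a·(w^(−1/a) − 1) for
shape a. Pairs at or past a model's validity bound (JC: p ≥ ¾) become NaN
with a logged count, never 0.

## Neighbour joining

Saitou–Nei agglomeration with the Studier–Keppler Q-criterion; ties in Q
break at the lowest (row, column) index pair, so dendrograms are identical
across platforms. Negative estimated branch lengths are clamped to zero and
the clamped total logged. On additive matrices the algorithm is exact —
that exactness is property-tested, because it is what makes the
RF-dendrogram-of-topologies trustworthy.

## Concordance factors

gCF of a reference branch = 100 × (gene trees whose split set contains the
branch, after restricting it to the taxa that gene tree has) / (gene trees
decisive for it — both restricted sides retain ≥ 2 leaves). With complete
taxon overlap all gene trees are decisive.

sCF samples `n_quartets` quartets per branch (default 100), one leaf drawn
uniformly from each of the four subtrees surrounding the branch, from a
mandatory seed. A column is decisive for a quartet when all four leaves
show unambiguous bases in a clean two-state 2+2 pattern; it then supports
exactly one of the three quartet topologies. sCF is the mean over decisive
quartets of the percent of decisive sites siding with the reference;
quartets with no decisive site are skipped and counted. Subtree order and
branch orientation are derived from leaf labels, not memory layout, so
results are bitwise reproducible across processes.

## Likelihoods and the SH test

GTR+I+G: the reversible rate matrix is scaled to one expected substitution
per site; transition probabilities come from the eigendecomposition of the
symmetrised matrix (valid stochastic matrices at any branch length).
Discrete gamma uses 4 categories by default with mean-of-quantile-interval
rates; with a proportion of invariant sites p_inv, the variable classes are
rescaled by 1/(1−p_inv) so the overall mean rate stays 1. Gaps and
ambiguity codes enter the pruning as partial states (all compatible bases
equally likely). Model parameters are supplied by configuration — the
defaults are empirical-frequency GTR with shape and p_inv set by the user —
rather than estimated by joint maximum likelihood, which is the province of
dedicated inference software and out of scope here.

Branch lengths are optimised per topology by coordinate-wise bounded scalar
search (bounds 1e−8 to 20, xatol 1e−6), sweeping until the total
log-likelihood improves by less than `tol` (default 1e−3); the search warns
rather than fails if the sweep budget (20) runs out.

The SH test uses RELL with B = 1000 replicates by default and a mandatory
seed: site log-likelihood columns are resampled by multinomial weights,
each tree's replicate totals are centred on their own replicate mean, and
p(tree) is the fraction of replicates whose centred deficit from the
replicate-best tree reaches the observed deficit. The maximum-likelihood
tree gets p = 1 by construction. Fewer than 100 replicates is refused
unless explicitly overridden. Which alignment a tree set is tested on is an
explicit argument; the pipeline default tests every topology against the
full concatenated alignment.

## Saturation regression

Uncorrected p-distance (response) is regressed on corrected distance
(predictor) by OLS with a **free intercept** (forcing the origin was the
other defensible choice; slope and intercept are both reported so either
reading is available). Pairs with undefined corrections are excluded and
counted; a partition whose exclusions exceed 25% of pairs (configurable) is
skipped entirely rather than reported with an inflated slope. An alignment
with no divergence raises an error instead of reporting slope 0.

## Sequential ANOVA

RF distance is decomposed by Type-I (sequential) sums of squares in the
fixed order saturation slope → alignment length → length×PI interaction;
the order matters and is configurable with that caveat. Topology-derived
metrics (polytomies, bifurcating nodes, mean support) are deliberately
excluded as predictors because they are intrinsically linked to RF
distance. The reference row is excluded; incomplete rows are dropped; a
constant predictor is an error naming the term.

## The simulator

The generator emulates the structure of a partitioned mitogenome study:
Yule or birth–death trees (optionally rescaled to a target root height),
GTR+I+G site evolution with per-partition rate multipliers, and a default
configuration of 51 taxa and 15 partitions whose lengths span 168 bp (ATP8)
to 1,840 bp (ND5) plus both rRNAs — the input shape of a real mitogenome
panel. All randomness flows from one mandatory seed. Two deliberate
idealisations: no indels (alignments are simulated aligned; gap handling is
exercised through hand-built fixtures instead) and no heterotachy or codon
structure. Passing tests therefore demonstrate correctness of the
machinery, not robustness to alignment error in real data.

`min_branch_length` optionally floors branch lengths after height scaling.
Yule trees regularly contain internal edges of length ~1e−3 and below; at
realistic alignment lengths such splits are unidentifiable (fewer than one
expected substitution on the edge), and recovery experiments that include
them measure luck, not estimator quality.

`make_concordance_fixture` produces gene-tree sets in which designated
branches appear in exactly round(fraction × n) trees; elsewhere the branch
is collapsed and the polytomy re-resolved at random, with resolutions that
would recreate a forbidden split rejected. gCF on such a set recovers the
requested percentages exactly, giving a ground-truth fixture for the
concordance machinery.

## Reference experiments and problem sizes

Two canned experiments (`mitoconcord.experiments`) fix a reference regime:

- **Length versus recovery** (12 taxa; partitions 150–4,800 bp; mild
  transition-biased GTR, gamma shape 0.5; root height 0.7 with internal
  edges floored at 0.03; NJ on gamma-matched JC distances; 20 replicates).
  Height and floor were chosen so that the question is identifiable: deep
  enough that short genes err, shallow enough that corrected distances stay
  defined, and with no near-zero splits that no alignment length could
  resolve. The gamma-matched correction keeps the distance estimator
  consistent with the generating process — with plain JC distances the
  correction bias does not vanish with alignment length and the
  concatenation stops dominating, which would measure estimator
  misspecification rather than marker information content.
- **SH calibration** (6 taxa, 400 bp, gamma shape 0.7, height 0.4, 500 RELL
  replicates, 100 runs): the test's type-I error against a one-NNI
  alternative. The SH test is known to be conservative, and the observed
  rejection rate at the 5% level is well below nominal.

These sizes keep the whole suite and both experiments in the minutes range
on one CPU; all knobs accept larger values.

## Known limitations

- Branch-length optimisation re-evaluates the full pruning per proposal
  (no partial-likelihood caching); fine at experiment scale, slow for
  likelihood work on dozens of taxa — which the pipeline's SH configuration
  acknowledges by being switchable per run.
- TN93 uses empirical base frequencies pooled over the whole alignment, not
  per pair.
- gCF treats every input tree as an independent vote; it does not weight by
  gene length or support.
- The NJ estimator is a recovery-experiment tool, not a substitute for
  likelihood or Bayesian inference on real data.
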