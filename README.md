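# mitoconcord

Tools for asking a practical phylogenetics question: **how well do single
mitochondrial genes reconstruct the phylogeny you would get from the whole
mitogenome?** Short Sanger-era gene fragments (ND2, COI, 16S, ...) dominate
public sequence repositories, and whether they are adequate proxies for
mitogenome-scale data decides whether decades of accumulated single-gene data
remain useful. `mitoconcord` takes one reference tree (e.g. the mitogenome
consensus) plus one tree and alignment per gene, and quantifies, per
partition, how much topology and information each marker carries — with a
built-in simulator so the whole pipeline can be exercised end-to-end on
synthetic data shaped like a real 51-taxon, 15-gene mitogenome study.

## What it computes

For gene trees T₁…Tₖ against a reference tree T*:

- **Robinson–Foulds distance** RF(Tᵢ, T*) = |S(Tᵢ) Δ S(T*)|, the symmetric
  difference of nontrivial bipartition (split) sets after unrooting; plus the
  full pairwise RF matrix and its **neighbour-joining dendrogram of
  topologies** (Saitou–Nei with the Studier–Keppler Q-criterion, exact on
  additive matrices).
- **Per-tree resolution metrics**: branches emanating from polytomies,
  fully bifurcating node count (n−1 for a resolved rooted tree on n leaves),
  and mean node support over annotated nodes only.
- **Alignment informativeness**: parsimony-informative (PI) sites (≥2 states,
  each in ≥2 sequences; gaps/ambiguities are missing data) and
  **SIC** — standardized information content = PI sites per kilobase.
- **Concordance factors** on every internal branch of the reference: gCF
  (percent of decisive gene trees containing the branch) and sCF (mean
  percent of decisive sites supporting the branch's quartet topology over
  seeded quartet samples).
- **Saturation**: OLS slope of uncorrected p-distance on model-corrected
  distance (JC69/K80/TN93, optional gamma-rate correction); the lower the
  slope, the more saturated the marker.
- **SH topology test**: Shimodaira–Hasegawa with RELL resampling over
  per-site log-likelihoods under GTR+I+G (Felsenstein pruning,
  discrete-gamma rates, branch lengths optimised per topology).
- **Sequential ANOVA** decomposing RF distance into saturation, alignment
  length and a length×PI interaction.

## Worked example

The packaged demo simulates a 12-taxon, 6-partition dataset (150–900 bp
genes, GTR+G), estimates NJ gene trees and runs every stage including the
SH test (about a minute on one CPU):

```bash
mitoconcord run -c configs/demo.yaml
```

`results/demo/summary.csv` then starts:

```
partition,polytomy_branches,saturation_slope,mean_node_support,bifurcating_nodes,alignment_length_bp,pi_sites,sic,rf_from_reference,sh_p_value
reference,0,0.624,,11,3150,1686,535.24,0,1.0
g150,3,0.682,,9,150,68,453.33,4,0.002
g300,3,0.624,,9,300,161,536.67,0,0.881
```

Read: the reference (the tree the data were simulated on) is fully resolved,
at RF 0 from itself, with SH p = 1 by construction. The 150 bp partition
lands 4 splits away from the truth and is firmly rejected by the SH test
(p = 0.002), while already at 300 bp this replicate recovers the topology
exactly (RF 0, p = 0.881). The other deliverables land beside it:
`rf_matrix.csv`, `dendrogram.nwk`, `concordance.csv`,
`reference_annotated.nwk` (gCF/sCF as node comments), `length_vs_rf.csv`,
`saturation/*.csv`, `sh_test.csv`, `anova.csv` and `run.log`.

The `analysis/` scripts run the same machinery as a narrative study at full
scale — `01_simulate_study.py` (51 taxa, 15 partitions, 14 kb),
`02_congruence_summary.py` (summary table, dendrogram, concordance, ANOVA),
`03_length_vs_rf.py` and `04_sh_calibration.py` (replicated experiments).
On the default seed, the full-scale ANOVA finds alignment length explaining
RF distance (F = 17.05, p = 0.002) with no saturation effect (p = 0.11),
and the recovery experiment gives a negative length–RF correlation in 20/20
replicates with the concatenation attaining the minimum RF in 19/20.

## Scope

The pipeline consumes trees; it does not infer them (beyond the
distance-based NJ estimator used for simulation experiments). ML/Bayesian
tree inference, model selection, consensus-tree construction and figure
rendering are deliberately out of scope — all outputs are plain CSV and
Newick from which figures can be drawn.
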