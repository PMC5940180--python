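# phosphonet

Inference of stress-activated phospho-signaling subnetworks from
quantitative phospho-proteomics and a background protein-interaction
network.

## The problem

A cell responding to an acute stress (the motivating system is budding
yeast shifted into 0.7 M NaCl) rewires phosphorylation across thousands of
sites within minutes. Mass spectrometry measures those changes as
per-peptide fold-change ratios, and knockout of a candidate regulator
(e.g. the Hog1 kinase, the PKA-regulating phosphodiesterase Pde2, or the
Cdc14 phosphatase) reveals which changes depend on it — but neither
experiment says *how* the signal travels from regulator to site.
`phosphonet` reconstructs that wiring:

1. **Responsiveness and dependency calls.** A peptide is stress-responsive
   if it changes ≥1.5-fold in 2 of 3 early replicates, in both late time
   points, ≥2-fold in a single late time point, or is flagged significant
   by an external count-based test. Mutant-vs-wild-type ratios call each
   responsive site *defective* or *amplified* per regulator (1.3-fold in
   both replicates or 1.5-fold in a single one; 1.15/1.3 for the milder
   cdc14 allele).
2. **Submodules.** Responsive peptides are partitioned by direction of
   change, then by phosphorylation motif (an iterative motif-x style
   binomial extraction against the background proteome: width 13, ≥10
   occurrences, p < 1e-6), then by mutant-dependency signature. Each
   (direction × motif × dependency) set is a *submodule* — the unit the
   network must explain.
3. **Shared interactors (SIs).** For each submodule, proteins with more
   interaction-network neighbours among its constituents than chance
   predicts (hypergeometric upper tail, BH FDR < 0.05) are attached by
   directed input/output edges. This tolerates missing interactions: the
   SI need not touch every constituent.
4. **ILP subnetwork selection.** All acyclic paths of ≤3 edges
   (submodule-to-constituent hops are free) from each interrogated source
   regulator to its dependent submodules are enumerated, and a binary
   integer linear program selects paths by a four-stage lexicographic
   objective: maximize connected source–submodule pairs, then included SI
   edges, then minimize non-source/non-submodule/non-SI intermediates,
   then maximize selected paths. Each stage's optimum is pinned before the
   next runs (HiGHS via `scipy.optimize.milp`).
5. **Ensemble and consensus.** The ILP is re-solved with a 5% random
   holdout of the previous solution's intermediate nodes; paths present in
   ≥75% of solutions form the consensus, every node and edge carrying its
   ensemble frequency as confidence. No-phenotype submodules whose SI
   landed in the consensus are re-attached with a direct SI edge.
6. **Annotation and evaluation.** Module position-weight matrices are
   matched against kinase specificity PWMs by Kullback–Leibler divergence
   with a column-permutation null; networks are scored by precision/recall
   against a true-positive regulator list and against degree-preserving
   scrambled backgrounds.

A fully seeded synthetic-data module plants source → kinase → target
cascades with motif-bearing windows, log-normal replicate noise, knockout
propagation and a thinned/decoyed background network, so every stage is
testable without downloads.

## Worked example

Simulate a scenario (2 sources, 3 kinases, 60 targets), build submodules,
find shared interactors, and infer the consensus network:

```sh
phosphonet --seed 11 --outdir demo simulate --n-targets 60
phosphonet --seed 11 --outdir demo submodules --wt demo/wt.tsv \
    --mutant src1=demo/mutant_src1.tsv --mutant src2=demo/mutant_src2.tsv \
    --proteome demo/proteome.fasta
phosphonet --seed 11 --outdir demo si --network demo/network.tsv \
    --submodules demo/submodules.tsv
phosphonet --seed 11 --outdir demo infer --network demo/network.tsv \
    --si-edges demo/si_edges.tsv --submodules demo/submodules.tsv \
    --sources SRC1,SRC2 --iterations 50
```

which prints `consensus: 8 nodes, 6 edges` and writes, among others,
`si_edges.tsv`:

```
si    submodule     role   N    K   n   k   p            q
KIN3  M0.inc.src1-  input  465  15  22  15  2.72674e-23  2.72674e-23
KIN1  M1.inc.src1-  input  465  12  20  12  6.81279e-19  6.81279e-19
KIN2  M2.dec.src2-  input  465  14  20  13  1.66018e-19  1.66018e-19
```

— each planted kinase is recovered as the shared interactor of its own
submodule (k of its n network neighbours sit among the submodule's K
constituent proteins, out of a 465-protein universe) — and
`consensus_nodes.tsv`:

```
id            role                confidence
KIN1          shared-interactor   0.98
KIN2          shared-interactor   0.98
KIN3          shared-interactor   0.98
M0.inc.src1-  submodule           0.98
...
SRC1          source              1
```

so the consensus consists of the two sources, the three planted kinase
intermediates (each present in 98% of the 50 ensemble solutions) and the
three dependent submodules. Scoring against a regulator list containing
the kinases plus a decoy (`evaluate --tp-list ...`) yields the PR point
`precision 1.0, recall 0.75` for the maximal-confidence group.

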