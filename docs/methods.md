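# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of `phosphonet`, in the spirit of a
package methods appendix. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Phospho-site positions are 1-based residue indices; sequence windows are 13
residues labelled −6…+6 with the phospho-acceptor (S or T) at 0. Windows
truncated at protein termini are padded with `_`, which is excluded from
every count, frequency and PWM normalization — a padded position simply
carries no sequence information. A peptide with several localized sites
becomes one measurement per site sharing the quantification, because motifs
and kinase specificities are properties of sites, not peptides. All
fold-changes are linear ratios; "changed ≥ f-fold" always means ratio ≥ f
or ≤ 1/f. Interchange files are tab-separated UTF-8 with a mandatory
header and `#` comment lines; the network writer records isolated nodes as
`#node` lines so that read(write(x)) reproduces node and edge sets exactly.

All randomness descends from a single seed in `RunConfig`; each component
(ensemble, permutation null, scrambling, simulation) draws from its own
CRC-derived substream, so reruns are bit-reproducible and components do not
perturb each other when one changes its number of draws.

## Selection rules

Wild-type responsiveness fires on any of: external significance flag
(stand-in for a count-based replicate test at FDR < 0.05, consumed, not
re-implemented); ≥1.5-fold in ≥2 of 3 early replicates *in the same
direction*; both late time points ≥1.5-fold in the same direction; one late
time point ≥2-fold. The call's direction is the shared sign of the firing
rules; if two rules fire in opposite directions the peptide is excluded as
`ambiguous-direction` with a warning — the upstream analysis this models
does not specify a resolution, and silently picking a side would corrupt
motif grouping.

Mutant dependency is judged on the mutant-vs-wild-type ratio of the stress
response, against the wild-type direction: a change reproducibly *smaller*
in the mutant is defective, reproducibly *greater* is amplified. Two or
more replicates must all pass the dual threshold (1.3; 1.15 for the milder
cdc14 allele); a single detection must pass the stricter single-replicate
threshold (1.5; 1.3). Mixed-direction replicate evidence is `none` —
"reproducible" is taken literally. Mutants not named in the configuration
fall back to the 1.3/1.5 pair.

## Motif discovery

Greedy iterative extraction over (position, residue) pairs: the binomial
upper tail P(X ≥ k) of the foreground count k against the background
residue frequency at that position, restricted to currently matching
windows, with acceptance requiring p < 1e-6 and k ≥ 10 (width 13). Ties
break by larger foreground count, then position ascending, then residue
alphabetical, making extraction deterministic. S- and T-centred runs are
separate; motifs with identical constraint sets merge into one S/T motif.
If a residue is absent from the background at a position its frequency is
floored at 1/(n_bg + 1) rather than 0, so no constraint is accepted on the
strength of a degenerate p = 0. Matched windows are removed before the
next motif starts, so motif membership is disjoint by construction, and a
peptide keeps its discovery-time assignment.

The test for this stage depends on the background dwarfing the foreground:
when planted sites are an appreciable fraction of the background, the
conditional background frequencies absorb the planted signal and secondary
constraints fail the threshold. This mirrors real usage, where the
background is a whole proteome; the synthetic generator therefore defaults
to a 400-protein decoy proteome around the ≤60 foreground sites.

## Shared interactors

Universe N = all nodes of the background network; K = submodule
constituents present in the network (absent constituents dropped with a
warning); n = candidate's distinct interaction partners (multi-edges count
once; a candidate that is itself a constituent never counts itself);
k = partners among constituents. p is the exact hypergeometric upper tail,
BH-corrected *within* each submodule (SIs are defined per submodule;
pooling would couple unrelated tests — a `global` scope is available).
Candidates need k ≥ 2: a single shared neighbour cannot be "more
interactions than expected" and only inflates the correction burden
(switchable to 1). An SI's edge is an *output* (submodule → SI) only when
every SI–constituent interaction is directed toward the SI; any undirected
or SI-directed interaction makes it an *input*, the permissive default,
since undirected records may be unrecognized directed ones.

## Kinase-specificity matching

Module PWMs: residue counts per position plus 1 pseudocount, normalized;
kinase array intensities: (intensity + 0.01)/Σ per position, so undetected
residues keep strictly positive probability — KLD requires q > 0
everywhere. The score is D(module ‖ kinase) in bits over the positions
both matrices cover: the module is the observed data and the kinase the
model; direction and base are this package's convention. The central
column is excluded by default (arrays fix the acceptor, so it is
zero-information; `include_center` restores it). The null randomizes each
kinase PWM by permuting probabilities within each position column and then
shuffling column order — both operations preserve column multisets, hence
valid PWMs — and pools all kinases × permutations; FDR is the fraction of
null scores *strictly* smaller than observed, so a perfect match has
FDR 0. Designation additionally requires a compatible specificity group
(basophilic / proline-directed / acidophilic, a user-editable table);
kinases without a declared group are labelled `unknown-recognition` and
never designated. The default designation cutoff is 0.002.

## Network inference

Augmentation adds one directed edge per (SI, submodule) according to role
and one submodule → constituent edge per in-network constituent; submodules
with no significant SI are unreachable and are dropped from augmentation.
Path enumeration is a depth-first search: directed edges forward only,
undirected either way, no repeated nodes, at most 3 *billed* edges
(constituent hops are free). A path terminates at a submodule whose
dependency names its source; submodules met mid-path must be no-phenotype
and are exited through constituent edges only. Sources may appear as
intermediates on other sources' paths — the biology requires it.

The ILP has binary variables for paths (p), source–submodule connections
(c), undirected-edge orientations (d, 1 = lexicographic-forward), SI edges
(x) and billable intermediate nodes (y). Constraints: p ≤ d or p ≤ 1−d per
traversed undirected edge; p ≤ c and c ≤ Σp per pair; p ≤ x and x ≤ Σp per
SI edge (no free-floating SI edges — this is what makes the stage-2
"valid subnetwork" meaningful); p ≤ y and y ≤ Σp per intermediate. The
four stages maximize Σc, maximize Σx, minimize Σy, maximize Σp, each pinned
to its optimum as an equality before the next solve. The backend is
HiGHS through `scipy.optimize.milp` — exact, single-threaded and
deterministic; ties among optima within one iteration are accepted as
solver-returned, the ensemble being the remedy for solution multiplicity.

Ensemble: iteration 1 is unrestricted; iteration t > 1 excludes, with
independent probability 0.05 each, the non-source non-submodule nodes of
solution t−1 (for that iteration only, implemented by zeroing all paths
through the held node). Consensus: paths in ≥75% of solutions, with node
and edge confidences equal to ensemble frequencies. Add-back re-attaches
each no-phenotype submodule with ≥1 consensus SI via a direct SI →
submodule edge; added elements inherit the anchoring SI's confidence
(they are not themselves ensemble-selected, so they have no frequency of
their own), and pre-existing confidences are never modified.

## Evaluation

Precision = fraction of retained network proteins that are true positives;
recall = fraction of the true-positive list retrieved; submodule and
source nodes are excluded from both sides. The confidence sweep treats a
tie group as one atomic point — ensembles genuinely produce large
maximal-confidence groups, and any within-group order would be arbitrary.
Degree-preserving scrambling performs double-edge swaps separately within
the undirected class (preserving undirected degree) and the directed class
(preserving in- and out-degree), rejecting swaps that create self-loops or
duplicate (pair, class) records; the default budget is 10 accepted swaps
per edge. Co-IP interactor calling requires detection in both biological
replicates at either timepoint and ≥2-fold enrichment over the untagged
control in both; salt dependence requires ≥1.5-fold pre-vs-post shifts of
the same sign in both replicates; missing intensities impute at the run's
1st percentile, and proteins absent from the control entirely take the
control floor (the most permissive call, flagged as such).

## Synthetic scenarios

The generator plants a layered DAG (sources → kinases → targets), one
distinct motif per kinase from a small library of yeast-flavoured motifs
(R-R-x-S / R-x-x-S basophilic, S-P proline-directed, S-x-x-E acidophilic),
one regulated site per target whose window embeds the kinase's motif, and
alternating up/down directions per kinase. Defaults are the package's
study conditions: 2 sources, 3 kinases, 60 targets, effect 2.0, log-normal
replicate noise with σ = 0.15, 10% false-negative edge deletion, 100
undirected decoy edges, 400 decoy proteins. Noise is multiplicative
log-normal because the data are ratios; knockouts abolish effects by
transitive closure over the planted DAG, mirroring the predominance of
indirect mutant effects in real data. What the generator does **not**
emulate: isobaric-tag ratio compression, correlated replicate noise,
peptides mapping to several proteins, multi-parent kinases, or motifs with
degenerate residue classes — so passing recovery tests demonstrates the
machinery is correct under the stated statistical assumptions, not that
real-data performance reaches the same numbers.

Recovery scoring conditions the headline planted-intermediate fraction on
*recoverability*: a kinase whose source edge or all-but-one substrate
edges were deleted from the observed background cannot be implicated by
any neighbour-sharing method, so it is excluded from the denominator (the
raw fraction over all planted kinases is reported alongside).

## Problem sizes in the checks

The acceptance checks run at sizes chosen to keep the whole suite fast on
one CPU while still exercising every code path: 200 random ≤12-node
instances against exhaustive path-subset enumeration, all hypergeometric
instances with N ≤ 12 against direct combinatorics plus 1e5-draw sampling
checks, 100 planted-motif foregrounds, 200-iteration ensembles on a
~50-node background, and 20 end-to-end seeds at the generator defaults
with 15-iteration ensembles. Production-scale defaults (1000 iterations,
1000 permutations) remain the configured values.

## Known limitations

* Path enumeration is exponential in the billed-length bound; bounds > 4
  on dense backgrounds will enumerate very large catalogs before the ILP
  sees them.
* BH within-submodule correction treats submodules as independent test
  families; constituent overlap between submodules is not modelled.
* The two reported motif-coverage figures in the motivating study (71% vs
  80%) cannot both be targeted; this implementation treats neither as a
  specification and reports its own coverage.
* The designation cutoff for kinase matches (0.002 vs 0.2 in different
  descriptions of the same analysis) is ambiguous at the source; 0.002 is
  the default and the alternative is one config field away.
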