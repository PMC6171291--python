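# Methods

## The relatedness measure and the exclusivity statistic

The package treats relatedness of two genomes as the patristic distance —
the sum of branch lengths on the path between their leaves — averaged over
the maximum-likelihood trees of all single-copy core genes.  Averaging is
the key modelling decision: individual gene trees disagree (horizontal
transfer, recombination, estimation noise), but if transfers draw donors
and recipients from diverse lineages, the mean over many genes converges
on the dominant vertical signal.  The average is an entrywise arithmetic
mean over label-aligned matrices; gene trees must share an identical leaf
set (genes absent from any genome are, by construction, not core genes).

A group `G` is scored as

    score(G) = min out-group distance − max in-group distance,

so `score(G) > 0` means every member is closer to every other member than
any member is to any outsider.  The score is invariant under adding a
constant to all distances and scales linearly with the matrix, so it is
comparable only within one collection.  Singletons have a maximum in-group
distance of zero and are trivially exclusive.  The full label set has no
outside and is never scored.

Enumeration of exclusive groups relies on the classical property that
every exclusive group of a distance matrix is a cluster of its UPGMA
dendrogram; the suite cross-validates this against exhaustive subset
search on hundreds of random matrices (n ≤ 12).  Scored clades are the
internal non-root nodes of the rooted UPGMA tree; the two clades flanking
the root are both scored (one may be the complement of the other's
exclusive group), the root itself never.

## Core/pan construction (orthology stage)

Protein hits are accepted when E-value ≤ 1e-3, HSSP distance ≥ 20 and the
local alignment covers ≥ 30% of the shorter sequence (denominator
configurable to the longer).  The HSSP distance is percent identity minus
the length-dependent homology threshold curve
`480 · L^(−0.32·(1+exp(−L/1000)))` for alignment lengths 11 < L ≤ 450 and
the constant 19.5 beyond 450 residues; the two regimes join continuously
to within 0.1 and the curve is undefined at L ≤ 11 (such hits fail).
Orthology edges require reciprocal best hits between genomes (best by bit
score, ties by lower E-value then smallest subject id — a total order, so
the graph is independent of input order) and ≥ 60% global amino-acid
identity.  Global identity is computed by end-to-end dynamic programming
with BLOSUM62 and affine gaps (open 11, extend 1), identity = identical
columns / alignment columns; when sequences are unavailable it is
approximated as `pident · length / max(qlen, slen)` and flagged in the
log.  Graphs are clustered by Markov clustering at inflation 1.8.  The
MCL details left open by its common description are fixed for
determinism: self-loop weight equals the node's maximum incident edge
weight, entries below 1e-12 are pruned each iteration, convergence is a
maximum entry change below 1e-8 with a 200-iteration cap (warn and emit),
and clusters are connected components of the converged support — so
vertices in different input components can never merge.

Genome completeness is enforced against the clusters shared by all
*complete* genomes: a genome is kept when it holds at least
`ceil(f · |reference core|)` of them, with `f = 0.957` by default.  The
threshold is exposed as a fraction rather than an absolute count so it
generalizes to any reference-core size.  Core clusters are those present
in every retained genome; the pan-genome is every cluster present in at
least two genomes (the core is a subset); genome-unique clusters belong to
neither and are reported separately.

## Tree comparison and the RF null

Robinson–Foulds distances are computed on non-trivial unrooted
bipartitions; rooted inputs are interpreted unrooted (a binary root's two
edges form one split).  The null model is two independent uniformly random
fully resolved unrooted trees.  The expected number of shared splits is
computed exactly by linearity: a fixed split with side sizes (a, n−a) is
contained in `r(a)·r(n−a)` of the `b(n) = (2n−5)!!` trees, where
`r(k) = (2k−3)!!` counts rooted trees, so

    E[S] = 1/2 · Σ_{a=2}^{n−2} C(n,a) · (r(a)·r(n−a)/b(n))²

and `E[RF] = 2(n−3) − 2·E[S]`.  For n = 4 this gives 4/3 (two uniform
quartets agree with probability 1/3), verified against exhaustive topology
enumeration for n = 4–6 and Monte-Carlo sampling for n = 10, 20, 701.  The
far tail `P(RF ≤ x)` uses the Poisson limit of the shared-split count with
the exact mean (E[S] → 1/8 for large n), evaluated entirely in log10 space
because the probabilities of interest are far below floating-point
underflow.  For a 701-leaf collection the expectation is 1395.75 (≈ 1396)
and the probability of two random trees agreeing on 399 or more splits
(RF ≤ 598) is of order 10⁻¹²²⁵.  The Poisson tail is an approximation —
the exact tail of the shared-split distribution is not computed — but at
these magnitudes only the order of magnitude is meaningful.

## Gain/loss mapping

Gene presence/absence characters are mapped onto the core tree by Fitch
parsimony generalized to multifurcations (intersection of child state
sets if non-empty, else union).  The change total always equals the
parsimony minimum (verified against exhaustive ancestral labelings).
Ambiguity at the root is resolved to *absent* by default — auxiliary genes
missing from the core are parsimoniously ancestral absences, which is also
what makes gains outnumber losses on real collections — and the top-down
pass keeps the parent state wherever the child's Fitch set allows it,
placing changes as close to the root as permitted (ACCTRAN-style).  The
convention is configurable to root-present.  Per-branch averages divide by
the unrooted branch count `2n−3` of a fully resolved tree, since the two
edges of a rooted binary root are one unrooted branch.

## Clustering

UPGMA uses classic proportional (cluster-size-weighted) averaging;
WPGMA's unweighted means are available as an option.  Merge heights are
half the merged distance, so the tree is ultrametric by construction and
exactly reconstructs ultrametric inputs.  Ties on the minimum distance are
broken by the lexicographically smallest member label of the candidate
pair, then the second label, making results independent of input order.
Gene-content distances are binary Jaccard on presence sets (copy counts
binarized): shared absences carry no evidence of relatedness, and
all-zero columns or duplicated columns leave distances unchanged.

## Species delimitation

Species are the most inclusive clades of the UPGMA tree of the averaged
patristic matrix that are exclusive (score > −slack; slack 0 by default,
0.01 in relaxed mode — stored scores are always raw, the slack applies
only at classification time) and whose members satisfy ANI ≥ 96.5% and
AF ≥ 0.60.  The tree is walked root-down and the first qualifying clade
on each path wins, without lookahead; nestedness of clades guarantees a
partition.  Three similarity modes exist:

- `complete` — every within-group pair meets the threshold;
- `single` (default) — the within-group threshold graph is connected.
  This is single-linkage proper; it is the mode under which a noiseless
  simulated collection recovers its planted species exactly;
- `single_literal` — every member meets the threshold with at least one
  other member.  This weaker reading admits groups whose threshold graph
  is disconnected (two internally coherent subgroups with no
  cross-threshold pair), which in practice lumps heavily; it is kept
  because it is the phrasing often used to describe single linkage.

Directional ANI/AF pairs are symmetrized by arithmetic mean (configurable
to min); pairs absent from the table fail the criterion, which splits
rather than lumps.  The conspecific-split report counts, among genome
pairs meeting the threshold, the fraction placed in different species by
the exclusivity requirement.

## The synthetic generator

Scenarios emulate the statistical structure the analyses assume, not any
particular organism.  The species tree is clock-like with height 1 (time
units are arbitrary; branch lengths act as substitutions per site):
a Yule-type backbone over `n_species` species whose internal nodes are
rescaled into [`backbone_min` = 0.25, 1], with within-species subtrees
below `species_crown_max` = 0.05 — so planted species are exactly the
maximal shallow clades and the two depth scales are well separated.
Defaults: 60 genomes, 12 species, 50 core genes, 400 auxiliary clusters.

Gene trees copy the species tree and apply a Poisson number of
horizontal-transfer events per gene; each event picks a time uniformly
over the tree height and moves one lineage alive at that time onto
another contemporaneous edge, so gene trees stay clock-like, then all
branch lengths are scaled by a lognormal gene-rate factor (σ = 0.3; a
global scaling does not change between-gene correlations).  The default
transfer mean (5 events/gene) is calibrated so the mean between-gene
patristic R² on the default scenario sits near 0.44, the level typical of
real bacterial core genes; the suite asserts ±0.1 of that level at a
fixed seed.  Transfers are topological prune–regraft moves: no donor
tracking, no recombination tracts, no replacement bias.

Auxiliary gene content arises from one origin per cluster (edge chosen
proportionally to branch length) followed by loss along descendant
branches with probability `1 − exp(−loss_rate·ℓ)` and no regain;
all-absent columns are never emitted and core clusters are all-present.
ANI and AF decay exponentially in averaged distance
(`ANI = 100·e^(−0.3 d)`, `AF = 0.95·e^(−2 d)`, Gaussian noise, clamped to
their ranges); the scales place the 96.5%/0.60 thresholds strictly
between the within- and between-species distance ranges of the default
tree.  Real ANI/AF values are not exponential in patristic distance —
the map only needs monotonicity and a threshold gap, so passing recovery
tests shows the delimitation logic is correct, not that any particular
ANI model holds.

All randomness flows from one integer-seeded NumPy generator in a fixed
stage order, so scenarios are byte-reproducible across runs and platforms.

## Numerical choices

Distances are serialized with 10 significant digits and compared in tests
at absolute tolerance 1e-8; matrix symmetry and ultrametricity use 1e-9.
Matrix readers accept TSV-with-header (canonical) and square PHYLIP.
Label matching is exact, case-sensitive string equality.  The
depth-profile uses 25 equal-width bins over the max-in-group distance by
default (bins with one point report a mean only); subsampling defaults to
25 replicates per size.  Test and acceptance problem sizes — 701 leaves
for the analytic tree quantities, n ≤ 40 matrices for the UPGMA oracle,
n ≤ 12 for exhaustive subset enumeration, 20–60 genomes for simulated
scenarios, 100–10,000 Monte-Carlo tree pairs — were chosen so every
property is exercised at full strength while the whole suite stays
desk-scale.

## Limitations

Gene trees are consumed, never estimated; alignment and ML inference
happen upstream.  ANI/AF values are consumed as a table; no aligner is
run.  Fitch parsimony assumes gains and losses cost the same and gives a
minimum, not an estimate, of event counts.  The exclusivity score depends
on the sampled collection: adding a genome can break a group's
exclusivity, which is why the subsampling robustness analysis exists.
Assigning Linnaean names, or adjusting ranks for ecology or clinical
practice, is left to human judgment.
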