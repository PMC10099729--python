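# Methods

## Splice graphs and events

A gene's transcripts are collapsed by cutting the merged exonic cover at
every exon boundary observed in any isoform. The resulting non-overlapping
exonic *nodes* are indexed 1..N in transcription order (reverse of genomic
order on the '-' strand), so "upstream" always means transcriptionally
upstream. Edges are *adjacency* (two contiguous nodes read through within
one exon; a zero-length intron also collapses to adjacency) or *junction*
(a splice between non-contiguous nodes). Every input transcript is, by
construction, a path through this graph, and the builder verifies that each
exon is an exact concatenation of nodes.

Node types are assigned by an ordered rule cascade (first match wins):

1. **RI** — contiguous with both neighbours in some transcript while a
   junction spans its position (the node lies inside another isoform's
   intron);
2. **AF / AL** — first (last) node of some transcript, attached to the gene
   body by a junction, in a gene with ≥ 2 distinct first (last) nodes;
3. **TS / TE** — terminal node attached only by adjacency (a tandem
   transcription-start or polyadenylation extension);
4. **AA / AD** — a piece contiguous with its downstream (upstream)
   neighbour that other transcripts bypass with a junction landing on
   (leaving from) that neighbour — an alternative acceptor (donor)
   extension;
5. **CE** — any other node touched by a junction; nodes read through by
   adjacency in every isoform and never spanned are **NONE**.

The cascade is deterministic and fully testable; it is our operational
definition of the eight standard splice-graph node types, not a claim of
bit-equivalence with any external tool's internal rules.

An event's **anchors** are the nearest nodes up- and downstream of the
focal node through which *every* transcript overlapping the node's region
(containing it or splicing over it) passes. All distinct edge-paths between
the anchors are enumerated by depth-first search on the (acyclic, forward-
directed) local graph; when a gene end falls inside the window the open side
is replaced by the relevant transcripts' start/end nodes. Enumeration is
capped (default `max_paths = 128`, i.e. complexity K7); events exceeding the
cap are flagged truncated and excluded from quantification. One consequence
of the overlap-based anchor rule: a pure tandem extension node (TS/TE) forms
a single-path event of its own, and the tandem usage signal instead appears
at the first *shared* node, whose event distinguishes the long and short
starts (ends). Single-exon and single-isoform genes still build graphs; all
their nodes carry one-path events, which is what makes constitutive calls
possible.

## Quantification

Path abundances are estimated from edge read counts by EM with uniform
initialization: the E-step splits each edge's count across the paths
containing that edge in proportion to current abundances; the M-step
averages each path's assigned count over its number of edges and
renormalizes. The per-edge averaging matters: the simulator's read model
gives every edge an intensity equal to the summed abundance of the paths
through it, so without averaging, longer paths would be over-weighted; with
it, the true abundance vector is a fixed point of the update. Convergence is
an L1 change below `tol = 1e-6` (at most 1000 iterations); all-zero counts
return the uniform distribution flagged `no_data`. All edges count equally
(no length normalization) and an event's supporting reads are the counts
summed over the edges inside its anchors.

Node Ψ is the summed abundance of node-containing paths; entropy is Shannon
entropy of the path distribution in bits with 0·log₂0 ≡ 0; the complexity
bin is K(n), n = ⌈log₂ m⌉ for m paths (K0 for a single path), which bounds
the entropy. Events are kept when the host gene is expressed (TPM ≥ 1;
TPM is consumed as input — expression quantification is upstream of this
package) and the event has ≥ 10 supporting reads. Down-sampling to a common
depth is multivariate-hypergeometric across edges (sampling reads without
replacement), seeded.

## Classification and tissue comparison

Within a sample, 0 < Ψ < 0.97 is alternative and Ψ ≥ 0.97 constitutive
(given the expression filter); entropy ≥ 1.0 bits marks high complexity
(≥ two effective outcomes; 1.5 is a stricter sensitivity cutoff). For a
tissue pair, classifiable events (quantifiable, 0 < Ψ < 0.97) fall into
K1/K2/K3 × Low (0, 0.2] / Middle (0.2, 0.8) / High [0.8, 0.97); the printed
bin boundaries put Ψ = 0.2 in Low and Ψ = 0.8 in High, and K ≥ 4 events are
folded into the K3 classes (the full bin is retained in the event table).
An event classifiable in only one tissue is "Others" on the other side;
events classifiable in neither are dropped from the pair. The transition
table is a 10×10 contingency whose marginals equal the per-tissue class
histograms.

## Splicing ages

Per species, an event is A if alternative in at least one tissue, C if at
least one tissue is quantifiable and all quantifiable tissues are
constitutive, NA otherwise. First and last transcript exons are excluded
before the orthology join; orthology itself is consumed as an event-to-event
map (coordinate lifting is an upstream requirement).

On the rooted seven-species tree (human, chimpanzee, gorilla, macaque,
mouse, opossum; chicken as outgroup — topology from standard divergence
references), an event's complete A/C pattern is explained, when possible, by
one state flip on one branch. Every (branch, direction) scenario is
enumerated; uniform patterns are VCA/VCC; the outgroup-split patterns —
which admit both a gain-in-mammals and a loss-in-outgroup reading — get the
dedicated MCA/MCC labels with both scenarios recorded; any other single
scenario labels the event `<clade>_gain` or `<clade>_loss` (clades named by
their boundary leaves in tree order, e.g. `human-opossum`); patterns with no
scenario are `complex`. On a binary rooted tree, two scenarios can coexist
only at the root split, so off-root labels are unique; should several remain
(non-binary trees), the smaller changed clade is preferred and all scenarios
are kept in the output. Missing data makes an event `unassignable` under the
default complete-pattern requirement; a tolerant mode judging scenarios on
observed leaves only exists but is explicitly non-canonical.

Cross-species summaries: Spearman correlation of entropy over shared
orthologous events (undefined below 3 shared events); the top-entropy
species only when it beats the runner-up by ≥ 1.0 bits; monotonic trends
are non-decreasing (non-increasing) orderings with a positive (negative)
total change toward the reference species; per-age-group ratios are the
fractions of events with max-over-tissues entropy ≥ 1.0 and with
cross-tissue entropy range ≥ 1.0.

## Developmental dynamics

Whippet-style posterior calling is reconstructed as an explicit Bayesian
model, since only the thresholds — not the estimator — are published: per
condition Ψ ~ Beta(incl + ½, excl + ½) (Jeffreys prior on the event's
inclusion/exclusion reads), the posterior is the fraction of paired draws
(default 2000, seeded) with |Ψₐ − Ψᵦ| ≥ 0.1, and a stage is significant when
the point-estimate |ΔΨ| ≥ 0.1 *and* the posterior ≥ 0.85. An event is a
Dev-event when significant in ≥ 5 stages versus the reference stage (the
reference is configurable per tissue, as testis develops on a shifted
clock). For multi-path events the binary summarization uses reads on edges
exclusive to node-containing paths as inclusion and reads on edges exclusive
to skipping paths as exclusion; entropy always uses the full path
distribution. Entropy-dynamic events have an entropy range ≥ 0.5 bits over
stages with more than 20 reads and host-gene TPM above 10, with at least
five such stages. The Dev × dynamic crosstab reports the fraction of
dynamic events among non-Dev events. (The 0.5-bit figure is an entropy
*change* threshold throughout, which is the operative definition; an
absolute-entropy reading that appears in one figure legend of the source
analyses is not used.)

## Gene context

tau = Σ(1 − xᵢ/max x)/(n − 1) over n ≥ 2 tissues; undefined for an all-zero
vector; scale-invariant by construction. Binary gene groups at the standard
cutpoints: tau ≥ 0.3 (high specificity), TPM ≥ 50 (high expression),
dN/dS > 0.0993 (fast-evolving), median split for PPI degree, plus the
housekeeping flag and young/old age class, all consumed as annotation.
Events inherit their host gene's label, and entropy values enter the
comparison per event per tissue (observations, not genes). Group entropies
are compared by a two-sided Wilcoxon rank-sum test with mid-ranks for ties;
for combined sizes ≤ 12 the p-value is computed by exhaustive permutation
(so it agrees exactly with full enumeration), otherwise by the
tie-corrected normal approximation.

## Exon features and entropy regression

A compact ~17-feature set covers the standard categories: target exon
length/GC, flanking exon lengths/GC, flanking intron lengths/GC/pyrimidine
content, exon rank, and four splice-site strengths (the event's acceptor and
donor plus the upstream exon's donor and downstream exon's acceptor).
Splice-site strength is a position-weight-matrix log-odds score against a
uniform background, with donor windows of 3 exonic + 6 intronic and acceptor
windows of 20 intronic + 3 exonic bases; the PWMs are trained on the input
annotation's own junction sites (pseudocount 1), making the extractor
self-contained. Non-ACGT bases contribute 0. This set deliberately does not
reproduce any external tool's full 59-feature catalogue; the regression
interface accepts externally computed feature TSVs so such output can be
dropped in.

Regression uses seeded 5-fold cross-validation with pooled held-out
predictions; metrics are Pearson and Spearman correlation and R², and
importances are permutation importances of a full-data refit. Families:
linear (standardized least squares), gradient-boosted trees, random forest,
and SVR. The mean entropy target averages over tissues where the event
passes filters. The `SplicingEntropyModel` / `SplicingEntropyResults` pair
wraps this as a fit/results interface with a text `summary()`.

## Synthetic data: what it emulates and what it does not

The generator's defaults emulate a desk-scale six-tissue, seven-species
study with a ten-stage developmental series: 200 genes with 4–9 exons and
2–4 isoforms; an event mix of 50% CE and 10% each AA/AD/RI with the
remainder split over AF/AL/TS/TE; multinomial edge reads at depth 200 per
event-condition; gene TPM fixed at 50 so expression filters are exercised
but not the binding constraint. Path abundances are symmetric Dirichlet
draws whose concentration controls entropy; the 50/50 mixture of
concentration 0.08 (near one-hot, low entropy) and 12.0 (near uniform, high
entropy) was calibrated once to reproduce the characteristic two-peaked
entropy landscape of real tissue data and is verified by a distribution
test. The genome emitter plants canonical GT/AG dinucleotides at every
annotated intron boundary (strand-aware) in otherwise uniform random
sequence.

Evolutionary histories flip a binary A/C state along tree branches with
per-direction probabilities; the single-change mode rejection-samples
histories with ≤ 1 flip and records the flipped branch, which is the truth
for parsimony-recovery tests. The species panel plants four age groups
(human_gain → human-macaque_gain → MCA → VCA) whose events receive the
high-entropy regime with increasing probability (0.10/0.35/0.65/0.90);
constitutive observations put zero flux on skipping paths, alternative ones
keep node Ψ in a range that survives sampling noise. Stage series come in
three kinds — null (constant abundances), dev (logistic node-Ψ sweep,
default amplitude 0.3), dynamic (≈ 0.8-bit entropy sweep at constant node
Ψ, only possible for ≥ 3-path events) — and the developmental panel plants
its composition by stratified assignment, so the planted non-Dev dynamic
fraction is exact rather than binomially noisy.

What the generator does *not* model: read sequences (counts are emitted at
edge level; no alignment, no FASTQ), read errors or GC bias, fragment-length
effects, overdispersion beyond multinomial sampling, expression variation
entangled with splicing, correlated evolution between neighbouring exons,
and cell-type mixtures within tissues. Passing tests therefore demonstrate
the correctness and statistical calibration of the algorithms under a clean
generative model, not robustness to alignment artefacts or biological
confounders in real data.

## Numerical choices and degenerate inputs

Entropy clamps 0·log₂0 to 0 and is capped at log₂(m) against floating-point
drift. EM guards zero-intensity edges and returns uniform/`no_data` on empty
counts. Ties at the top of the per-event species entropies return no
top-entropy species. Empty groups are omitted from age summaries; a
crosstab without non-Dev events has an undefined (NaN) ratio. Rank-sum
groups smaller than two report medians with an undefined p. The ΔΨ caller
returns an undefined call when either condition has zero reads, and series
with fewer than five defined non-reference stages are unclassifiable rather
than non-Dev. All randomness flows through explicit seeds or
`numpy.random.Generator` instances; every simulator output is a pure
function of (config, seed).

## Problem sizes used in the shipped checks

The reproduction script runs 10⁴ random events for the entropy bound, all
128 leaf patterns plus 1000 single-change histories for parsimony, 200 EM
replicates at depth 10⁴, 500 null and 200 sweep series for the
developmental caller, full permutation enumeration for all rank-sum group
sizes with combined n ≤ 10, and end-to-end panels of 200 orthologous events
(7 species × 6 tissues) and 300 stage series (10 stages). These sizes give
stable recovery rates at desk scale on a single CPU.
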