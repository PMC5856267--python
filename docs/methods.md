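# Methods

## Model

A mitochondrial gene order is modelled as a **signed circular permutation**:
an ordered ring of gene labels, each read on one of the two strands (sign).
Two orders are the same genome when one is a rotation of the other or a
rotation of its reversal-with-negation, so an order of *n* genes has exactly
2*n* linear representations (a linear genome has 2).  Gene identity is by
label only; orientation is state.  Duplicated genes are rejected at parse
time — paralogy is outside the model.

Three elementary rearrangements connect genomes: **inversion** (a block is
replaced by its reversal-with-negation in place), **transposition** (a block
moves between two other successive genes) and **reverse transposition** (the
block moves and flips).  Tandem-duplication/random-loss is deliberately not
modelled.  Gene **gain/loss** is handled outside the path model: before any
pairwise computation both genomes are reduced to their common genes and the
removed labels are reported as annotations; they never count as path steps
and are never placed on branches automatically.

The **distance** d(G, G′) is the length of the shortest rearrangement path.
It is a metric (identity, symmetry via path reversal, triangle inequality
via concatenation).  Two admissible facts drive the pruning:

* **Breakpoint bound.** An adjacency of G absent from G′ (in either reading
  direction) is a breakpoint; one rearrangement removes at most three, so
  3·d ≥ nb_breakpoints(G, G′).
* **Shared blocks.** A maximal run of preserved adjacencies is a block
  present in both genomes (possibly inverted).  Among the minimal paths at
  least one never breaks a shared block ("cut-free"); empirically every
  minimal circular path we enumerate is cut-free, while for linear genomes
  a minimal path may require a cut (the packaged 5-gene example needs 3
  linear steps, one of which breaks a shared block).

## Distance and path search

The search is backtracking depth-first over k-paths.  A three-valued test
classifies each partial path: YES when the target is reached with the budget
spent; NO when the budget is spent elsewhere, when the target is reached
early (no rearrangement is a no-op, so lingering is impossible), or — with
the breakpoint rule (HT2) — when breakpoints exceed three per remaining
step; INDETERMINATE otherwise.  Shared-block pruning (HT1) drops candidate
moves that would cut inside a block shared with the target.  Because a
shared adjacency is exactly an internal adjacency of a maximal shared block,
HT1 reduces to: every cut position of the move must be a breakpoint.  Moving
a whole maximal shared block as a unit is therefore allowed (its boundary
adjacencies are breakpoints by maximality).  HT1 can prune valid paths but —
by the shared-block property — never all minimal ones, so distances are
unaffected; ancestral inference runs with HT1 off because it needs the
exhaustive path set.

Exact distances come from **iterative deepening**: complete k-path searches
at k = 0, 1, 2, … until the first success, so a returned distance is never
an overestimate and a budget miss (k_max exceeded, default k_max = 8) is an
explicit failure, never a wrong value.

Equivalent operations collapse: circularity makes three transpositions (or
two inversions) produce the same gene order, so children are deduplicated by
the resulting genome (canonical representation), not by operation
parameters, and paths are sequences of genomes.  The canonical
representation is the lexicographically least of the 2n representations
under a fixed label order (a dataset's registration order where one exists,
sorted labels otherwise); children are explored in canonical order, making
every run reproducible.

### Accelerated kernel

Large simulations and distance matrices use a compiled (numba) kernel
implementing the identical algorithm, restricted to circular distance
queries.  On top of HT2 it prunes with a second admissible bound from the
breakpoint graph of the pair: inversions are 2-breaks (cycle count gain at
most 1), transpositions and reverse transpositions 3-breaks (gain at most
2), and the genomes coincide exactly when all n cycles are trivial, hence
d ≥ ⌈(n − c)/2⌉.  Admissibility means results are bit-identical to the
reference engine — asserted by tests exhaustively at 4 genes and on random
6–7-gene pairs — while the explored tree shrinks by orders of magnitude.
The reference engine keeps the plain two-rule contract verbatim.

## Distance matrices and the fast-evolver rule

`build_matrix` reduces every unordered pair to its common genes (≥ 3
required), records removals, and computes exact distances; taxa with equal
gene orders are merged first (the analysis is over distinct genomes), and
cells that exceed k_max are marked lower bounds and barred from tree
building.  Because reduction is pairwise, the matrix is not a metric on a
single gene universe; downstream consumers take it as given.

Random 14–15-gene pairs are nearly always ≥ 6 steps apart (see the
simulation module), so large observed distances carry almost no signal.
`flag_fast_evolving` flags taxa at distance > 5 from strictly more than 95%
of the others (both thresholds configurable; the inequality is strict).

## Tree enumeration

A candidate phylogeny is an unrooted tree over N observed gene orders
(OTUs — allowed at internal positions) and M anonymous ancestors (HTUs);
every edge is one rearrangement.  Admissibility: simple, undirected,
connected, acyclic (P1–P3); every OTU–OTU tree path at least as long as the
pairwise distance (P4); every imposed monophyly constraint (PPH) realized
relative to a root taxon (P5), where a clade is the OTU set on the non-root
side of some edge, HTUs ignored.  Parsimony selects the smallest V = N + M
admitting an admissible tree; V is searched upward from N, with a
configurable ceiling (default M ≤ N + 4) and explicit failure.

Enumeration is complete by construction: every labeled tree on V nodes is
generated through the Prüfer bijection, filtered, and deduplicated up to
renaming of the anonymous HTUs (canonical edge-list signature minimized over
HTU permutations).  HTUs of degree 1 are excluded structurally: a pendant
hypothetical ancestor constrains nothing and deleting it yields an equally
admissible smaller tree, so it cannot occur at the minimal V; allowing them
would also make ancestral validation vacuous at escalated V.

Forbidden subtrees (from failed ancestral validation) are matched by
injective embedding preserving edges, OTU labels and HTU degrees.  Degree
preservation keeps exclusion sound: any tree containing the embedded
fragment reproduces the same empty intersection of candidate ancestors.

## Ancestral inference (P6)

For a candidate tree, the constraining pairs are the OTU pairs whose
connecting path passes only through HTUs.  For each such pair with tree
path length k, all k-paths between the two observed genomes are enumerated
exhaustively (HT1 off, HT2 on); k may exceed the distance (P4 permits it) up
to a slack budget (default 2) beyond which the run aborts with a distinct
budget error — and a k with no k-path at all (the operation set has no
universal parity filler) invalidates the tree.  Each HTU on the pair's path
collects the set of genomes occurring at its position across all k-paths.

An HTU whose covering pairs all share one OTU endpoint sits on the pendant
branch to that OTU: its candidates are the union of what those paths
propose (the paths commute along a branch).  Any other HTU is at or between
branching points and must satisfy every crossing pair: its candidates are
the intersection over all covering pairs (processing order is irrelevant).
An empty candidate set rejects the tree and emits the smallest forbidden
subtree: pairs are greedily dropped (deterministic order, keeping at least
two and no common endpoint) while the intersection stays empty; the pattern
is the union of the remaining pairs' paths with ancestors anonymized.

Ancestral inference presumes one gene universe; the solver therefore runs
P6 on the gene orders reduced to the genes shared by the whole dataset,
while P4 uses the pairwise-reduced matrix.

## The solving loop

At each V the solver enumerates admissible trees (skipping any that contain
an accumulated forbidden subtree), validates each by P6, converts failures
into new exclusions, and repeats until a round learns nothing new.  If no
tree at V survives, V is escalated — parsimony semantics require trying the
next-smallest domain rather than declaring unsatisfiability (the packaged
three-taxon example with pairwise-disjoint path midpoints exercises exactly
this: the 4-node star fails, the 5-node trees succeed).  The first V with
survivors yields the complete solution set.

A **logical consequence** is a statement true in every solution: clades
monophyletic in all trees, OTU–OTU edges present in all trees, and
ancestral identities — a clade whose basal gene order equals one OTU's
genome in every solution ("Ur-" identity).  Each emitted fact is re-checked
by direct evaluation on every solution.

## Random-genome simulations

The generator draws a uniform signed permutation — every ordering equally
likely, every sign an independent fair coin — and reads it as circular.
Since each circular class contains exactly 2n signed sequences, classes are
equiprobable (χ²-checked at 3 genes).  Pairs are two independent draws,
equivalent by symmetry to fixing one endpoint at the identity.

The distribution runs use 500 pairs per condition (14 and 15 genes, fixed
seeds, k_max = 8): large enough that the two dominant bins are estimated to
a couple of percentage points, small enough for a single-CPU run in
minutes.  At 15 genes the mass concentrates near distance 7 (~79%) with
~20% at 6; at 14 genes it splits ~54%/42% between 6 and 7.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_max` | 8 | search budget (steps); distances beyond it fail explicitly |
| `use_ht1` / `use_ht2` | on / on | shared-block and breakpoint pruning (off for ancestral path sets: HT1) |
| `slack` | 2 | ancestral enumeration covers k ≤ distance + slack |
| `dist_threshold`, `frac_threshold` | 5, 0.95 | fast-evolver removal rule |
| `max_htus` | N + 4 | ceiling on hypothetical ancestors before explicit failure |
| minimum genes | 3 shared | below this the rearrangement space is degenerate |

## What the synthetic data does and does not show

Synthetic fixtures are uniform random signed circular permutations and
planted-ancestor star datasets (leaves one rearrangement from a hidden
genome).  They exercise exact distances, complete enumeration, ancestral
recovery and the solver loop under fully known ground truth.  They do not
emulate real mitochondrial evolution: no rate heterogeneity across
lineages, no rearrangement hotspots, no gene gain/loss along branches, no
tRNA-scale gene counts (tests run mostly at 5–15 genes).  A green suite
shows the machinery is exact and complete under its model assumptions, not
that the model captures any particular clade's history.

## Numerical and degenerate-input choices

* Canonical representation ties are impossible (rotation never equals
  reflection for duplicate-free genomes), so keys are unique.
* Genomes need ≥ 2 genes to parse (2-gene circles are needed to demonstrate
  inversion equivalence); neighborhoods and distances need ≥ 3.
* A transposition may not re-insert a block at its own boundary, and a
  reverse transposition at the original position is an inversion: both are
  rejected as parameter errors.
* Identical genomes have no defined shared-block set (every block would be
  shared while a whole genome is not a block); callers must handle equality
  first, and duplicate taxa are merged before any pipeline stage.
* All iteration orders (children, pairs, tree signatures) are sorted, so
  every run of every stage is deterministic; only the simulation module
  consumes a seed.

## Known limitations

* Complete enumeration is exponential; practical datasets are small (the
  intended workflow splits large taxonomies into overlapping sub-analyses
  and recombines solution sets by hand).
* The 3-break cycle bound is implemented in the kernel only; the reference
  engine relies on the two classical pruning rules and is correspondingly slower.
* Exclusion patterns are a sound cache, not a complete rejection test:
  trees that embed a failure in a different degree environment are caught
  by direct revalidation instead.
* Distances above the k_max budget are reported as bounds and excluded from
  tree building rather than estimated.
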