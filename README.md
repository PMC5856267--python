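# mitorder

Exact, complete analysis of mitochondrial gene-order evolution: rearrangement
distances and *all* minimal scenarios between signed circular genomes, the
*complete* set of most-parsimonious phylogenies under distance and monophyly
constraints, and exhaustive inference of the possible ancestral gene orders at
every internal node.

It is written for people who compare mitochondrial genome maps — the order and
strand of the protein-coding and rRNA genes — across animal taxa and want
answers with a completeness guarantee rather than a heuristic tree: every
returned solution is checked, and no solution is missing, so any statement true
across the whole set (a "logical consequence") is a robust result.

## The model in brief

A genome is a signed circular permutation `[s₀ s₁ … sₙ₋₁]`; it equals all its
rotations and the rotations of its reversal-with-negation (2n representations).
Three elementary events transform genomes: inversion (a block `B` becomes
`−B` in place), transposition (a block moves elsewhere) and reverse
transposition (moves and flips). Gene gain/loss is handled by reducing each
pair to its common genes and reporting the removals; duplications (TDRL) are
outside the model. The distance `d(G, G′)` is the length of a minimal event
path and is a metric. Search is exact: complete depth-first enumeration of
k-paths with iterative deepening, pruned by two admissible rules —

* breakpoint bound: `3·d(G, G′) ≥ nb_breakpoints(G, G′)`;
* shared blocks: moves never need to cut a block shared with the target, since
  some minimal path is always cut-free.

Trees place the N observed genomes (possibly at internal nodes) plus M
hypothetical ancestors so that every edge is one rearrangement, tree paths are
never shorter than pairwise distances, and required clades are monophyletic;
the smallest N + M wins. Each candidate tree is then validated by
re-enumerating all paths between the observed genomes through its ancestors:
an ancestor with no consistent gene order rejects the tree and every other
tree containing the same subtree, and the loop repeats until the solution set
is exact.

## Worked example

The packaged 5-gene pair `[1 -2 -3 -5 -4]` vs `[1 2 3 4 5]`:

```
$ mitorder distance "1 -2 -3 -5 -4" "1 2 3 4 5" --kmax 4
distance: 2

$ mitorder paths "1 -2 -3 -5 -4" "1 2 3 4 5"
8 minimal path(s) of length 2
  1 -2 -3 -5 -4  ->  -2 -1 4 5 -3  ->  -2 -1 -5 -4 -3
  1 -2 -3 -5 -4  ->  -2 -1 -3 -5 -4  ->  -3 -2 -1 -5 -4
  ...
```

Two rearrangements separate the genomes, and the complete enumeration finds
exactly eight two-step scenarios, every one cut-free. (Treated as *linear*
sequences the same pair needs three steps, one of which must cut a shared
block — circularity matters.)

Solving the pair as a two-taxon dataset infers the possible ancestors:

```
$ printf 'A\t1 -2 -3 -5 -4\nB\t1 2 3 4 5\n' > toy.tsv
$ mitorder solve toy.tsv --out run
1 solution(s) on 3 nodes; 0 logical consequence(s) -> run/
$ cat run/solution_001.nwk
((B:1)HTU#1:1)A;
$ head -2 run/solution_001.nwk.htus.tsv
HTU#1	3 2 -1 -5 -4
HTU#1	-3 1 -2 -5 -4
```

The single most-parsimonious topology is `A — ancestor — B` and the ancestor
(`HTU#1`) may carry any of the eight midpoint gene orders, listed in the
sidecar.

Other subcommands: `breakpoints`, `matrix` (pairwise distance matrix with
gain/loss annotations and the distance-above-5 fast-evolver flag),
`trees` (complete tree enumeration from a matrix), `ancestors` (validate one
tree), `simulate` (random-genome distance distributions). The library API
mirrors the CLI (`mitorder.distance`, `mitorder.enumerate_minimal_paths`,
`mitorder.build_matrix`, `mitorder.solve`, …). A packaged example dataset of
the human mitochondrial protein-coding/rRNA gene order lives in
`mitorder.io.example_data("human_mtdna.tsv")`.

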