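# Methods

## Model

A genome of size `n` is an alternating sequence of `n` gene labels and
`n−1` intergenic regions, each region modeled only by its size in
nucleotides (a non-negative integer).  Labels are opaque tokens; genes
are unsigned (no orientation).  All public indices are 1-based: gene
`i` is `S_i`, and intergenic region `i` (size `Ŝ_i`) lies between genes
`i` and `i+1`.  Two genomes are *balanced* when their label multisets
and their total intergenic sizes agree — the precondition for comparing
them under conservative events — and *co-tailed* when they share their
first and last genes, which capping both genomes of a pair with the
same artificial label pair guarantees.

The two events are exact integer rewrites of the gene and region lists:

- τ(i,j,k)(x,y,z), 2 ≤ i < j < k ≤ n, exchanges segments
  `S_i..S_{j−1}` and `S_j..S_{k−1}`; `x, y, z` say how many nucleotides
  of the three affected regions `Ŝ_{i−1}, Ŝ_{j−1}, Ŝ_{k−1}` stay on
  their left side.  The three new regions hold `x+y′`, `z+x′`, `y+z′`
  with `x′ = Ŝ_{i−1}−x` etc.
- ρ(i,j)(x,y), 2 ≤ i < j ≤ n−1, reverses `S_i..S_j` and its internal
  regions; the flanking regions become `x+y` and `x′+y′`.

Both conserve the gene multiset, the total intergenic size, and the
first and last gene.  Application is a pure function; every operation
record stores parameters only.

## Partitions and the 2k approximation

A *direct intergenic partition* cuts both genomes into blocks that
match one-to-one as equal genomes (labels **and** intergenic sizes); a
*reverse* partition also accepts a reversed match.  Cost = number of
cuts, equal on both sides.  Minimizing the cost (MCISP / RMCISP) is
NP-hard, so the package ships:

- `greedy_partition` (`mcisp_partition` / `rmcisp_partition`): repeated
  breakpoint insertion.  `T_min` is the set of containment-minimal
  subgenomes whose occurrence counts differ between the current block
  sequences of the two sides (occurrences are counted inside single
  blocks; congruent windows count in reverse mode, a palindromic window
  once).  Each iteration cuts one occurrence of one `T_min` entry, on
  the side with the excess, always at the breakpoint associated with
  that entry, until every subgenome has weight zero; by the
  weight-zero/block-matching equivalence the result is then a valid
  partition with at most `2k·|T_min|` cuts, `k` the maximum label
  multiplicity.
- `brute_force_min_partition`: exhaustive search over source-side cut
  subsets in increasing cardinality, feasibility tested by
  backtracking-tiling the target genome with the block multiset.
  Guarded to `n ≤ 12`.
- `induced_partition`: the unique minimal partition of an orthologous
  assignment ξ (a label-preserving bijection between gene positions).
  In direct mode the region after gene `i` survives iff ξ maps `i, i+1`
  to consecutive target positions in order with equal region sizes; in
  reverse mode a maximal run may instead be consistently
  reverse-adjacent, and a direction flip forces a cut.

Deterministic tie-breaks in the greedy algorithm (the published
procedure leaves them open): the `T_min` entry with the smallest
(size, gene labels, intergenic sizes) is processed first, and the
leftmost eligible occurrence is cut.  The breakpoint associated with an
initial `T_min` entry is its **first** intergenic region; an entry
acquiring non-zero weight mid-run inherits the offset of the
chronologically first cut that fell inside one of its occurrences
(offset mirrored for a reversed occurrence).  Cutting at the stored
offset makes the new breakpoint equivalent (congruent, in reverse mode)
to the entry's breakpoint by construction.  These choices reproduce the
reference execution trace's final blocks; other choices would satisfy
the same bound.

Breakpoint classification follows the assignment: a source breakpoint
after gene `i` is *hard* when ξ(S_{i+1}) immediately follows ξ(S_i) in
the target (the cut then exists only because the sizes disagree:
*overcharged* if `Ŝ_i` is larger than its image region, *undercharged*
if smaller) and *soft* otherwise.  Reading "adjacent" as ordered
adjacency is what makes a hard breakpoint removable by fixing its size
alone; the unordered reading would not.

## Sorting within certified bounds

Given balanced co-tailed genomes and an assignment ξ with induced cost
`c`, the sorters return explicit operation sequences:

- **Transpositions, ≤ c+1 ops** (`sort_by_transpositions`): a case
  loop.  (1) Two or more overcharged breakpoints: a two-transposition
  redistribution (see below) sets both to their image sizes and parks
  the excess on a third breakpoint, closing two cuts with two ops.
  (2) A soft breakpoint holding at least its image region's
  nucleotides: one transposition closes it.  The transposition's three
  cut regions are always existing breakpoints (the qualifying soft
  breakpoint, the breakpoint before the gene whose image
  forward-follows ξ(S_i), and an auxiliary breakpoint), so the cost
  strictly decreases; cut values are solved exactly — a new-region
  triple is achievable iff each value is bounded by the sum of the two
  old regions it draws from and the total is conserved — and the
  solver prefers closing more junctions and creating fewer overcharged
  breakpoints.  (3) A single overcharged breakpoint: paired with an
  undercharged one, or its excess is parked on a soft breakpoint (the
  one step that may spend the "+1").
- **Reversals, ≤ 2c ops** (`sort_by_reversals`): left-to-right block
  placement over the reverse induced partition.  Each target slot
  chooses among the unplaced source blocks congruent to its target
  block: a block in the wrong orientation is swept to the front by one
  reversal (palindromic blocks, including singletons, always use this
  route); a block in the right orientation takes two (flip while
  moving, flip back).  The reversal cuts set the junction region to its
  target size; when the regions at hand cannot fill it, one extra
  reversal per donor junction pulls nucleotides in first.  Mis-sized
  regions remaining at the end are repaired without net gene movement:
  exact search (breadth-first over raw reversals, or a Dijkstra over
  palindromic-span reversals plus restoring pairs) when the state space
  is small, otherwise nucleotide routing by restoring reversal pairs —
  a pair over one span moves nucleotides between two regions at
  distance ≥ 2 and restores the genes — retiring one mis-sized region
  per pair, with relays around adjacent regions.  An iterative-deepening
  search first looks for a minimal retirement plan; otherwise two
  greedy retirement policies (largest imbalance first / best partner
  improvement first) run.  Three placement strategies (differing in how
  strongly a mis-sized in-place block is penalised) are tried
  deterministically and the shortest overall sequence kept.
- **Mixed, ≤ ⌈3c/2⌉ ops** (`sort_by_reversals_and_transpositions`):
  the same placement machinery, but a right-orientation block moves by
  a single transposition, and leftover mis-sized regions are settled in
  triples by two-transposition redistributions (two exact, one takes
  the spill).  The result is compared against the reversal-only
  sequence and the shorter kept, so the mixed model is never worse.

The two-transposition redistribution primitive
(`redistribute_three`) sets any three intergenic regions to any target
triple of the same total without changing the gene order: the first
transposition moves the regions to an intermediate triple bounded by
`A ≤ min(a+b, t_a+t_b)` (and symmetrically) — bounds that always sum to
at least the conserved total, so an intermediate exists — and the
second swaps the segments back while landing on the targets.  It
returns the empty sequence when the targets already hold.

Every sorter re-applies its sequence and verifies bit-exact equality
with the target before returning, and raises (rather than returning a
wrong statistic) if the certified bound is exceeded.  The bound proofs
this construction follows are stated for the literature's constructions
rather than this one, so the bound is enforced empirically per run; the
test suite exercises it over an exhaustive tiny-instance family and
randomized larger instances.

Lower bounds: any transposition removes at most 3 breakpoints of a
minimal induced partition and any reversal at most 2, so the minimum
partition cost `p*` gives `⌈p*/3⌉` (transpositions, mixed) and
`⌈p*/2⌉` (reversals) as distance lower bounds
(`partition_lower_bound`, exhaustive `p*`).  `bfs_exact_distance` is a
breadth-first oracle over all valid operations, guarded by default to
`n ≤ 6` and intergenic total ≤ 6 (configurable); conservation bounds
the state space.  An explicit unreachable signal exists because tiny
degenerate instances occur — with `n = 4` no reversal can cut the
middle intergenic region, so a pair differing there is genuinely
unsortable under reversals.

`estimate_distance` samples orthologous assignments uniformly — per
label family an independent uniform bijection, or, when guided by a
partition, a uniform matching within each block congruence class with
positional gene mapping (mirrored for reversed matches; palindromic
matches flip a fair coin) — sorts under the chosen model for each, and
reports the minimum and mean certified sequence lengths.

## Simulated-genome benchmark

`simulation` emulates a standard benchmark protocol: source genomes of
`n_genes` labels drawn uniformly from an `m`-letter alphabet with
intergenic sizes uniform on the inclusive interval `[0, 100]`; targets
obtained by applying `o` random events — indices uniform over the valid
tuples, then cuts uniform over their current ranges, the mixed model
interleaving ⌊o/2⌋ reversals and ⌈o/2⌉ transpositions in uniformly
shuffled order.  Events are applied to the uncapped genome; both
genomes of a pair are then capped with one fresh label pair and
identical gap sizes (drawn uniformly on `[0, 100]`), keeping the pair
balanced and co-tailed by construction (the gap sizes of the reference
protocol are unspecified; equal gaps is this package's choice, as
balance requires equal added totals).  With `n_genes = 100` every
genome has final size 102, the reference benchmark scale; the package
defaults are reduced (`n_genes = 30`, 10 pairs, 20 assignments) so that
a full three-model comparison runs in minutes on one core.  The
experiment driver estimates each pair's distance twice — assignments
consistent with the computed partition vs. unconstrained — and reports
Min/Avg/Max of the per-pair minima and means.

What the generator does *not* emulate: real gene-family size
distributions (labels are i.i.d. uniform), nucleotide content of
intergenic regions (sizes only), unbalanced gene content
(insertions/deletions), and signed genes.  Passing tests therefore
certify the combinatorial machinery and the direction of the
partition-vs-no-partition comparison, not biological realism.  The
exact cell values of any published benchmark table are not
reproducible — they depend on unrecoverable random streams — so the
suite checks the directional finding (partition-guided estimates are
lower) at fixed seeds, plus the certified bounds above.

## Numerical and design choices

- Integer arithmetic throughout; no tolerances.
- Every stochastic function takes an explicit `random.Random`; the CLI
  derives all streams from one `--seed`; experiment sub-streams are
  derived per pair and arm so results are reproducible and
  order-independent.
- Occurrence counting is a naive window scan (reference semantics);
  `T_min` is recomputed from scratch each iteration.  This is O(n³)-ish
  per partition and entirely adequate at the package's scale (n ≤ a few
  hundred); the suffix-tree accelerations known for this algorithm are
  deliberately not implemented.
- Size-1 genomes (empty intergenic list) are valid everywhere; size-1
  blocks and palindromic blocks get special-cased placement because a
  reversal span must hold at least two genes.
- `n < 4` with unequal genomes raises "unsortable": no operation is
  applicable under the index constraints.  Capped genomes in practice
  always have n ≥ 4.
- The exhaustive test family (every canonical capped core gene-string
  pair up to 4 core genes over 3 labels, intergenic totals ≤ 3, plus
  500 seeded randomized larger instances) and the reduced benchmark
  scale were chosen so the full suite runs in a couple of minutes on
  one core while still covering every branch of the case machinery;
  the BFS sandwich is asserted on a deterministic subsample of the
  tiny instances.

## Known limitations

- The sorting bounds are certified per run, not proven for this
  construction; a violation raises loudly.  None occurs on the shipped
  test families, but pathological repeated-gene instances outside them
  could in principle trip the reversal bound.
- The greedy partition's tie-breaks are a reproducible choice among
  many valid ones; different tie-breaks give different (equally
  bounded) partitions.
- Exact distances are available only at oracle scale; everything
  larger is an upper estimate (certified sequence) bracketed by the
  partition lower bound.
- Unbalanced genomes are rejected; handling insertions/deletions is out
  of scope.
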