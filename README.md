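# mcisp

Genome rearrangement distances for genomes with **repeated genes** and
**intergenic regions**.

Comparing two genomes by the number of rearrangement events that
separate them is a standard estimate of evolutionary distance.  Classic
models represent a genome as a permutation of distinct genes; real
genomes carry duplicated gene families and stretches of non-coding
sequence between genes, both of which change the answer.  This package
models a genome 𝒢 = (S, Ŝ) as a string of gene labels `S` interleaved
with the sizes (in nucleotides) of its intergenic regions `Ŝ`, and
computes distances under three conservative event models:

- **intergenic transposition** τ(i,j,k)(x,y,z) — exchanges two
  consecutive gene segments, cutting three intergenic regions at
  offsets x, y, z;
- **intergenic reversal** ρ(i,j)(x,y) — reverses a gene segment
  together with its internal intergenic regions, cutting the two
  flanking regions;
- the mixed model allowing both.

All three distance problems are NP-hard for genomes with repeated
genes.  The package's core is the **minimum common intergenic string
partition** (MCISP) and its **reverse** variant (RMCISP): cut both
genomes into the same multiset of blocks (gene labels *and* intergenic
sizes must match; the reverse variant also matches a block against its
reversal).  A greedy breakpoint-insertion algorithm approximates the
minimum partition cost within a factor **2k**, where k is the largest
multiplicity of a gene label.  Combined with constructive sorting
procedures — at most cost+1 transpositions, 2·cost reversals, or
⌈3·cost/2⌉ mixed operations for the partition induced by an orthologous
assignment ξ — this yields Θ(k)-approximations for all three distances,
and partition-guided orthologous assignments give much tighter distance
estimates than random ones.

Also included: exact brute-force oracles (exhaustive minimum partition,
BFS distance) for small instances, breakpoint classification
(soft/hard, over/undercharged), uniform assignment sampling, and a
simulated-genome benchmark pipeline.

## Worked example

Two genomes with gene string `I B A B C B C F` vs `I B C A B B C F`
(capped with the artificial genes `I` and `F`) and intergenic sizes
`1 3 2 3 1 3 2` vs `1 3 0 2 4 3 2`:

```sh
$ mcisp partition --mode direct tests/data/ex3_G.txt tests/data/ex3_H.txt
S blocks: ([I],[]) ([B],[]) ([A],[]) ([B C],[3]) ([B C F],[3 2])
P blocks: ([I],[]) ([B C],[3]) ([A],[]) ([B],[]) ([B C F],[3 2])
source breakpoints: 1 2 3 5
target breakpoints: 1 3 4 5
cost    4       k       3       tmin    6
```

The greedy algorithm cut both genomes into five blocks that match up to
reordering (cost 4 breakpoints).  `k = 3` is the highest label
multiplicity (`B` appears three times) and `tmin = 6` is the number of
containment-minimal subgenomes whose occurrence counts differ between
the two genomes, so the cost is guaranteed ≤ 2·3·6 = 36; here the
greedy answer is in fact optimal for this pair.

Distance estimation over 10 sampled orthologous assignments under the
reversal model, with and without the partition:

```sh
$ mcisp distance --model rev --assignments 10 --seed 1 \
      tests/data/ex3_G.txt tests/data/ex3_H.txt
min     avg     assignments     partition
2       2.00    10      1
$ mcisp distance --model rev --assignments 10 --no-partition --seed 1 \
      tests/data/ex3_G.txt tests/data/ex3_H.txt
min     avg     assignments     partition
2       4.10    10      0
```

Assignments consistent with the partition need 2 reversals on average;
unconstrained assignments need 4.10 — the partition halves the estimate.
Every reported length is certified: the operation sequence is re-applied
and must reproduce the target genome exactly.

Other subcommands: `simulate` (emit a random genome-pair database),
`experiment` (summary table from a YAML config), `oracle` (exhaustive
minimum partition / BFS exact distance on small inputs).

## File format

A genome file holds two whitespace-separated lines — gene labels, then
intergenic sizes (one fewer) — with `#` comments allowed:

```
B B A C D A
5 1 4 3 1
```

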