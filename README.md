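# msaforge

A unified framework for **progressive multiple sequence alignment (MSA)**
of proteins, built to compare alignment *techniques* rather than tools.
It is aimed at researchers who want to know, on a level playing field,
what similarity scoring, guide-tree clustering, consistency
transformation, and iterative refinement each contribute to alignment
quality — and at anyone who needs a transparent, fully tested
progressive aligner whose every stage can be swapped out.

## The model

Progressive alignment runs in stages:

1. **Similarity scoring** — every pair of the *n* sequences gets a score
   *M<sub>i,j</sub>* ∈ [0, 100] in a triangular similarity matrix.  Five
   techniques are provided: **F**ULL (identity of the optimal global
   affine-gap alignment), **Q**UICK (shared tuples), **L**CS (longest
   common subsequence over the shorter length), **K**MERS (shared k-mer
   count over the shorter length), and **P**ROBA (pair-HMM
   maximum-expected-accuracy score from posterior residue-match
   probabilities).
2. **Guide tree** — the matrix is clustered into a rooted binary tree by
   UPGMA-style average linkage, the single-linkage variants SLMIN/SLMAX,
   or Neighbor-Joining on d = (100 − M)/100.
3. **Consistency transformation** (optional) — a constraint library of
   weighted residue pairs, built from pair-HMM posteriors, is extended by
   the triplet rule W′(i<sub>x</sub>, j<sub>y</sub>) = W + Σ<sub>z,k</sub>
   min(W(i<sub>x</sub>, z<sub>k</sub>), W(z<sub>k</sub>, j<sub>y</sub>))
   and added to the profile match scores as anchor points.
4. **Profile alignment** — the tree is traversed bottom-up, aligning
   child profiles by a global affine-gap dynamic program with tree-based
   sequence weights and position-specific gap penalties ("once a gap,
   always a gap").
5. **Iterative refinement** (optional) — tree-restricted partitioning:
   cut an edge, strip all-gap columns, realign the two sides, and accept
   only strict improvements of the weighted sum-of-pairs objective

   WSP(A) = Σ<sub>l≤L</sub> Σ<sub>i&lt;j</sub> w<sub>i,j</sub> ·
   S(a<sub>i,l</sub>, a<sub>j,l</sub>),

   with w<sub>i,j</sub> = 1 recovering plain SP; up to 100 sweeps.

Five scorers × four tree builders give **20 variations**; each variation
runs under four heuristic classes — **P** (progressive only), **C**
(consistency), **I** (iterative), **CI** (both) — for **80 strategies**.
Strategies sharing a variation reuse the similarity matrix, guide tree
and posterior computations through a content-addressed cache.

Alignment quality is measured by the **Developer Score** (fraction of
reference residue pairs recovered, counting only reference columns with
< 20 % gaps), and instances are banded by reference **identity** (mean
pairwise matched-residue fraction over non-gap-only columns: < 20 %,
20–40 %, 40–80 %).  Strategy classes are compared per band with paired
one-sided **Wilcoxon signed-rank tests** (exact distribution up to
n = 25, tie-corrected normal approximation above) plus tied-best /
unique-best class frequencies.

## Worked example

```bash
python examples/01_align_with_strategies.py
```

```
family of 6 sequences, reference identity 42.0%

F.UPGMA+P   developer score 0.628   WSP    2121.4
F.UPGMA+C   developer score 0.744   WSP    2143.6
F.UPGMA+I   developer score 0.646   WSP    2546.2
F.UPGMA+CI  developer score 0.754   WSP    2318.9
```

A synthetic six-sequence family is evolved with tracked homology, so its
true alignment is known.  At 42 % identity the consistency-based classes
(C, CI) recover clearly more of the reference (DS 0.74–0.75 vs 0.63–0.65),
while refinement raises WSP (2546 vs 2121 for I vs P) without necessarily
raising accuracy — the two observations that motivate comparing classes
statistically instead of trusting any single objective.

The other scripts in `examples/` walk through the similarity scorers and
tree builders, the constraint library, refinement repairing a misplaced
gap, and the benchmark/statistics harness.  The same capabilities are
available from the shell via the `msaforge` CLI (`align`, `sweep`,
`score`, `bench`, `compare`, `fixtures`).

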