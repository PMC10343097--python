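# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind msaforge, in the spirit of a methods appendix.

## Data model and conventions

Sequences are protein strings over the 20 standard residues plus `X`;
readers map non-standard codes (B, Z, J, U, O, …) to `X` by default and
reject them in strict mode, because curated benchmark files routinely
contain them.  The gap symbol is `-` internally; `.` and `~` dialects are
normalised on input.  Positions and columns are 0-based in the API and
1-based in user-facing reports.  BLOSUM matrices come from Biopython's
distributed set and are symmetrised over the extended alphabet with an
all-zero gap row appended for scoring convenience.

## Stage 1 — similarity techniques

All five scorers return values on a common 0–100 scale and are symmetric,
so later stages are method-agnostic.

* **FULL.** Identity percentage of the optimal global affine-gap
  alignment (Gotoh three-state DP; a fresh gap of length g costs
  `gap_open + g·gap_extend`, defaults 10 / 0.5 for scoring).  Identity is
  counted over columns where neither sequence is gapped — the denominator
  choice is documented and pinned by tests, since "identity of the
  alignment" is ambiguous.  The DP is full-matrix (quadratic space);
  at the family sizes targeted here the linear-space formulation would
  change memory use only, never scores.
* **QUICK.** Distinct k-tuples shared by the two sequences divided by
  `min(len) − k + 1`, with k = 1 by default (the classic fast protein
  heuristic).  Window/diagonal refinements of the original heuristic are
  deliberately omitted.
* **LCS.** Longest-common-subsequence length over `min(len)`, computed
  with two rolling rows (linear space), verified against the quadratic DP.
* **KMERS.** Shared k-mer count — Σ over distinct k-mers of the smaller
  occurrence count — divided by `min(len)`, k = 3 by default.  Note the
  denominator is the sequence length, so identical sequences top out at
  `(L − k + 1)/L`, not 100; this follows the k-mer fraction definition
  used by fast iterative aligners.
* **PROBA.** A three-state pair-HMM (match + two inserts, no
  insert-to-insert transitions, no explicit end state by default)
  produces posterior residue-match probabilities by forward–backward;
  the score is 100 × (maximum-expected-accuracy alignment value) /
  `min(len)`.  Default emissions invert BLOSUM62's half-bit log-odds
  against the published BLOSUM62 background (p_ij ∝ q_i q_j 2^(s_ij/2),
  renormalised); `X` emits as an average residue.  Gap open δ = 0.02 and
  extend ε = 0.4 are typical protein values; all parameters are
  overridable.  Forward–backward runs in probability space with per-row
  rescaling, which is exact to machine precision and immune to underflow;
  posteriors are assembled in log space from the row scales.

## Stage 2 — guide trees

The average-linkage builder follows the scheme in which the score between
a merged cluster and any other is the plain average of the two replaced
scores (WPGMA); a size-weighted flag gives textbook UPGMA.  SLMIN/SLMAX
are the single-linkage variants; note the naming is inverted relative to
similarity intuition (SLMAX propagates the minimum of the two removed
scores, SLMIN the maximum) and is kept as conventionally printed rather
than "fixed".  Heights are mapped from similarity by h = (100 − s)/200 so
branch lengths live on the d = (100 − M)/100 distance scale; negative
increments from non-monotone linkage are clamped to zero.

Neighbor-Joining uses the standard Q-criterion on d = (100 − M)/100 and
is rooted at the midpoint of the final join, because progressive
alignment needs a root.  Negative limb lengths are clamped to zero.  For
three taxa the Q-criterion is a mathematical three-way tie; whichever
pair joins first, the resulting rooted tree reproduces all pairwise
distances (tested).  Ties everywhere are broken toward the
lexicographically smallest (cluster label, cluster label) pair, making
every builder deterministic.

## Stage 3 — consistency

The primary constraint library is filled from pair-HMM posteriors
regardless of the Stage-1 technique (posteriors are cached and shared
with PROBA scoring); entries below ε = 0.01 are dropped to keep it
sparse.  An alignment-sourced mode (residue pairs of the pairwise global
alignment, weighted by that alignment's identity) is available for
speed.  One round of triplet extension is applied — the default of the
consistency tools this mirrors; original entries are retained and the
transform is monotone by construction.  During profile alignment,
library weights are rescaled so the maximum weight equals the maximum
substitution score (λ = "auto"), keeping bonuses commensurate with gap
penalties; λ = 0 switches consistency off exactly, which is the basis of
the class-degeneracy tests.

## Stage 4 — profile alignment

Sequence weights follow the tree-based scheme: each leaf sums, along its
root path, branch length divided by the number of leaves below the
branch, normalised to mean 1 (all-zero trees fall back to unit weights).
The profile–profile match score of two columns is the weight-normalised
average substitution score over member residue pairs (gap symbols score
zero), plus the per-member-pair mean of library bonuses when a library is
given.

Gap penalties are affine (defaults 10 / 0.2) with two position-specific
rules: (a) the opening charge drops inside and near existing gap columns
— at a gap column the multiplier is `0.3 × (1 − gap fraction)` floored at
0.05, relaxing linearly back to 1 over a 4-column window — so new gaps
coalesce with old ones; (b) terminal gaps pay no opening charge (flag
on by default).  Hydrophilic-stretch and residue-specific modifiers of
the classical implementation are intentionally not modelled.  Delayed
alignment (reordering low-similarity sequences to the end) is likewise
not implemented: merge order is exactly the guide tree's, so earlier
stages' effects stay identifiable.  DP ties prefer match, then the gap
in the second profile, then the first, making outputs byte-deterministic.
The optional adaptive matrix ladder selects BLOSUM80/62/50/45 at mean
cross-profile similarity thresholds 60/40/20 (the distributed BLOSUM
series; fixed BLOSUM62 is the default).

## Stage 5 — iterative refinement

WSP sums substitution scores over columns and sequence pairs; pairs
involving a gap contribute zero (the objective has no affine term).
Pair weights default to products of the Stage-4 sequence weights
normalised to mean 1; an SP mode sets them to 1.  One iteration is a
full sweep over guide-tree edges, deepest first; each step bipartitions
the rows by the cut edge, strips all-gap columns per side, realigns the
two profiles with the Stage-4 engine (including the library for CI), and
accepts only a strictly higher WSP than the best alignment so far
(global-best semantics; strictness guarantees termination).  The sweep
cap is 100.  Improving WSP can worsen the Developer Score; the harness
records both and never asserts otherwise.

## Evaluation and statistics

Developer Score: reference residue pairs are collected from columns
whose gap fraction is strictly below 0.2 (read as "fewer than 20 % gaps"
per column); a pair matches when the same two residues — identified by
sequence id and residue ordinal, never by column index — share a column
in the test alignment.  The denominator is qualifying pairs, not
columns.  Identity bands are half-open ([20, 40), [40, 80)); values ≥ 80
are tagged "high" and excluded from banded comparisons.

The Wilcoxon signed-rank test drops zero differences by default (a Pratt
mode keeps them for ranking).  For effective n ≤ 25 the exact conditional
distribution of the positive-rank sum is built by convolution over
doubled ranks, which remains exact under tied (mid-)ranks; above that, a
normal approximation with tie correction (Var = Σr²/4) and a 0.5
continuity correction is used.  All-zero differences give p = 1 by
convention.  Developer-score ties are compared exactly (they are ratios
of small integers), with no epsilon.

## Synthetic families

The generator evolves a root sequence (length 100 by default) down a
random binary topology with unit branches: per-branch substitution
probability per site (drawn from the BLOSUM62 background, resampled until
different), geometric indels (mean length 2, insertion and deletion
probability 0.02 per position per branch).  Homology is tracked exactly
— inserted residues get fresh site ids, deletions leave gaps only in
descendants — so the true alignment is known by construction and de-gaps
to the leaf sequences.  Band suites rejection-sample the per-branch
substitution probability (windows 0.28–0.50, 0.14–0.30, 0.04–0.15 for
bands 1–3) until the reference identity lands in the requested band.

What the generator does *not* emulate: rate heterogeneity across sites,
conserved motifs or domain architecture, long terminal extensions, and
realistic indel hotspots.  Passing the recovery tests therefore shows the
machinery is correct and well-behaved on families of controlled
divergence; it does not by itself certify accuracy on curated structural
benchmarks, which remain external inputs the benchmark runner can consume
(instance directories of unaligned FASTA + reference alignment).

## Problem sizes and determinism

Default test and acceptance runs use families of 4–6 sequences with root
length 30–100 and 8–10 instances per suite — large enough for every code
path (indels, bands, all 80 strategies' plumbing) while keeping the whole
suite in the minutes range.  A single seed drives all randomness
(fixtures only; the aligner is deterministic), and repeated runs are
byte-identical, which the tests assert.

## Known limitations

* The pairwise and profile DPs are quadratic time and space; very long
  sequences (≫ 1 kb) will be slow in pure Python/NumPy.
* The pair-HMM is a single global model; no local or repeat modes.
* Consistency uses one extension round and a single evidence source
  (posteriors or pairwise alignments), not mixed libraries.
* Guide trees are never re-estimated from an intermediate alignment
  (no second pass).
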